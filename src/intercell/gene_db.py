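"""Gene-coded protein annotation database.

Each gene carries three layers of annotation used to decide whether its
product can plausibly take part in cell-cell communication:

* subcellular localization, drawn from a closed 13-category vocabulary with
  an integer confidence on a 1-5 scale (a protein may appear in several
  compartments, each with its own confidence);
* a functional taxonomy of 132 fine-grained classes partitioned into 16
  coarse groups (cytokine, receptor, enzyme, ...);
* Gene Ontology term memberships.

The query surface is :func:`select_genes`, which applies localization,
function and GO constraints conjunctively across the three layers and
disjunctively within each layer.
"""

from __future__ import annotations

import gzip
import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import SchemaError, ValidationError

#: Closed vocabulary of subcellular localization categories.
LOCALIZATION_CATEGORIES: tuple[str, ...] = (
    "extracellular region",
    "plasma membrane",
    "cytosol",
    "cytoskeleton",
    "peroxisome",
    "lysosome",
    "endoplasmic reticulum",
    "Golgi apparatus",
    "endosome",
    "mitochondrion",
    "cytoplasm",
    "nucleus",
    "other",
)

#: Localization confidence bounds (inclusive).
MIN_CONFIDENCE, MAX_CONFIDENCE = 1, 5

#: Recommended minimum localization confidence: keep annotations scored 4-5.
DEFAULT_MIN_CONFIDENCE = 4

SPECIES = ("human", "mouse")

_GENE_TABLE_COLUMNS = (
    "symbol",
    "species",
    "loc_category",
    "loc_confidence",
    "function_class",
    "go_terms",
)


def _load_taxonomy() -> pd.DataFrame:
    ref = importlib.resources.files("intercell.data").joinpath(
        "function_classes.tsv"
    )
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t")


@dataclass(frozen=True)
class FunctionTaxonomy:
    """Closed functional taxonomy: fine classes partitioned into groups.

    Every class maps to exactly one group; the bundled default has 132
    classes in 16 groups.
    """

    class_to_group: Mapping[str, str]

    @classmethod
    def default(cls) -> "FunctionTaxonomy":
        df = _load_taxonomy()
        return cls(dict(zip(df["function_class"], df["function_group"])))

    @property
    def classes(self) -> frozenset[str]:
        return frozenset(self.class_to_group)

    @property
    def groups(self) -> frozenset[str]:
        return frozenset(self.class_to_group.values())

    def group_of(self, klass: str) -> str:
        return self.class_to_group[klass]


@dataclass(frozen=True)
class LocalizationAnnotation:
    """One compartment assignment with its 1-5 confidence."""

    category: str
    confidence: int

    def __post_init__(self) -> None:
        if self.category not in LOCALIZATION_CATEGORIES:
            raise ValidationError(
                f"unknown localization category {self.category!r}; "
                f"expected one of {sorted(LOCALIZATION_CATEGORIES)}"
            )
        if not (MIN_CONFIDENCE <= int(self.confidence) <= MAX_CONFIDENCE):
            raise ValidationError(
                f"localization confidence {self.confidence!r} outside "
                f"[{MIN_CONFIDENCE}, {MAX_CONFIDENCE}]"
            )


@dataclass
class GeneRecord:
    symbol: str
    species: str
    localizations: list[LocalizationAnnotation] = field(default_factory=list)
    function_classes: set[str] = field(default_factory=set)
    go_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValidationError("gene symbol must be nonempty")
        if self.species not in SPECIES:
            raise ValidationError(
                f"species {self.species!r} not in {SPECIES}"
            )
        seen = [loc.category for loc in self.localizations]
        if len(seen) != len(set(seen)):
            raise ValidationError(
                f"gene {self.symbol}: duplicate localization category"
            )

    def localization_confidence(self, category: str) -> int | None:
        for loc in self.localizations:
            if loc.category == category:
                return loc.confidence
        return None


def normalize_symbol(symbol: str, species: str) -> str:
    """Normalize gene-symbol casing per species convention.

    Human symbols are upper-cased (IL6), mouse symbols are capitalized
    (Il6).  Matching across inputs (DEG tables vs databases) is done on
    the normalized form.
    """
    s = symbol.strip()
    if species == "mouse":
        return s[:1].upper() + s[1:].lower()
    return s.upper()


@dataclass(frozen=True)
class GeneSelectionSpec:
    """Constraints for :func:`select_genes`; ``None`` fields are inactive.

    Constraints combine conjunctively across the three annotation layers
    (localization AND function AND GO) and disjunctively within one layer
    (any listed category / class / group / term suffices).
    """

    localization_categories: frozenset[str] | None = None
    min_confidence: int = DEFAULT_MIN_CONFIDENCE
    function_groups: frozenset[str] | None = None
    function_classes: frozenset[str] | None = None
    go_terms: frozenset[str] | None = None

    @classmethod
    def make(
        cls,
        localization_categories: Iterable[str] | None = None,
        min_confidence: int = DEFAULT_MIN_CONFIDENCE,
        function_groups: Iterable[str] | None = None,
        function_classes: Iterable[str] | None = None,
        go_terms: Iterable[str] | None = None,
    ) -> "GeneSelectionSpec":
        fs = lambda x: None if x is None else frozenset(x)
        return cls(
            localization_categories=fs(localization_categories),
            min_confidence=min_confidence,
            function_groups=fs(function_groups),
            function_classes=fs(function_classes),
            go_terms=fs(go_terms),
        )


class GeneDatabase:
    """Indexed collection of :class:`GeneRecord`, one species per database."""

    def __init__(
        self,
        records: Iterable[GeneRecord],
        species: str,
        taxonomy: FunctionTaxonomy | None = None,
    ) -> None:
        self.species = species
        self.taxonomy = taxonomy or FunctionTaxonomy.default()
        self._records: dict[str, GeneRecord] = {}
        for rec in records:
            if rec.species != species:
                raise ValidationError(
                    f"record {rec.symbol}: species {rec.species!r} does not "
                    f"match database species {species!r}"
                )
            if rec.symbol in self._records:
                raise ValidationError(f"duplicate gene symbol {rec.symbol!r}")
            self._records[rec.symbol] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._records

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._records.values())

    def get(self, symbol: str) -> GeneRecord | None:
        return self._records.get(symbol)

    @property
    def symbols(self) -> set[str]:
        return set(self._records)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "r")


def load_gene_db(
    path,
    species: str,
    taxonomy: FunctionTaxonomy | None = None,
) -> GeneDatabase:
    """Read a gene annotation table (TSV, optionally gzipped).

    One row per (symbol, localization category, function class) combination;
    duplicate (symbol, category) localization rows collapse to the maximum
    confidence.  Rows with categories or classes outside the closed
    vocabularies are rejected with the offending row number.
    """
    if species not in SPECIES:
        raise ValidationError(f"species {species!r} not in {SPECIES}")
    taxonomy = taxonomy or FunctionTaxonomy.default()
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"gene table {path}: missing mandatory column(s) {missing}"
        )

    # accumulators keyed by normalized symbol
    locs: dict[str, dict[str, int]] = {}
    classes: dict[str, set[str]] = {}
    gos: dict[str, set[str]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.species != species:
            continue
        sym = normalize_symbol(row.symbol, species)
        if not sym:
            raise ValidationError(f"gene table row {i}: empty symbol")
        cat = row.loc_category
        if cat:
            if cat not in LOCALIZATION_CATEGORIES:
                raise ValidationError(
                    f"gene table row {i}: unknown localization category "
                    f"{cat!r}"
                )
            try:
                conf = int(row.loc_confidence)
            except ValueError:
                raise ValidationError(
                    f"gene table row {i}: non-integer confidence "
                    f"{row.loc_confidence!r}"
                ) from None
            if not (MIN_CONFIDENCE <= conf <= MAX_CONFIDENCE):
                raise ValidationError(
                    f"gene table row {i}: confidence {conf} outside "
                    f"[{MIN_CONFIDENCE}, {MAX_CONFIDENCE}]"
                )
            d = locs.setdefault(sym, {})
            d[cat] = max(d.get(cat, 0), conf)
        else:
            locs.setdefault(sym, {})
        klass = row.function_class
        if klass:
            if klass not in taxonomy.classes:
                raise ValidationError(
                    f"gene table row {i}: unknown function class {klass!r}"
                )
            classes.setdefault(sym, set()).add(klass)
        else:
            classes.setdefault(sym, set())
        terms = {t for t in str(row.go_terms).split(";") if t}
        gos.setdefault(sym, set()).update(terms)

    records = [
        GeneRecord(
            symbol=sym,
            species=species,
            localizations=[
                LocalizationAnnotation(cat, conf)
                for cat, conf in sorted(locs[sym].items())
            ],
            function_classes=classes[sym],
            go_terms=gos[sym],
        )
        for sym in locs
    ]
    return GeneDatabase(records, species=species, taxonomy=taxonomy)


def save_gene_db(db: GeneDatabase, path) -> None:
    """Serialize a database back to the annotation-table format."""
    rows = []
    for rec in sorted(db, key=lambda r: r.symbol):
        go = ";".join(sorted(rec.go_terms))
        loc_pairs = [(l.category, l.confidence) for l in rec.localizations] or [
            ("", "")
        ]
        klasses = sorted(rec.function_classes) or [""]
        for cat, conf in loc_pairs:
            for klass in klasses:
                rows.append((rec.symbol, rec.species, cat, conf, klass, go))
    pd.DataFrame(rows, columns=_GENE_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def select_genes(db: GeneDatabase, spec: GeneSelectionSpec) -> set[str]:
    """Return symbols satisfying every active constraint of *spec*.

    An empty spec selects the whole database.  Unknown categories or group
    names in the spec raise :class:`ValidationError` rather than silently
    selecting nothing.
    """
    if spec.localization_categories is not None:
        bad = spec.localization_categories - set(LOCALIZATION_CATEGORIES)
        if bad:
            raise ValidationError(
                f"unknown localization categories in spec: {sorted(bad)}"
            )
    if spec.function_groups is not None:
        bad = spec.function_groups - db.taxonomy.groups
        if bad:
            raise ValidationError(
                f"unknown function groups in spec: {sorted(bad)}"
            )
    if spec.function_classes is not None:
        bad = spec.function_classes - db.taxonomy.classes
        if bad:
            raise ValidationError(
                f"unknown function classes in spec: {sorted(bad)}"
            )

    selected: set[str] = set()
    for rec in db:
        if spec.localization_categories is not None:
            ok = any(
                loc.category in spec.localization_categories
                and loc.confidence >= spec.min_confidence
                for loc in rec.localizations
            )
            if not ok:
                continue
        if spec.function_groups is not None or spec.function_classes is not None:
            ok = False
            for klass in rec.function_classes:
                if spec.function_classes is not None and klass in spec.function_classes:
                    ok = True
                    break
                if (
                    spec.function_groups is not None
                    and db.taxonomy.group_of(klass) in spec.function_groups
                ):
                    ok = True
                    break
            if not ok:
                continue
        if spec.go_terms is not None:
            if not (rec.go_terms & spec.go_terms):
                continue
        selected.add(rec.symbol)
    return selected
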