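"""Protein-protein interaction database with evidence provenance.

Interactions are stored per unordered gene pair.  Each record carries

* per-channel evidence scores (experimental assays, curated pathways, and
  the predicted channels: neighborhood, fusion, co-occurrence, homology,
  co-expression, text mining, plus their transferred variants);
* a combined credibility score on 1-1000, binned into four confidence
  levels at the conventional cutoffs 400 / 700 / 900;
* action records describing the functional interplay (mode) and the
  direction of expression influence (effect).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import pandas as pd

from .errors import SchemaError, ValidationError

#: The 8 action modes (functional interplay between the two proteins).
ACTION_MODES: tuple[str, ...] = (
    "activation",
    "binding",
    "catalysis",
    "expression",
    "inhibition",
    "ptmod",
    "reaction",
    "other",
)

#: The 4 action effects (direction of expression influence).
ACTION_EFFECTS: tuple[str, ...] = (
    "positive",
    "negative",
    "unspecified",
    "undirected",
)

#: Evidence channels.  ``experiments`` drives the experiment-validated flag,
#: ``database`` the pathway-curated flag; every other channel (including the
#: transferred variants of the first two) counts as predicted evidence.
EVIDENCE_CHANNELS: tuple[str, ...] = (
    "experiments",
    "experiments_transferred",
    "database",
    "database_transferred",
    "neighborhood",
    "neighborhood_transferred",
    "fusion",
    "cooccurence",
    "homology",
    "coexpression",
    "coexpression_transferred",
    "textmining",
    "textmining_transferred",
)

EVIDENCE_CLASSES: tuple[str, ...] = (
    "experiment_validated",
    "pathway_curated",
    "predicted",
)

#: Credibility bin edges: level -> minimum credibility.
CONFIDENCE_LEVELS: tuple[str, ...] = ("highest", "high", "medium", "low")
_LEVEL_MIN = {"highest": 900, "high": 700, "medium": 400, "low": 1}

MIN_CREDIBILITY, MAX_CREDIBILITY = 1, 1000


def confidence_level(credibility: int) -> str:
    """Bin a 1-1000 credibility score into its confidence level.

    The bins partition the scale: highest >= 900 > high >= 700 > medium
    >= 400 > low.
    """
    if not (MIN_CREDIBILITY <= credibility <= MAX_CREDIBILITY):
        raise ValidationError(
            f"credibility {credibility!r} outside "
            f"[{MIN_CREDIBILITY}, {MAX_CREDIBILITY}]"
        )
    if credibility >= 900:
        return "highest"
    if credibility >= 700:
        return "high"
    if credibility >= 400:
        return "medium"
    return "low"


@dataclass(frozen=True)
class ActionRecord:
    mode: str
    effect: str = "undirected"
    is_directional: bool = False
    acting_partner: str = "unknown"  # which gene exerts the effect: a/b/unknown

    def __post_init__(self) -> None:
        if self.mode not in ACTION_MODES:
            raise ValidationError(
                f"unknown action mode {self.mode!r}; "
                f"expected one of {ACTION_MODES}"
            )
        if self.effect not in ACTION_EFFECTS:
            raise ValidationError(
                f"unknown action effect {self.effect!r}; "
                f"expected one of {ACTION_EFFECTS}"
            )
        if self.acting_partner not in ("a", "b", "unknown"):
            raise ValidationError(
                f"acting_partner must be 'a', 'b' or 'unknown', "
                f"got {self.acting_partner!r}"
            )
        if self.effect == "undirected" and self.is_directional:
            raise ValidationError(
                "an undirected action cannot be directional"
            )


def _evidence_flags(channel_scores: dict[str, int]) -> frozenset[str]:
    flags = set()
    if channel_scores.get("experiments", 0) > 0:
        flags.add("experiment_validated")
    if channel_scores.get("database", 0) > 0:
        flags.add("pathway_curated")
    if any(
        v > 0
        for k, v in channel_scores.items()
        if k not in ("experiments", "database")
    ):
        flags.add("predicted")
    return frozenset(flags)


@dataclass(frozen=True)
class InteractionRecord:
    """One unordered gene pair with evidence and action annotations."""

    gene_a: str
    gene_b: str
    channel_scores: tuple[tuple[str, int], ...]
    credibility: int
    actions: tuple[ActionRecord, ...] = ()

    def __post_init__(self) -> None:
        for ch, v in self.channel_scores:
            if ch not in EVIDENCE_CHANNELS:
                raise ValidationError(f"unknown evidence channel {ch!r}")
            if v < 0:
                raise ValidationError(
                    f"negative evidence score {v} on channel {ch!r}"
                )
        confidence_level(self.credibility)  # validates range

    @classmethod
    def make(
        cls,
        gene_a: str,
        gene_b: str,
        channel_scores: dict[str, int] | None = None,
        credibility: int = 1,
        actions: Iterable[ActionRecord] = (),
    ) -> "InteractionRecord":
        scores = {k: int(v) for k, v in (channel_scores or {}).items() if v}
        return cls(
            gene_a=gene_a,
            gene_b=gene_b,
            channel_scores=tuple(sorted(scores.items())),
            credibility=int(credibility),
            actions=tuple(actions),
        )

    @property
    def scores(self) -> dict[str, int]:
        return dict(self.channel_scores)

    @property
    def evidence_class_flags(self) -> frozenset[str]:
        return _evidence_flags(self.scores)

    @property
    def confidence_level(self) -> str:
        return confidence_level(self.credibility)

    @property
    def pair(self) -> tuple[str, str]:
        """Canonical (sorted) unordered pair key."""
        return tuple(sorted((self.gene_a, self.gene_b)))  # type: ignore


@dataclass(frozen=True)
class InteractionFilterSpec:
    """Constraints for :func:`subset_interactions`; ``None`` = inactive.

    ``min_level`` expresses the credibility threshold as a named confidence
    level; ``min_credibility`` as a raw score.  Both may be given; the
    stricter applies.
    """

    evidence_classes: frozenset[str] | None = None
    min_level: str | None = None
    min_credibility: int | None = None
    modes: frozenset[str] | None = None
    effects: frozenset[str] | None = None

    @classmethod
    def make(
        cls,
        evidence_classes: Iterable[str] | None = None,
        min_level: str | None = None,
        min_credibility: int | None = None,
        modes: Iterable[str] | None = None,
        effects: Iterable[str] | None = None,
    ) -> "InteractionFilterSpec":
        fs = lambda x: None if x is None else frozenset(x)
        return cls(
            evidence_classes=fs(evidence_classes),
            min_level=min_level,
            min_credibility=min_credibility,
            modes=fs(modes),
            effects=fs(effects),
        )

    def validate(self) -> None:
        if self.evidence_classes is not None:
            bad = self.evidence_classes - set(EVIDENCE_CLASSES)
            if bad:
                raise ValidationError(f"unknown evidence classes {sorted(bad)}")
            if not self.evidence_classes:
                raise ValidationError("evidence class set must not be empty")
        if self.min_level is not None and self.min_level not in _LEVEL_MIN:
            raise ValidationError(
                f"unknown confidence level {self.min_level!r}; "
                f"expected one of {CONFIDENCE_LEVELS}"
            )
        if self.modes is not None:
            bad = self.modes - set(ACTION_MODES)
            if bad:
                raise ValidationError(f"unknown action modes {sorted(bad)}")
            if not self.modes:
                raise ValidationError("mode set must not be empty")
        if self.effects is not None:
            bad = self.effects - set(ACTION_EFFECTS)
            if bad:
                raise ValidationError(f"unknown action effects {sorted(bad)}")
            if not self.effects:
                raise ValidationError("effect set must not be empty")

    @property
    def credibility_floor(self) -> int:
        floor = MIN_CREDIBILITY
        if self.min_level is not None:
            floor = max(floor, _LEVEL_MIN[self.min_level])
        if self.min_credibility is not None:
            floor = max(floor, self.min_credibility)
        return floor


class InteractionDatabase:
    """Interactions indexed by unordered gene pair."""

    def __init__(self, records: Iterable[InteractionRecord]) -> None:
        self._by_pair: dict[tuple[str, str], InteractionRecord] = {}
        for rec in records:
            key = rec.pair
            if key in self._by_pair:
                raise ValidationError(
                    f"duplicate interaction for pair {key}"
                )
            self._by_pair[key] = rec

    def __len__(self) -> int:
        return len(self._by_pair)

    def __iter__(self) -> Iterator[InteractionRecord]:
        return iter(self._by_pair.values())

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(sorted(pair)) in self._by_pair

    def get(self, gene_a: str, gene_b: str) -> InteractionRecord | None:
        return self._by_pair.get(tuple(sorted((gene_a, gene_b))))

    def partners_of(self, gene: str) -> set[str]:
        out = set()
        for a, b in self._by_pair:
            if a == gene:
                out.add(b)
            elif b == gene:
                out.add(a)
        return out

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self._by_pair)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "r")


def _parse_actions(token_field: str, row_no: int) -> tuple[ActionRecord, ...]:
    actions = []
    for tok in str(token_field).split(";"):
        tok = tok.strip()
        if not tok:
            continue
        parts = tok.split("|")
        if len(parts) != 4:
            raise ValidationError(
                f"interaction table row {row_no}: malformed action token "
                f"{tok!r} (expected mode|effect|direction|acting_partner)"
            )
        mode, effect, direction, partner = parts
        if direction not in ("directional", "nondirectional"):
            raise ValidationError(
                f"interaction table row {row_no}: direction must be "
                f"'directional' or 'nondirectional', got {direction!r}"
            )
        try:
            actions.append(
                ActionRecord(
                    mode=mode,
                    effect=effect,
                    is_directional=direction == "directional",
                    acting_partner=partner,
                )
            )
        except ValidationError as exc:
            raise ValidationError(
                f"interaction table row {row_no}: {exc}"
            ) from None
    return tuple(actions)


def load_interaction_db(path) -> InteractionDatabase:
    """Read an interaction table (TSV, optionally gzipped).

    Columns: gene_a, gene_b, one column per evidence channel (absent
    channels default to 0), credibility, actions (semicolon-joined
    ``mode|effect|direction|acting_partner`` tokens).
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene_a", "gene_b", "credibility"):
        if col not in df.columns:
            raise SchemaError(
                f"interaction table {path}: missing mandatory column {col!r}"
            )
    channel_cols = [c for c in EVIDENCE_CHANNELS if c in df.columns]
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            credibility = int(d["credibility"])
        except ValueError:
            raise ValidationError(
                f"interaction table row {i}: non-integer credibility "
                f"{d['credibility']!r}"
            ) from None
        if not (MIN_CREDIBILITY <= credibility <= MAX_CREDIBILITY):
            raise ValidationError(
                f"interaction table row {i}: credibility {credibility} "
                f"outside [{MIN_CREDIBILITY}, {MAX_CREDIBILITY}]"
            )
        scores = {}
        for ch in channel_cols:
            v = d.get(ch, "") or "0"
            try:
                scores[ch] = int(v)
            except ValueError:
                raise ValidationError(
                    f"interaction table row {i}: non-integer score {v!r} "
                    f"on channel {ch!r}"
                ) from None
        actions = _parse_actions(d.get("actions", ""), i)
        records.append(
            InteractionRecord.make(
                gene_a=d["gene_a"],
                gene_b=d["gene_b"],
                channel_scores=scores,
                credibility=credibility,
                actions=actions,
            )
        )
    return InteractionDatabase(records)


def save_interaction_db(db: InteractionDatabase, path) -> None:
    rows = []
    for rec in sorted(db, key=lambda r: r.pair):
        d = {"gene_a": rec.gene_a, "gene_b": rec.gene_b}
        scores = rec.scores
        for ch in EVIDENCE_CHANNELS:
            d[ch] = scores.get(ch, 0)
        d["credibility"] = rec.credibility
        d["actions"] = ";".join(
            f"{a.mode}|{a.effect}|"
            f"{'directional' if a.is_directional else 'nondirectional'}|"
            f"{a.acting_partner}"
            for a in rec.actions
        )
        rows.append(d)
    cols = ["gene_a", "gene_b", *EVIDENCE_CHANNELS, "credibility", "actions"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def _action_matches(
    action: ActionRecord, spec: InteractionFilterSpec
) -> bool:
    if spec.modes is not None and action.mode not in spec.modes:
        return False
    if spec.effects is not None and action.effect not in spec.effects:
        return False
    return True


def subset_interactions(
    db: InteractionDatabase, spec: InteractionFilterSpec
) -> InteractionDatabase:
    """Filter the database by evidence class, credibility and actions.

    A record survives iff its evidence flags intersect the requested
    classes, its credibility passes the threshold, and at least one of its
    action records matches both the mode and the effect constraints.
    Surviving records keep only the matching action records.  An empty spec
    returns the database unchanged (idempotent, monotone).
    """
    spec.validate()
    floor = spec.credibility_floor
    action_constrained = spec.modes is not None or spec.effects is not None
    kept = []
    for rec in db:
        if spec.evidence_classes is not None and not (
            rec.evidence_class_flags & spec.evidence_classes
        ):
            continue
        if rec.credibility < floor:
            continue
        if action_constrained:
            matching = tuple(
                a for a in rec.actions if _action_matches(a, spec)
            )
            if not matching:
                continue
            rec = replace(rec, actions=matching)
        kept.append(rec)
    return InteractionDatabase(kept)


@dataclass(frozen=True)
class MatchedInteraction:
    """An interaction record oriented for a sender -> receiver query."""

    record: InteractionRecord
    sender_gene: str
    receiver_gene: str

    @property
    def sender_is_a(self) -> bool:
        return self.record.gene_a == self.sender_gene


def match_pair(
    db: InteractionDatabase, sender_gene: str, receiver_gene: str
) -> list[MatchedInteraction]:
    """Look up the unordered pair; record which member plays the sender.

    An absent pair yields an empty list, never an error.
    """
    rec = db.get(sender_gene, receiver_gene)
    if rec is None:
        return []
    return [
        MatchedInteraction(
            record=rec, sender_gene=sender_gene, receiver_gene=receiver_gene
        )
    ]
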