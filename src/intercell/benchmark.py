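"""Database- and method-comparison metrics.

Three summary statistics compare interaction resources and inference
methods on a common footing:

* coverage ratio — the fraction of another database's gene pairs that a
  reference database also contains;
* average fetched-pair count — the mean number of pairs a method reports
  per ordered cluster pair, over all N x N combinations;
* average overlapped-pair count — the mean number of a method's pairs per
  cluster pair that at least one other method also reports.

Pairs are compared without orientation (canonically sorted within pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import ValidationError

Pair = tuple[str, str]


def canonical_pair(gene_a: str, gene_b: str) -> Pair:
    return tuple(sorted((gene_a, gene_b)))  # type: ignore[return-value]


@dataclass(frozen=True)
class PairSet:
    """A named set of unordered gene pairs, stored canonically."""

    name: str
    pairs: frozenset[Pair] = field(default_factory=frozenset)

    @classmethod
    def from_pairs(cls, name: str, pairs: Iterable[tuple[str, str]]) -> "PairSet":
        return cls(name, frozenset(canonical_pair(a, b) for a, b in pairs))

    def __len__(self) -> int:
        return len(self.pairs)


def read_pair_set(path, name: str | None = None) -> PairSet:
    """Load a 2-column TSV (gene_a, gene_b) as a PairSet."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"pair table {path}: expected two columns")
    a, b = df.columns[:2]
    return PairSet.from_pairs(
        name or str(path), zip(df[a], df[b])
    )


def write_pair_set(ps: PairSet, path) -> None:
    pd.DataFrame(
        sorted(ps.pairs), columns=["gene_a", "gene_b"]
    ).to_csv(path, sep="\t", index=False)


def coverage_ratio(reference: PairSet, other: PairSet) -> float:
    """|reference ∩ other| / |other|: how much of *other* is covered."""
    if len(other) == 0:
        raise ValidationError(
            f"coverage ratio undefined: pair set {other.name!r} is empty"
        )
    return len(reference.pairs & other.pairs) / len(other)


def average_pair_count(
    per_clusterpair_results: Mapping[tuple[str, str], PairSet],
    n_clusters: int,
) -> float:
    """Mean fetched-pair count over all N x N ordered cluster pairs.

    Cluster pairs absent from the mapping contribute zero.
    """
    if n_clusters < 1:
        raise ValidationError("n_clusters must be >= 1")
    total = sum(len(ps) for ps in per_clusterpair_results.values())
    return total / (n_clusters * n_clusters)


def average_overlap_count(
    results_by_method: Mapping[str, Mapping[tuple[str, str], PairSet]],
    focal_method: str,
    n_clusters: int,
) -> float:
    """Mean count of the focal method's pairs confirmed by >= 1 other method."""
    if n_clusters < 1:
        raise ValidationError("n_clusters must be >= 1")
    if focal_method not in results_by_method:
        raise ValidationError(
            f"focal method {focal_method!r} absent from results "
            f"(known: {sorted(results_by_method)})"
        )
    if len(results_by_method) < 2:
        raise ValidationError("overlap requires at least two methods")
    focal = results_by_method[focal_method]
    total = 0
    for key, ps in focal.items():
        others: set[Pair] = set()
        for method, results in results_by_method.items():
            if method == focal_method:
                continue
            other_ps = results.get(key)
            if other_ps is not None:
                others |= other_ps.pairs
        total += len(ps.pairs & others)
    return total / (n_clusters * n_clusters)


def comparison_report(
    reference: PairSet, others: Iterable[PairSet]
) -> pd.DataFrame:
    """Coverage of each comparison database by the reference, as a table."""
    rows = [
        (ps.name, len(ps), len(reference.pairs & ps.pairs),
         coverage_ratio(reference, ps))
        for ps in others
    ]
    return pd.DataFrame(
        rows, columns=["database", "n_pairs", "n_covered", "coverage_ratio"]
    )
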