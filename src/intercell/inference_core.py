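"""Sender -> receiver candidate-pair inference.

The strength of a candidate interaction between gene *A* expressed by a
sender cluster and gene *B* expressed by a receiver cluster is the product
of the two cluster-mean normalized expressions::

    power(A, B) = mean_expr_sender(A) * mean_expr_receiver(B)

Significance comes from a cell-label permutation test: the full cluster
label vector is shuffled (cluster sizes preserved), the power recomputed
under each shuffle, and the p-value is the fraction of permutations whose
power reaches the observed one (upper tail).  Candidate pairs are the
cross product of the DEG- and annotation-selected sender and receiver gene
sets, restricted to pairs present in the interaction database, and kept
when p < alpha.

Per ordered cluster pair, the retained pairs aggregate into a network
edge: M = pair count, W = sum of pair powers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression_input import (
    DEFAULT_MAX_ADJ_P,
    DEFAULT_MIN_ABS_LOG2FC,
    DegEntry,
    LabeledExpression,
    select_regulated,
)
from .gene_db import GeneDatabase, GeneSelectionSpec, select_genes
from .interaction_db import (
    ActionRecord,
    InteractionDatabase,
    InteractionFilterSpec,
    subset_interactions,
)

logger = logging.getLogger(__name__)

#: Default number of label permutations.
DEFAULT_N_PERM = 100

#: Default significance level for retaining candidate pairs.
DEFAULT_ALPHA = 0.05

_REL_TOL = 1e-12


def compute_power(exprs_a: float, exprs_b: float) -> float:
    """Interaction power: product of the two cluster-mean expressions."""
    if exprs_a < 0 or exprs_b < 0:
        raise ValidationError(
            f"expression means must be non-negative, got "
            f"({exprs_a}, {exprs_b})"
        )
    return float(exprs_a) * float(exprs_b)


@dataclass(frozen=True)
class CandidatePair:
    sender_cluster: str
    receiver_cluster: str
    sender_gene: str
    receiver_gene: str
    power: float
    power_fc: float
    p_value: float
    actions: tuple[ActionRecord, ...] = ()
    credibility: int | None = None
    confidence_level: str | None = None


@dataclass(frozen=True)
class NetworkSummary:
    sender_cluster: str
    receiver_cluster: str
    pair_count: int
    aggregated_power: float


@dataclass(frozen=True)
class ClusterGeneSpec:
    """Gene selection for one side of a cluster pair.

    Combines the DEG filter (direction / fold change / adjusted p) with
    annotation constraints (localization, function, GO).
    """

    selection: GeneSelectionSpec = field(default_factory=GeneSelectionSpec)
    direction: str = "up"
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC
    max_adj_p: float = DEFAULT_MAX_ADJ_P


def _sorted_candidates(pairs: Iterable[CandidatePair]) -> list[CandidatePair]:
    # deterministic ranking: power desc, p asc, then lexicographic
    return sorted(
        pairs,
        key=lambda c: (
            -c.power,
            c.p_value,
            c.sender_cluster,
            c.receiver_cluster,
            c.sender_gene,
            c.receiver_gene,
        ),
    )


# ---------------------------------------------------------------------------
# permutation machinery


def _cluster_means(
    rows: np.ndarray, codes: np.ndarray, n_clusters: int
) -> np.ndarray:
    """Mean of each row within each label group -> (n_clusters, n_rows)."""
    counts = np.bincount(codes, minlength=n_clusters)
    if (counts == 0).any():
        raise ValidationError("every cluster must contain at least one cell")
    sums = np.zeros((n_clusters, rows.shape[0]))
    np.add.at(sums, codes, rows.T)
    return sums / counts[:, None]


def permuted_cluster_means(
    rows: np.ndarray,
    codes: np.ndarray,
    n_clusters: int,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cluster means of each row under ``n_perm`` global label shuffles.

    Returns an array of shape (n_perm, n_clusters, n_rows).  The whole
    label vector is permuted, so cluster sizes are preserved exactly.
    """
    n = codes.size
    out = np.empty((n_perm, n_clusters, rows.shape[0]))
    for p in range(n_perm):
        shuffled = codes[rng.permutation(n)]
        out[p] = _cluster_means(rows, shuffled, n_clusters)
    return out


def _iter_label_arrangements(codes: np.ndarray):
    """All distinct arrangements of the label multiset (lexicographic)."""

    def rec(counts: np.ndarray, prefix: list[int], n_left: int):
        if n_left == 0:
            yield np.array(prefix, dtype=np.intp)
            return
        for c in range(counts.size):
            if counts[c]:
                counts[c] -= 1
                prefix.append(c)
                yield from rec(counts, prefix, n_left - 1)
                prefix.pop()
                counts[c] += 1

    counts = np.bincount(codes)
    yield from rec(counts.copy(), [], codes.size)


def _resolve_pair_context(
    x: LabeledExpression,
    sender_cluster: str,
    receiver_cluster: str,
    genes: Sequence[str],
):
    codes, cats = x.label_codes()
    for cl in (sender_cluster, receiver_cluster):
        if cl not in cats:
            raise ValidationError(f"cluster {cl!r} not present in labels")
    rows = np.vstack([x.gene_row(g) for g in genes])
    return rows, codes, cats


def permutation_pvalue(
    x: LabeledExpression,
    sender_cluster: str,
    receiver_cluster: str,
    gene_a: str,
    gene_b: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    tail: str = "upper",
    conservative_p: bool = False,
) -> float:
    """Monte-Carlo label-permutation p-value for one gene pair.

    ``tail='upper'`` counts permutations whose power reaches the observed
    power (strong pairs get small p); ``tail='lower'`` counts permutations
    at or below it.  With ``conservative_p`` the estimate is
    (1 + hits) / (1 + N), which cannot be exactly zero.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if tail not in ("upper", "lower"):
        raise ValidationError(f"tail must be 'upper' or 'lower', got {tail!r}")
    rows, codes, cats = _resolve_pair_context(
        x, sender_cluster, receiver_cluster, [gene_a, gene_b]
    )
    si, ri = cats.index(sender_cluster), cats.index(receiver_cluster)
    obs_means = _cluster_means(rows, codes, len(cats))
    observed = compute_power(obs_means[si, 0], obs_means[ri, 1])
    rng = np.random.default_rng(seed)
    null_means = permuted_cluster_means(rows, codes, len(cats), n_perm, rng)
    null = null_means[:, si, 0] * null_means[:, ri, 1]
    hits = _tail_hits(null, observed, tail)
    if conservative_p:
        return float((1 + hits) / (1 + n_perm))
    return float(min(1.0, hits / n_perm))


def _tail_hits(null: np.ndarray, observed: float, tail: str) -> int:
    tol = _REL_TOL * max(1.0, abs(observed))
    if tail == "upper":
        return int(np.sum(null >= observed - tol))
    return int(np.sum(null <= observed + tol))


def exact_permutation_pvalue(
    x: LabeledExpression,
    sender_cluster: str,
    receiver_cluster: str,
    gene_a: str,
    gene_b: str,
    tail: str = "upper",
) -> float:
    """Exact p by exhaustive enumeration of all distinct label splits.

    Feasible only for very small cell numbers; used as the ground truth
    the Monte-Carlo estimate must converge to.
    """
    rows, codes, cats = _resolve_pair_context(
        x, sender_cluster, receiver_cluster, [gene_a, gene_b]
    )
    si, ri = cats.index(sender_cluster), cats.index(receiver_cluster)
    obs_means = _cluster_means(rows, codes, len(cats))
    observed = compute_power(obs_means[si, 0], obs_means[ri, 1])
    hits = total = 0
    for arrangement in _iter_label_arrangements(codes):
        means = _cluster_means(rows, arrangement, len(cats))
        power = means[si, 0] * means[ri, 1]
        hits += _tail_hits(np.array([power]), observed, tail)
        total += 1
    return hits / total


# ---------------------------------------------------------------------------
# pipeline


def _deg_lookup(degs: Sequence[DegEntry]) -> dict[tuple[str, str], float]:
    return {(d.gene, d.cluster): d.log2fc for d in degs}


def _select_side(
    x: LabeledExpression,
    degs: Sequence[DegEntry],
    cluster: str,
    spec: ClusterGeneSpec,
    gdb: GeneDatabase | None,
) -> set[str]:
    genes = select_regulated(
        degs,
        cluster,
        direction=spec.direction,
        min_abs_log2fc=spec.min_abs_log2fc,
        max_adj_p=spec.max_adj_p,
    )
    if gdb is not None:
        genes &= select_genes(gdb, spec.selection)
    return {g for g in genes if g in x.gene_index}


def infer_pairs(
    x: LabeledExpression,
    degs: Sequence[DegEntry],
    sender_cluster: str,
    receiver_cluster: str,
    sender_spec: ClusterGeneSpec,
    receiver_spec: ClusterGeneSpec,
    gdb: GeneDatabase | None,
    idb: InteractionDatabase,
    ifilter: InteractionFilterSpec | None = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    tail: str = "upper",
    adjust_p: bool = False,
) -> list[CandidatePair]:
    """Score all database-matched sender -> receiver gene pairs.

    Sender genes are the cluster's DEGs passing the sender annotation
    constraints; receiver genes likewise.  Their cross product is matched
    against the (optionally filtered) interaction database; matched pairs
    receive a power, a fold-change power variant (sum of the two genes'
    log2FC) and a permutation p-value, and pairs with p < alpha are
    returned ranked by power.  With ``adjust_p`` the permutation p-values
    are Benjamini-Hochberg corrected across the matched pairs before the
    alpha cut (off by default: per-pair reporting is the convention).
    """
    senders = sorted(
        _select_side(x, degs, sender_cluster, sender_spec, gdb)
    )
    receivers = sorted(
        _select_side(x, degs, receiver_cluster, receiver_spec, gdb)
    )
    if not senders or not receivers:
        logger.info(
            "no candidate genes for %s -> %s (senders=%d, receivers=%d)",
            sender_cluster, receiver_cluster, len(senders), len(receivers),
        )
        return []
    fdb = subset_interactions(idb, ifilter) if ifilter is not None else idb
    matched: list[tuple[str, str]] = [
        (ga, gb)
        for ga in senders
        for gb in receivers
        if fdb.get(ga, gb) is not None
    ]
    if not matched:
        logger.info(
            "no database-matched pairs for %s -> %s",
            sender_cluster, receiver_cluster,
        )
        return []

    genes = sorted({g for pair in matched for g in pair})
    gidx = {g: i for i, g in enumerate(genes)}
    rows, codes, cats = _resolve_pair_context(
        x, sender_cluster, receiver_cluster, genes
    )
    si, ri = cats.index(sender_cluster), cats.index(receiver_cluster)
    obs_means = _cluster_means(rows, codes, len(cats))
    rng = np.random.default_rng(seed)
    null_means = permuted_cluster_means(rows, codes, len(cats), n_perm, rng)
    fc = _deg_lookup(degs)

    powers = []
    pvals = []
    for ga, gb in matched:
        ia, ib = gidx[ga], gidx[gb]
        observed = compute_power(obs_means[si, ia], obs_means[ri, ib])
        null = null_means[:, si, ia] * null_means[:, ri, ib]
        powers.append(observed)
        pvals.append(min(1.0, _tail_hits(null, observed, tail) / n_perm))
    if adjust_p:
        from scipy.stats import false_discovery_control

        pvals = [
            float(min(1.0, q))
            for q in false_discovery_control(pvals, method="bh")
        ]

    out = []
    for (ga, gb), observed, p in zip(matched, powers, pvals):
        if p >= alpha:
            continue
        rec = fdb.get(ga, gb)
        out.append(
            CandidatePair(
                sender_cluster=sender_cluster,
                receiver_cluster=receiver_cluster,
                sender_gene=ga,
                receiver_gene=gb,
                power=observed,
                power_fc=fc.get((ga, sender_cluster), 0.0)
                + fc.get((gb, receiver_cluster), 0.0),
                p_value=float(p),
                actions=rec.actions,
                credibility=rec.credibility,
                confidence_level=rec.confidence_level,
            )
        )
    return _sorted_candidates(out)


def pairs_table(pairs: Iterable[CandidatePair]) -> pd.DataFrame:
    """Flatten candidate pairs to a TSV-ready table (actions joined)."""
    rows = [
        (
            p.sender_cluster, p.receiver_cluster, p.sender_gene,
            p.receiver_gene, p.power, p.power_fc, p.p_value,
            p.credibility, p.confidence_level,
            ";".join(f"{a.mode}|{a.effect}" for a in p.actions),
        )
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sender_cluster", "receiver_cluster", "sender_gene",
            "receiver_gene", "power", "power_fc", "p_value",
            "credibility", "confidence_level", "actions",
        ],
    )


def pairs_from_table(df: pd.DataFrame) -> list[CandidatePair]:
    out = []
    for r in df.itertuples(index=False):
        actions = tuple(
            ActionRecord(mode=m, effect=e)
            if e == "undirected"
            else ActionRecord(mode=m, effect=e, is_directional=True,
                              acting_partner="a")
            for tok in str(getattr(r, "actions", "") or "").split(";")
            if tok
            for m, e in [tok.split("|")]
        )
        out.append(
            CandidatePair(
                sender_cluster=str(r.sender_cluster),
                receiver_cluster=str(r.receiver_cluster),
                sender_gene=str(r.sender_gene),
                receiver_gene=str(r.receiver_gene),
                power=float(r.power),
                power_fc=float(r.power_fc),
                p_value=float(r.p_value),
                actions=actions,
                credibility=int(r.credibility)
                if not pd.isna(r.credibility) else None,
                confidence_level=str(r.confidence_level)
                if not pd.isna(r.confidence_level) else None,
            )
        )
    return out


def group_pairs(
    pairs: Iterable[CandidatePair],
) -> dict[tuple[str, str], list[CandidatePair]]:
    grouped: dict[tuple[str, str], list[CandidatePair]] = {}
    for p in pairs:
        grouped.setdefault(
            (p.sender_cluster, p.receiver_cluster), []
        ).append(p)
    return grouped


def network_summary(
    pairs_by_cluster_pair: Mapping[tuple[str, str], Sequence[CandidatePair]],
) -> list[NetworkSummary]:
    """Aggregate retained pairs per ordered cluster pair: M and W."""
    out = []
    for (s, r), pairs in sorted(pairs_by_cluster_pair.items()):
        out.append(
            NetworkSummary(
                sender_cluster=s,
                receiver_cluster=r,
                pair_count=len(pairs),
                aggregated_power=float(sum(p.power for p in pairs)),
            )
        )
    return out


def scan_pair_across_clusters(
    x: LabeledExpression,
    degs: Sequence[DegEntry],
    gene_a: str,
    gene_b: str,
    cluster_list: Sequence[str] | None = None,
    sender_spec: ClusterGeneSpec | None = None,
    receiver_spec: ClusterGeneSpec | None = None,
    gdb: GeneDatabase | None = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    exclude_self: bool = False,
    tail: str = "upper",
) -> pd.DataFrame:
    """Score one named gene pair over every ordered cluster pair.

    A row is emitted for each ordered (sender, receiver) combination in
    which ``gene_a`` passes the sender selection and ``gene_b`` the
    receiver selection; it carries the power and permutation p-value of
    the pair in that context.
    """
    for g in (gene_a, gene_b):
        if g not in x.gene_index:
            raise ValidationError(f"gene {g!r} not in expression matrix")
    sender_spec = sender_spec or ClusterGeneSpec()
    receiver_spec = receiver_spec or ClusterGeneSpec()
    clusters = list(cluster_list) if cluster_list is not None else x.clusters
    rows_out = []
    for s in clusters:
        if gene_a not in _select_side(x, degs, s, sender_spec, gdb):
            continue
        for r in clusters:
            if exclude_self and s == r:
                continue
            if gene_b not in _select_side(x, degs, r, receiver_spec, gdb):
                continue
            p = permutation_pvalue(
                x, s, r, gene_a, gene_b, n_perm=n_perm, seed=seed, tail=tail
            )
            rows, codes, cats = _resolve_pair_context(x, s, r, [gene_a, gene_b])
            means = _cluster_means(rows, codes, len(cats))
            power = compute_power(
                means[cats.index(s), 0], means[cats.index(r), 1]
            )
            rows_out.append((s, r, gene_a, gene_b, power, p))
    return pd.DataFrame(
        rows_out,
        columns=["sender", "receiver", "sender_gene", "receiver_gene",
                 "power", "p_value"],
    )


def scan_gene_partners(
    x: LabeledExpression,
    degs: Sequence[DegEntry],
    gene: str,
    gdb: GeneDatabase | None,
    idb: InteractionDatabase,
    role: str = "any",
    sender_spec: ClusterGeneSpec | None = None,
    receiver_spec: ClusterGeneSpec | None = None,
    ifilter: InteractionFilterSpec | None = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    exclude_self: bool = False,
) -> list[CandidatePair]:
    """Off-target scan: every candidate pair involving one named gene.

    Enumerates all ordered cluster pairs and keeps the significant
    candidate pairs where the gene appears in the stated role (sender,
    receiver, or either).
    """
    if role not in ("any", "sender", "receiver"):
        raise ValidationError(f"role must be any/sender/receiver, got {role!r}")
    if gene not in x.gene_index:
        raise ValidationError(f"gene {gene!r} not in expression matrix")
    sender_spec = sender_spec or ClusterGeneSpec()
    receiver_spec = receiver_spec or ClusterGeneSpec()
    clusters = x.clusters
    out: list[CandidatePair] = []
    for s in clusters:
        for r in clusters:
            if exclude_self and s == r:
                continue
            pairs = infer_pairs(
                x, degs, s, r, sender_spec, receiver_spec, gdb, idb,
                ifilter=ifilter, n_perm=n_perm, seed=seed, alpha=alpha,
            )
            for p in pairs:
                if role == "sender" and p.sender_gene != gene:
                    continue
                if role == "receiver" and p.receiver_gene != gene:
                    continue
                if role == "any" and gene not in (
                    p.sender_gene, p.receiver_gene
                ):
                    continue
                out.append(p)
    return _sorted_candidates(out)
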