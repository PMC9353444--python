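"""Plot-ready tables behind the four display types.

Each function returns the tabular record a renderer would draw (dot
network, action-mode pie, pair dot plot, two-cell spatial diagram).
Correctness lives in these tables; rendering them is cosmetic and left to
downstream plotting code.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .gene_db import GeneDatabase
from .inference_core import CandidatePair, NetworkSummary
from .interaction_db import ACTION_MODES

#: The four diagram zones of the two-cell spatial layout.
SPATIAL_ZONES: tuple[str, ...] = (
    "extracellular space",
    "cytomembrane",
    "cytoplasm",
    "cell nucleus",
)

#: Collapse of the 13 localization categories onto the 4 diagram zones.
ZONE_OF_CATEGORY: dict[str, str] = {
    "extracellular region": "extracellular space",
    "plasma membrane": "cytomembrane",
    "nucleus": "cell nucleus",
    # every other compartment sits inside the cell body
    "cytosol": "cytoplasm",
    "cytoskeleton": "cytoplasm",
    "peroxisome": "cytoplasm",
    "lysosome": "cytoplasm",
    "endoplasmic reticulum": "cytoplasm",
    "Golgi apparatus": "cytoplasm",
    "endosome": "cytoplasm",
    "mitochondrion": "cytoplasm",
    "cytoplasm": "cytoplasm",
    "other": "cytoplasm",
}

FALLBACK_ZONE = "cytoplasm"


def network_dot_table(summaries: Sequence[NetworkSummary]) -> pd.DataFrame:
    """Network dot plot: dot size = pair count, dot color = aggregated power."""
    rows = [
        (s.sender_cluster, s.receiver_cluster, s.pair_count,
         s.aggregated_power)
        for s in summaries
        if s.pair_count > 0
    ]
    rows.sort()
    return pd.DataFrame(
        rows, columns=["sender", "receiver", "dot_size", "dot_color"]
    )


def action_mode_composition(pairs: Iterable[CandidatePair]) -> pd.DataFrame:
    """Pie-plot table: count and fraction of matched actions per mode."""
    counts: dict[str, int] = {}
    for p in pairs:
        for a in p.actions:
            counts[a.mode] = counts.get(a.mode, 0) + 1
    total = sum(counts.values())
    rows = [
        (mode, counts[mode], counts[mode] / total)
        for mode in ACTION_MODES
        if mode in counts
    ]
    return pd.DataFrame(rows, columns=["mode", "count", "fraction"])


def pair_dot_table(
    pairs: Sequence[CandidatePair],
    power_mode: str = "expr_product",
) -> pd.DataFrame:
    """Pair dot plot: dot size from confidence (1 - p), color from power.

    ``power_mode`` chooses which power ranks the rows: the expression
    product or the log2-fold-change sum; both columns are always present.
    """
    if power_mode not in ("expr_product", "log2fc_sum"):
        raise ValidationError(
            f"power_mode must be 'expr_product' or 'log2fc_sum', "
            f"got {power_mode!r}"
        )
    key = "power" if power_mode == "expr_product" else "power_fc"
    ordered = sorted(
        pairs,
        key=lambda c: (
            -getattr(c, key), c.p_value, c.sender_gene, c.receiver_gene,
        ),
    )
    rows = [
        (
            f"{c.sender_gene}->{c.receiver_gene}",
            f"{c.sender_cluster}->{c.receiver_cluster}",
            1.0 - c.p_value,
            c.power,
            c.power_fc,
            getattr(c, key),
        )
        for c in ordered
    ]
    return pd.DataFrame(
        rows,
        columns=["pair", "cluster_pair", "dot_size", "power",
                 "power_fc", "dot_color"],
    )


def _zone_for(gdb: GeneDatabase | None, gene: str) -> tuple[str, bool]:
    """Best zone for a gene: highest-confidence localization, mapped."""
    rec = gdb.get(gene) if gdb is not None else None
    if rec is None or not rec.localizations:
        return FALLBACK_ZONE, True
    best = max(rec.localizations, key=lambda l: l.confidence)
    return ZONE_OF_CATEGORY[best.category], False


def spatial_pattern_layout(
    pairs: Sequence[CandidatePair],
    gdb: GeneDatabase | None,
    gene_log2fc: dict[tuple[str, str], float] | None = None,
) -> dict:
    """Two-cell spatial diagram record.

    Each of the two cell areas (sender, receiver) holds four zones;
    genes are placed in the zone of their highest-confidence localization
    (fallback: cytoplasm, flagged).  Node size encodes |log2FC|, node
    color the regulation direction (red = up, green = down); edges carry
    the action mode as color and the effect as arrow style.

    ``gene_log2fc`` optionally maps (gene, cluster) to the gene's own
    log2FC; without it each gene is shown with half of the pair's
    fold-change sum.
    """
    gene_log2fc = gene_log2fc or {}
    nodes: dict[tuple[str, str], dict] = {}
    edges = []
    warnings = []
    for c in pairs:
        for side, gene, cluster in (
            ("sender", c.sender_gene, c.sender_cluster),
            ("receiver", c.receiver_gene, c.receiver_cluster),
        ):
            fc = gene_log2fc.get((gene, cluster), c.power_fc / 2.0)
            key = (side, gene)
            if key not in nodes:
                zone, fell_back = _zone_for(gdb, gene)
                if fell_back:
                    warnings.append(
                        f"{gene}: no localization annotation; placed in "
                        f"{FALLBACK_ZONE}"
                    )
                nodes[key] = {
                    "cell": side,
                    "gene": gene,
                    "zone": zone,
                    "size": abs(fc),
                    "color": "red" if fc >= 0 else "green",
                }
        for a in c.actions:
            edges.append(
                {
                    "sender_gene": c.sender_gene,
                    "receiver_gene": c.receiver_gene,
                    "edge_color": a.mode,
                    "arrow": a.effect,
                }
            )
    return {
        "zones": list(SPATIAL_ZONES),
        "cells": ["sender", "receiver"],
        "nodes": sorted(
            nodes.values(), key=lambda n: (n["cell"], n["gene"])
        ),
        "edges": edges,
        "warnings": warnings,
    }
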