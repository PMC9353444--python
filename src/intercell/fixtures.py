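"""Synthetic fixture generator with planted sender -> receiver signal.

Generates an internally consistent toy quadruple — gene annotation
database, interaction database, labeled expression matrix, DEG table —
plus a machine-readable ground-truth table of the planted ligand ->
receptor pairs.

The expression model is a right-skewed non-negative baseline
(log-normal noise, mimicking log-normalized single-cell cluster means)
on which each planted gene receives an additive shift of ``effect_size``
in its designated cluster.  Planted ligands are annotated as secreted
cytokines (extracellular region, confidence 5), planted receptors as
plasma-membrane receptors (confidence 5), and every planted pair enters
the interaction database as an experimentally validated binding record
with credibility in the highest bin — so the canonical selection
pipeline (secreted cytokine -> membrane receptor, binding mode, highest
confidence) recovers exactly the planted signal.  DEG statistics are
computed from the generated matrix itself (cluster-vs-rest log2 mean
ratio, rank-sum p, Benjamini-Hochberg adjusted).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .expression_input import (
    DegEntry,
    LabeledExpression,
    write_deg_table,
)
from .gene_db import (
    GeneDatabase,
    GeneRecord,
    GeneSelectionSpec,
    LOCALIZATION_CATEGORIES,
    LocalizationAnnotation,
    save_gene_db,
)
from .inference_core import ClusterGeneSpec
from .interaction_db import (
    ACTION_EFFECTS,
    ACTION_MODES,
    ActionRecord,
    InteractionDatabase,
    InteractionFilterSpec,
    InteractionRecord,
    save_interaction_db,
)

#: Immune-response GO term used to tag planted genes.
PLANTED_GO_TERM = "GO:0006955"

_GO_POOL = (
    "GO:0006955", "GO:0008283", "GO:0006412", "GO:0016049",
    "GO:0055085", "GO:0007165",
)

#: Default planted signal: two ligand -> receptor routes across 3 clusters.
DEFAULT_PLANTED = (
    ("C0", "C1", "LIGA", "RECA", 2.0),
    ("C1", "C2", "LIGB", "RECB", 2.0),
)


def canonical_sender_spec(**deg_kwargs) -> ClusterGeneSpec:
    """Secreted-cytokine sender selection (extracellular, confidence >= 4)."""
    return ClusterGeneSpec(
        selection=GeneSelectionSpec.make(
            localization_categories=["extracellular region"],
            min_confidence=4,
            function_groups=["cytokine"],
        ),
        **deg_kwargs,
    )


def canonical_receiver_spec(**deg_kwargs) -> ClusterGeneSpec:
    """Membrane-receptor receiver selection (plasma membrane, conf >= 4)."""
    return ClusterGeneSpec(
        selection=GeneSelectionSpec.make(
            localization_categories=["plasma membrane"],
            min_confidence=4,
            function_groups=["receptor"],
        ),
        **deg_kwargs,
    )


def canonical_interaction_filter() -> InteractionFilterSpec:
    """Binding-mode, highest-credibility, experimentally validated records."""
    return InteractionFilterSpec.make(
        evidence_classes=["experiment_validated"],
        min_level="highest",
        modes=["binding"],
    )


@dataclass
class Fixture:
    gene_db: GeneDatabase
    interaction_db: InteractionDatabase
    expression: LabeledExpression
    degs: list[DegEntry]
    ground_truth: pd.DataFrame

    def write(self, outdir) -> dict[str, Path]:
        """Serialize all components; byte-identical for identical seeds."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": outdir / "genes.tsv",
            "interactions": outdir / "interactions.tsv",
            "matrix": outdir / "matrix.tsv",
            "labels": outdir / "labels.tsv",
            "degs": outdir / "degs.tsv",
            "ground_truth": outdir / "ground_truth.tsv",
        }
        save_gene_db(self.gene_db, paths["genes"])
        save_interaction_db(self.interaction_db, paths["interactions"])
        x = self.expression
        pd.DataFrame(
            x.matrix, index=x.gene_index, columns=x.cell_index
        ).to_csv(paths["matrix"], sep="\t", float_format="%.8g")
        x.labels.to_csv(paths["labels"], sep="\t", header=False)
        write_deg_table(self.degs, paths["degs"])
        self.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False)
        return paths


def _deg_table_from_matrix(x: LabeledExpression) -> list[DegEntry]:
    """Cluster-vs-rest DEG statistics from the generated matrix.

    log2FC of (cluster mean + eps) over (rest mean + eps); p from the
    Wilcoxon rank-sum test, Benjamini-Hochberg adjusted within cluster.
    """
    eps = 0.01
    codes, cats = x.label_codes()
    degs: list[DegEntry] = []
    for ci, cluster in enumerate(cats):
        inside = x.matrix[:, codes == ci]
        outside = x.matrix[:, codes != ci]
        log2fc = np.log2(
            (inside.mean(axis=1) + eps) / (outside.mean(axis=1) + eps)
        )
        pvals = np.array([
            stats.ranksums(inside[g], outside[g]).pvalue
            for g in range(x.n_genes)
        ])
        adj = stats.false_discovery_control(pvals, method="bh")
        for g, gene in enumerate(x.gene_index):
            degs.append(
                DegEntry(
                    gene=gene,
                    cluster=cluster,
                    log2fc=float(log2fc[g]),
                    adj_p=float(min(1.0, adj[g])),
                )
            )
    return degs


def make_fixture(
    n_clusters: int = 3,
    cells_per_cluster: int = 20,
    n_genes: int = 30,
    planted=DEFAULT_PLANTED,
    noise_sd: float = 0.35,
    seed: int = 0,
    n_decoy_interactions: int | None = None,
) -> Fixture:
    """Build the synthetic study: planted signal on a noise background.

    ``planted`` lists (sender_cluster, receiver_cluster, ligand, receptor,
    effect_size) tuples; clusters are named ``C0..C{n-1}``; decoy genes
    fill the matrix up to ``n_genes`` and also receive random annotations
    and random decoy interaction records.
    """
    rng = np.random.default_rng(seed)
    clusters = [f"C{i}" for i in range(n_clusters)]
    planted = [tuple(p) for p in planted]
    for s, r, lig, rec, eff in planted:
        if s not in clusters or r not in clusters:
            raise ValidationError(
                f"planted clusters ({s}, {r}) outside {clusters}"
            )
        if eff < 0:
            raise ValidationError("effect_size must be >= 0")

    planted_genes = []
    for _, _, lig, rec, _ in planted:
        for g in (lig, rec):
            if g not in planted_genes:
                planted_genes.append(g)
    n_decoys = n_genes - len(planted_genes)
    if n_decoys < 0:
        raise ValidationError(
            f"n_genes={n_genes} too small for {len(planted_genes)} "
            f"planted genes"
        )
    decoys = [f"G{i:03d}" for i in range(1, n_decoys + 1)]
    collision = set(decoys) & set(planted_genes)
    if collision:
        raise ValidationError(
            f"planted gene names collide with decoy names: {sorted(collision)}"
        )
    genes = planted_genes + decoys

    # --- gene annotation database ------------------------------------
    taxonomy_classes = None
    records = []
    ligands = {lig for _, _, lig, _, _ in planted}
    receptors = {rec for _, _, _, rec, _ in planted}
    for g in genes:
        if g in ligands:
            locs = [LocalizationAnnotation("extracellular region", 5)]
            classes = {"cytokine"}
            go = {PLANTED_GO_TERM}
        elif g in receptors:
            locs = [LocalizationAnnotation("plasma membrane", 5)]
            classes = {"receptor"}
            go = {PLANTED_GO_TERM}
        else:
            n_loc = int(rng.integers(1, 3))
            cats = rng.choice(
                len(LOCALIZATION_CATEGORIES), size=n_loc, replace=False
            )
            locs = [
                LocalizationAnnotation(
                    LOCALIZATION_CATEGORIES[c], int(rng.integers(1, 6))
                )
                for c in cats
            ]
            if taxonomy_classes is None:
                from .gene_db import FunctionTaxonomy

                taxonomy_classes = sorted(FunctionTaxonomy.default().classes)
            classes = {taxonomy_classes[int(rng.integers(len(taxonomy_classes)))]}
            go = {_GO_POOL[int(rng.integers(len(_GO_POOL)))]}
        records.append(
            GeneRecord(
                symbol=g, species="human", localizations=locs,
                function_classes=classes, go_terms=go,
            )
        )
    gdb = GeneDatabase(records, species="human")

    # --- interaction database ----------------------------------------
    irecords = []
    for _, _, lig, rec, _ in planted:
        if any(r.pair == tuple(sorted((lig, rec))) for r in irecords):
            continue
        irecords.append(
            InteractionRecord.make(
                gene_a=lig,
                gene_b=rec,
                channel_scores={
                    "experiments": int(rng.integers(400, 900)),
                    "database": int(rng.integers(100, 400)),
                },
                credibility=int(rng.integers(930, 991)),
                actions=(
                    ActionRecord("binding", "undirected", False, "unknown"),
                    ActionRecord("activation", "positive", True, "a"),
                ),
            )
        )
    if n_decoy_interactions is None:
        n_decoy_interactions = max(3, n_decoys // 2)
    seen = {r.pair for r in irecords}
    attempts = 0
    while len(irecords) - len(planted) < n_decoy_interactions and attempts < 1000:
        attempts += 1
        a, b = rng.choice(len(decoys), size=2, replace=False) if n_decoys >= 2 else (0, 0)
        if n_decoys < 2:
            break
        ga, gb = decoys[int(a)], decoys[int(b)]
        key = tuple(sorted((ga, gb)))
        if key in seen:
            continue
        seen.add(key)
        mode = ACTION_MODES[int(rng.integers(len(ACTION_MODES)))]
        effect = ACTION_EFFECTS[int(rng.integers(len(ACTION_EFFECTS)))]
        irecords.append(
            InteractionRecord.make(
                gene_a=ga,
                gene_b=gb,
                channel_scores={
                    "experiments": int(rng.integers(0, 500)),
                    "textmining": int(rng.integers(0, 500)),
                    "coexpression": int(rng.integers(0, 300)),
                },
                credibility=int(rng.integers(1, 1001)),
                actions=(
                    ActionRecord(
                        mode,
                        effect,
                        is_directional=effect not in ("undirected",),
                        acting_partner="a" if effect != "undirected" else "unknown",
                    ),
                ),
            )
        )
    idb = InteractionDatabase(irecords)

    # --- expression matrix -------------------------------------------
    n_cells = n_clusters * cells_per_cluster
    barcodes = [f"cell{i:04d}" for i in range(n_cells)]
    labels = pd.Series(
        np.repeat(clusters, cells_per_cluster), index=barcodes, name="cluster"
    )
    matrix = rng.lognormal(mean=0.0, sigma=noise_sd, size=(n_genes, n_cells))
    gidx = {g: i for i, g in enumerate(genes)}
    for s, r, lig, rec, eff in planted:
        matrix[gidx[lig], labels.values == s] += eff
        matrix[gidx[rec], labels.values == r] += eff
    x = LabeledExpression(
        matrix=matrix,
        gene_index=pd.Index(genes),
        cell_index=pd.Index(barcodes),
        labels=labels,
    )

    degs = _deg_table_from_matrix(x)
    truth = pd.DataFrame(
        planted,
        columns=["sender_cluster", "receiver_cluster", "sender_gene",
                 "receiver_gene", "effect_size"],
    )
    return Fixture(
        gene_db=gdb,
        interaction_db=idb,
        expression=x,
        degs=degs,
        ground_truth=truth,
    )
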