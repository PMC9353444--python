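# Methods

## Scoring model

A candidate interaction is an ordered tuple (sender cluster *i*,
receiver cluster *j*, sender gene *A*, receiver gene *B*). Its score is

    Power(A, B) = Exprs_i(A) · Exprs_j(B),

where Exprs is the **arithmetic cluster mean of normalized expression
over all cells of the cluster**. Two deliberate choices sit inside this
definition:

* *Mean, not fraction-expressing or median.* The product of means makes
  the permutation null well defined under label shuffling and is
  equivariant under global rescaling (multiplying the matrix by c > 0
  multiplies every power by c² and changes no p-value, since the
  permutation test is a rank statistic of the power).
* *All cells of the cluster, not only DEG-passing cells.* The DEG filter
  acts on gene selection only; expression summaries always use the full
  cluster.

Input expression is assumed non-negative and already normalized
(log-normalized counts are typical). Normalization, clustering and DEG
calling are upstream concerns; a strictly-negative-value check rejects
z-scored matrices with a clear message, but no further enforcement is
attempted.

## Permutation test

The null hypothesis is that cluster identity carries no information
about the joint expression of the pair. The full label vector over
**all** cells (not just the two clusters involved) is shuffled
uniformly; cluster sizes are preserved exactly because labels are
permuted, not resampled. With N shuffles (default N = 100),

    p = #{ n : Power^(n) ≥ Power_observed } / N.

* *Tail.* The upper tail is the default: strong pairs get small p. A
  `tail="lower"` flag inverts the count for users probing depleted
  pairs.
* *No pseudo-count.* p can be exactly 0 at finite N, matching the plain
  /N denominator; a `conservative_p` flag switches to (1 + hits)/(1 + N)
  for users who prefer an estimate bounded away from zero.
* *Ties.* Permuted powers within a relative 1e-12 of the observed power
  count as hits, so constant genes yield p = 1 exactly.
* *Exact oracle.* For small cell numbers, `exact_permutation_pvalue`
  enumerates all distinct arrangements of the label multiset (20 splits
  for 3+3 cells) and returns the exact tail fraction. Because every
  distinct arrangement has equal multiplicity under uniform permutation
  of the label vector, the Monte-Carlo estimate converges to this exact
  value; the test suite asserts agreement within three binomial standard
  errors at N = 10,000. Under a continuous null the discrete estimator
  satisfies P(p < 0.05) = 5/101 ≈ 0.0495 at N = 100, which is why the
  type-I calibration check is centred on 0.05.

All randomness flows through `numpy.random.default_rng(seed)`; identical
seeds and inputs give bit-identical output tables, and results are
invariant to the gene-row order of the input matrix because permutations
act on labels only.

## Candidate enumeration and filtering

For one ordered cluster pair the pipeline is:

1. sender genes = DEGs of the sender cluster passing the sender
   annotation spec; receiver genes likewise (defaults: up-regulated,
   |log2FC| > 0.25, adjusted p ≤ 0.05);
2. cross product, restricted to pairs present in the (optionally
   filtered) interaction database — matching is on the unordered pair,
   the sender/receiver gene selections impose direction, so an
   undirected database record can legitimately appear once per
   orientation;
3. power, fold-change power (sum of the two genes' log2FC in their
   respective clusters), and permutation p;
4. retain p < alpha (default 0.05, no multiple-testing correction — the
   permutation test is reported per pair as is);
5. deterministic ranking: power descending, p ascending, then
   lexicographic on (sender gene, receiver gene).

Self cluster pairs (i, i) are included unless `exclude_self` is set:
autocrine signaling is a legitimate finding.

Annotation constraints combine conjunctively across the three layers
(localization AND function AND GO) and disjunctively within a layer.
The localization constraint passes if **any** annotation of the gene has
a listed category at confidence ≥ the minimum (default 4, i.e. keep
4–5); a gene may carry several localizations and duplicate
(symbol, category) rows collapse to the maximum confidence at load time.
Interaction filtering keeps a record when its evidence flags intersect
the requested classes, its credibility passes the threshold, and at
least one action record matches both the mode and the effect
constraints; surviving records are stripped to the matching actions, so
downstream mode-composition tables reflect the filter. Both filters are
monotone and idempotent by construction.

## Vocabularies and bins

* Localization: 13 fixed categories; confidence integer 1–5.
* Function: 132 classes partitioned into 16 groups. The group names are
  the standard coarse taxonomy (cytokine, receptor, enzyme, ...); the
  bundled class list (`data/function_classes.tsv`) is a synthetic
  stand-in taxonomy with the correct cardinalities and a total
  class → group mapping, sufficient for selection semantics; users with
  a curated 132-class table can load their own mapping.
* Evidence classes: experiment_validated ⇔ `experiments` > 0,
  pathway_curated ⇔ `database` > 0, predicted ⇔ any other channel > 0
  (including the transferred variants of the first two). The flags are
  not mutually exclusive.
* Credibility 1–1000, binned highest ≥ 900 > high ≥ 700 > medium ≥ 400
  > low. The bins partition the scale; boundary scores 400/700/900 land
  in medium/high/highest.
* Gene symbols are normalized per species before matching (human:
  upper case; mouse: capitalized), since case mismatch between DEG
  tables and databases is the dominant practical failure mode.

## Synthetic studies

`make_fixture` generates the four inputs with planted ground truth.
Defaults define the standard study: 3 clusters × 20 cells, 30 genes,
two planted ligand → receptor routes at additive effect size 2.0 on a
log-normal baseline (σ = 0.35, median 1). The geometry is deliberately
desk-scale: large enough that cluster-vs-rest rank tests and the
permutation test behave, small enough that the full grid of ordered
cluster pairs runs in seconds.

What the generator emulates: non-negative right-skewed expression with
controllable cluster separation; internally consistent annotations
(planted ligands are secreted cytokines at confidence 5, planted
receptors are plasma-membrane receptors at confidence 5); an interaction
database where every planted pair is an experimentally validated
binding record with credibility ≥ 930, among decoy records with random
channels, modes and credibilities; and a DEG table computed from the
generated matrix itself (log2 ratio of cluster-vs-rest means with a 0.01
pseudo-offset; Wilcoxon rank-sum p, Benjamini–Hochberg adjusted within
cluster).

What it does not emulate: dropout and library-size variation, gene–gene
correlation, batch effects, cluster-size imbalance, or realistic
annotation error. Passing the recovery and calibration checks therefore
demonstrates the correctness of the machinery — selection logic, the
permutation null, conservation laws — not robustness to the failure
modes of real data. Effect size 0 is explicitly allowed so the same
generator provides exact null studies for type-I calibration.

## Numerical and degenerate-input choices

* Power comparisons in the permutation test use a 1e-12 relative
  tolerance for tie handling; everything else is plain float64.
* An empty sender or receiver gene set is a logged empty result, not an
  error; an unknown cluster, an absent gene, or an out-of-vocabulary
  token is always a raised validation error — silent empties are
  reserved for legitimately empty biology.
* Coverage ratio is undefined (error) for an empty comparison set;
  absent cluster pairs contribute zero to the averaged benchmark counts.
* The two-cell spatial layout collapses the 13 localization categories
  onto 4 zones (extracellular region → extracellular space; plasma
  membrane → cytomembrane; nucleus → cell nucleus; everything else →
  cytoplasm). A gene with no localization annotation is placed in the
  cytoplasm with a warning. A gene's zone is that of its
  highest-confidence annotation.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on generated
data: the 6-cell (3+3) exact-enumeration example (20 splits, Monte
Carlo at N = 10,000), 200 replicate null fixtures at the default
geometry (400 null p-values at N = 100), and the standard 3 × 20-cell
recovery fixture. These sizes were chosen as the smallest at which each
property is statistically meaningful; the whole suite runs in well
under a minute.

## Known limitations

* The score uses cluster means only; cluster-size differences affect
  the variance of the null but not its centre, and no
  fraction-expressing threshold is applied.
* No multiple-testing correction by default across the candidate grid
  (an optional Benjamini–Hochberg utility is deliberately not wired into
  the default path, mirroring the per-pair reporting convention).
* Complex (multi-subunit) entries from other databases must be
  pre-expanded to binary pairs before benchmark comparison.
* The package consumes pre-extracted annotation/interaction tables in
  its documented TSV schema; it does not download or parse native
  upstream dumps.
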