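import math

import numpy as np
import pandas as pd
import pytest

import intercell as ic
from intercell.errors import ValidationError
from intercell.inference_core import _iter_label_arrangements, pairs_table


def _run_all_cluster_pairs(fx, seed=1, alpha=0.05, ifilter="canonical"):
    ifl = ic.canonical_interaction_filter() if ifilter == "canonical" else ifilter
    pairs = []
    for s in fx.expression.clusters:
        for r in fx.expression.clusters:
            pairs += ic.infer_pairs(
                fx.expression, fx.degs, s, r,
                ic.canonical_sender_spec(), ic.canonical_receiver_spec(),
                fx.gene_db, fx.interaction_db,
                ifilter=ifl, seed=seed, alpha=alpha,
            )
    return pairs


def test_compute_power():
    assert ic.compute_power(2.0, 3.0) == 6.0
    assert ic.compute_power(0.0, 7.5) == 0.0
    with pytest.raises(ValidationError):
        ic.compute_power(-1.0, 2.0)


def test_power_matches_hand_computed_cluster_means(standard_fixture):
    fx = standard_fixture
    x = fx.expression
    pairs = ic.infer_pairs(
        x, fx.degs, "C0", "C1",
        ic.canonical_sender_spec(), ic.canonical_receiver_spec(),
        fx.gene_db, fx.interaction_db,
        ifilter=ic.canonical_interaction_filter(), seed=1,
    )
    assert pairs
    mask_s = (x.labels == "C0").to_numpy()
    mask_r = (x.labels == "C1").to_numpy()
    for p in pairs:
        expected = (
            x.gene_row(p.sender_gene)[mask_s].mean()
            * x.gene_row(p.receiver_gene)[mask_r].mean()
        )
        assert p.power == pytest.approx(expected)


def test_constant_genes_give_p_one():
    genes = pd.Index(["A", "B"])
    cells = pd.Index([f"c{i}" for i in range(6)])
    x = ic.LabeledExpression(
        np.full((2, 6), 3.0), genes, cells,
        pd.Series(["S"] * 3 + ["R"] * 3, index=cells),
    )
    for seed in (0, 11, 99):
        assert ic.permutation_pvalue(x, "S", "R", "A", "B", seed=seed) == 1.0


def test_label_arrangement_enumeration_counts():
    codes = np.array([0, 0, 0, 1, 1, 1], dtype=np.intp)
    arrangements = list(_iter_label_arrangements(codes))
    assert len(arrangements) == 20  # C(6,3)
    assert len({tuple(a) for a in arrangements}) == 20


def test_monte_carlo_converges_to_exact_p(six_cell_expression):
    x = six_cell_expression
    exact = ic.exact_permutation_pvalue(x, "S", "R", "A", "B")
    assert exact == pytest.approx(1 / 20)  # only the true split separates
    n_perm = 10_000
    mc = ic.permutation_pvalue(x, "S", "R", "A", "B", n_perm=n_perm, seed=3)
    se = math.sqrt(exact * (1 - exact) / n_perm)
    assert abs(mc - exact) <= 3 * se


def test_lower_tail_complements_upper(six_cell_expression):
    x = six_cell_expression
    up = ic.exact_permutation_pvalue(x, "S", "R", "A", "B", tail="upper")
    low = ic.exact_permutation_pvalue(x, "S", "R", "A", "B", tail="lower")
    # the two tails overlap exactly on ties, so they sum to >= 1
    assert up + low >= 1.0
    assert low == 1.0  # observed split is the maximum


def test_conservative_p_never_zero(six_cell_expression):
    p = ic.permutation_pvalue(
        six_cell_expression, "S", "R", "A", "B",
        n_perm=50, seed=0, conservative_p=True,
    )
    assert p >= 1 / 51


def test_absent_gene_raises(six_cell_expression):
    with pytest.raises(ValidationError):
        ic.permutation_pvalue(six_cell_expression, "S", "R", "A", "ZZZ")


def test_recovers_exactly_planted_pairs(standard_fixture):
    fx = standard_fixture
    got = {
        (p.sender_cluster, p.receiver_cluster, p.sender_gene, p.receiver_gene)
        for p in _run_all_cluster_pairs(fx)
    }
    expected = {
        tuple(r)
        for r in fx.ground_truth[
            ["sender_cluster", "receiver_cluster", "sender_gene",
             "receiver_gene"]
        ].itertuples(index=False)
    }
    assert got == expected


def test_binding_filter_excludes_activation_only_record(standard_fixture):
    fx = standard_fixture
    x, degs = fx.expression, fx.degs
    # a database whose only matching record carries no binding action
    idb = ic.InteractionDatabase([
        ic.InteractionRecord.make(
            "LIGA", "RECA", {"experiments": 500}, 950,
            actions=(ic.ActionRecord("activation", "positive", True, "a"),),
        )
    ])
    pairs = ic.infer_pairs(
        x, degs, "C0", "C1",
        ic.canonical_sender_spec(), ic.canonical_receiver_spec(),
        fx.gene_db, idb,
        ifilter=ic.InteractionFilterSpec.make(modes=["binding"]), seed=1,
    )
    assert pairs == []


def test_alpha_one_equals_brute_force_join(standard_fixture):
    fx = standard_fixture
    x, degs = fx.expression, fx.degs
    spec = ic.ClusterGeneSpec()  # DEG filter only, no annotation constraint
    pairs = ic.infer_pairs(
        x, degs, "C0", "C1", spec, spec, None, fx.interaction_db,
        ifilter=None, seed=1, alpha=1.01,
    )
    senders = ic.select_regulated(degs, "C0")
    receivers = ic.select_regulated(degs, "C1")
    expected = {
        (a, b)
        for a in senders
        for b in receivers
        if fx.interaction_db.get(a, b) is not None
    }
    assert {(p.sender_gene, p.receiver_gene) for p in pairs} == expected


def test_bh_adjustment_never_adds_pairs(standard_fixture):
    fx = standard_fixture
    spec = ic.ClusterGeneSpec()
    common = dict(ifilter=None, seed=1, alpha=0.05)
    raw = ic.infer_pairs(
        fx.expression, fx.degs, "C0", "C1", spec, spec, None,
        fx.interaction_db, **common,
    )
    adjusted = ic.infer_pairs(
        fx.expression, fx.degs, "C0", "C1", spec, spec, None,
        fx.interaction_db, adjust_p=True, **common,
    )
    key = lambda ps: {(p.sender_gene, p.receiver_gene) for p in ps}
    assert key(adjusted) <= key(raw)
    raw_p = {(p.sender_gene, p.receiver_gene): p.p_value for p in raw}
    for p in adjusted:
        assert p.p_value >= raw_p[(p.sender_gene, p.receiver_gene)]


def test_empty_gene_set_returns_empty_not_error(standard_fixture):
    fx = standard_fixture
    spec = ic.ClusterGeneSpec(min_abs_log2fc=50.0)  # nothing passes
    out = ic.infer_pairs(
        fx.expression, fx.degs, "C0", "C1", spec, spec,
        fx.gene_db, fx.interaction_db, seed=1,
    )
    assert out == []


def test_network_summary_hand_sum():
    mk = lambda pw: ic.CandidatePair("A", "B", "x", "y", pw, 0.0, 0.01)
    grouped = {("A", "B"): [mk(1.5), mk(2.0), mk(0.5)], ("B", "A"): []}
    summaries = {
        (s.sender_cluster, s.receiver_cluster): s
        for s in ic.network_summary(grouped)
    }
    assert summaries[("A", "B")].pair_count == 3
    assert summaries[("A", "B")].aggregated_power == pytest.approx(4.0)
    assert summaries[("B", "A")].pair_count == 0
    assert summaries[("B", "A")].aggregated_power == 0.0


def test_network_conservation(standard_fixture):
    pairs = _run_all_cluster_pairs(standard_fixture)
    summaries = ic.network_summary(ic.group_pairs(pairs))
    assert sum(s.aggregated_power for s in summaries) == pytest.approx(
        sum(p.power for p in pairs)
    )
    assert sum(s.pair_count for s in summaries) == len(pairs)


def test_scale_equivariance(standard_fixture):
    fx = standard_fixture
    x = fx.expression
    c = 3.0
    scaled = ic.LabeledExpression(
        x.matrix * c, x.gene_index, x.cell_index, x.labels
    )
    args = (
        fx.degs, "C0", "C1",
        ic.canonical_sender_spec(), ic.canonical_receiver_spec(),
        fx.gene_db, fx.interaction_db,
    )
    base = ic.infer_pairs(x, *args,
                          ifilter=ic.canonical_interaction_filter(), seed=5)
    scaled_pairs = ic.infer_pairs(
        scaled, *args, ifilter=ic.canonical_interaction_filter(), seed=5
    )
    assert len(base) == len(scaled_pairs) > 0
    for b, s in zip(base, scaled_pairs):
        assert s.power == pytest.approx(b.power * c * c)
        assert s.p_value == b.p_value


def test_determinism_and_row_order_invariance(standard_fixture):
    fx = standard_fixture
    x = fx.expression
    run = lambda xx: pairs_table(ic.infer_pairs(
        xx, fx.degs, "C0", "C1",
        ic.canonical_sender_spec(), ic.canonical_receiver_spec(),
        fx.gene_db, fx.interaction_db,
        ifilter=ic.canonical_interaction_filter(), seed=42,
    ))
    t1, t2 = run(x), run(x)
    pd.testing.assert_frame_equal(t1, t2)
    # shuffle gene rows; identical seed must give the identical table
    rng = np.random.default_rng(0)
    order = rng.permutation(x.n_genes)
    shuffled = ic.LabeledExpression(
        x.matrix[order], x.gene_index[order], x.cell_index, x.labels
    )
    pd.testing.assert_frame_equal(run(shuffled), t1)


def test_scan_pair_across_clusters_finds_planted_context(standard_fixture):
    fx = standard_fixture
    table = ic.scan_pair_across_clusters(
        fx.expression, fx.degs, "LIGA", "RECA",
        sender_spec=ic.canonical_sender_spec(),
        receiver_spec=ic.canonical_receiver_spec(),
        gdb=fx.gene_db, seed=1,
    )
    assert list(zip(table["sender"], table["receiver"])) == [("C0", "C1")]
    assert (table["p_value"] < 0.05).all()


def test_scan_gene_partners_role_is_subset(standard_fixture):
    fx = standard_fixture
    common = dict(
        gdb=fx.gene_db, idb=fx.interaction_db,
        sender_spec=ic.canonical_sender_spec(),
        receiver_spec=ic.canonical_receiver_spec(),
        ifilter=ic.canonical_interaction_filter(), seed=1,
    )
    anyrole = ic.scan_gene_partners(
        fx.expression, fx.degs, "LIGA", role="any", **common
    )
    sender = ic.scan_gene_partners(
        fx.expression, fx.degs, "LIGA", role="sender", **common
    )
    key = lambda ps: {
        (p.sender_cluster, p.receiver_cluster, p.sender_gene, p.receiver_gene)
        for p in ps
    }
    assert key(sender) <= key(anyrole)
    assert key(sender) == {("C0", "C1", "LIGA", "RECA")}
    with pytest.raises(ValidationError):
        ic.scan_gene_partners(
            fx.expression, fx.degs, "NOPE", role="any", **common
        )
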