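import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import intercell as ic
from intercell.errors import ValidationError
from intercell.interaction_db import EVIDENCE_CHANNELS, MatchedInteraction


def test_record_flags_and_level():
    rec = ic.InteractionRecord.make(
        "A", "B", {"experiments": 150}, 920,
        actions=(ic.ActionRecord("binding"),),
    )
    assert rec.evidence_class_flags == {"experiment_validated"}
    assert rec.confidence_level == "highest"


@pytest.mark.parametrize(
    "credibility,level",
    [
        (1, "low"), (399, "low"), (400, "medium"), (699, "medium"),
        (700, "high"), (899, "high"), (900, "highest"), (1000, "highest"),
    ],
)
def test_credibility_binning_boundaries(credibility, level):
    assert ic.confidence_level(credibility) == level


@given(st.integers(min_value=1, max_value=1000))
@settings(derandomize=True, max_examples=60)
def test_binning_partitions_scale(credibility):
    level = ic.confidence_level(credibility)
    assert level in ("highest", "high", "medium", "low")
    # each score lands in exactly one half-open bin
    bins = {"highest": (900, 1001), "high": (700, 900),
            "medium": (400, 700), "low": (1, 400)}
    lo, hi = bins[level]
    assert lo <= credibility < hi


@pytest.mark.parametrize("credibility", [0, 1001, -5])
def test_credibility_out_of_range(credibility):
    with pytest.raises(ValidationError):
        ic.confidence_level(credibility)


def test_predicted_flag_covers_transferred_channels():
    rec = ic.InteractionRecord.make(
        "A", "B", {"experiments_transferred": 50, "textmining": 10}, 200
    )
    assert rec.evidence_class_flags == {"predicted"}


def test_unknown_action_mode_rejected():
    with pytest.raises(ValidationError, match="phosphorylation"):
        ic.ActionRecord("phosphorylation", "positive", True, "a")


def test_undirected_effect_cannot_be_directional():
    with pytest.raises(ValidationError):
        ic.ActionRecord("binding", "undirected", True, "a")


def test_load_rejects_unknown_mode_token(tmp_path):
    path = tmp_path / "bad.tsv"
    pd.DataFrame(
        {
            "gene_a": ["A"], "gene_b": ["B"], "experiments": [10],
            "credibility": [500],
            "actions": ["phosphorylation|positive|directional|a"],
        }
    ).to_csv(path, sep="\t", index=False)
    with pytest.raises(ValidationError, match="row 2"):
        ic.load_interaction_db(path)


def test_round_trip(toy_interaction_db, tmp_path):
    path = tmp_path / "interactions.tsv"
    ic.save_interaction_db(toy_interaction_db, path)
    db2 = ic.load_interaction_db(path)
    assert db2.pairs == toy_interaction_db.pairs
    for rec in toy_interaction_db:
        rec2 = db2.get(rec.gene_a, rec.gene_b)
        assert rec2.credibility == rec.credibility
        assert rec2.scores == rec.scores
        assert rec2.actions == rec.actions


def test_subset_by_mode_strips_nonmatching_actions(toy_interaction_db):
    spec = ic.InteractionFilterSpec.make(modes=["binding"])
    sub = ic.subset_interactions(toy_interaction_db, spec)
    assert sub.pairs == {("A", "B"), ("A", "C")}
    for rec in sub:
        assert all(a.mode == "binding" for a in rec.actions)
        assert rec.actions  # at least one action retained


def test_subset_empty_spec_is_identity(toy_interaction_db):
    sub = ic.subset_interactions(
        toy_interaction_db, ic.InteractionFilterSpec()
    )
    assert sub.pairs == toy_interaction_db.pairs


def test_subset_evidence_and_credibility(toy_interaction_db):
    spec = ic.InteractionFilterSpec.make(
        evidence_classes=["experiment_validated"], min_credibility=900
    )
    sub = ic.subset_interactions(toy_interaction_db, spec)
    assert sub.pairs == {("A", "B")}
    # pathway-curated-only record excluded despite wanting exp evidence
    spec2 = ic.InteractionFilterSpec.make(
        evidence_classes=["experiment_validated"]
    )
    assert ("A", "C") not in ic.subset_interactions(
        toy_interaction_db, spec2
    ).pairs


def test_subset_idempotent_and_monotone(toy_interaction_db):
    loose = ic.InteractionFilterSpec.make(min_level="low")
    tight = ic.InteractionFilterSpec.make(
        min_level="high", modes=["binding", "inhibition"]
    )
    sub_loose = ic.subset_interactions(toy_interaction_db, loose)
    sub_tight = ic.subset_interactions(toy_interaction_db, tight)
    assert sub_tight.pairs <= sub_loose.pairs
    again = ic.subset_interactions(sub_tight, tight)
    assert again.pairs == sub_tight.pairs


def test_empty_mode_set_is_contradictory(toy_interaction_db):
    with pytest.raises(ValidationError):
        ic.subset_interactions(
            toy_interaction_db, ic.InteractionFilterSpec.make(modes=[])
        )


def test_single_class_filters_union_to_any_positive_channel(standard_fixture):
    db = standard_fixture.interaction_db
    union = set()
    for klass in ("experiment_validated", "pathway_curated", "predicted"):
        sub = ic.subset_interactions(
            db, ic.InteractionFilterSpec.make(evidence_classes=[klass])
        )
        union |= sub.pairs
    expected = {
        rec.pair for rec in db if any(v > 0 for v in rec.scores.values())
    }
    assert union == expected


def test_match_pair_is_orientation_free(toy_interaction_db):
    hits = ic.match_pair(toy_interaction_db, "B", "A")
    assert len(hits) == 1
    m = hits[0]
    assert isinstance(m, MatchedInteraction)
    assert m.sender_gene == "B" and m.receiver_gene == "A"
    assert m.record.pair == ("A", "B")


def test_match_pair_self_and_absent(toy_interaction_db):
    assert len(ic.match_pair(toy_interaction_db, "E", "E")) == 1
    assert ic.match_pair(toy_interaction_db, "A", "Z") == []


def test_channel_vocabulary_contains_transferred_variants():
    base = {"experiments", "database", "neighborhood", "coexpression",
            "textmining"}
    assert base <= set(EVIDENCE_CHANNELS)
    assert {c + "_transferred" for c in base} <= set(EVIDENCE_CHANNELS)
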