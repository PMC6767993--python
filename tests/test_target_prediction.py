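"""Tanimoto scoring, max-Tc target prediction against the brute-force
oracle, curated/predicted merging, and target-set comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from htnet.errors import ValidationError
from htnet.io_formats import CompoundRecord, DrugRecord, TargetLigandSet
from htnet.target_prediction import (
    CTIRecord,
    drug_sharing,
    merge_cti,
    overlap_with_disease,
    predict_targets,
    tanimoto,
)
from oracles import brute_predict


def fp(bits, length=16):
    v = np.zeros(length, dtype=np.uint8)
    v[list(bits)] = 1
    return v


# ---------------------------------------------------------------------------
# tanimoto


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ({1, 2, 3}, {1, 2, 3}, 1.0),       # identical nonzero
        ({0, 1}, {2, 3}, 0.0),              # disjoint
        ({1, 2, 3}, {2, 3, 4, 5}, 0.4),     # |i|=2, |u|=5
        (set(), set(), 0.0),                # both all-zero: 0 by convention
        (set(), {1}, 0.0),
    ],
)
def test_tanimoto_worked_examples(a, b, expected):
    assert tanimoto(fp(a), fp(b)) == pytest.approx(expected)


def test_tanimoto_length_mismatch_rejected():
    with pytest.raises(ValidationError):
        tanimoto(fp({1}, 16), fp({1}, 17))


@given(
    st.lists(st.booleans(), min_size=16, max_size=16),
    st.lists(st.booleans(), min_size=16, max_size=16),
)
@settings(derandomize=True, max_examples=200)
def test_tanimoto_symmetric_bounded_reflexive(a_bits, b_bits):
    a, b = np.array(a_bits, np.uint8), np.array(b_bits, np.uint8)
    tab, tba = tanimoto(a, b), tanimoto(b, a)
    assert tab == tba
    assert 0.0 <= tab <= 1.0
    if a.any():
        assert tanimoto(a, a) == 1.0
    # equality attains 1 only for identical nonzero vectors
    if tab == 1.0:
        assert np.array_equal(a, b) and a.any()


# ---------------------------------------------------------------------------
# prediction


def _compound(cid, bits):
    return CompoundRecord(cid, cid, "herb01", fp(bits))


def test_identity_ligand_predicts_with_score_one():
    comp = _compound("C1", {1, 2, 3})
    target = TargetLigandSet("T1", [fp({9, 10}), fp({1, 2, 3})])
    records = predict_targets([comp], [target], 0.57)
    assert records == [CTIRecord("C1", "T1", "predicted", 1.0)]


def test_below_threshold_pair_not_emitted():
    # max Tc to every ligand is 2/5 = 0.4 < 0.57
    comp = _compound("C1", {1, 2, 3})
    target = TargetLigandSet("T1", [fp({2, 3, 4, 5})])
    assert predict_targets([comp], [target], 0.57) == []


def test_hand_built_pairs_match_direct_set_arithmetic():
    compounds = [
        _compound("C1", {0, 1, 2, 3}),
        _compound("C2", {4, 5}),
        _compound("C3", {0, 1}),
    ]
    ligand_sets = [
        TargetLigandSet("TA", [fp({0, 1, 2, 3}), fp({8, 9})]),  # C1: 1.0, C3: 0.5
        TargetLigandSet("TB", [fp({4, 5, 6})]),                 # C2: 2/3
    ]
    got = {
        (r.compound_id, r.target_id): r.score
        for r in predict_targets(compounds, ligand_sets, 0.57)
    }
    assert got == {("C1", "TA"): 1.0, ("C2", "TB"): pytest.approx(2 / 3)}


def test_prediction_agrees_with_bruteforce_oracle():
    rng = np.random.default_rng(42)
    compounds = [
        CompoundRecord(f"C{i}", f"c{i}", "h", (rng.random(24) < 0.4).astype(np.uint8))
        for i in range(50)
    ]
    ligand_sets = [
        TargetLigandSet(
            f"T{j}", [(rng.random(24) < 0.4).astype(np.uint8) for _ in range(3)]
        )
        for j in range(20)
    ]
    for threshold in (0.3, 0.57, 0.8):
        got = {
            (r.compound_id, r.target_id, round(r.score, 12))
            for r in predict_targets(compounds, ligand_sets, threshold)
        }
        assert got == brute_predict(compounds, ligand_sets, threshold)


def test_raising_threshold_never_adds_predictions():
    rng = np.random.default_rng(3)
    compounds = [
        CompoundRecord(f"C{i}", f"c{i}", "h", (rng.random(24) < 0.4).astype(np.uint8))
        for i in range(30)
    ]
    ligand_sets = [
        TargetLigandSet(f"T{j}", [(rng.random(24) < 0.4).astype(np.uint8)])
        for j in range(10)
    ]
    previous = None
    for threshold in (0.2, 0.4, 0.57, 0.7, 0.9):
        pairs = {r.key for r in predict_targets(compounds, ligand_sets, threshold)}
        if previous is not None:
            assert pairs <= previous
        previous = pairs


def test_empty_ligand_sets_rejected():
    with pytest.raises(ValidationError):
        predict_targets([_compound("C1", {1})], [], 0.57)
    with pytest.raises(ValidationError):
        predict_targets([_compound("C1", {1})], [TargetLigandSet("T", [])], 0.57)


# ---------------------------------------------------------------------------
# merge / overlap / drug sharing


def test_merge_collision_prefers_known_and_keeps_score():
    known = [CTIRecord("C1", "T1", "known")]
    predicted = [CTIRecord("C1", "T1", "predicted", 0.8)]
    merged = merge_cti(known, predicted)
    assert merged == [CTIRecord("C1", "T1", "known", 0.8)]


def test_merge_disjoint_is_union():
    known = [CTIRecord("C1", "T1", "known"), CTIRecord("C1", "T2", "known")]
    predicted = [
        CTIRecord("C2", "T1", "predicted", 0.9),
        CTIRecord("C2", "T3", "predicted", 0.7),
        CTIRecord("C3", "T1", "predicted", 0.6),
    ]
    assert len(merge_cti(known, predicted)) == 5


def test_merge_empty_predicted_is_identity():
    known = [CTIRecord("C1", "T1", "known")]
    assert merge_cti(known, []) == known


def test_disease_overlap_is_exact_intersection():
    assert overlap_with_disease({"A", "B", "C"}, {"B", "C", "D"}) == {"B", "C"}
    assert overlap_with_disease({"A"}, {"B"}) == set()
    assert overlap_with_disease({"A", "B"}, {"a", "b"}) == {"A", "B"}  # canonicalized


def test_drug_sharing_counts_sorting_and_omission():
    drugs = [
        DrugRecord("D1", "zeta", "NSAID", frozenset({"T1", "T2"})),
        DrugRecord("D2", "alpha", "DMARD", frozenset({"T2", "T3", "T4", "T9"})),
        DrugRecord("D3", "mid", "NSAID", frozenset({"T2", "T3", "T4"})),
        DrugRecord("D4", "none", "NSAID", frozenset({"X1"})),
    ]
    table = drug_sharing({"T1", "T2", "T3", "T4"}, drugs)
    # D4 shares nothing and is omitted; count descending, name breaks the tie
    assert list(table["drug_id"]) == ["D2", "D3", "D1"]
    assert list(table["shared_targets"]) == [3, 3, 2]
    assert "D4" not in set(table["drug_id"])


def test_drug_sharing_ties_break_by_name_ascending():
    drugs = [
        DrugRecord("D1", "zeta", "NSAID", frozenset({"T1", "T2"})),
        DrugRecord("D2", "alpha", "NSAID", frozenset({"T1", "T2"})),
    ]
    table = drug_sharing({"T1", "T2"}, drugs)
    assert list(table["name"]) == ["alpha", "zeta"]
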