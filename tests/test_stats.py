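import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_bh
from conftest import correlation_from_distance

from topofc import square_fixture
from topofc.data_io import GroupTable
from topofc.stats import (
    bh_fdr,
    compare_groups,
    mad_index,
    robustness_protocol,
    spearman,
    term_enrichment_null,
    two_sample_ttest,
)


# ------------------------------------------------------------------ t tests

def test_ttest_textbook_example():
    res = two_sample_ttest([1, 2, 3], [4, 5, 6])
    # pooled variance 1, se = sqrt(2/3), t = -3/se on 4 df
    assert res.t == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0), abs=1e-10)
    assert res.p == pytest.approx(0.021312, abs=1e-5)


def test_ttest_identical_samples():
    res = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t == 0.0 and res.p == pytest.approx(1.0)


def test_ttest_tail_convention():
    res = two_sample_ttest([0, 0.1, 0.2], [10, 10.1, 10.2], tail="less")
    assert res.p < 0.5
    res_gt = two_sample_ttest([0, 0.1, 0.2], [10, 10.1, 10.2], tail="greater")
    assert res_gt.p > 0.5


def test_ttest_degenerate_zero_variance():
    res = two_sample_ttest([2.0, 2.0], [2.0, 2.0])
    assert res.degenerate and res.t == 0.0 and res.p == 1.0
    res2 = two_sample_ttest([1.0, 1.0], [2.0, 2.0])
    assert res2.degenerate and res2.p == 0.0


def test_ttest_welch_differs_from_pooled():
    x, y = [1.0, 2.0, 3.0, 4.0], [10.0, 30.0]
    assert two_sample_ttest(x, y, variant="welch").t != pytest.approx(
        two_sample_ttest(x, y, variant="pooled").t
    )
    with pytest.raises(ValueError):
        two_sample_ttest([1.0], [2.0, 3.0])


# ---------------------------------------------------------------------- FDR

@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.5], [0.01, 0.5]),
        ([], []),
    ],
)
def test_bh_fdr_examples(p, expected):
    assert bh_fdr(np.array(p)).tolist() == pytest.approx(expected)


def test_bh_fdr_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_fdr_matches_step_up_definition(p):
    p = np.array(p)
    assert bh_fdr(p) == pytest.approx(brute_force_bh(p), abs=1e-12)
    assert (bh_fdr(p) >= p - 1e-15).all()


# ----------------------------------------------------------------- spearman

def test_spearman_examples():
    x = [1.0, 2.0, 5.0, 9.0]
    assert spearman(x, [2.0, 3.0, 8.0, 20.0])[0] == pytest.approx(1.0)
    assert spearman(x, [-1.0, -2.0, -3.0, -4.0])[0] == pytest.approx(-1.0)
    assert spearman([1, 2, 3, 4], [1, 3, 2, 4])[0] == pytest.approx(0.8)
    rho, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert math.isnan(rho)


# ---------------------------------------------------------------------- MAD

def test_mad_examples():
    assert mad_index([1, 2, 3, 4, 5]) == (1.0, pytest.approx(1.0 / 3.0))
    assert mad_index([7, 7, 7]) == (0.0, 0.0)
    mad, madm = mad_index([0, 0, 1])
    assert mad == 0.0 and math.isnan(madm)


@settings(max_examples=40, derandomize=True)
@given(
    v=st.lists(st.floats(-5, 5), min_size=1, max_size=20),
    shift=st.floats(-10, 10),
    scale=st.floats(0.1, 10),
)
def test_mad_shift_and_scale_invariance(v, shift, scale):
    v = np.array(v)
    mad, _ = mad_index(v)
    mad_shifted, _ = mad_index(v + shift)
    assert mad_shifted == pytest.approx(mad, abs=1e-9)
    _, madm = mad_index(np.abs(v) + 1.0)  # positive median
    _, madm_scaled = mad_index(scale * (np.abs(v) + 1.0))
    assert madm_scaled == pytest.approx(madm, rel=1e-9)


# ------------------------------------------------------------ group testing

def _measure_frame(values_by_subject, measure="m"):
    rows = [
        {"subject_id": s, "measure": measure, "feature": f, "value": v}
        for s, feats in values_by_subject.items()
        for f, v in feats.items()
    ]
    return pd.DataFrame(rows)


def test_compare_groups_single_feature_matches_raw():
    frame = _measure_frame(
        {"a1": {"f": 1.0}, "a2": {"f": 2.0}, "a3": {"f": 3.0},
         "b1": {"f": 4.0}, "b2": {"f": 5.0}, "b3": {"f": 6.0}}
    )
    groups = GroupTable({f"a{i}": "A" for i in (1, 2, 3)} | {f"b{i}": "B" for i in (1, 2, 3)})
    res = compare_groups(frame, groups)
    assert len(res) == 1
    assert res.p_adj.iloc[0] == pytest.approx(res.p_raw.iloc[0])
    assert res.direction.iloc[0] == "A<B"


def test_compare_groups_errors():
    frame = _measure_frame({"a": {"f": 1.0}, "b": {"f": 2.0}})
    with pytest.raises(ValueError):
        compare_groups(frame, GroupTable({"a": "A", "b": "B", "c": "C"}))
    with pytest.raises(ValueError):
        compare_groups(frame, GroupTable({"a": "A"}))


def test_compare_groups_null_calibration():
    """Under a global null, few replicates show any FDR-significant feature."""
    rng = np.random.default_rng(5)
    groups = GroupTable(
        {f"a{i}": "A" for i in range(10)} | {f"b{i}": "B" for i in range(10)}
    )
    hits = 0
    reps = 40
    for _ in range(reps):
        frame = _measure_frame(
            {
                s: {f"f{k}": rng.normal() for k in range(50)}
                for s in groups.membership
            }
        )
        res = compare_groups(frame, groups, alpha=0.05)
        hits += int(res.significant.any())
    assert hits / reps <= 0.10


# --------------------------------------------------------------- robustness

def test_robustness_identity_permutations_degenerate(square):
    C = correlation_from_distance(square.values)
    identity = np.arange(4)
    summ = robustness_protocol(
        [C], R=2, seed=0, permutations=[identity, identity]
    )
    assert (summ.per_node.mad_mean == 0).all()
    for mat in summ.spearman.values():
        assert np.allclose(mat, 1.0)


def test_robustness_square_order_invariant():
    """A single planted square gives NP = 1 on all nodes for any order."""
    C = correlation_from_distance(square_fixture().values)
    summ = robustness_protocol([C], R=3, seed=123)
    npn = summ.per_node[summ.per_node.measure == "node_persistence"]
    assert (npn.mad_mean == 0).all()
    assert np.allclose(summ.spearman["node_persistence"], 1.0)


def test_robustness_seeded_reproducibility(small_cohort):
    subjects, groups = small_cohort
    a = robustness_protocol(subjects[:4], R=3, seed=9)
    b = robustness_protocol(subjects[:4], R=3, seed=9)
    pd.testing.assert_frame_equal(a.per_node, b.per_node)
    for m in a.spearman:
        assert np.array_equal(a.spearman[m], b.spearman[m])


def test_robustness_validates_inputs(small_cohort):
    subjects, _ = small_cohort
    with pytest.raises(ValueError):
        robustness_protocol(subjects[:2], R=1, seed=0)
    with pytest.raises(ValueError):
        robustness_protocol([], R=2, seed=0)


# --------------------------------------------------------------- enrichment

def test_enrichment_degenerate_everywhere_term():
    ann = {f"n{i}": {"T"} for i in range(10)}
    res = term_enrichment_null(ann, {"n0", "n1"}, B=200, seed=1)
    assert math.isnan(res.Z.iloc[0])


def test_enrichment_planted_term_detected():
    ann = {f"n{i}": {"bg"} for i in range(40)}
    for i in range(5):
        ann[f"n{i}"] = {"planted", "bg"}
    res = term_enrichment_null(ann, {f"n{i}" for i in range(5)}, B=1000, seed=2)
    row = res.set_index("term").loc["planted"]
    assert row.Z > 0 and row.p < 0.05


def test_enrichment_whole_universe_is_null():
    ann = {f"n{i}": {"T"} if i < 3 else {"U"} for i in range(6)}
    res = term_enrichment_null(ann, set(ann), B=200, seed=3)
    assert (res.Z == 0).all()


def test_enrichment_validates():
    ann = {"a": {"T"}, "b": {"U"}}
    with pytest.raises(ValueError):
        term_enrichment_null(ann, set(), B=200, seed=0)
    with pytest.raises(ValueError):
        term_enrichment_null(ann, {"z"}, B=200, seed=0)
    with pytest.raises(ValueError):
        term_enrichment_null(ann, {"a"}, B=10, seed=0)
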