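"""Scoring: normalization chains, A/D scores, EGF filter, RMSE oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egfrda.scoring import (
    MUTANT,
    WT,
    ScoreError,
    activation_score,
    combine_replicates,
    deviation_score,
    filter_egf_dependent,
    normalize_to_reference,
    prepare_for_fitting,
    rmse,
    rmse_per_protein,
    score_table,
    self_normalize,
)

from conftest import table_from_dict

GRID = (0.0, 1.0, 5.0, 20.0)


class TestNormalization:
    def test_divides_by_wt_anchor(self):
        t = table_from_dict({("p1", WT): (1.2, 2.0, 1.6)}, (1, 5, 20))
        out = normalize_to_reference(t)
        np.testing.assert_allclose(out.series("p1", WT), (0.6, 1.0, 0.8))

    def test_idempotent(self):
        t = table_from_dict({("p1", WT): (1.2, 2.0, 1.6),
                             ("p1", MUTANT): (0.4, 1.0, 2.0)}, (1, 5, 20))
        once = normalize_to_reference(t)
        twice = normalize_to_reference(once)
        assert once.data.equals(twice.data)

    def test_missing_anchor_falls_back_to_1min(self):
        t = table_from_dict({("p1", WT): (2.0, np.nan, 4.0)}, (1, 5, 20))
        out = normalize_to_reference(t)
        np.testing.assert_allclose(out.series("p1", WT), (1.0, np.nan, 2.0))
        assert any(f.startswith("anchor_fallback:1") for f in out.flags["p1"])

    def test_all_anchors_missing_drops_protein(self):
        t = table_from_dict({("p1", WT): (np.nan, np.nan, np.nan),
                             ("p2", WT): (1.0, 2.0, 4.0)}, (1, 5, 20))
        out = normalize_to_reference(t)
        assert out.proteins == ["p2"]


class TestCombineReplicates:
    def test_quoted_arithmetic_example(self):
        """rep1 (2,2,4) and rep2 (1,1,2) with 5-min anchor, ratio 1.5 ->
        (1.5, 1.5, 3.0)."""
        rep1 = table_from_dict({("p1", MUTANT): (2.0, 2.0, 4.0)}, (1, 5, 20))
        rep2 = table_from_dict({("p1", MUTANT): (1.0, 1.0, 2.0)}, (1, 5, 20))
        out = combine_replicates(rep1, rep2, {"p1": 1.5})
        np.testing.assert_allclose(out.series("p1", MUTANT), (1.5, 1.5, 3.0))

    def test_identical_replicates(self):
        rep = table_from_dict({("p1", MUTANT): (1.0, 2.0, 3.0)}, (1, 5, 20))
        out = combine_replicates(rep, rep.copy(), {"p1": 2.0})
        np.testing.assert_allclose(out.series("p1", MUTANT),
                                   np.array([1.0, 2.0, 3.0]) / 2.0 * 2.0)

    def test_unit_ratio_gives_mean_of_self_normalized(self):
        rep1 = table_from_dict({("p1", MUTANT): (2.0, 4.0, 2.0)}, (1, 5, 20))
        rep2 = table_from_dict({("p1", MUTANT): (3.0, 3.0, 3.0)}, (1, 5, 20))
        out = combine_replicates(rep1, rep2, {"p1": 1.0})
        np.testing.assert_allclose(out.series("p1", MUTANT),
                                   [(0.5 + 1.0) / 2, 1.0, (0.5 + 1.0) / 2])

    def test_missing_anchor_uses_fallback(self):
        rep1 = table_from_dict({("p1", MUTANT): (2.0, 4.0, 2.0)}, (1, 5, 20))
        rep2 = table_from_dict({("p1", MUTANT): (3.0, np.nan, 3.0)}, (1, 5, 20))
        out = combine_replicates(rep1, rep2, {"p1": 1.0})
        # rep2 self-normalizes by its 1-min value instead
        np.testing.assert_allclose(out.series("p1", MUTANT)[0], (0.5 + 1.0) / 2)
        assert any("anchor_fallback" in f for f in out.flags["p1"])


class TestActivationScore:
    def test_identical_profiles(self):
        t = table_from_dict({("p1", WT): (0, 1, 1, 1),
                             ("p1", MUTANT): (0, 1, 1, 1)}, GRID)
        assert activation_score(t, "p1") == pytest.approx(1.0)

    def test_doubled_profile(self):
        t = table_from_dict({("p1", WT): (0, 1, 1, 1),
                             ("p1", MUTANT): (0, 2, 2, 2)}, GRID)
        assert activation_score(t, "p1") == pytest.approx(2.0)

    def test_zero_wt_area_is_an_error(self):
        t = table_from_dict({("p1", WT): (0, 0, 0, 0),
                             ("p1", MUTANT): (0, 1, 1, 1)}, GRID)
        with pytest.raises(ScoreError, match="undefined"):
            activation_score(t, "p1")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 10), mut_fold=st.floats(0.2, 5))
    def test_common_rescaling_invariance(self, scale, mut_fold):
        wt = np.array([0.2, 1.0, 1.0, 0.7])
        t1 = table_from_dict({("p1", WT): wt, ("p1", MUTANT): mut_fold * wt}, GRID)
        t2 = table_from_dict({("p1", WT): scale * wt,
                              ("p1", MUTANT): scale * mut_fold * wt}, GRID)
        assert activation_score(t1, "p1") == pytest.approx(
            activation_score(t2, "p1"))
        assert activation_score(t1, "p1") == pytest.approx(mut_fold)


class TestDeviationScore:
    def test_hand_rms(self):
        """Self-normalized (0,1,1,1) vs (0,1,1,3) -> sqrt(4/4) = 1."""
        t = table_from_dict({("p1", WT): (0, 1, 1, 1),
                             ("p1", MUTANT): (0, 1, 1, 3)}, GRID)
        assert deviation_score(t, "p1") == pytest.approx(1.0)

    def test_sum_variant(self):
        t = table_from_dict({("p1", WT): (0, 1, 1, 1),
                             ("p1", MUTANT): (0, 1, 1, 3)}, GRID)
        assert deviation_score(t, "p1", form="sum") == pytest.approx(2.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(c=st.floats(0.05, 20))
    def test_proportional_profiles_have_zero_deviation(self, c):
        wt = np.array([0.3, 0.9, 1.0, 0.6])
        t = table_from_dict({("p1", WT): wt, ("p1", MUTANT): c * wt}, GRID)
        assert deviation_score(t, "p1") == pytest.approx(0.0, abs=1e-12)


class TestEgfFilter:
    def test_constant_profiles_are_dropped(self):
        t = table_from_dict({("p1", WT): (1, 1, 1, 1),
                             ("p1", MUTANT): (1, 1, 1, 1)}, GRID)
        assert filter_egf_dependent(t) == []

    def test_threshold_boundary_is_inclusive(self):
        t = table_from_dict({("p1", WT): (1.0, 1.6, 1.0)}, (0, 5, 20))
        assert filter_egf_dependent(t, 1.5) == ["p1"]
        assert filter_egf_dependent(t, 1.61) == []

    def test_either_condition_suffices(self):
        t = table_from_dict({("p1", WT): (1, 1, 1, 1),
                             ("p1", MUTANT): (1, 3, 3, 1)}, GRID)
        assert filter_egf_dependent(t) == ["p1"]

    def test_single_time_point_excluded(self):
        t = table_from_dict({("p1", WT): (np.nan, np.nan, 2.0, np.nan)}, GRID)
        assert filter_egf_dependent(t) == []

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.2, 5.0), min_size=4, max_size=4),
           st.floats(1.0, 3.0), st.floats(0.0, 2.0))
    def test_monotone_in_threshold(self, vals, thr_lo, delta):
        t = table_from_dict({("p1", WT): vals}, GRID)
        hi = set(filter_egf_dependent(t, thr_lo + delta))
        lo = set(filter_egf_dependent(t, thr_lo))
        assert hi <= lo


class TestPrepareForFitting:
    def test_three_step_chain(self):
        """WT (0.5, 2.0) at (0, 5) -> (0.25,1.0) -> (0,0.75) -> (0,1.0)."""
        t = table_from_dict({("p1", WT): (0.5, 2.0)}, (0, 5))
        out = prepare_for_fitting(t)
        np.testing.assert_allclose(out.series("p1", WT), (0.0, 1.0))

    def test_zero_baseline_makes_subtraction_a_noop(self):
        t = table_from_dict({("p1", WT): (0.0, 1.0, 2.0, 1.0)}, GRID)
        out = prepare_for_fitting(t)
        np.testing.assert_allclose(out.series("p1", WT), (0.0, 0.5, 1.0, 0.5))

    def test_constant_profile_flagged_unusable(self):
        t = table_from_dict({("p1", WT): (1.0, 1.0, 1.0, 1.0)}, GRID)
        out = prepare_for_fitting(t)
        assert "unusable_for_fitting" in out.flags["p1"]

    def test_mutant_shares_wt_denominator(self):
        t = table_from_dict({("p1", WT): (0.0, 1.0, 2.0, 1.0),
                             ("p1", MUTANT): (0.0, 2.0, 4.0, 6.0)}, GRID)
        out = prepare_for_fitting(t)
        np.testing.assert_allclose(out.series("p1", MUTANT), (0, 1, 2, 3))


class TestRmse:
    def test_perfect_fit(self):
        t = table_from_dict({("p1", WT): (0.0, 1.0, 2.0, 1.0)}, GRID)
        assert rmse({"p1": (0.0, 1.0, 2.0, 1.0)}, t, WT) == 0.0

    def test_constant_residual(self):
        t = table_from_dict({("p1", WT): (0.0, 1.0, 2.0, 1.0)}, GRID)
        sim = np.array([0.0, 1.0, 2.0, 1.0]) + 0.5
        assert rmse({"p1": sim}, t, WT) == pytest.approx(0.5)

    def test_two_point_hand_value(self):
        t = table_from_dict({("p1", WT): (0.0, 1.0)}, (0, 5))
        assert rmse({"p1": (0.3, 1.4)}, t, WT) == pytest.approx(
            math.sqrt((0.3 ** 2 + 0.4 ** 2) / 2), abs=1e-6)

    def test_missing_points_excluded(self):
        t = table_from_dict({("p1", WT): (0.0, np.nan, 2.0, np.nan)}, GRID)
        assert rmse({"p1": (0.1, 99.0, 2.1, 99.0)}, t, WT) == pytest.approx(
            0.1, abs=1e-9)

    def test_per_protein_breakdown_pools_to_overall(self):
        t = table_from_dict({("p1", WT): (0.0, 1.0, 1.0, 1.0),
                             ("p2", WT): (0.0, 2.0, 2.0, 2.0)}, GRID)
        sim = {"p1": (0.1, 1.1, 1.1, 1.1), "p2": (0.3, 2.3, 2.3, 2.3)}
        per = rmse_per_protein(sim, t, WT)
        assert per["p1"] == pytest.approx(0.1)
        assert per["p2"] == pytest.approx(0.3)
        pooled = math.sqrt((4 * 0.1 ** 2 + 4 * 0.3 ** 2) / 8)
        assert rmse(sim, t, WT) == pytest.approx(pooled)

    def test_no_overlap_is_an_error(self):
        t = table_from_dict({("p1", WT): (np.nan,) * 4}, GRID)
        with pytest.raises(ScoreError):
            rmse({"p1": (0, 0, 0, 0)}, t, WT)


class TestScoreTable:
    def test_columns_and_flags(self):
        t = table_from_dict({("p1", WT): (0.5, 1.0, 1.0, 1.0),
                             ("p1", MUTANT): (0.5, 2.0, 2.0, 2.0),
                             ("p2", WT): (1.0, 1.0, 1.0, 1.0),
                             ("p2", MUTANT): (1.0, 1.0, 1.0, 1.0)}, GRID)
        df = score_table(t).set_index("protein_id")
        assert list(df.columns) == ["A", "log2_A", "D", "egf_dependent"]
        assert bool(df.loc["p1", "egf_dependent"])
        assert not bool(df.loc["p2", "egf_dependent"])
        assert df.loc["p2", "A"] == pytest.approx(1.0)
        assert df.loc["p1", "log2_A"] == pytest.approx(
            math.log2(df.loc["p1", "A"]))
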