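import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressrep import (
    CurveMatrix,
    MetricError,
    StressCurveDataset,
    count_crossings,
    fill_missing_replicates,
    hpa_flexibility_score,
    kl_divergence_score,
    profile_repeatability,
    score_dataset,
)
from stressrep.metrics import generalized_kl, max_crossings

from .conftest import random_complete_curve


def brute_force_crossings(values):
    """Independent oracle: exhaustive pair x interval sign enumeration."""
    n_rep, n_time = values.shape
    count = 0
    for i in range(n_rep):
        for j in range(i + 1, n_rep):
            for t in range(n_time - 1):
                d0 = values[i, t] - values[j, t]
                d1 = values[i, t + 1] - values[j, t + 1]
                if d0 * d1 < 0:
                    count += 1
    return count


class TestFillMissing:
    def test_interior_midpoint(self):
        # rep2 missing at one timepoint between rep1=2 and rep3=6
        cm = CurveMatrix("a", [0, 30], [[2, 1], [np.nan, 1], [6, 1]])
        filled, m = fill_missing_replicates(cm)
        assert m == 1
        assert filled.values[1, 0] == 4.0

    def test_missing_first_replicate_uses_cyclic_mean(self):
        # rep1 missing, rep2=4, rep3=8: fill = mean(last present 8, next present 4)
        cm = CurveMatrix("a", [0, 30], [[np.nan, 1], [4, 1], [8, 1]])
        filled, m = fill_missing_replicates(cm)
        assert m == 1
        assert filled.values[0, 0] == 6.0

    def test_missing_last_replicate_uses_cyclic_mean(self):
        cm = CurveMatrix("a", [0, 30], [[4, 1], [8, 1], [np.nan, 1]])
        filled, _ = fill_missing_replicates(cm)
        assert filled.values[2, 0] == 6.0

    def test_unequal_gaps_interpolate_linearly(self):
        # reps 1 and 4 present (values 0 and 9); reps 2, 3 missing
        col = [0.0, np.nan, np.nan, 9.0]
        cm = CurveMatrix("a", [0, 30], np.column_stack([col, [1, 1, 1, 1]]))
        filled, m = fill_missing_replicates(cm)
        assert m == 2
        np.testing.assert_allclose(filled.values[:, 0], [0, 3, 6, 9])

    def test_complete_matrix_identity(self, parallel_curve):
        filled, m = fill_missing_replicates(parallel_curve)
        assert m == 0
        np.testing.assert_array_equal(filled.values, parallel_curve.values)


class TestCountCrossings:
    def test_parallel_curves_no_crossings(self, parallel_curve):
        assert count_crossings(parallel_curve) == 0

    def test_single_crossing(self, crossing_curve):
        # d goes -2 -> +2 over the single interval
        assert count_crossings(crossing_curve) == 1

    def test_three_replicate_example(self):
        cm = CurveMatrix("a", [0, 15, 30], [[1, 5, 1], [3, 3, 3], [5, 1, 5]])
        assert count_crossings(cm) == 6
        assert count_crossings(cm) == brute_force_crossings(cm.values)

    def test_touching_is_not_a_crossing(self):
        cm = CurveMatrix("a", [0, 15, 30], [[1, 2, 1], [2, 2, 2]])
        assert count_crossings(cm) == 0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        curve = random_complete_curve(rng)
        assert count_crossings(curve) == brute_force_crossings(curve.values)

    def test_max_crossings_formula(self):
        assert max_crossings(2, 2) == 1
        assert max_crossings(4, 4) == 18


class TestProfileRepeatability:
    def test_identical_replicates_score_one(self):
        cm = CurveMatrix("a", [0, 15, 30], [[1, 5, 2]] * 4)
        score, detail = profile_repeatability(cm)
        assert score == 1.0
        assert detail.raw_dispersion == 0.0
        assert detail.crossings == 0

    def test_parallel_hand_computed(self, parallel_curve):
        # G=5, each column variance 2 -> v=0.08; S = 0.16; PR = 1/1.16
        score, detail = profile_repeatability(parallel_curve)
        assert score == pytest.approx(1 / 1.16)
        np.testing.assert_allclose(detail.per_time_variance, [0.08, 0.08])
        assert detail.crossings == 0

    def test_crossing_lowers_score(self, parallel_curve, crossing_curve):
        # same values rearranged to cross: S doubles to 0.32
        score, detail = profile_repeatability(crossing_curve)
        assert detail.crossings == 1
        assert detail.max_crossings == 1
        assert score == pytest.approx(1 / 1.32)
        assert score < profile_repeatability(parallel_curve)[0]

    def test_score_in_unit_interval_random(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            score, _ = profile_repeatability(random_complete_curve(rng))
            assert 0.0 < score <= 1.0

    def test_score_one_only_for_identical(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            curve = random_complete_curve(rng)
            score, _ = profile_repeatability(curve)
            identical = not np.ptp(curve.values, axis=0).any()
            assert (score == 1.0) == identical

    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(min_value=0, max_value=2**32 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        curve = random_complete_curve(rng)
        scaled = CurveMatrix(curve.individual_id, curve.times, curve.values * scale)
        s0, _ = profile_repeatability(curve)
        s1, _ = profile_repeatability(scaled)
        assert s1 == pytest.approx(s0, rel=1e-9)

    def test_monotone_decrease_under_growing_noise(self):
        rng = np.random.default_rng(42)
        base = np.tile([5.0, 20.0, 30.0, 15.0], (4, 1))
        times = [0.0, 10.0, 20.0, 30.0]
        noise = rng.normal(size=base.shape)
        scores = []
        for sigma in [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]:
            values = np.maximum(0.1, base + sigma * noise)
            scores.append(profile_repeatability(CurveMatrix("a", times, values))[0])
        assert all(b <= a for a, b in zip(scores, scores[1:]))
        assert scores[-1] < scores[0]

    def test_interpolation_penalty_applied(self):
        complete = CurveMatrix("a", [0, 30], [[4, 10], [5, 11], [6, 12]])
        with_gap = CurveMatrix("a", [0, 30], [[4, 10], [np.nan, 11], [6, 12]])
        s_complete, _ = profile_repeatability(complete)
        s_gap, detail = profile_repeatability(with_gap)
        assert detail.n_interpolated == 1
        # filled value equals the original, so only the penalty differs
        assert s_gap < s_complete

    def test_zero_grand_mean_rejected(self):
        cm = CurveMatrix("a", [0, 30], [[-1, 1], [1, -1]])
        with pytest.raises(MetricError, match="grand mean"):
            profile_repeatability(cm)

    def test_missing_cells_raise_score_below_complete_twin(self):
        rng = np.random.default_rng(9)
        curve = random_complete_curve(rng, n_rep=5, n_time=3)
        values = curve.values.copy()
        values[2, 1] = np.nan
        gappy = CurveMatrix("a", curve.times, values)
        _, detail = profile_repeatability(gappy)
        assert detail.n_interpolated == 1


class TestKlDivergence:
    def test_identical_curves_zero(self):
        cm = CurveMatrix("a", [0, 30], [[2, 3], [2, 3], [2, 3]])
        score, detail = kl_divergence_score(cm)
        assert score == 0.0
        np.testing.assert_array_equal(detail.pairwise_divergences, [0.0, 0.0])

    def test_two_replicate_example(self):
        # p=(1,2), q=(2,1): D = 1*ln(1/2)+2*ln(2/1) = ln 2 (sums equal)
        cm = CurveMatrix("a", [0, 30], [[1, 2], [2, 1]])
        score, _ = kl_divergence_score(cm)
        assert score == pytest.approx(math.log(2))

    def test_order_asymmetry(self):
        forward = CurveMatrix("a", [0, 30], [[1, 3], [2, 2]])
        backward = CurveMatrix("a", [0, 30], [[2, 2], [1, 3]])
        s_fwd, _ = kl_divergence_score(forward)
        s_bwd, _ = kl_divergence_score(backward)
        assert s_fwd == pytest.approx(math.log(0.5) + 3 * math.log(1.5))
        assert s_bwd == pytest.approx(2 * math.log(2) + 2 * math.log(2 / 3))
        assert s_fwd != pytest.approx(s_bwd)

    def test_nonnegative_on_random_curves(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            score, detail = kl_divergence_score(random_complete_curve(rng))
            assert score >= 0.0
            assert (detail.pairwise_divergences >= 0.0).all()

    def test_plain_kl_would_be_negative_here(self):
        # witness for the -p+q correction: same shapes, unequal masses
        p, q = np.array([1.0, 1.0]), np.array([3.0, 3.0])
        assert np.sum(p * np.log(p / q)) < 0
        assert generalized_kl(p, q) > 0

    def test_nonpositive_value_names_cell(self):
        cm = CurveMatrix("a", [0, 30], [[1, 2], [0.0, 3]])
        with pytest.raises(MetricError, match="replicate 2"):
            kl_divergence_score(cm)

    def test_missing_cell_rejected(self):
        cm = CurveMatrix("a", [0, 30], [[1, np.nan], [2, 3], [4, 5]])
        with pytest.raises(MetricError, match="missing"):
            kl_divergence_score(cm)


class TestHpaFlexibility:
    def test_equal_means_zero(self):
        cm = CurveMatrix("a", [0, 30], [[1, 3], [2, 2], [3, 1]])
        score, detail = hpa_flexibility_score(cm)
        assert score == 0.0
        np.testing.assert_array_equal(detail.replicate_means, [2, 2, 2])

    def test_closed_form_example(self):
        # replicate means (1, 2, 4) -> sqrt((1+4)/2) = sqrt(2.5)
        cm = CurveMatrix("a", [0, 30], [[1, 1], [2, 2], [4, 4]])
        score, _ = hpa_flexibility_score(cm)
        assert score == pytest.approx(math.sqrt(2.5))

    def test_order_sensitivity(self):
        reordered = CurveMatrix("a", [0, 30], [[1, 1], [4, 4], [2, 2]])
        score, _ = hpa_flexibility_score(reordered)
        assert score == pytest.approx(math.sqrt(6.5))
        assert score != pytest.approx(math.sqrt(2.5))

    @given(
        means=st.lists(
            st.floats(min_value=0.1, max_value=100.0), min_size=2, max_size=10
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_oracle(self, means):
        values = np.repeat(np.asarray(means)[:, None], 2, axis=1)
        cm = CurveMatrix("a", [0, 30], values)
        score, _ = hpa_flexibility_score(cm)
        expected = math.sqrt(
            sum((b - a) ** 2 for a, b in zip(means, means[1:])) / (len(means) - 1)
        )
        assert score == pytest.approx(expected)

    def test_missing_cell_rejected(self):
        cm = CurveMatrix("a", [0, 30], [[1, np.nan], [2, 3], [4, 5]])
        with pytest.raises(MetricError, match="missing"):
            hpa_flexibility_score(cm)


class TestScoreDataset:
    def test_row_count(self, synthetic_style_dataset):
        table = score_dataset(synthetic_style_dataset)
        assert len(table) == 33
        assert set(table["metric"]) == {"PR", "KL", "RMSSD"}

    def test_deterministic(self, synthetic_style_dataset):
        a = score_dataset(synthetic_style_dataset)
        b = score_dataset(synthetic_style_dataset)
        assert a.equals(b)

    def test_pr_tolerates_missing(self):
        curves = (
            CurveMatrix("a", [0, 30], [[1, np.nan], [2, 3], [4, 5]]),
            CurveMatrix("b", [0, 30], [[1, 2], [2, 3], [4, 5]]),
        )
        ds = StressCurveDataset("m", curves)
        table = score_dataset(ds, ["PR"])
        assert len(table) == 2

    def test_kl_on_missing_names_individual(self):
        curves = (
            CurveMatrix("a", [0, 30], [[1, np.nan], [2, 3], [4, 5]]),
            CurveMatrix("b", [0, 30], [[1, 2], [2, 3], [4, 5]]),
        )
        ds = StressCurveDataset("m", curves)
        with pytest.raises(MetricError, match="'a'"):
            score_dataset(ds, ["PR", "KL"])

    def test_unknown_metric_rejected(self, small_dataset):
        with pytest.raises(MetricError, match="unknown metric"):
            score_dataset(small_dataset, ["PR", "XX"])
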