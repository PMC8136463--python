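"""Consensus construction and agreement statistics against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import special

from echodim import (
    DimensionAgreement,
    abs_quantiles,
    bias_and_precision,
    consensus_reference,
    cumulative_error_curve,
    f_test_sd,
    icc_absolute_agreement,
    per_expert_measurement,
    wilcoxon_abs_errors,
)
from echodim.stats import signed_deviations


class TestPerExpertAndConsensus:
    @pytest.mark.parametrize(
        "readings, expected",
        [([40.0, 42.0], 41.0), ([40.0, np.nan], 40.0), ([np.nan, np.nan], np.nan)],
    )
    def test_per_expert_median_of_available_readings(self, readings, expected):
        got = per_expert_measurement(readings)
        assert got == pytest.approx(expected) if not np.isnan(expected) else np.isnan(got)

    @pytest.mark.parametrize(
        "values, expected",
        [([39.0, 40.0, 42.0], 40.0), ([39.0, 40.0, 42.0, 44.0], 41.0)],
    )
    def test_consensus_median_conventions(self, values, expected):
        assert consensus_reference(values) == pytest.approx(expected)

    def test_consensus_permutation_invariant_and_bounded(self, rng):
        vals = list(rng.normal(45, 5, 9))
        ref = consensus_reference(vals)
        for perm in itertools.islice(itertools.permutations(vals), 50):
            assert consensus_reference(list(perm)) == ref
        assert min(vals) <= ref <= max(vals)

    def test_consensus_requires_min_experts(self):
        assert np.isnan(consensus_reference([40.0, 41.0], min_experts=3))

    def test_breakdown_fewer_than_half_corrupted(self, rng):
        """Corrupting < half the experts keeps the median in the clean range."""
        clean = list(rng.normal(45, 2, 7))
        for corrupt in ([1e6] * 3, [-1e6, 1e6, 1e6], [1e9] * 2):
            ref = consensus_reference(clean + list(corrupt))
            assert min(clean) <= ref <= max(clean)


class TestSignedDeviations:
    def test_worked_example_plus_two_mm(self):
        """AI reads LVID 41 mm where consensus is 39 mm: deviation +2 mm."""
        methods = pd.DataFrame(
            {
                "frame_id": ["f1"],
                "method_id": ["AI"],
                "phase": ["ED"],
                "dimension": ["lvid"],
                "measurement_mm": [41.0],
            }
        )
        reference = pd.DataFrame({"lvid_mm": [39.0]}, index=pd.Index(["f1"], name="frame_id"))
        dev, n_excluded = signed_deviations(methods, reference)
        assert dev["signed_deviation_mm"].iloc[0] == 2.0
        assert n_excluded == 0

    def test_missing_measurement_excluded_and_counted(self):
        methods = pd.DataFrame(
            {
                "frame_id": ["f1", "f2"],
                "method_id": ["AI", "AI"],
                "phase": ["ED", "ED"],
                "dimension": ["lvid", "lvid"],
                "measurement_mm": [41.0, np.nan],
            }
        )
        reference = pd.DataFrame(
            {"lvid_mm": [39.0, 40.0]}, index=pd.Index(["f1", "f2"], name="frame_id")
        )
        dev, n_excluded = signed_deviations(methods, reference)
        assert len(dev) == 1 and n_excluded == 1


class TestBiasPrecisionQuantiles:
    def test_closed_form_pair(self):
        bias, sd = bias_and_precision([2.0, -2.0])
        assert bias == 0.0
        assert sd == pytest.approx(np.sqrt(8.0))  # n-1 denominator

    def test_all_zero(self):
        assert bias_and_precision([0.0, 0.0, 0.0]) == (0.0, 0.0)

    def test_translation_shifts_bias_not_sd(self, rng):
        d = rng.normal(0, 2, 50)
        b0, s0 = bias_and_precision(d)
        b1, s1 = bias_and_precision(d + 3.5)
        assert b1 == pytest.approx(b0 + 3.5)
        assert s1 == pytest.approx(s0)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            bias_and_precision([1.0])

    def test_quantile_linear_interpolation(self):
        q = abs_quantiles([-1.0, 2.0, -3.0, 4.0], probs=(0.5, 1.0))
        assert q[0] == pytest.approx(2.5)  # halfway between order stats 2 and 3
        assert q[1] == 4.0

    def test_single_value_any_probability(self):
        np.testing.assert_allclose(abs_quantiles([3.0]), [3.0] * 4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            abs_quantiles([])

    def test_quantiles_nondecreasing(self, rng):
        q = abs_quantiles(rng.normal(0, 3, 101))
        assert (np.diff(q) >= 0).all()


class TestCumulativeErrorCurve:
    def test_constant_sample_steps_to_one(self):
        fracs, errs = cumulative_error_curve([1.0, 1.0, 1.0, 1.0])
        assert fracs[-1] == 1.0
        np.testing.assert_allclose(errs, 1.0)

    def test_curve_nondecreasing_both_axes(self, rng):
        fracs, errs = cumulative_error_curve(rng.normal(0, 2, 40))
        assert (np.diff(fracs) >= 0).all() and (np.diff(errs) >= 0).all()

    def test_median_consistent_with_abs_quantiles(self, rng):
        d = rng.normal(0, 2, 39)
        fracs, errs = cumulative_error_curve(d)
        interp = np.interp(0.5, fracs, errs)
        assert interp == pytest.approx(abs_quantiles(d, probs=(0.5,))[0])


def _hand_anova_icc2(data: np.ndarray) -> float:
    """Independent oracle: ICC(2,1) from explicit mean-squares definitions."""
    n, k = data.shape
    grand = data.mean()
    msr = k * sum((data[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((data[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (data[i, j] - data[i].mean() - data[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    WORKED = np.array(
        [[40.0, 41.0], [35.0, 36.5], [52.0, 50.0], [47.0, 47.5], [44.0, 42.0], [38.0, 39.0]]
    )

    def test_matches_hand_anova_on_worked_table(self):
        icc, lo, hi = icc_absolute_agreement(self.WORKED[:, 0], self.WORKED[:, 1])
        assert icc == pytest.approx(_hand_anova_icc2(self.WORKED), abs=1e-12)
        assert lo <= icc <= hi

    def test_matches_pingouin_cross_check(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(47, 6.4, 40)
        y = x + rng.normal(0, 3.5, 40)
        icc, lo, hi = icc_absolute_agreement(x, y)
        data = pd.DataFrame(
            {
                "target": np.tile(np.arange(40), 2),
                "rater": np.repeat(["m", "r"], 40),
                "score": np.concatenate([x, y]),
            }
        )
        row = (
            pg.intraclass_corr(data=data, targets="target", raters="rater", ratings="score")
            .set_index("Type")
            .loc["ICC(A,1)"]
        )
        assert icc == pytest.approx(float(row["ICC"]), abs=1e-10)
        # pingouin stores its CI rounded to 2 decimals
        assert lo == pytest.approx(row["CI95"][0], abs=0.005)
        assert hi == pytest.approx(row["CI95"][1], abs=0.005)

    def test_identical_columns_give_one(self, rng):
        x = rng.normal(47, 6.4, 20)
        icc, _, _ = icc_absolute_agreement(x, x)
        assert icc == pytest.approx(1.0)

    def test_noise_dominated_near_zero(self, rng):
        x = rng.normal(0, 1, 200)
        y = x + rng.normal(0, 50, 200)
        icc, _, _ = icc_absolute_agreement(x, y)
        assert abs(icc) < 0.2

    def test_monotone_in_noise_level(self, rng):
        truth = rng.normal(47, 6.4, 80)
        iccs = []
        for sd in (1.0, 3.0, 8.0):
            noisy = truth + rng.normal(0, sd, 80)
            iccs.append(icc_absolute_agreement(noisy, truth)[0])
        assert iccs[0] > iccs[1] > iccs[2]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute_agreement([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])


class TestFTest:
    def test_equal_samples_f_one_p_one(self, rng):
        d = rng.normal(0, 2, 15)
        f, p = f_test_sd(d, d)
        assert f == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_p_matches_f_distribution_oracle(self, rng):
        """Two-sided p equals 2*min(tails) of the F CDF via the beta function."""
        a = rng.normal(0, 2, 10)
        b = rng.normal(0, 1, 10)
        f, p = f_test_sd(a, b)
        d1 = d2 = 9
        cdf = special.betainc(d1 / 2, d2 / 2, d1 * f / (d1 * f + d2))
        assert p == pytest.approx(2 * min(cdf, 1 - cdf), rel=1e-9)

    def test_swapping_samples_inverts_f_keeps_p(self, rng):
        a = rng.normal(0, 3, 12)
        b = rng.normal(0, 1, 20)
        f_ab, p_ab = f_test_sd(a, b)
        f_ba, p_ba = f_test_sd(b, a)
        assert f_ab == pytest.approx(1 / f_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_zero_denominator_variance_rejected(self):
        with pytest.raises(ValueError):
            f_test_sd([1.0, 2.0], [3.0, 3.0])

    def test_type_one_error_rate_near_alpha(self, rng):
        """Equal-SD samples: rejection at alpha=0.05 in 5% +/- 2% of 2000 runs."""
        rejections = 0
        for _ in range(2000):
            a = rng.normal(0, 1.7, 25)
            b = rng.normal(0, 1.7, 25)
            _, p = f_test_sd(a, b)
            rejections += p < 0.05
        assert 0.03 <= rejections / 2000 <= 0.07


def _exact_wilcoxon_p(d: np.ndarray) -> float:
    """Oracle: enumerate all sign assignments of the ranked |differences|."""
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.asarray(ws)
    p = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(1.0, p)


class TestWilcoxon:
    def test_six_positive_differences_exact(self):
        d = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        w, p = wilcoxon_abs_errors(d)
        assert w == 21.0
        assert p == pytest.approx(0.03125)
        assert p == pytest.approx(_exact_wilcoxon_p(d))

    def test_enumeration_oracle_mixed_signs(self):
        d = np.array([1.2, -0.4, 2.1, -3.0, 0.9, 1.7, -0.2])
        _, p = wilcoxon_abs_errors(d)
        assert p == pytest.approx(_exact_wilcoxon_p(d), rel=1e-9)

    def test_antisymmetric_differences_centered(self):
        d = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        w, p = wilcoxon_abs_errors(d)
        assert w == pytest.approx(10.5)  # n(n+1)/4, the null centre
        assert p > 0.9

    def test_scale_invariance(self, rng):
        d = rng.normal(0.5, 1, 18)
        _, p1 = wilcoxon_abs_errors(d)
        _, p2 = wilcoxon_abs_errors(d * 7.3)
        assert p1 == pytest.approx(p2)

    def test_zeros_dropped_all_zero_rejected(self):
        w, p = wilcoxon_abs_errors(np.array([0.0, 0.0, 1.0, 2.0, 3.0]))
        assert w == 6.0
        with pytest.raises(ValueError):
            wilcoxon_abs_errors(np.zeros(5))

    def test_large_sample_normal_approximation(self, rng):
        d = rng.normal(0.3, 1, 60)
        _, p = wilcoxon_abs_errors(d)
        assert 0.0 < p < 1.0


class TestSelfInclusionBias:
    def test_consensus_including_expert_flatters_them(self, noisy_tables):
        """An expert scored against a consensus containing their own readings
        shows smaller deviation SD than against a leave-one-out consensus."""
        model = DimensionAgreement(noisy_tables.annotations, noisy_tables.frames)
        incl = model.fit(leave_one_out=False).summaries
        excl = model.fit(leave_one_out=True).summaries

        def pooled_sd(s):
            sel = s[(s.method_id != "AI") & (s.phase == "pooled") & (s.dimension == "lvid")]
            return sel.set_index("method_id")["precision_sd_mm"]

        diff = pooled_sd(incl) - pooled_sd(excl)
        assert diff.mean() < 0
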