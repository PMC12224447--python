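"""Outlier screening, normality gating, gated tests, partial correlation, FDR."""

import warnings

import numpy as np
import pytest
from scipy import stats as sps

from vamkit import (
    OutlierConfig,
    bh_fdr,
    correlate,
    normality_gate,
    partial_correlation,
    rout_outliers,
    two_group_compare,
    voi_mean,
)


def bh_stepup_bruteforce(pvals, q):
    """Independent step-up oracle: largest k with p_(k) <= k*q/m."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestVoiMean:
    def test_constant_region(self):
        vals = np.zeros((4, 4, 2))
        labels = np.zeros((4, 4, 2), dtype=int)
        labels[1:3, 1:3, :] = 3
        vals[labels == 3] = 5.0
        out = voi_mean(vals, labels, 3)
        assert out["mean"] == 5.0 and out["sd"] == 0.0
        assert out["n_voxels"] == 8
        assert out["ci95"] == (5.0, 5.0)

    def test_mean_over_valid_half_only(self):
        vals = np.full((4, 4, 2), 2.0)
        labels = np.ones((4, 4, 2), dtype=int)
        vals[:2] = np.nan  # half the VOI invalid
        out = voi_mean(vals, labels, 1)
        assert out["mean"] == 2.0 and out["n_voxels"] == 16

    def test_no_valid_voxels_gives_missing_row(self):
        vals = np.full((2, 2, 2), np.nan)
        labels = np.ones((2, 2, 2), dtype=int)
        out = voi_mean(vals, labels, 1)
        assert out["n_voxels"] == 0 and np.isnan(out["mean"])


class TestRout:
    def test_clean_normals_rarely_flagged(self):
        """FDR control: on pure Normal(0,1) columns the flag rate stays
        below the ROUT Q = 1% level across 200 repetitions."""
        rng = np.random.default_rng(123)
        total_flags = 0
        reps = 200
        for _ in range(reps):
            flags = rout_outliers(rng.normal(size=50))
            total_flags += flags.sum()
        assert total_flags / reps <= 1.0  # expected flags per column <= 1
        assert total_flags / (reps * 50) <= 0.01  # spurious-flag rate <= Q

    def test_ten_sigma_plant_always_caught(self):
        rng = np.random.default_rng(456)
        caught = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(size=51)
            x[0] = 10.0
            if rout_outliers(x)[0]:
                caught += 1
        assert caught / reps >= 0.99

    def test_identical_values_unflagged(self):
        assert not rout_outliers(np.full(20, 3.14)).any()

    def test_small_sample_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="n >= 10"):
            flags = rout_outliers(np.arange(5.0))
        assert not flags.any()

    def test_flag_cap_at_30_percent(self):
        x = np.concatenate([np.zeros(10), np.full(10, 100.0)])
        assert rout_outliers(x).sum() <= 6

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError):
            OutlierConfig(rout_q=0.7)


class TestNormalityGate:
    def test_type_one_error_calibrated(self):
        """D'Agostino-Pearson rejects a true normal ~5% of the time
        (1000 repetitions of n = 5000)."""
        rng = np.random.default_rng(789)
        draws = rng.normal(size=(1000, 5000))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, pvals = sps.normaltest(draws, axis=1)
        rate = np.mean(pvals < 0.05)
        assert abs(rate - 0.05) <= 0.01
        # and the gate agrees with the vectorized recomputation
        verdict, p = normality_gate(draws[0])
        assert p == pytest.approx(pvals[0])
        assert verdict == ("non_gaussian" if pvals[0] < 0.05 else "gaussian")

    def test_exponential_detected(self):
        rng = np.random.default_rng(321)
        hits = sum(normality_gate(rng.exponential(size=200))[0] == "non_gaussian"
                   for _ in range(100))
        assert hits >= 99

    def test_small_sample_routed_nonparametric(self):
        with pytest.warns(UserWarning, match="n >= 8"):
            verdict, _ = normality_gate(np.arange(5.0))
        assert verdict == "non_gaussian"


class TestTwoGroupCompare:
    def test_identical_groups_null_pvalue(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        res = two_group_compare(a, a.copy())
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_large_shift_always_detected(self):
        """Power: Normal(0,1) vs Normal(2,1) at n = 40/30 (Cohen's d = 2)."""
        rng = np.random.default_rng(99)
        rejections = sum(
            two_group_compare(rng.normal(0, 1, 40),
                              rng.normal(2, 1, 30)).p_value < 0.05
            for _ in range(100))
        assert rejections >= 99

    def test_label_swap_symmetry(self, rng):
        a, b = rng.normal(0, 1, 25), rng.normal(0.5, 1, 30)
        r1 = two_group_compare(a, b)
        r2 = two_group_compare(b, a)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
        assert r1.effect_direction == -r2.effect_direction
        assert r1.test_name == r2.test_name

    def test_nonnormal_routes_to_mann_whitney(self, rng):
        a = rng.exponential(size=40) ** 3
        b = rng.exponential(size=40) ** 3
        assert two_group_compare(a, b).test_name == "mann-whitney"

    def test_tiny_group_missing(self):
        assert two_group_compare(np.array([1.0]), np.arange(10.0)) is None


class TestCorrelate:
    def test_perfect_linear(self, rng):
        x = rng.normal(size=40)
        res = correlate(x, 2 * x + 3)
        assert res.r == pytest.approx(1.0)

    def test_monotone_nonlinear_spearman_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=60)
        y = x**3  # heavy-tailed -> routed to Spearman
        res = correlate(x, y)
        assert res.test_name == "spearman"
        assert res.r == pytest.approx(1.0)
        assert sps.pearsonr(x, y).statistic < 1.0

    def test_null_respects_critical_value(self):
        """|r| < r_crit(alpha=.05, df=70) in ~95% of independent draws."""
        rng = np.random.default_rng(8)
        crit = 0.2319  # t-quantile-based critical value at n = 72
        inside = sum(
            abs(sps.pearsonr(rng.normal(size=72), rng.normal(size=72)).statistic)
            < crit
            for _ in range(400))
        assert 0.91 <= inside / 400 <= 0.99

    def test_degenerate_variance_missing(self):
        assert correlate(np.ones(20), np.arange(20.0)) is None


class TestPartialCorrelation:
    def test_matches_residual_regression_oracle(self, rng):
        """Formula equals the correlation of OLS residuals to 1e-10."""
        n = 200
        z = rng.normal(size=n)
        x = 0.5 * z + rng.normal(size=n)
        y = -0.3 * z + rng.normal(size=n)
        res = partial_correlation(x, y, z, method="pearson")
        zd = np.column_stack([np.ones(n), z])
        rx = x - zd @ np.linalg.lstsq(zd, x, rcond=None)[0]
        ry = y - zd @ np.linalg.lstsq(zd, y, rcond=None)[0]
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert abs(res.r - oracle) < 1e-10

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        n = 80
        z = rng.normal(size=n)
        x = 0.4 * z + rng.normal(size=n)
        y = 0.6 * x - 0.2 * z + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z",
                                    method="pearson")
        res = partial_correlation(x, y, z, method="pearson")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]),
                                            abs=1e-9)

    def test_perfect_confound_gives_zero(self, rng):
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        res = partial_correlation(x, z.copy(), z, method="pearson")
        assert res is None or abs(res.r) < 1e-12

    def test_independent_confound_approximates_marginal(self):
        rng = np.random.default_rng(31)
        n = 10_000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        z = rng.normal(size=n)  # independent of both
        res = partial_correlation(x, y, z, method="pearson")
        marginal = np.corrcoef(x, y)[0, 1]
        assert abs(res.r - marginal) < 0.02

    def test_spearman_path_uses_ranks(self, rng):
        x = rng.normal(size=60)
        y = np.exp(2 * x) + rng.normal(scale=0.01, size=60)
        z = rng.normal(size=60)
        res = partial_correlation(x, y, z, method="spearman")
        assert res.test_name == "partial-spearman"
        assert res.r > 0.95


class TestBhFdr:
    def test_stepup_by_hand_all_rejected(self):
        reject, q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        assert reject.all()  # p_(4) = 0.04 <= 0.05 -> all four
        assert np.all(q <= 0.05)

    def test_stepup_by_hand_one_rejected(self):
        reject, _ = bh_fdr(np.array([0.001, 0.9, 0.9, 0.9]), q=0.05)
        assert reject.tolist() == [True, False, False, False]

    def test_matches_bruteforce_enumeration(self):
        """Implementation equals the exhaustive step-up oracle, m <= 10."""
        rng = np.random.default_rng(17)
        for m in range(1, 11):
            for _ in range(40):
                p = rng.uniform(size=m) ** rng.uniform(0.3, 3.0)
                reject, qvals = bh_fdr(p, q=0.05)
                oracle = bh_stepup_bruteforce(p, 0.05)
                assert np.array_equal(reject, oracle)
                # q-value consistency: rejected iff q <= Q
                assert np.array_equal(qvals <= 0.05, reject)

    def test_null_uniform_controls_fdr(self):
        rng = np.random.default_rng(23)
        total_rej = 0
        reps = 100
        for _ in range(reps):
            reject, _ = bh_fdr(rng.uniform(size=100), q=0.05)
            total_rej += reject.sum()
        # under the global null every rejection is false; FDR = P(any)
        assert total_rej / reps <= 0.05 * 100 * 0.2  # loose: ~5 expected max

    def test_qvalues_monotone_in_p(self, rng):
        p = rng.uniform(size=30)
        _, q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)

    def test_nan_passthrough(self):
        reject, q = bh_fdr(np.array([0.001, np.nan, 0.5]))
        assert not reject[1] and np.isnan(q[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.1, 1.5]))
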