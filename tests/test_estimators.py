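"""Wald ratio, IVW, weighted median, MR-Egger, and report transformations."""

import math

import numpy as np
import pytest
from scipy import stats

from mrmediate.estimators import (MethodPanel, MREstimate, bonferroni_adjust,
                                  ivw, mr_egger, significance_rule,
                                  to_odds_ratio, wald_ratio, weighted_median)

from conftest import build_harmonized


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(0.5, 0.05, 0.25, 0.1)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)
        assert est.method == "wald" and est.n_snp == 1

    def test_null_outcome(self):
        est = wald_ratio(0.5, 0.05, 0.0, 0.1)
        assert est.beta == 0.0 and est.pval == 1.0

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError, match="undefined ratio"):
            wald_ratio(0.0, 0.05, 0.25, 0.1)

    def test_se_close_to_monte_carlo_ratio_sd(self):
        # strong instrument: |beta_exp/se_exp| = 25
        bx, sx, by, sy = 0.5, 0.02, 0.25, 0.1
        est = wald_ratio(bx, sx, by, sy)
        rng = np.random.default_rng(0)
        draws = rng.normal(by, sy, 100_000) / rng.normal(bx, sx, 100_000)
        assert est.se == pytest.approx(np.std(draws), rel=0.10)


class TestIvw:
    def test_single_snp_equals_wald(self, harmonized_builder):
        h = harmonized_builder([0.5], [0.05], [0.25], [0.1])
        est = ivw(h)
        ref = wald_ratio(0.5, 0.05, 0.25, 0.1)
        assert (est.beta, est.se, est.pval) == (ref.beta, ref.se, ref.pval)
        assert est.method == "wald"

    def test_identical_ratios_no_heterogeneity_inflation(self, harmonized_builder):
        bx = np.array([0.1, 0.2, 0.3, 0.15, 0.25])
        h = harmonized_builder(bx, 0.01 * np.ones(5), 0.5 * bx,
                               0.1 * np.ones(5))
        est = ivw(h)
        assert est.beta == pytest.approx(0.5, abs=1e-12)
        # zero residuals: reported SE equals the fixed-effect SE
        assert est.se == pytest.approx(1.0 / math.sqrt(np.sum(100 * bx**2)))

    def test_matches_weighted_least_squares_oracle(self, harmonized_builder):
        import statsmodels.api as sm
        rng = np.random.default_rng(7)
        bx = rng.normal(0.2, 0.05, 5)
        sy = rng.uniform(0.02, 0.05, 5)
        by = 0.4 * bx + rng.normal(0, 0.2, 5)  # heterogeneous: sigma > 1
        h = harmonized_builder(bx, 0.01 * np.ones(5), by, sy)
        est = ivw(h)
        fit = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
        assert est.beta == pytest.approx(fit.params[0], abs=1e-10)
        assert est.se == pytest.approx(fit.bse[0], abs=1e-10)

    def test_fixed_effect_beta_invariant_to_common_se_rescale(
            self, harmonized_builder):
        rng = np.random.default_rng(3)
        bx = rng.normal(0.2, 0.05, 8)
        by = 0.3 * bx + rng.normal(0, 0.05, 8)
        sy = rng.uniform(0.05, 0.1, 8)
        b1 = ivw(build := harmonized_builder(bx, 0.01 * np.ones(8), by, sy)).beta
        b2 = ivw(harmonized_builder(bx, 0.01 * np.ones(8), by, 3.7 * sy)).beta
        assert b1 == pytest.approx(b2, abs=1e-12)

    def test_all_zero_exposure_betas_rejected(self, harmonized_builder):
        h = harmonized_builder([0.0, 0.0], [0.01, 0.01], [0.1, 0.2], [0.1, 0.1])
        with pytest.raises(ValueError, match="no instrument signal"):
            ivw(h)


def brute_force_weighted_median(ratios, weights):
    """Independent cumulative-weight search with linear interpolation."""
    order = sorted(range(len(ratios)), key=lambda j: ratios[j])
    b = [ratios[j] for j in order]
    w = [weights[j] for j in order]
    total = sum(w)
    s = []
    run = 0.0
    for wj in w:
        s.append((run + wj / 2.0) / total)
        run += wj
    if 0.5 <= s[0]:
        return b[0]
    if 0.5 >= s[-1]:
        return b[-1]
    j = max(i for i in range(len(s)) if s[i] <= 0.5)
    return b[j] + (b[j + 1] - b[j]) * (0.5 - s[j]) / (s[j + 1] - s[j])


class TestWeightedMedian:
    def test_equal_weights_plain_median(self, harmonized_builder):
        h = harmonized_builder([1.0, 1.0, 1.0], [0.01] * 3, [0.1, 0.5, 0.9],
                               [0.1] * 3)
        assert weighted_median(h, n_boot=100, seed=0).beta == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self, harmonized_builder):
        rng = np.random.default_rng(11)
        for _ in range(20):
            bx = rng.normal(0.3, 0.1, 7)
            bx[np.abs(bx) < 0.01] = 0.05
            by = rng.normal(0.1, 0.2, 7)
            sy = rng.uniform(0.05, 0.2, 7)
            h = build_harmonized(bx, 0.01 * np.ones(7), by, sy)
            est = weighted_median(h, n_boot=100, seed=1)
            expected = brute_force_weighted_median(
                list(by / bx), list(bx**2 / sy**2))
            assert est.beta == pytest.approx(expected, abs=1e-12)

    def test_majority_valid_robustness(self, harmonized_builder):
        rng = np.random.default_rng(5)
        n_valid, n_out = 14, 6
        bx = rng.uniform(0.2, 0.4, n_valid + n_out)
        ratios = np.r_[np.full(n_valid, 0.5), np.full(n_out, 3.0)]
        by = ratios * bx + rng.normal(0, 0.01, n_valid + n_out)
        h = harmonized_builder(bx, 0.005 * np.ones(20), by,
                               0.05 * np.ones(20))
        assert weighted_median(h, seed=2).beta == pytest.approx(0.5, abs=0.05)

    def test_bootstrap_se_reproducible(self, harmonized_builder):
        rng = np.random.default_rng(9)
        bx = rng.normal(0.3, 0.05, 6)
        by = 0.2 * bx + rng.normal(0, 0.05, 6)
        h = harmonized_builder(bx, 0.01 * np.ones(6), by, 0.1 * np.ones(6))
        assert weighted_median(h, seed=4).se == weighted_median(h, seed=4).se

    def test_too_few_instruments(self, harmonized_builder):
        h = harmonized_builder([0.1, 0.2], [0.01] * 2, [0.1, 0.1], [0.1] * 2)
        with pytest.raises(ValueError):
            weighted_median(h)


class TestMrEgger:
    def test_exact_linear_data(self, harmonized_builder):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        by = 0.1 + 0.4 * bx
        h = harmonized_builder(bx, 0.01 * np.ones(5), by, 0.1 * np.ones(5))
        slope, intercept = mr_egger(h)
        assert slope.beta == pytest.approx(0.4, abs=1e-12)
        assert intercept.beta == pytest.approx(0.1, abs=1e-12)

    def test_matches_two_parameter_wls_oracle(self, harmonized_builder):
        import statsmodels.api as sm
        rng = np.random.default_rng(17)
        bx = rng.uniform(0.05, 0.5, 6)
        sy = rng.uniform(0.02, 0.06, 6)
        by = 0.05 + 0.4 * bx + rng.normal(0, 0.25, 6)  # sigma > 1
        h = harmonized_builder(bx, 0.01 * np.ones(6), by, sy)
        slope, intercept = mr_egger(h)
        fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
        assert slope.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert intercept.beta == pytest.approx(fit.params[0], abs=1e-10)
        assert slope.se == pytest.approx(fit.bse[1], abs=1e-10)
        # statsmodels OLS-family inference is t-based with n-2 df as well
        assert slope.pval == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_pvalues_use_t_with_n_minus_2_df(self, harmonized_builder):
        rng = np.random.default_rng(23)
        n = 10
        bx = rng.uniform(0.1, 0.5, n)
        by = 0.3 * bx + rng.normal(0, 0.1, n)
        h = harmonized_builder(bx, 0.01 * np.ones(n), by, 0.08 * np.ones(n))
        slope, _ = mr_egger(h)
        assert slope.pval == pytest.approx(
            2 * stats.t.sf(abs(slope.beta) / slope.se, n - 2), abs=1e-14)

    def test_orientation_invariance(self, harmonized_builder):
        rng = np.random.default_rng(29)
        bx = rng.normal(0.0, 0.3, 8)
        by = 0.2 * bx + rng.normal(0, 0.05, 8)
        h1 = harmonized_builder(bx, 0.01 * np.ones(8), by, 0.1 * np.ones(8))
        h2 = harmonized_builder(-bx, 0.01 * np.ones(8), -by, 0.1 * np.ones(8))
        s1, i1 = mr_egger(h1)
        s2, i2 = mr_egger(h2)
        assert s1.beta == pytest.approx(s2.beta, abs=1e-12)
        assert i1.beta == pytest.approx(i2.beta, abs=1e-12)

    def test_underdetermined(self, harmonized_builder):
        h = harmonized_builder([0.1, 0.2], [0.01] * 2, [0.1, 0.1], [0.1] * 2)
        with pytest.raises(ValueError, match="underdetermined"):
            mr_egger(h)


class TestReportTransforms:
    def test_protective_genus_worked_example(self):
        or_, lo, hi, p = to_odds_ratio(-2.521, 0.581)
        assert or_ == pytest.approx(0.080, abs=5e-4)
        assert lo == pytest.approx(0.026, abs=5e-4)
        assert hi == pytest.approx(0.251, abs=5e-4)
        assert p == pytest.approx(1.42e-5, rel=0.01)

    def test_risk_genus_or(self):
        assert to_odds_ratio(0.964, 0.441)[0] == pytest.approx(2.622, abs=5e-4)

    def test_null_beta(self):
        or_, lo, hi, p = to_odds_ratio(0.0, 0.5)
        assert or_ == 1.0 and p == 1.0 and lo < 1.0 < hi

    def test_log_round_trip(self):
        beta = -1.23456789
        assert math.log(to_odds_ratio(beta, 0.3)[0]) == pytest.approx(
            beta, abs=1e-12)

    def test_estimate_ci_consistency(self):
        est = MREstimate("ivw", 5, beta=0.3, se=0.1, pval=0.0027)
        assert est.ci_low < est.or_ < est.ci_high
        assert est.or_ == pytest.approx(math.exp(0.3))


class TestSignificanceRule:
    def _panel(self, p_ivw, b_ivw, b_wm, b_egger):
        panel = MethodPanel("taxon", "disease")
        panel.estimates["ivw"] = MREstimate("ivw", 9, b_ivw, 0.3, p_ivw)
        panel.estimates["weighted_median"] = MREstimate(
            "weighted_median", 9, b_wm, 0.4, 0.2)
        panel.estimates["mr_egger_slope"] = MREstimate(
            "mr_egger_slope", 9, b_egger, 1.0, 0.5)
        return panel

    def test_concordant_significant(self):
        assert significance_rule(self._panel(0.03, -0.5, -0.6, -1.0))

    def test_discordant_direction_not_significant(self):
        assert not significance_rule(self._panel(0.03, -0.5, -0.6, 1.0))

    def test_ivw_above_alpha_not_significant(self):
        assert not significance_rule(self._panel(0.06, -0.5, -0.6, -1.0))

    def test_zero_beta_counts_as_mismatch(self):
        assert not significance_rule(self._panel(0.01, -0.5, 0.0, -1.0))

    def test_missing_method_errors(self):
        panel = MethodPanel("taxon", "disease")
        panel.estimates["ivw"] = MREstimate("ivw", 9, -0.5, 0.3, 0.01)
        with pytest.raises(ValueError, match="missing method"):
            significance_rule(panel)


class TestBonferroni:
    def test_screen_family_adjustment(self):
        adj = bonferroni_adjust([1.42e-5], 196)[0]
        assert f"{adj:.2g}" == "0.0028"

    def test_capped_at_one(self):
        assert bonferroni_adjust([0.01], 196)[0] == 1.0

    def test_single_comparison_unchanged(self):
        np.testing.assert_array_equal(bonferroni_adjust([0.2, 0.7], 1),
                                      [0.2, 0.7])
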