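"""Univariable estimators against independent oracles: explicit normal
equations for IVW/Egger, dense-grid quantile inversion for the weighted
median, grid-search argmax for the modes, hand arithmetic for Cochran Q."""

import numpy as np
import pytest

from conftest import make_harmonized
from mrmediate.estimators import (InsufficientInstruments, cochran_q, egger,
                                  ivw, mode_estimator, run_sensitivity_suite,
                                  wald_ratio, weighted_median)


class TestWaldRatio:
    def test_zero_numerator(self):
        est = wald_ratio(0.1, 0.01, 0.0, 0.02)
        assert est.beta == 0.0
        assert est.se == pytest.approx(0.2)

    def test_arithmetic(self):
        est = wald_ratio(0.2, 0.01, 0.1, 0.02)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_second_order_se_strictly_larger(self):
        first = wald_ratio(0.05, 0.02, 0.1, 0.02)
        second = wald_ratio(0.05, 0.02, 0.1, 0.02, second_order=True)
        # closed form: adds Gamma^2 se_gamma^2 / gamma^4 > 0
        assert second.se > first.se
        expected = np.sqrt(0.02**2 / 0.05**2 + 0.1**2 * 0.02**2 / 0.05**4)
        assert second.se == pytest.approx(expected)

    def test_zero_gamma_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.1, 0.02)


def ivw_oracle(g, sg, G, sG):
    """Explicit normal-equation solution with multiplicative SE scaling."""
    g, G, sG = map(np.asarray, (g, G, sG))
    w = 1 / sG**2
    beta = np.sum(w * g * G) / np.sum(w * g * g)
    q = np.sum(w * (G - beta * g) ** 2)
    se = np.sqrt(q / (len(g) - 1) / np.sum(w * g * g))
    return beta, se, q


class TestIVW:
    def test_consistency_equal_ratios(self):
        b = 0.42
        g = np.array([0.1, 0.2, 0.3])
        h = make_harmonized(g, [0.01] * 3, b * g, [0.02] * 3)
        est = ivw(h)
        assert est.beta == pytest.approx(b, rel=1e-12)
        assert est.q_stat == pytest.approx(0.0, abs=1e-20)

    def test_single_snp_equals_wald(self):
        h = make_harmonized([0.2], [0.01], [0.1], [0.02])
        with pytest.warns(UserWarning):
            est = ivw(h)
        ref = wald_ratio(0.2, 0.01, 0.1, 0.02)
        assert est.beta == ref.beta and est.se == ref.se

    def test_matches_wls_oracle(self, three_snp_set):
        est = ivw(three_snp_set)
        b, se, q = ivw_oracle(three_snp_set.gamma, three_snp_set.se_gamma,
                              three_snp_set.Gamma, three_snp_set.se_Gamma)
        assert est.beta == pytest.approx(b, rel=1e-10)
        assert est.se == pytest.approx(se, rel=1e-10)
        assert est.q_stat == pytest.approx(q, rel=1e-10)

    def test_sign_flip_invariance(self, three_snp_set):
        """Simultaneously flipping (gamma, Gamma) of any subset is a no-op."""
        base = ivw(three_snp_set).beta
        t = three_snp_set.table.copy()
        t.loc[1, ["gamma", "Gamma"]] *= -1
        flipped = make_harmonized(t["gamma"], t["se_gamma"], t["Gamma"], t["se_Gamma"])
        assert ivw(flipped).beta == pytest.approx(base, rel=1e-12)

    def test_mre_floor_option(self):
        # nearly-exact fit: unfloored se shrinks below fixed-effect se
        g = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_harmonized(g, [0.01] * 4, 0.5 * g + 1e-6, [0.02] * 4)
        assert ivw(h, mre_floor=True).se > ivw(h, mre_floor=False).se

    def test_all_zero_gamma_degenerate(self):
        h = make_harmonized([0.0, 0.0], [0.01] * 2, [0.1, 0.2], [0.02] * 2)
        with pytest.raises(ValueError):
            ivw(h)


def egger_oracle(g, G, sG):
    """Two-parameter weighted normal equations after gamma >= 0 orientation."""
    g, G, sG = map(np.asarray, (g, G, sG))
    s = np.where(g < 0, -1.0, 1.0)
    g, G = s * g, s * G
    w = 1 / sG**2
    A = np.array([[np.sum(w), np.sum(w * g)],
                  [np.sum(w * g), np.sum(w * g * g)]])
    rhs = np.array([np.sum(w * G), np.sum(w * g * G)])
    a, b = np.linalg.solve(A, rhs)
    resid = G - a - b * g
    q = np.sum(w * resid**2)
    cov = np.linalg.inv(A) * q / (len(g) - 2)
    return a, b, np.sqrt(cov[0, 0]), np.sqrt(cov[1, 1]), q


class TestEgger:
    def test_exact_linear_fit(self):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        c, b = 0.02, 0.5
        h = make_harmonized(g, [0.01] * 4, c + b * g, [0.02] * 4)
        est = egger(h)
        assert est.intercept == pytest.approx(c, rel=1e-10)
        assert est.beta == pytest.approx(b, rel=1e-10)
        assert est.q_stat == pytest.approx(0.0, abs=1e-18)

    def test_matches_two_parameter_oracle(self):
        h = make_harmonized([0.1, -0.2, 0.15, 0.3], [0.01] * 4,
                            [0.06, -0.08, 0.09, 0.14], [0.02, 0.03, 0.025, 0.02])
        est = egger(h)
        a, b, se_a, se_b, q = egger_oracle(h.gamma, h.Gamma, h.se_Gamma)
        assert est.intercept == pytest.approx(a, rel=1e-10)
        assert est.beta == pytest.approx(b, rel=1e-10)
        assert est.intercept_se == pytest.approx(se_a, rel=1e-10)
        assert est.se == pytest.approx(se_b, rel=1e-10)

    def test_orientation_invariance(self):
        h1 = make_harmonized([0.1, 0.2, 0.3, 0.15], [0.01] * 4,
                             [0.05, 0.11, 0.16, 0.08], [0.02] * 4)
        t = h1.table.copy()
        t.loc[[0, 2], ["gamma", "Gamma"]] *= -1
        h2 = make_harmonized(t["gamma"], t["se_gamma"], t["Gamma"], t["se_Gamma"])
        assert egger(h2).beta == pytest.approx(egger(h1).beta, rel=1e-12)
        assert egger(h2).intercept == pytest.approx(egger(h1).intercept, rel=1e-12)

    def test_balanced_pleiotropy_null_intercept(self):
        """Zero-mean, gamma-independent pleiotropy: intercept CI covers 0."""
        rng = np.random.default_rng(2024)
        J = 1000
        g = rng.uniform(0.05, 0.2, J)
        pleio = rng.normal(0, 0.01, J)
        sG = np.full(J, 0.02)
        G = 0.3 * g + pleio + rng.normal(0, sG)
        h = make_harmonized(g, np.full(J, 0.005), G, sG)
        est = egger(h)
        assert abs(est.intercept) < 1.959964 * est.intercept_se * 1.5

    def test_too_few_instruments(self):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(InsufficientInstruments):
            egger(h)


def weighted_median_oracle(b, w, grid_n=2_000_001):
    """Numerical inversion of the interpolated weighted-quantile function."""
    order = np.argsort(b)
    bs, ws = np.asarray(b)[order], np.asarray(w)[order]
    ws = ws / ws.sum()
    s = np.cumsum(ws) - ws / 2
    qs = np.linspace(s[0], s[-1], grid_n)
    vals = np.interp(qs, s, bs)
    return vals[np.argmin(np.abs(qs - 0.5))]


class TestWeightedMedian:
    def test_middle_element_equal_weights(self):
        h = make_harmonized([1.0, 1.0, 1.0], [0.01] * 3,
                            [0.1, 0.5, 0.9], [1.0, 1.0, 1.0])
        est = weighted_median(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_outlier_breakdown_robustness(self):
        rng = np.random.default_rng(5)
        g = rng.uniform(0.1, 0.3, 10)
        G = 0.5 * g + rng.normal(0, 0.002, 10)
        G[0] = 20 * g[0]  # wild outlier ratio
        h = make_harmonized(g, [0.01] * 10, G, [0.01] * 10)
        est = weighted_median(h, n_boot=50, seed=1)
        assert 0.4 < est.beta < 0.6

    def test_matches_quantile_scan_oracle(self):
        rng = np.random.default_rng(11)
        g = rng.uniform(0.05, 0.3, 9)
        G = 0.4 * g + rng.normal(0, 0.01, 9)
        sG = rng.uniform(0.01, 0.03, 9)
        h = make_harmonized(g, [0.01] * 9, G, sG)
        est = weighted_median(h, n_boot=50, seed=1)
        b = G / g
        w = g**2 / sG**2
        assert est.beta == pytest.approx(weighted_median_oracle(b, w), abs=1e-6)


class TestModeEstimator:
    def test_identical_ratios_returned_directly(self):
        g = np.array([0.1, 0.2, 0.4])
        h = make_harmonized(g, [0.01] * 3, 0.7 * g, [0.02] * 3)
        est = mode_estimator(h, weighted=False, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.7, rel=1e-12)

    def test_bimodal_majority_cluster_wins_simple_mode(self):
        rng = np.random.default_rng(3)
        ratios = np.concatenate([0.4 + 0.01 * rng.standard_normal(7),
                                 1.5 + 0.01 * rng.standard_normal(3)])
        g = np.ones(10)
        h = make_harmonized(g, [0.01] * 10, ratios, [0.05] * 10)
        est = mode_estimator(h, weighted=False, n_boot=50, seed=1)
        assert 0.3 < est.beta < 0.5

    def test_grid_search_oracle_agreement(self):
        """Independent dense-grid argmax of the same kernel density."""
        rng = np.random.default_rng(9)
        ratios = np.concatenate([0.4 + 0.02 * rng.standard_normal(7),
                                 1.5 + 0.02 * rng.standard_normal(3)])
        h = make_harmonized(np.ones(10), [0.01] * 10, ratios, [0.05] * 10)
        est = mode_estimator(h, weighted=False, n_boot=50, seed=1)
        b = ratios
        sd = np.std(b, ddof=1)
        from scipy.stats import median_abs_deviation
        s = min(sd, median_abs_deviation(b, scale="normal"))
        hb = 0.9 * s * 10 ** (-0.2)
        grid = np.linspace(b.min() - 3 * hb, b.max() + 3 * hb, 65_536)
        dens = np.exp(-0.5 * ((grid[:, None] - b[None, :]) / hb) ** 2).sum(axis=1)
        oracle = grid[np.argmax(dens)]
        # agreement limited by the estimator's own 512-point grid resolution
        impl_spacing = (b.max() - b.min() + 6 * hb) / 511
        assert est.beta == pytest.approx(oracle, abs=1.5 * impl_spacing)

    def test_weighted_mode_moves_toward_precise_minority(self):
        rng = np.random.default_rng(4)
        ratios = np.concatenate([0.4 + 0.02 * rng.standard_normal(7),
                                 1.5 + 0.002 * rng.standard_normal(3)])
        sG = np.array([0.2] * 7 + [0.001] * 3)  # minority is very precise
        h = make_harmonized(np.ones(10), [0.01] * 10, ratios, sG)
        simple = mode_estimator(h, weighted=False, n_boot=20, seed=1)
        weighted = mode_estimator(h, weighted=True, n_boot=20, seed=1)
        assert weighted.beta > simple.beta
        assert weighted.beta == pytest.approx(1.5, abs=0.1)


class TestCochranQ:
    def test_homogeneous_zero(self):
        g = np.array([0.1, 0.2, 0.3])
        h = make_harmonized(g, [0.01] * 3, 0.5 * g, [0.02] * 3)
        q, df, p, i2 = cochran_q(h, 0.5)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert i2 == 0.0 and df == 2

    def test_two_snp_hand_arithmetic(self):
        # ratios (0, 2z) with unit ratio-se around beta = z gives Q = 2 z^2
        z = 1.7
        h = make_harmonized([1.0, 1.0], [0.01] * 2, [0.0, 2 * z], [1.0, 1.0])
        q, df, p, i2 = cochran_q(h, z)
        assert q == pytest.approx(2 * z**2, rel=1e-12)
        assert df == 1

    def test_i2_tracks_injected_heterogeneity(self):
        """At large J, I^2 approaches tau^2 / (tau^2 + mean se^2)."""
        rng = np.random.default_rng(77)
        J, tau, se = 3000, 0.1, 0.1
        g = np.ones(J)
        true_b = 0.3 + rng.normal(0, tau, J)
        G = true_b + rng.normal(0, se, J)
        h = make_harmonized(g, np.full(J, 1e-6), G, np.full(J, se))
        est = ivw(h)
        expected = tau**2 / (tau**2 + se**2)
        assert est.i2 == pytest.approx(expected, abs=0.04)


class TestSensitivitySuite:
    def _consistent(self, seed=1, b=0.5, J=12):
        rng = np.random.default_rng(seed)
        g = rng.uniform(0.1, 0.3, J)
        sG = np.full(J, 0.01)
        G = b * g + rng.normal(0, sG)
        return make_harmonized(g, np.full(J, 0.005), G, sG)

    def test_concordant_significant_is_indicative(self):
        suite = run_sensitivity_suite(self._consistent(), n_boot=50, seed=2)
        assert suite.get("ivw_mre").pval < 0.05
        assert suite.verdict == "causal-indicative"

    def test_nonsignificant_ivw_not_indicative(self):
        rng = np.random.default_rng(8)
        g = rng.uniform(0.1, 0.3, 12)
        sG = np.full(12, 0.05)
        G = rng.normal(0, sG)  # null
        h = make_harmonized(g, np.full(12, 0.005), G, sG)
        suite = run_sensitivity_suite(h, n_boot=50, seed=2)
        assert suite.verdict == "not-indicative"

    def test_egger_sign_flip_breaks_concordance(self):
        # constant positive pleiotropy with a negative slope: IVW slope
        # positive and precise, Egger slope negative
        g = np.linspace(0.1, 0.5, 10)
        G = 0.08 - 0.05 * g
        h = make_harmonized(g, np.full(10, 0.005), G, np.full(10, 0.001))
        suite = run_sensitivity_suite(h, n_boot=50, seed=2)
        assert suite.get("ivw_mre").beta > 0
        assert suite.get("egger").beta < 0
        assert suite.verdict == "not-indicative"
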