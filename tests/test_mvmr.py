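"""Multivariable MR: matrix-oracle equivalence, reduction to univariable
IVW, robustness methods on constructed pleiotropy, set assembly."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_harmonized, make_mv
from mrmediate.estimators import ivw
from mrmediate.mvmr import (CollinearityError, build_mv_set, mvmr_egger,
                            mvmr_ivw, mvmr_lasso, mvmr_median, mvmr_qhet,
                            mvmr_robust)
from mrmediate.simulate import TruthRecord, generate_study


def mv_ivw_oracle(X, y, sG, K_df=None):
    """Explicit weighted normal equations with multiplicative scaling."""
    w = 1 / np.asarray(sG) ** 2
    A = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(A, X.T @ (w * y))
    q = np.sum(w * (y - X @ beta) ** 2)
    J, K = X.shape
    cov = np.linalg.inv(A) * q / (J - K)
    return beta, np.sqrt(np.diag(cov)), q


def _fixture(seed=0, J=12, b=(0.15, 0.31)):
    rng = np.random.default_rng(seed)
    X = np.column_stack([rng.uniform(0.05, 0.3, J), rng.uniform(0.05, 0.3, J)])
    sG = np.full(J, 0.01)
    y = X @ np.asarray(b) + rng.normal(0, sG)
    SE_X = np.full((J, 2), 0.004)
    return make_mv(X, SE_X, y, sG)


class TestMvIvw:
    def test_matches_normal_equation_oracle(self):
        m = _fixture(seed=1, J=6)
        est = mvmr_ivw(m)
        beta, se, q = mv_ivw_oracle(m.G, m.Gamma, m.se_Gamma)
        assert np.allclose(est.beta, beta, rtol=1e-10)
        assert np.allclose(est.se, se, rtol=1e-10)
        assert est.diagnostics["q_stat"] == pytest.approx(q, rel=1e-10)

    def test_orthogonal_null_second_exposure_recovers_univariable(self):
        """A zero-column second exposure leaves the first exposure's
        estimate equal to univariable IVW on the same rows."""
        rng = np.random.default_rng(2)
        J = 8
        g1 = rng.uniform(0.1, 0.3, J)
        sG = np.full(J, 0.01)
        w = 1 / sG**2
        y = 0.4 * g1 + rng.normal(0, sG)
        # second column exactly w-orthogonal to the first: normal equations
        # decouple, so the first coefficient is the univariable slope
        e = rng.normal(0, 0.1, J)
        g2 = e - g1 * np.sum(w * g1 * e) / np.sum(w * g1 * g1)
        m = make_mv(np.column_stack([g1, g2]), np.full((J, 2), 0.004), y, sG)
        est = mvmr_ivw(m)
        h = make_harmonized(g1, np.full(J, 0.004), y, sG)
        assert est.beta[0] == pytest.approx(ivw(h).beta, rel=1e-10)

    def test_k1_reduces_to_univariable(self):
        rng = np.random.default_rng(3)
        J = 7
        g = rng.uniform(0.1, 0.3, J)
        sG = np.full(J, 0.01)
        y = 0.4 * g + rng.normal(0, sG)
        m = make_mv(g[:, None], np.full((J, 1), 0.004), y, sG, labels=("x",))
        est = mvmr_ivw(m)
        uni = ivw(make_harmonized(g, np.full(J, 0.004), y, sG))
        assert est.beta[0] == pytest.approx(uni.beta, rel=1e-12)
        assert est.se[0] == pytest.approx(uni.se, rel=1e-10)

    def test_collinear_design_raises(self):
        g = np.linspace(0.1, 0.3, 6)
        X = np.column_stack([g, 2 * g])
        m = make_mv(X, np.full((6, 2), 0.004), 0.4 * g, np.full(6, 0.01))
        with pytest.raises(CollinearityError):
            mvmr_ivw(m)

    def test_unit_rescaling_equivariance(self):
        """Scaling one exposure's gammas by c divides its beta by c."""
        m = _fixture(seed=4)
        base = mvmr_ivw(m)
        t = m.table.copy()
        t["gamma_x2"] *= 10
        t["se_gamma_x2"] *= 10
        m2 = make_mv(np.column_stack([t["gamma_x1"], t["gamma_x2"]]),
                     np.column_stack([t["se_gamma_x1"], t["se_gamma_x2"]]),
                     t["Gamma"], t["se_Gamma"])
        scaled = mvmr_ivw(m2)
        assert scaled.beta[1] == pytest.approx(base.beta[1] / 10, rel=1e-10)
        assert scaled.beta[0] == pytest.approx(base.beta[0], rel=1e-10)


class TestRobustVariants:
    def test_clean_fixture_all_methods_agree(self):
        m = _fixture(seed=5, J=14)
        ref = mvmr_ivw(m)
        ests = {
            "egger": mvmr_egger(m),
            "median": mvmr_median(m, n_boot=100, seed=1),
            "robust": mvmr_robust(m),
            "lasso": mvmr_lasso(m),
            "qhet": mvmr_qhet(m, n_boot=30, seed=2),
        }
        for name, est in ests.items():
            for k in range(2):
                lo = min(ref.ci_low[k], est.ci_low[k])
                hi = max(ref.ci_high[k], est.ci_high[k])
                # point estimates fall inside the union of the two CIs
                assert lo <= est.beta[k] <= hi, name
                assert abs(est.beta[k] - ref.beta[k]) < 0.15, name

    def test_lasso_zeroes_exactly_the_pleiotropic_snps(self):
        m = _fixture(seed=6, J=12)
        t = m.table.copy()
        bad = [2, 7]
        t.loc[bad, "Gamma"] += 0.25  # large directional intercepts
        m2 = make_mv(np.column_stack([t["gamma_x1"], t["gamma_x2"]]),
                     np.column_stack([t["se_gamma_x1"], t["se_gamma_x2"]]),
                     t["Gamma"], t["se_Gamma"])
        est = mvmr_lasso(m2)
        removed = set(m2.table["snp_id"]) - set(est.diagnostics["retained_snps"])
        assert removed == {m2.table["snp_id"].iloc[i] for i in bad}
        truth = np.array([0.15, 0.31])
        naive = mvmr_ivw(m2)
        med = mvmr_median(m2, n_boot=50, seed=1)
        rob = mvmr_robust(m2)
        for robust_est in (med, rob, est):
            assert np.linalg.norm(robust_est.beta - truth) < \
                np.linalg.norm(naive.beta - truth)

    def test_qhet_less_null_biased_with_weak_instruments(self):
        """With large exposure-side noise, naive IVW attenuates toward zero;
        the generalized-Q estimator should attenuate less (on average)."""
        truth = np.array([0.3, 0.4])
        diffs = []
        for seed in range(5):
            rng = np.random.default_rng(900 + seed)
            J = 40
            Xtrue = np.column_stack([rng.normal(0, 0.05, J), rng.normal(0, 0.05, J)])
            SE_X = np.full((J, 2), 0.03)  # weak: noise comparable to signal
            Xobs = rng.normal(Xtrue, SE_X)
            sG = np.full(J, 0.01)
            y = Xtrue @ truth + rng.normal(0, sG)
            m = make_mv(Xobs, SE_X, y, sG)
            naive = mvmr_ivw(m).beta
            qh = mvmr_qhet(m, n_boot=5, seed=seed).beta
            diffs.append(np.linalg.norm(qh - truth) - np.linalg.norm(naive - truth))
        assert np.mean(diffs) < 0  # qhet closer to truth on average


class TestBuildMvSet:
    def _study(self, seed=21):
        return generate_study(TruthRecord(n_instruments=40, n_cis=4,
                                          n_outcome_instruments=0,
                                          gamma_sd=0.1, seed=seed))

    def test_union_semantics_and_row_count(self):
        st = self._study()
        m = build_mv_set([st.exposure_instruments, st.cis_instruments],
                         [st.exposure, st.mediator], st.outcome, ld=st.ld)
        ids = set(m.table["snp_id"]) | {s for s, _ in m.exclusions}
        union = set(st.exposure_instruments) | set(st.cis_instruments)
        assert ids <= union
        assert m.n_snps + len([e for e in m.exclusions if e[0] in union]) >= len(union) - 2

    def test_shared_snp_appears_once(self):
        st = self._study(seed=22)
        shared = st.exposure_instruments[:3]
        m = build_mv_set([st.exposure_instruments, shared + st.cis_instruments],
                         [st.exposure, st.mediator], st.outcome, ld=st.ld)
        assert m.table["snp_id"].is_unique

    def test_missing_from_second_exposure_excluded_with_reason(self):
        st = self._study(seed=23)
        # remove one instrument from the mediator dataset, no proxy possible
        victim = st.exposure_instruments[5]
        med_tab = st.mediator.table[st.mediator.table["snp_id"] != victim]
        from mrmediate.sumstats import SumStats
        mediator = SumStats("mediator", "", False, med_tab.reset_index(drop=True))
        m = build_mv_set([st.exposure_instruments, st.cis_instruments],
                         [st.exposure, mediator], st.outcome, ld=None)
        reasons = dict(m.exclusions)
        assert victim in reasons
        assert "absent from exposure mediator" in reasons[victim]

    def test_mediation_structure_recovered(self):
        """On generator data the two direct effects are recovered."""
        st = generate_study(TruthRecord(n_instruments=300, gamma_sd=0.1, seed=30))
        m = build_mv_set([st.exposure_instruments, st.cis_instruments],
                         [st.exposure, st.mediator], st.outcome, ld=st.ld)
        est = mvmr_ivw(m)
        i_exp = est.exposures.index("exposure")
        i_med = est.exposures.index("mediator")
        t = st.truth
        assert est.beta[i_exp] == pytest.approx(t.beta2_true, abs=3 * est.se[i_exp])
        assert est.beta[i_med] == pytest.approx(t.beta1_true, abs=3 * est.se[i_med])
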