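"""Multivariable MR: joint direct effects of K exposures on an outcome.

The design matrix stacks each SNP's associations with all K exposures;
weighted regression of the SNP-outcome effects on it (no intercept,
weights 1/se_Gamma^2) gives each exposure's direct effect conditional on
the others.  Robust variants: Egger (intercept after orientation), median
(weighted least absolute deviations), Robust (Tukey-bisquare M-estimation),
Lasso (L1-penalized per-SNP intercepts with a heterogeneity stopping rule)
and Q(het) (minimizing a generalized Q that propagates exposure-side
uncertainty, for weak instruments).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .estimators import InsufficientInstruments
from .harmonize import HarmonizationPolicy, HarmonizedSet, harmonize
from .ld import LDPanel
from .sumstats import SumStats, VariantAssociation, Z_95

__all__ = [
    "MVHarmonizedSet", "MVMREstimate", "build_mv_set", "mvmr_ivw",
    "mvmr_egger", "mvmr_median", "mvmr_robust", "mvmr_lasso", "mvmr_qhet",
]


class CollinearityError(ValueError):
    pass


@dataclass
class MVHarmonizedSet:
    """Per-SNP K-exposure/outcome effect matrix, aligned to a common
    effect allele per SNP."""

    table: pd.DataFrame  # snp_id, gamma_<label>..., se_gamma_<label>..., Gamma, se_Gamma
    exposures: list[str]
    exclusions: list[tuple[str, str]] = field(default_factory=list)
    outcome_trait: str = ""
    outcome_binary: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # K = 1 is allowed as a container (it reduces to univariable IVW);
        # build_mv_set itself demands >= 2 exposures
        if len(self.exposures) < 1:
            raise ValueError("need at least one exposure")

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def K(self) -> int:
        return len(self.exposures)

    @property
    def G(self) -> np.ndarray:
        return self.table[[f"gamma_{e}" for e in self.exposures]].to_numpy(float)

    @property
    def SE_G(self) -> np.ndarray:
        return self.table[[f"se_gamma_{e}" for e in self.exposures]].to_numpy(float)

    @property
    def Gamma(self) -> np.ndarray:
        return self.table["Gamma"].to_numpy(float)

    @property
    def se_Gamma(self) -> np.ndarray:
        return self.table["se_Gamma"].to_numpy(float)

    def univariable_view(self, exposure: str) -> HarmonizedSet:
        """The rows as a univariable set for one exposure column."""
        t = pd.DataFrame({
            "snp_id": self.table["snp_id"],
            "gamma": self.table[f"gamma_{exposure}"],
            "se_gamma": self.table[f"se_gamma_{exposure}"],
            "Gamma": self.table["Gamma"], "se_Gamma": self.table["se_Gamma"],
            "allele_flipped": False, "proxy_substituted": False,
            "palindromic_inferred": False, "proxy_id": "",
        })
        return HarmonizedSet(table=t, exposure_trait=exposure,
                             outcome_trait=self.outcome_trait,
                             outcome_binary=self.outcome_binary)


@dataclass
class MVMREstimate:
    """Per-exposure direct-effect estimates from one MVMR method."""

    method: str
    exposures: list[str]
    beta: np.ndarray
    se: np.ndarray
    pval: np.ndarray
    n_snps: int
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ci_low is None:
            self.ci_low = self.beta - Z_95 * self.se
        if self.ci_high is None:
            self.ci_high = self.beta + Z_95 * self.se

    def exposure_effect(self, label: str) -> dict:
        i = self.exposures.index(label)
        return {
            "beta": float(self.beta[i]), "se": float(self.se[i]),
            "ci_low": float(self.ci_low[i]), "ci_high": float(self.ci_high[i]),
            "pval": float(self.pval[i]),
        }

    def to_rows(self, or_scale: bool = False) -> list[dict]:
        rows = []
        for i, e in enumerate(self.exposures):
            d = {"method": self.method, "exposure": e,
                 "beta": float(self.beta[i]), "se": float(self.se[i]),
                 "ci_low": float(self.ci_low[i]), "ci_high": float(self.ci_high[i]),
                 "pval": float(self.pval[i]), "n_snps": self.n_snps}
            if or_scale:
                d["or"] = float(np.exp(self.beta[i]))
                d["or_ci_low"] = float(np.exp(self.ci_low[i]))
                d["or_ci_high"] = float(np.exp(self.ci_high[i]))
            rows.append(d)
        return rows


_ORIENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _align_to(rec: VariantAssociation, ref: VariantAssociation) -> tuple[float, float] | None:
    """(beta, se) of ``rec`` expressed on ``ref``'s effect allele, by letter
    comparison with strand-complement fallback for non-palindromic pairs."""
    if (rec.effect_allele, rec.other_allele) == (ref.effect_allele, ref.other_allele):
        return rec.beta, rec.se
    if (rec.effect_allele, rec.other_allele) == (ref.other_allele, ref.effect_allele):
        return -rec.beta, rec.se
    if rec.is_palindromic or ref.is_palindromic:
        return None
    cea = "".join(_ORIENT.get(b, "N") for b in rec.effect_allele)
    coa = "".join(_ORIENT.get(b, "N") for b in rec.other_allele)
    if (cea, coa) == (ref.effect_allele, ref.other_allele):
        return rec.beta, rec.se
    if (cea, coa) == (ref.other_allele, ref.effect_allele):
        return -rec.beta, rec.se
    return None


def build_mv_set(
    exposure_sets: list[list[str]],
    exposure_sumstats: list[SumStats],
    outcome: SumStats,
    ld: LDPanel | None = None,
    policy: HarmonizationPolicy | None = None,
    r2_max: float = 0.05,
) -> MVHarmonizedSet:
    """Assemble the joint instrument matrix for MVMR.

    Instruments are the union of the per-exposure sets, jointly re-clumped
    greedily with priority by the minimum p-value across exposures.  Each
    retained SNP must be present in every exposure dataset (missing ones
    are excluded with a reason); alleles are aligned to the first
    containing exposure's record, and the outcome is harmonized exactly as
    in the univariable pipeline (proxies, palindrome rules).
    """
    if len(exposure_sumstats) < 2:
        raise ValueError("need >= 2 exposures")
    labels = [s.trait_name for s in exposure_sumstats]
    K = len(labels)

    union: list[str] = []
    seen = set()
    for ids in exposure_sets:
        for s in ids:
            if s not in seen:
                seen.add(s)
                union.append(s)

    def min_p(snp: str) -> float:
        ps = [rec.pval for s in exposure_sumstats if (rec := s.get(snp)) is not None]
        return min(ps) if ps else 1.0

    ordered = sorted(union, key=lambda s: (min_p(s), s))
    kept: list[str] = []
    exclusions: list[tuple[str, str]] = []
    for snp in ordered:
        if ld is not None:
            conflict = next((k for k in kept if ld.r2(snp, k) > r2_max), None)
            if conflict is not None:
                exclusions.append((snp, f"joint clump: r2 > {r2_max:g} with {conflict}"))
                continue
        kept.append(snp)

    rows: list[dict] = []
    for snp in kept:
        ref = next((s.get(snp) for s in exposure_sumstats if snp in s), None)
        if ref is None:
            exclusions.append((snp, "absent from every exposure dataset"))
            continue
        row: dict = {"snp_id": snp}
        ok = True
        for lbl, s in zip(labels, exposure_sumstats):
            rec = s.get(snp)
            if rec is None:
                exclusions.append((snp, f"absent from exposure {lbl}"))
                ok = False
                break
            aligned = _align_to(rec, ref)
            if aligned is None:
                exclusions.append((snp, f"incompatible alleles in exposure {lbl}"))
                ok = False
                break
            row[f"gamma_{lbl}"], row[f"se_gamma_{lbl}"] = aligned
        if not ok:
            continue
        hset = harmonize([ref], outcome, ld=ld, policy=policy)
        if hset.n_snps == 0:
            exclusions.append((snp, f"outcome: {hset.exclusions[0][1]}"))
            continue
        row["Gamma"] = float(hset.table["Gamma"].iloc[0])
        row["se_Gamma"] = float(hset.table["se_Gamma"].iloc[0])
        rows.append(row)

    cols = (["snp_id"]
            + [c for lbl in labels for c in (f"gamma_{lbl}", f"se_gamma_{lbl}")]
            + ["Gamma", "se_Gamma"])
    table = pd.DataFrame(rows, columns=cols)
    if len(table) < K + 1:
        raise InsufficientInstruments(
            f"MVMR needs >= {K + 1} SNPs, only {len(table)} survived assembly")
    return MVHarmonizedSet(
        table=table, exposures=labels, exclusions=exclusions,
        outcome_trait=outcome.trait_name, outcome_binary=outcome.is_binary_outcome,
        provenance={"union_size": len(union), "jointly_clumped": len(kept)},
    )


def _check_rank(X: np.ndarray, exposures: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(
            f"rank-deficient exposure design among {exposures}")


def mvmr_ivw(m: MVHarmonizedSet, mre_floor: bool = False) -> MVMREstimate:
    """Multivariable IVW: weighted regression of Gamma on the K-column
    exposure matrix, no intercept, multiplicative random-effects scaling
    with df J-K (no floor by default)."""
    X, y, w = m.G, m.Gamma, 1.0 / m.se_Gamma**2
    J, K = X.shape
    if J < K + 1:
        raise InsufficientInstruments(f"need >= {K + 1} SNPs, got {J}")
    _check_rank(X * np.sqrt(w)[:, None], m.exposures)
    fit = sm.WLS(y, X, weights=w).fit()
    phi2 = float(fit.scale)  # Q/(J-K): the multiplicative scale
    adj = 1.0
    if mre_floor and 0 < phi2 < 1:
        adj = 1.0 / np.sqrt(phi2)
    beta, se = np.asarray(fit.params, float), np.asarray(fit.bse, float) * adj
    pval = 2 * stats.norm.sf(np.abs(beta / se))
    q = float(np.sum(w * (y - X @ beta) ** 2))
    return MVMREstimate(
        method="mvmr_ivw", exposures=list(m.exposures), beta=beta, se=se,
        pval=pval, n_snps=J,
        diagnostics={"q_stat": q, "q_df": J - K,
                     "q_pval": float(stats.chi2.sf(q, J - K))},
    )


def mvmr_egger(m: MVHarmonizedSet, mre_floor: bool = False) -> MVMREstimate:
    """MVMR-Egger: intercept added after orienting every row so the first
    exposure's association is non-negative."""
    X, y, w = m.G.copy(), m.Gamma.copy(), 1.0 / m.se_Gamma**2
    J, K = X.shape
    if J < K + 2:
        raise InsufficientInstruments(f"MVMR-Egger needs >= {K + 2} SNPs, got {J}")
    s = np.where(X[:, 0] < 0, -1.0, 1.0)
    X, y = X * s[:, None], y * s
    Xc = sm.add_constant(X)
    _check_rank(Xc * np.sqrt(w)[:, None], ["intercept"] + m.exposures)
    fit = sm.WLS(y, Xc, weights=w).fit()
    phi2 = float(fit.scale)
    adj = 1.0 / np.sqrt(phi2) if (mre_floor and 0 < phi2 < 1) else 1.0
    params, bse = np.asarray(fit.params, float), np.asarray(fit.bse, float) * adj
    beta, se = params[1:], bse[1:]
    pval = 2 * stats.norm.sf(np.abs(beta / se))
    return MVMREstimate(
        method="mvmr_egger", exposures=list(m.exposures), beta=beta, se=se,
        pval=pval, n_snps=J,
        intercept=float(params[0]), intercept_se=float(bse[0]),
        intercept_pval=float(2 * stats.norm.sf(abs(params[0] / bse[0]))),
    )


def _lad_fit(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted least-absolute-deviations via linear programming (HiGHS)."""
    J, K = X.shape
    c = np.concatenate([np.zeros(2 * K), w, w])
    # beta = bp - bn, residual split u+ - u-
    A_eq = np.hstack([X, -X, np.eye(J), -np.eye(J)])
    res = optimize.linprog(c, A_eq=A_eq, b_eq=y, method="highs",
                           bounds=[(0, None)] * (2 * K + 2 * J))
    if not res.success:
        raise RuntimeError(f"LAD solve failed: {res.message}")
    return res.x[:K] - res.x[K:2 * K]


def mvmr_median(m: MVHarmonizedSet, n_boot: int = 200, seed: int = 0) -> MVMREstimate:
    """MVMR-Median: minimizes weighted absolute residuals (weights
    1/se_Gamma^2); se by seeded parametric bootstrap."""
    X, y, w = m.G, m.Gamma, 1.0 / m.se_Gamma**2
    J, K = X.shape
    if J < K + 1:
        raise InsufficientInstruments(f"need >= {K + 1} SNPs, got {J}")
    beta = _lad_fit(X, y, w)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, K))
    for i in range(n_boot):
        Xs = rng.normal(X, m.SE_G)
        ys = rng.normal(y, m.se_Gamma)
        boots[i] = _lad_fit(Xs, ys, w)
    se = boots.std(axis=0, ddof=1)
    pval = 2 * stats.norm.sf(np.abs(beta / se))
    return MVMREstimate(method="mvmr_median", exposures=list(m.exposures),
                        beta=beta, se=se, pval=pval, n_snps=J)


def mvmr_robust(m: MVHarmonizedSet, tuning: float = 4.685) -> MVMREstimate:
    """MVMR-Robust: Tukey-bisquare M-estimation on the precision-weighted
    design (default tuning constant 4.685)."""
    X, y = m.G, m.Gamma
    J, K = X.shape
    if J < K + 1:
        raise InsufficientInstruments(f"need >= {K + 1} SNPs, got {J}")
    sw = 1.0 / m.se_Gamma
    fit = sm.RLM(y * sw, X * sw[:, None],
                 M=sm.robust.norms.TukeyBiweight(c=tuning)).fit()
    beta = np.asarray(fit.params, float)
    se = np.asarray(fit.bse, float)
    pval = 2 * stats.norm.sf(np.abs(beta / se))
    return MVMREstimate(method="mvmr_robust", exposures=list(m.exposures),
                        beta=beta, se=se, pval=pval, n_snps=J)


def mvmr_lasso(
    m: MVHarmonizedSet,
    n_lambda: int = 50,
    het_alpha: float = 0.05,
) -> MVMREstimate:
    """MVMR-Lasso: per-SNP intercepts shrunk by L1, penalty chosen by the
    heterogeneity stopping rule.

    Walking the penalty path from large to small, the first lambda whose
    zero-intercept (valid) subset has Cochran Q below its chi-square
    critical value is selected and plain MVMR-IVW is run on that subset.
    Falls back, flagged, to full-set IVW if no usable subset emerges.
    """
    X, y, w = m.G, m.Gamma, 1.0 / m.se_Gamma**2
    J, K = X.shape
    if J < K + 1:
        raise InsufficientInstruments(f"need >= {K + 1} SNPs, got {J}")

    def _ivw_beta(mask: np.ndarray) -> np.ndarray:
        Xm, ym, wm = X[mask], y[mask], w[mask]
        A = Xm.T @ (wm[:, None] * Xm)
        return np.linalg.solve(A, Xm.T @ (wm * ym))

    def _subset_q(mask: np.ndarray, beta: np.ndarray) -> float:
        r = y[mask] - X[mask] @ beta
        return float(np.sum(w[mask] * r**2))

    full = np.ones(J, bool)
    beta0 = _ivw_beta(full)
    resid0 = y - X @ beta0
    lam_max = float(np.max(w * np.abs(resid0))) * 1.0001
    lambdas = np.geomspace(lam_max, lam_max / 1000, n_lambda)

    chosen_mask: np.ndarray | None = None
    chosen_lam = np.nan
    theta = np.zeros(J)
    for lam in lambdas:
        beta = beta0.copy()
        for _ in range(100):
            r = y - X @ beta
            theta_new = np.sign(r) * np.maximum(0.0, np.abs(r) - lam / w)
            A = X.T @ (w[:, None] * X)
            beta_new = np.linalg.solve(A, X.T @ (w * (y - theta_new)))
            if np.max(np.abs(beta_new - beta)) < 1e-12:
                beta, theta = beta_new, theta_new
                break
            beta, theta = beta_new, theta_new
        valid = theta == 0.0
        if valid.sum() < K + 1:
            continue
        bhat = _ivw_beta(valid)
        q = _subset_q(valid, bhat)
        df = int(valid.sum()) - K
        if q <= stats.chi2.ppf(1 - het_alpha, df):
            chosen_mask, chosen_lam = valid, float(lam)
            break

    fallback = chosen_mask is None
    if fallback:
        warnings.warn("MVMR-Lasso found no valid subset passing the "
                      "heterogeneity rule; falling back to full-set IVW")
        chosen_mask = full
    sub = MVHarmonizedSet(
        table=m.table[chosen_mask].reset_index(drop=True),
        exposures=list(m.exposures), outcome_trait=m.outcome_trait,
        outcome_binary=m.outcome_binary)
    est = mvmr_ivw(sub)
    est.method = "mvmr_lasso"
    est.diagnostics.update({
        "lambda": chosen_lam,
        "retained_snps": m.table.loc[chosen_mask, "snp_id"].tolist(),
        "fallback_full_set": fallback,
    })
    return est


def mvmr_qhet(
    m: MVHarmonizedSet,
    n_boot: int = 100,
    seed: int = 0,
    tol: float = 1e-8,
) -> MVMREstimate:
    """MVMR-Q(het): estimates minimize a generalized Q statistic whose
    per-SNP variances propagate exposure-side uncertainty, reducing
    weak-instrument bias.  CI by seeded parametric bootstrap.
    """
    X, y = m.G, m.Gamma
    SE_X, se_y = m.SE_G, m.se_Gamma
    J, K = X.shape
    if J < K + 1:
        raise InsufficientInstruments(f"need >= {K + 1} SNPs, got {J}")

    def gen_q(beta: np.ndarray, Xm=X, ym=y) -> float:
        denom = se_y**2 + (SE_X**2) @ (beta**2)
        return float(np.sum((ym - Xm @ beta) ** 2 / denom))

    start = mvmr_ivw(m).beta

    def _minimize(fun, x0s):
        best = None
        for x0 in x0s:
            res = optimize.minimize(fun, x0, method="Nelder-Mead",
                                    options={"xatol": tol, "fatol": tol,
                                             "maxiter": 4000})
            if best is None or res.fun < best.fun:
                best = res
        return best.x

    starts = [start] + [start * (1 + d) + 0.05 * e
              for d, e in zip((0.5, -0.5), (np.ones(K), -np.ones(K)))]
    beta = _minimize(gen_q, starts)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, K))
    for i in range(n_boot):
        Xs = rng.normal(X, SE_X)
        ys = rng.normal(y, se_y)

        def q_i(b, Xs=Xs, ys=ys):
            denom = se_y**2 + (SE_X**2) @ (b**2)
            return float(np.sum((ys - Xs @ b) ** 2 / denom))

        boots[i] = _minimize(q_i, [beta])
    se = boots.std(axis=0, ddof=1)
    pval = 2 * stats.norm.sf(np.abs(beta / se))
    return MVMREstimate(method="mvmr_qhet", exposures=list(m.exposures),
                        beta=np.asarray(beta, float), se=se, pval=pval,
                        n_snps=J, diagnostics={"gen_q": gen_q(np.asarray(beta))})
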