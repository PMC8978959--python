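"""Univariable two-sample MR estimators.

The primary estimator is multiplicative random-effects IVW: weighted
regression of SNP-outcome effects Gamma_j on SNP-exposure effects gamma_j
through the origin with weights 1/se(Gamma_j)^2, standard errors scaled by
sqrt(Q/(J-1)) (residual overdispersion; not floored at 1 by default, which
matches the convention of fitting the weighted regression and using its
residual variance directly).  Sensitivity estimators: MR-Egger (intercept =
average directional pleiotropy), weighted median, and simple/weighted
mode-based estimation with a normal-kernel smoothed ratio density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .harmonize import HarmonizedSet
from .sumstats import Z_95

__all__ = [
    "MREstimate", "wald_ratio", "ivw", "egger", "weighted_median",
    "mode_estimator", "cochran_q", "run_sensitivity_suite", "SensitivitySuite",
]


class InsufficientInstruments(ValueError):
    pass


@dataclass
class MREstimate:
    """A causal-effect estimate with uncertainty and heterogeneity metadata."""

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int
    ci_low: float = np.nan
    ci_high: float = np.nan
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    i2: float | None = None

    def __post_init__(self) -> None:
        if np.isnan(self.ci_low):
            self.ci_low = self.beta - Z_95 * self.se
        if np.isnan(self.ci_high):
            self.ci_high = self.beta + Z_95 * self.se

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    def to_dict(self, or_scale: bool = False) -> dict:
        d = {
            "method": self.method, "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "pval": self.pval,
            "n_snps": self.n_snps, "q_stat": self.q_stat, "q_df": self.q_df,
            "q_pval": self.q_pval, "i2": self.i2, "intercept": self.intercept,
            "intercept_se": self.intercept_se, "intercept_pval": self.intercept_pval,
        }
        if or_scale:
            d["or"] = np.exp(self.beta)
            d["or_ci_low"] = np.exp(self.ci_low)
            d["or_ci_high"] = np.exp(self.ci_high)
        return d


def _pnorm2(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


def wald_ratio(
    gamma: float, se_gamma: float, Gamma: float, se_Gamma: float,
    second_order: bool = False,
) -> MREstimate:
    """Single-instrument ratio estimate Gamma/gamma.

    First-order delta se by default (se_Gamma/|gamma|); the second-order
    option adds the term from uncertainty in gamma.
    """
    if gamma == 0:
        raise ValueError("wald ratio undefined for gamma = 0")
    beta = Gamma / gamma
    var = se_Gamma**2 / gamma**2
    if second_order:
        var += Gamma**2 * se_gamma**2 / gamma**4
    se = float(np.sqrt(var))
    return MREstimate(method="wald_ratio", beta=float(beta), se=se,
                      pval=_pnorm2(beta / se), n_snps=1)


def _ratios(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP ratio estimates and their first-order ses; drops gamma == 0
    rows with a warning."""
    g, G, sG = h.gamma, h.Gamma, h.se_Gamma
    ok = g != 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} SNP(s) with zero exposure effect "
                      "excluded from ratio-based estimation")
    b = G[ok] / g[ok]
    se_b = sG[ok] / np.abs(g[ok])
    return b, se_b


def cochran_q(h: HarmonizedSet, beta: float) -> tuple[float, int, float, float]:
    """Cochran's Q over per-SNP ratio estimates around ``beta``.

    Weights are inverse squared first-order ratio ses (gamma^2/se_Gamma^2),
    so Q equals the weighted residual sum of squares of the origin
    regression.  Returns (Q, df, p, I^2) with I^2 = max(0, (Q-df)/Q).
    """
    b, se_b = _ratios(h)
    if b.size < 2:
        raise InsufficientInstruments("Cochran Q needs >= 2 instruments")
    w = 1.0 / se_b**2
    q = float(np.sum(w * (b - beta) ** 2))
    df = b.size - 1
    pval = float(stats.chi2.sf(q, df)) if q > 0 else 1.0
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return q, df, pval, i2


def ivw(h: HarmonizedSet, mre_floor: bool = False, use_t: bool = False) -> MREstimate:
    """Multiplicative random-effects inverse-variance-weighted estimate.

    Weighted regression of Gamma on gamma through the origin, weights
    1/se_Gamma^2.  The fixed-effect se is scaled by sqrt(Q/(J-1)); with
    ``mre_floor`` the scale is never allowed below 1.  A single instrument
    delegates to the Wald ratio with a warning.
    """
    g, G, sG = h.gamma, h.Gamma, h.se_Gamma
    J = g.size
    if J == 0:
        raise InsufficientInstruments("no instruments")
    if J == 1:
        warnings.warn("single instrument: IVW reduces to the Wald ratio")
        est = wald_ratio(g[0], h.se_gamma[0], G[0], sG[0])
        est.method = "ivw_mre"
        return est
    w = 1.0 / sG**2
    swg2 = float(np.sum(w * g * g))
    if swg2 == 0:
        raise ValueError("degenerate instrument set: all exposure effects zero")
    beta = float(np.sum(w * g * G) / swg2)
    se_fixed = float(np.sqrt(1.0 / swg2))
    q, q_df, q_pval, i2 = cochran_q(h, beta)
    phi = float(np.sqrt(q / (J - 1)))
    if mre_floor:
        phi = max(phi, 1.0)
    se = se_fixed * phi if phi > 0 else se_fixed * 1e-12
    if use_t:
        pval = float(2 * stats.t.sf(abs(beta / se), J - 1))
        zq = float(stats.t.ppf(0.975, J - 1))
    else:
        pval = _pnorm2(beta / se)
        zq = Z_95
    return MREstimate(
        method="ivw_mre", beta=beta, se=se, pval=pval, n_snps=J,
        ci_low=beta - zq * se, ci_high=beta + zq * se,
        q_stat=q, q_df=q_df, q_pval=q_pval, i2=i2,
    )


def egger(h: HarmonizedSet, mre_floor: bool = False, use_t: bool = False) -> MREstimate:
    """MR-Egger: weighted regression with an intercept after orienting all
    SNPs to gamma >= 0.

    The intercept estimates average directional pleiotropy; the slope is the
    causal estimate.  Multiplicative random-effects scaling uses df J-2.
    """
    g, G, sG = h.gamma, h.Gamma, h.se_Gamma
    J = g.size
    if J < 3:
        raise InsufficientInstruments(f"MR-Egger needs >= 3 instruments, got {J}")
    s = np.where(g < 0, -1.0, 1.0)
    gg, GG = s * g, s * G
    w = 1.0 / sG**2
    X = sm.add_constant(gg)
    fit = sm.WLS(GG, X, weights=w).fit()
    # statsmodels' sigma-hat is exactly the multiplicative scale Q/(J-2)
    phi2 = float(fit.scale)
    scale_adj = 1.0
    if mre_floor and phi2 < 1.0:
        scale_adj = 1.0 / np.sqrt(phi2) if phi2 > 0 else 1.0
    a, beta = float(fit.params[0]), float(fit.params[1])
    se_a, se_b = float(fit.bse[0]) * scale_adj, float(fit.bse[1]) * scale_adj
    resid = GG - a - beta * gg
    q = float(np.sum(w * resid**2))
    q_df = J - 2
    if use_t:
        pval = float(2 * stats.t.sf(abs(beta / se_b), q_df))
        a_pval = float(2 * stats.t.sf(abs(a / se_a), q_df))
        zq = float(stats.t.ppf(0.975, q_df))
    else:
        pval = _pnorm2(beta / se_b)
        a_pval = _pnorm2(a / se_a)
        zq = Z_95
    i2 = max(0.0, (q - q_df) / q) if q > 0 else 0.0
    return MREstimate(
        method="egger", beta=beta, se=se_b, pval=pval, n_snps=J,
        ci_low=beta - zq * se_b, ci_high=beta + zq * se_b,
        intercept=a, intercept_se=se_a, intercept_pval=a_pval,
        q_stat=q, q_df=q_df, q_pval=float(stats.chi2.sf(q, q_df)), i2=i2,
    )


def _weighted_median_point(b: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(b, kind="mergesort")
    bs, ws = b[order], w[order]
    ws = ws / ws.sum()
    s = np.cumsum(ws) - ws / 2
    return float(np.interp(0.5, s, bs))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median causal estimate over per-SNP ratios.

    Consistent when instruments contributing >= 50% of the weight are valid.
    The se comes from a seeded parametric bootstrap that redraws gamma and
    Gamma from normals with their reported ses.
    """
    if h.n_snps < 3:
        raise InsufficientInstruments("weighted median needs >= 3 instruments")
    b, se_b = _ratios(h)
    w = 1.0 / se_b**2
    est = _weighted_median_point(b, w)
    se = _bootstrap_ratio_se(h, n_boot, seed, lambda bb, ww: _weighted_median_point(bb, ww))
    return MREstimate(method="weighted_median", beta=est, se=se,
                      pval=_pnorm2(est / se), n_snps=h.n_snps)


def _mode_bandwidth(b: np.ndarray, factor: float) -> float:
    """Modified Silverman rule: 0.9 min(sd, standardized MAD) J^(-1/5)."""
    sd = float(np.std(b, ddof=1)) if b.size > 1 else 0.0
    mad = float(stats.median_abs_deviation(b, scale="normal"))
    s = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    return factor * 0.9 * s * b.size ** (-1 / 5)


def _mode_point(b: np.ndarray, w: np.ndarray, factor: float, grid_size: int = 512) -> float:
    hband = _mode_bandwidth(b, factor)
    if hband == 0 or not np.isfinite(hband):
        return float(b[0])
    grid = np.linspace(b.min() - 3 * hband, b.max() + 3 * hband, grid_size)
    dens = np.exp(-0.5 * ((grid[:, None] - b[None, :]) / hband) ** 2) @ w
    return float(grid[int(np.argmax(dens))])


def mode_estimator(
    h: HarmonizedSet,
    weighted: bool = True,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode-based estimate: argmax of the kernel-smoothed ratio density.

    Normal kernel; bandwidth = bandwidth_factor x modified-Silverman scale
    of the unweighted ratios; kernel weights 1/se(b_j)^2 when ``weighted``.
    Consistent when the largest group of instruments sharing a causal
    effect (ZEMPA) is valid.  If all ratios coincide the common ratio is
    returned directly.
    """
    if h.n_snps < 3:
        raise InsufficientInstruments("mode estimator needs >= 3 instruments")
    b, se_b = _ratios(h)

    def point(bb: np.ndarray, sb: np.ndarray) -> float:
        ww = 1.0 / sb**2 if weighted else np.ones_like(bb)
        return _mode_point(bb, ww / ww.sum(), bandwidth_factor)

    est = point(b, se_b)
    se = _bootstrap_ratio_se(
        h, n_boot, seed,
        lambda bb, ww: _mode_point(bb, ww / ww.sum(), bandwidth_factor),
        equal_weights=not weighted,
    )
    method = "weighted_mode" if weighted else "simple_mode"
    return MREstimate(method=method, beta=est, se=se,
                      pval=_pnorm2(est / se), n_snps=h.n_snps)


def _bootstrap_ratio_se(
    h: HarmonizedSet, n_boot: int, seed: int, point_fn, equal_weights: bool = False,
) -> float:
    """Parametric bootstrap over (gamma, Gamma) for ratio-based estimators."""
    rng = np.random.default_rng(seed)
    g, sg, G, sG = h.gamma, h.se_gamma, h.Gamma, h.se_Gamma
    ests = np.empty(n_boot)
    for i in range(n_boot):
        gs = rng.normal(g, sg)
        Gs = rng.normal(G, sG)
        ok = gs != 0
        bb = Gs[ok] / gs[ok]
        ww = np.ones_like(bb) if equal_weights else gs[ok] ** 2 / sG[ok] ** 2
        ests[i] = point_fn(bb, ww)
    return float(np.std(ests, ddof=1))


@dataclass
class SensitivitySuite:
    """Estimates from all univariable methods plus the concordance verdict."""

    estimates: list[MREstimate] = field(default_factory=list)
    verdict: str = "not-indicative"
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def get(self, method: str) -> MREstimate | None:
        return next((e for e in self.estimates if e.method == method), None)


def run_sensitivity_suite(
    h: HarmonizedSet,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    mre_floor: bool = False,
) -> SensitivitySuite:
    """Run IVW plus all sensitivity estimators and apply the concordance rule.

    Verdict is "causal-indicative" iff the IVW p-value is below ``alpha``
    and every available method's point estimate shares IVW's sign.  Methods
    whose instrument-count preconditions fail are recorded as skipped, not
    errors.
    """
    suite = SensitivitySuite()
    runners = [
        ("ivw_mre", lambda: ivw(h, mre_floor=mre_floor)),
        ("egger", lambda: egger(h, mre_floor=mre_floor)),
        ("weighted_median", lambda: weighted_median(h, n_boot=n_boot, seed=seed)),
        ("simple_mode", lambda: mode_estimator(h, weighted=False, n_boot=n_boot, seed=seed + 1)),
        ("weighted_mode", lambda: mode_estimator(h, weighted=True, n_boot=n_boot, seed=seed + 2)),
    ]
    for name, fn in runners:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                suite.estimates.append(fn())
        except (InsufficientInstruments, ValueError) as exc:
            suite.skipped.append((name, str(exc)))
    primary = suite.get("ivw_mre")
    if primary is not None and primary.pval < alpha:
        sign = np.sign(primary.beta)
        if all(np.sign(e.beta) == sign for e in suite.estimates):
            suite.verdict = "causal-indicative"
    return suite
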