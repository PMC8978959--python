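"""Product-of-coefficients mediation from MR estimates.

Given the univariable exposure-to-mediator effect alpha, the multivariable
(mediator-adjusted-for-exposure) direct effect beta1, and the univariable
total exposure-to-outcome effect, the indirect effect is alpha * beta1 and
the proportion mediated is indirect / total.  Uncertainty propagates by
the delta method (two-sample independence, covariances neglected), with a
seeded Monte-Carlo propagation as a cross-check.

For a binary outcome the effects are log-odds; odds-ratio
non-collapsibility can bias mediation estimates, a caveat lessened by the
product-of-coefficients decomposition and surfaced in the report output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .estimators import MREstimate
from .mvmr import MVMREstimate
from .sumstats import Z_95

__all__ = ["MediationResult", "indirect_effect", "proportion_mediated", "run_mediation"]

NONCOLLAPSIBILITY_NOTE = (
    "Binary-outcome effects are log-odds; odds-ratio non-collapsibility can "
    "bias mediation estimates, though the product-of-coefficients method "
    "lessens this."
)


def indirect_effect(
    alpha_beta: float,
    alpha_se: float,
    beta1_beta: float,
    beta1_se: float,
    mc_draws: int = 0,
    seed: int = 0,
) -> tuple[float, float]:
    """Indirect effect alpha * beta1 with delta-method se.

    se = sqrt(alpha^2 se(beta1)^2 + beta1^2 se(alpha)^2).  With
    ``mc_draws`` > 0 the se instead comes from seeded normal Monte-Carlo
    propagation (useful as an independent check of the delta formula).
    """
    if alpha_se <= 0 or beta1_se <= 0:
        raise ValueError("standard errors must be positive")
    ib = alpha_beta * beta1_beta
    if mc_draws:
        rng = np.random.default_rng(seed)
        draws = rng.normal(alpha_beta, alpha_se, mc_draws) * \
            rng.normal(beta1_beta, beta1_se, mc_draws)
        return float(ib), float(draws.std(ddof=1))
    se = float(np.sqrt(alpha_beta**2 * beta1_se**2 + beta1_beta**2 * alpha_se**2))
    return float(ib), se


def proportion_mediated(
    indirect_beta: float,
    indirect_se: float,
    total_beta: float,
    total_se: float,
    mc_draws: int = 0,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Proportion mediated = indirect / total, with a 95% CI.

    Default CI: delta method on the ratio (independence assumed).  With
    ``mc_draws`` the CI comes from percentiles of a seeded Monte-Carlo
    ratio propagation.  A proportion outside [-1, 1] is returned with a
    warning (possible when the component estimates are incoherent).
    """
    if total_beta == 0:
        raise ValueError("proportion mediated undefined: total effect is zero")
    p = indirect_beta / total_beta
    if mc_draws:
        rng = np.random.default_rng(seed)
        num = rng.normal(indirect_beta, indirect_se, mc_draws)
        den = rng.normal(total_beta, total_se, mc_draws)
        ratios = num / den
        lo, hi = np.percentile(ratios, [2.5, 97.5])
    else:
        var = (indirect_se**2 / total_beta**2
               + indirect_beta**2 * total_se**2 / total_beta**4)
        half = Z_95 * np.sqrt(var)
        lo, hi = p - half, p + half
    if abs(p) > 1:
        warnings.warn(f"proportion mediated outside [-1, 1]: {p:.3f}")
    return float(p), float(lo), float(hi)


@dataclass
class MediationResult:
    """Total/direct/indirect decomposition and proportion mediated."""

    alpha: MREstimate
    total: MREstimate
    beta1: dict        # mediator direct effect (from MVMR), beta/se/ci/pval
    beta2: dict        # exposure direct effect (from MVMR)
    indirect_beta: float
    indirect_se: float
    proportion: float
    proportion_ci_low: float
    proportion_ci_high: float
    ci_method: str = "delta"
    decomposition_discrepancy: float = np.nan
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "alpha": {"beta": self.alpha.beta, "se": self.alpha.se,
                      "ci_low": self.alpha.ci_low, "ci_high": self.alpha.ci_high},
            "total": {"beta": self.total.beta, "se": self.total.se,
                      "ci_low": self.total.ci_low, "ci_high": self.total.ci_high},
            "beta1_direct_mediator": self.beta1,
            "beta2_direct_exposure": self.beta2,
            "indirect": {"beta": self.indirect_beta, "se": self.indirect_se},
            "proportion_mediated": {
                "fraction": self.proportion,
                "percent": 100 * self.proportion,
                "ci_low": self.proportion_ci_low,
                "ci_high": self.proportion_ci_high,
                "ci_method": self.ci_method,
            },
            "decomposition_check": {
                "total_minus_direct_plus_indirect": self.decomposition_discrepancy,
                "note": ("informative only: two-sample MR estimates need not "
                         "be coherent"),
            },
            "notes": self.notes,
        }

    def write_report(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def run_mediation(
    univ_alpha: MREstimate,
    univ_total: MREstimate,
    mvmr: MVMREstimate,
    exposure_label: str,
    mediator_label: str,
    mc_draws: int = 0,
    seed: int = 0,
) -> MediationResult:
    """Assemble the mediation decomposition from its component analyses.

    ``univ_alpha`` is exposure -> mediator, ``univ_total`` is exposure ->
    outcome (both univariable); ``mvmr`` must contain both exposures.  The
    additive decomposition check total ~ beta2 + alpha*beta1 is reported as
    a discrepancy but never enforced.
    """
    if exposure_label not in mvmr.exposures or mediator_label not in mvmr.exposures:
        raise ValueError(
            f"MVMR exposures {mvmr.exposures} do not match labels "
            f"({exposure_label}, {mediator_label})")
    beta1 = mvmr.exposure_effect(mediator_label)
    beta2 = mvmr.exposure_effect(exposure_label)
    ib, ise = indirect_effect(univ_alpha.beta, univ_alpha.se,
                              beta1["beta"], beta1["se"],
                              mc_draws=mc_draws, seed=seed)
    p, lo, hi = proportion_mediated(ib, ise, univ_total.beta, univ_total.se,
                                    mc_draws=mc_draws, seed=seed + 1)
    disc = univ_total.beta - (beta2["beta"] + ib)
    notes = [NONCOLLAPSIBILITY_NOTE] if "log-odds" in (univ_total.method or "") else []
    return MediationResult(
        alpha=univ_alpha, total=univ_total, beta1=beta1, beta2=beta2,
        indirect_beta=ib, indirect_se=ise, proportion=p,
        proportion_ci_low=lo, proportion_ci_high=hi,
        ci_method="monte-carlo" if mc_draws else "delta",
        decomposition_discrepancy=float(disc),
        notes=notes or [NONCOLLAPSIBILITY_NOTE],
    )
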