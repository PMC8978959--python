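"""Harmonization of exposure instruments against an outcome dataset.

Aligns every SNP-outcome association to the exposure's effect allele,
resolving swapped alleles (sign flip), strand complements, palindromic
A/T / C/G variants (by allele-frequency concordance, else an LD proxy) and
variants missing from the outcome (LD proxy lookup).  Every input
instrument ends up either as a harmonized row or as a recorded exclusion —
never silently lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ld import LDPanel
from .sumstats import SumStats, VariantAssociation

__all__ = ["HarmonizationPolicy", "HarmonizedSet", "harmonize", "find_proxy"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _comp(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele)


@dataclass(frozen=True)
class HarmonizationPolicy:
    """Tunables for allele alignment.

    ``eaf_band`` is the ambiguity interval for palindromic strand inference:
    a palindromic SNP is kept only if both datasets' effect-allele
    frequencies fall outside the band.  ``proxy_r2_min`` is the minimum r²
    for proxy substitution.
    """

    eaf_band: tuple[float, float] = (0.42, 0.58)
    proxy_r2_min: float = 0.9
    use_proxies: bool = True


@dataclass
class HarmonizedSet:
    """Aligned per-SNP exposure/outcome effect pairs (gamma_j, Gamma_j).

    ``table`` columns: snp_id, gamma, se_gamma, Gamma, se_Gamma, plus boolean
    flag columns allele_flipped / proxy_substituted / palindromic_inferred
    and a proxy_id column.  Effects keep their signed scale relative to the
    exposure's effect allele (gamma >= 0 is not enforced).
    """

    table: pd.DataFrame
    exclusions: list[tuple[str, str]] = field(default_factory=list)
    exposure_trait: str = ""
    outcome_trait: str = ""
    outcome_binary: bool = False

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def gamma(self) -> np.ndarray:
        return self.table["gamma"].to_numpy(float)

    @property
    def se_gamma(self) -> np.ndarray:
        return self.table["se_gamma"].to_numpy(float)

    @property
    def Gamma(self) -> np.ndarray:
        return self.table["Gamma"].to_numpy(float)

    @property
    def se_Gamma(self) -> np.ndarray:
        return self.table["se_Gamma"].to_numpy(float)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def drop(self, snp_ids: Sequence[str]) -> "HarmonizedSet":
        """A copy without the named SNPs (exclusion list is not extended)."""
        drop = set(snp_ids)
        keep = ~self.table["snp_id"].isin(drop)
        return HarmonizedSet(
            table=self.table[keep].reset_index(drop=True),
            exclusions=list(self.exclusions),
            exposure_trait=self.exposure_trait, outcome_trait=self.outcome_trait,
            outcome_binary=self.outcome_binary,
        )

    def write_report(self, path: str | Path) -> None:
        """Exclusions and flags as a TSV audit trail."""
        rows = [{"snp_id": s, "status": "excluded", "detail": reason}
                for s, reason in self.exclusions]
        for r in self.table.itertuples(index=False):
            flags = [f for f in ("allele_flipped", "proxy_substituted",
                                 "palindromic_inferred") if getattr(r, f)]
            detail = ",".join(flags) if flags else "copied"
            if r.proxy_id:
                detail += f";proxy={r.proxy_id}"
            rows.append({"snp_id": r.snp_id, "status": "harmonized", "detail": detail})
        pd.DataFrame(rows, columns=["snp_id", "status", "detail"]).to_csv(
            path, sep="\t", index=False)


_ROW_COLS = ["snp_id", "gamma", "se_gamma", "Gamma", "se_Gamma",
             "allele_flipped", "proxy_substituted", "palindromic_inferred",
             "proxy_id"]


def _orientation(ea: str, oa: str, target_ea: str, target_oa: str) -> str | None:
    """'same' / 'swap' / None, allowing strand complements (non-palindromic)."""
    if (ea, oa) == (target_ea, target_oa):
        return "same"
    if (ea, oa) == (target_oa, target_ea):
        return "swap"
    cea, coa = _comp(ea), _comp(oa)
    if (cea, coa) == (target_ea, target_oa):
        return "same"
    if (cea, coa) == (target_oa, target_ea):
        return "swap"
    return None


def find_proxy(
    snp_id: str,
    ld: LDPanel,
    outcome: SumStats,
    r2_min: float = 0.9,
) -> tuple[str, float] | None:
    """Best non-palindromic LD proxy present in the outcome data.

    Highest r² wins; ties broken by smaller base-pair distance to the index
    variant, then lexicographic snp_id.  Returns (proxy_id, signed r) or
    None.
    """
    index_var = ld.variant(snp_id)
    index_pos = int(index_var["pos"]) if index_var is not None else None
    candidates = []
    for other, r in ld.neighbors(snp_id, r2_min=r2_min):
        if other not in outcome:
            continue
        var = ld.variant(other)
        if var is None:
            continue
        pair = {str(var["effect_allele"]), str(var["other_allele"])}
        if pair == {"A", "T"} or pair == {"C", "G"}:
            continue
        dist = abs(int(var["pos"]) - index_pos) if index_pos is not None else np.inf
        candidates.append((-r * r, dist, other, r))
    if not candidates:
        return None
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    _, _, proxy, r = candidates[0]
    return proxy, r


def _palindromic_align(
    v: VariantAssociation, o: VariantAssociation, band: tuple[float, float]
) -> tuple[float, bool] | None:
    """Resolve a palindromic SNP by allele-frequency concordance.

    Returns (aligned outcome beta, flipped?) or None when ambiguous.
    """
    if v.eaf is None or o.eaf is None:
        return None
    lo, hi = band
    # frequency of the allele the outcome file *writes* as effect allele,
    # re-expressed for the exposure's effect-allele letter
    if o.effect_allele == v.effect_allele:
        beta, f_out = o.beta, o.eaf
    elif o.effect_allele == v.other_allele:
        beta, f_out = -o.beta, 1 - o.eaf
    else:
        return None
    if not (v.eaf < lo or v.eaf > hi) or not (f_out < lo or f_out > hi):
        return None
    if (v.eaf < 0.5) == (f_out < 0.5):
        return beta, False
    # the written letters refer to opposite strands: true orientation is flipped
    return -beta, True


def harmonize(
    exposure_instruments: Sequence[VariantAssociation],
    outcome: SumStats,
    ld: LDPanel | None = None,
    policy: HarmonizationPolicy | None = None,
    exposure_trait: str = "",
) -> HarmonizedSet:
    """Align outcome associations to the exposure instruments' effect alleles.

    Per instrument: same-orientation records are copied; swapped alleles
    negate the outcome beta (flag ``allele_flipped``); palindromic variants
    are kept only when both effect-allele frequencies fall outside the
    ambiguity band and agree on orientation (flag ``palindromic_inferred``),
    otherwise a proxy is attempted; instruments absent from the outcome go
    through :func:`find_proxy`; everything else becomes a recorded
    exclusion.  |instruments| == |rows| + |exclusions| always holds.
    """
    policy = policy or HarmonizationPolicy()
    rows: list[dict] = []
    exclusions: list[tuple[str, str]] = []

    def _attempt_proxy(v: VariantAssociation) -> dict | None:
        if ld is None or not policy.use_proxies:
            return None
        hit = find_proxy(v.snp_id, ld, outcome, r2_min=policy.proxy_r2_min)
        if hit is None:
            return None
        proxy_id, r = hit
        o = outcome.get(proxy_id)
        pvar = ld.variant(proxy_id)
        ivar = ld.variant(v.snp_id)
        if o is None or pvar is None:
            return None
        # outcome record -> panel orientation of the proxy
        ori1 = _orientation(o.effect_allele, o.other_allele,
                            str(pvar["effect_allele"]), str(pvar["other_allele"]))
        if ori1 is None:
            return None
        beta = o.beta if ori1 == "same" else -o.beta
        # across the LD edge: sign of r carries the effect to the index
        # variant's panel-listed effect allele
        beta *= 1.0 if r >= 0 else -1.0
        # panel listing of the index variant -> exposure orientation
        if ivar is not None:
            ori2 = _orientation(str(ivar["effect_allele"]), str(ivar["other_allele"]),
                                v.effect_allele, v.other_allele)
            if ori2 is None:
                return None
            if ori2 == "swap":
                beta = -beta
        return {
            "snp_id": v.snp_id, "gamma": v.beta, "se_gamma": v.se,
            "Gamma": beta, "se_Gamma": o.se,
            "allele_flipped": False, "proxy_substituted": True,
            "palindromic_inferred": False, "proxy_id": proxy_id,
        }

    for v in exposure_instruments:
        o = outcome.get(v.snp_id)
        if o is None:
            row = _attempt_proxy(v)
            if row is not None:
                rows.append(row)
            else:
                exclusions.append((v.snp_id, "missing from outcome, no proxy"))
            continue
        if v.is_palindromic:
            aligned = _palindromic_align(v, o, policy.eaf_band)
            if aligned is None:
                row = _attempt_proxy(v)
                if row is not None:
                    rows.append(row)
                else:
                    exclusions.append((v.snp_id, "palindromic-ambiguous, no proxy"))
                continue
            beta, flipped = aligned
            rows.append({
                "snp_id": v.snp_id, "gamma": v.beta, "se_gamma": v.se,
                "Gamma": beta, "se_Gamma": o.se,
                "allele_flipped": flipped, "proxy_substituted": False,
                "palindromic_inferred": True, "proxy_id": "",
            })
            continue
        ori = _orientation(o.effect_allele, o.other_allele,
                           v.effect_allele, v.other_allele)
        if ori is None:
            exclusions.append((v.snp_id, "incompatible alleles"))
            continue
        rows.append({
            "snp_id": v.snp_id, "gamma": v.beta, "se_gamma": v.se,
            "Gamma": o.beta if ori == "same" else -o.beta, "se_Gamma": o.se,
            "allele_flipped": ori == "swap", "proxy_substituted": False,
            "palindromic_inferred": False, "proxy_id": "",
        })

    return HarmonizedSet(
        table=pd.DataFrame(rows, columns=_ROW_COLS),
        exclusions=exclusions,
        exposure_trait=exposure_trait or "exposure",
        outcome_trait=outcome.trait_name,
        outcome_binary=outcome.is_binary_outcome,
    )
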