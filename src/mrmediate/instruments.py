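"""Instrument selection: significance filtering, greedy LD clumping,
cis-window restriction and region exclusion."""

from __future__ import annotations

from dataclasses import dataclass, field

from .ld import GeneRegion, LDPanel, MHC_REGION
from .sumstats import SumStats

__all__ = ["ClumpResult", "select_instruments", "select_cis_instruments", "exclude_region"]

GENOME_WIDE_P = 5e-8


@dataclass
class ClumpResult:
    """Ordered retained instruments plus selection bookkeeping.

    Variants absent from the LD panel are treated as uncorrelated during
    clumping but listed in ``not_in_panel`` so the report can flag them.
    """

    snp_ids: list[str]
    dropped: list[tuple[str, str]] = field(default_factory=list)
    not_in_panel: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.snp_ids)

    def __len__(self) -> int:
        return len(self.snp_ids)


def select_instruments(
    s: SumStats,
    p_threshold: float = GENOME_WIDE_P,
    ld: LDPanel | None = None,
    r2_max: float = 0.05,
) -> ClumpResult:
    """Greedy p-value-ordered LD clumping of significant variants.

    Significant SNPs (p < ``p_threshold``) are visited in ascending p-value
    order (ties broken by snp_id for determinism); each is retained unless
    its r² with any already-retained SNP exceeds ``r2_max``.
    """
    sig = s.table[s.table["pval"] < p_threshold]
    result = ClumpResult(snp_ids=[])
    if sig.empty:
        result.warnings.append(
            f"{s.trait_name}: no variants at p < {p_threshold:g}")
        return result
    sig = sig.sort_values(["pval", "snp_id"], kind="mergesort")
    kept: list[str] = []
    for row in sig.itertuples(index=False):
        snp = row.snp_id
        if ld is not None and not ld.has_pairs(snp):
            result.not_in_panel.append(snp)
        if ld is not None:
            conflict = next((k for k in kept if ld.r2(snp, k) > r2_max), None)
            if conflict is not None:
                result.dropped.append((snp, f"r2 > {r2_max:g} with {conflict}"))
                continue
        kept.append(snp)
    result.snp_ids = kept
    return result


def select_cis_instruments(
    s: SumStats,
    region: GeneRegion,
    window_bp: int = 300_000,
    p_threshold: float = GENOME_WIDE_P,
    ld: LDPanel | None = None,
    r2_max: float = 0.1,
) -> ClumpResult:
    """Clump within ``region`` extended by ``window_bp`` on both sides.

    The window is inclusive at both boundaries.  Used for gene-proximal
    (cis) instrument selection, e.g. biomarker variants near the receptor
    gene they act through.
    """
    win = region.expanded(window_bp)
    mask = (s.table["chrom"].astype(str) == win.chrom) & \
        s.table["pos"].between(win.start, win.end)
    if not mask.any():
        res = ClumpResult(snp_ids=[])
        res.warnings.append(
            f"{s.trait_name}: no variants on chrom {win.chrom} in "
            f"{win.start}-{win.end}")
        return res
    sub = SumStats(
        trait_name=s.trait_name, trait_unit=s.trait_unit,
        is_binary_outcome=s.is_binary_outcome, table=s.table[mask].copy(),
    )
    return select_instruments(sub, p_threshold=p_threshold, ld=ld, r2_max=r2_max)


def exclude_region(
    instruments: list[str],
    s: SumStats,
    region: GeneRegion = MHC_REGION,
) -> tuple[list[str], list[str]]:
    """Drop instruments falling inside ``region`` (inclusive).

    Returns (retained, removed).  Positions are looked up in ``s``;
    variants without a record are retained.
    """
    retained, removed = [], []
    for snp in instruments:
        rec = s.get(snp)
        if rec is not None and region.contains(rec.chrom, rec.pos):
            removed.append(snp)
        else:
            retained.append(snp)
    return retained, removed
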