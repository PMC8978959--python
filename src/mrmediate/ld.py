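"""LD reference panels and gene regions.

The panel stores signed pairwise correlations r between variants (r² is
derived), together with a variant table giving each variant's position and
allele pair.  Signs are relative to the listed effect alleles, so a proxy
substitution with r < 0 must invert the borrowed effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = ["LDPanel", "GeneRegion", "read_ld_panel", "read_gene_regions"]


@dataclass(frozen=True)
class GeneRegion:
    """A 1-based, inclusive genomic interval (both window and region
    boundaries are inclusive throughout the package)."""

    name: str
    chrom: str
    start: int
    end: int
    assembly: str = "GRCh37"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.name}: require start < end")

    def contains(self, chrom: str, pos: int) -> bool:
        return str(chrom) == self.chrom and self.start <= pos <= self.end

    def expanded(self, window_bp: int) -> "GeneRegion":
        return GeneRegion(
            name=f"{self.name}+/-{window_bp}bp", chrom=self.chrom,
            start=max(1, self.start - window_bp), end=self.end + window_bp,
            assembly=self.assembly,
        )


#: MHC region excluded in sensitivity analyses (chr6, GRCh37; configurable)
MHC_REGION = GeneRegion("MHC", "6", 25_000_000, 35_000_000, "GRCh37")

#: IL-6 receptor gene, GRCh37 — default cis region for the IL-6 signaling proxy
IL6R_REGION = GeneRegion("IL6R", "1", 154_077_669, 154_741_926, "GRCh37")


class LDPanel:
    """Pairwise signed-correlation lookup with a variant table.

    variants: DataFrame with columns snp_id, chrom, pos, effect_allele,
    other_allele.  Correlations are symmetric; r(v, v) = 1.
    """

    def __init__(self, variants: pd.DataFrame, pairs: Iterable[tuple[str, str, float]] = ()):
        need = {"snp_id", "chrom", "pos", "effect_allele", "other_allele"}
        missing = need - set(variants.columns)
        if missing:
            raise ValueError(f"variant table missing columns: {sorted(missing)}")
        self.variants = variants.reset_index(drop=True)
        self._vindex = self.variants.set_index("snp_id")
        self._r: dict[tuple[str, str], float] = {}
        self._neighbors: dict[str, set[str]] = {}
        for a, b, r in pairs:
            self.add_pair(a, b, float(r))

    def add_pair(self, a: str, b: str, r: float) -> None:
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"r outside [-1,1]: {r}")
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        self._r[key] = r
        self._neighbors.setdefault(a, set()).add(b)
        self._neighbors.setdefault(b, set()).add(a)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._vindex.index

    def has_pairs(self, snp_id: str) -> bool:
        """Whether the panel records any correlation for this variant."""
        return snp_id in self._neighbors or snp_id in self._vindex.index

    def r(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r.get((a, b) if a < b else (b, a), 0.0)

    def r2(self, a: str, b: str) -> float:
        return self.r(a, b) ** 2

    def neighbors(self, snp_id: str, r2_min: float = 0.0) -> list[tuple[str, float]]:
        """(other variant, signed r) pairs with r² >= r2_min, unordered."""
        out = []
        for other in self._neighbors.get(snp_id, ()):
            r = self.r(snp_id, other)
            if r * r >= r2_min:
                out.append((other, r))
        return out

    def variant(self, snp_id: str) -> pd.Series | None:
        try:
            return self._vindex.loc[snp_id]
        except KeyError:
            return None

    def write(self, triplet_path: str | Path, variants_path: str | Path) -> None:
        rows = [{"snp_a": a, "snp_b": b, "r": r} for (a, b), r in sorted(self._r.items())]
        pd.DataFrame(rows, columns=["snp_a", "snp_b", "r"]).to_csv(
            triplet_path, sep="\t", index=False, float_format="%.8g")
        self.variants.to_csv(variants_path, sep="\t", index=False)


def read_ld_panel(triplet_path: str | Path, variants_path: str | Path) -> LDPanel:
    """Load a panel from a (snp_a, snp_b, r) triplet TSV plus a variant table."""
    variants = pd.read_csv(variants_path, sep="\t", dtype={"snp_id": str, "chrom": str})
    trip = pd.read_csv(triplet_path, sep="\t", dtype={"snp_a": str, "snp_b": str})
    return LDPanel(variants, trip.itertuples(index=False, name=None))


def read_gene_regions(path: str | Path) -> dict[str, GeneRegion]:
    """Read a gene-region table (name, chrom, start, end, assembly).

    Coordinates are 1-based and inclusive on both ends — a documented
    deviation from 0-based half-open BED.
    """
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "chrom": str})
    out = {}
    for row in df.itertuples(index=False):
        out[row.name] = GeneRegion(
            name=row.name, chrom=str(row.chrom), start=int(row.start),
            end=int(row.end), assembly=getattr(row, "assembly", "GRCh37"),
        )
    return out
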