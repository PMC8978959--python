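"""GWAS summary-statistic containers and readers.

Summary statistics are per-variant association records: an effect allele,
a per-allele effect estimate (beta on the trait scale, log-odds for binary
traits) with its standard error, and the usual identifiers.  Inputs that
report odds ratios with confidence intervals or p-values instead of
beta/se pairs are converted on read via :func:`or_to_beta`.

All tabular I/O is tab-separated text with a header row and ``NA`` as the
missing-value token.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantAssociation",
    "SumStats",
    "or_to_beta",
    "read_sumstats",
    "write_sumstats",
    "COLUMNS",
]

#: canonical column order for summary-statistic tables
COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

_NUCLEOTIDES = frozenset("ACGT")

#: z quantile for a two-sided 95% interval, fixed package-wide
Z_95 = 1.959964


class SumStatsError(ValueError):
    """Configuration or validation failure while reading summary statistics."""


@dataclass(frozen=True)
class VariantAssociation:
    """A single SNP-trait association.

    ``beta`` is on the trait's reported scale (log-odds for binary
    outcomes); ``se`` must be positive; ``eaf`` is the effect-allele
    frequency, strictly inside (0, 1) when present.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        problems = validate_fields(
            self.effect_allele, self.other_allele, self.beta, self.se,
            self.pval, self.eaf, self.pos,
        )
        if problems:
            raise SumStatsError(f"{self.snp_id}: {'; '.join(problems)}")

    @property
    def is_palindromic(self) -> bool:
        pair = {self.effect_allele, self.other_allele}
        return pair == {"A", "T"} or pair == {"C", "G"}


def validate_fields(effect_allele, other_allele, beta, se, pval, eaf, pos) -> list[str]:
    """Return human-readable invariant violations for one record (empty if valid)."""
    problems: list[str] = []
    ea, oa = str(effect_allele).upper(), str(other_allele).upper()
    if not ea or not set(ea) <= _NUCLEOTIDES:
        problems.append("invalid effect allele")
    if not oa or not set(oa) <= _NUCLEOTIDES:
        problems.append("invalid other allele")
    if ea == oa:
        problems.append("identical alleles")
    if beta is None or not np.isfinite(beta):
        problems.append("nonfinite beta")
    if se is None or not np.isfinite(se) or se <= 0:
        problems.append("nonpositive se")
    if pval is None or not np.isfinite(pval) or not (0 < pval <= 1):
        problems.append("pval outside (0,1]")
    if eaf is not None and not (np.isnan(eaf) or 0 < eaf < 1):
        problems.append("eaf outside (0,1)")
    if pos is not None and pos <= 0:
        problems.append("nonpositive position")
    return problems


@dataclass
class SumStats:
    """An ordered collection of :class:`VariantAssociation` for one trait.

    Backed by a pandas DataFrame in canonical column order; ``snp_id`` is
    unique within the table.
    """

    trait_name: str
    trait_unit: str
    is_binary_outcome: bool
    table: pd.DataFrame
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["line", "snp_id", "reason"])
    )

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.table.columns]
        if missing:
            raise SumStatsError(f"missing columns: {missing}")
        self.table = self.table[COLUMNS].reset_index(drop=True)
        if self.table["snp_id"].duplicated().any():
            dups = self.table.loc[self.table["snp_id"].duplicated(), "snp_id"]
            raise SumStatsError(f"duplicate snp_id(s): {sorted(set(dups))[:5]}")
        self._index = pd.Index(self.table["snp_id"])

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, snp_id: str) -> VariantAssociation | None:
        """Look up one record, or None if absent."""
        try:
            i = self._index.get_loc(snp_id)
        except KeyError:
            return None
        r = self.table.iloc[i]
        eaf = None if pd.isna(r["eaf"]) else float(r["eaf"])
        n = None if pd.isna(r["n"]) else int(r["n"])
        return VariantAssociation(
            snp_id=str(r["snp_id"]), chrom=str(r["chrom"]), pos=int(r["pos"]),
            effect_allele=str(r["effect_allele"]), other_allele=str(r["other_allele"]),
            beta=float(r["beta"]), se=float(r["se"]), pval=float(r["pval"]),
            eaf=eaf, n=n,
        )

    def records(self) -> Iterator[VariantAssociation]:
        for snp_id in self.table["snp_id"]:
            yield self.get(snp_id)  # type: ignore[misc]

    def subset(self, snp_ids: Sequence[str]) -> "SumStats":
        """Rows for the given identifiers, in the given order."""
        idx = [self._index.get_loc(s) for s in snp_ids if s in self._index]
        return SumStats(
            trait_name=self.trait_name, trait_unit=self.trait_unit,
            is_binary_outcome=self.is_binary_outcome,
            table=self.table.iloc[idx].copy(),
        )


def or_to_beta(
    or_value: float,
    ci_low: float | None = None,
    ci_high: float | None = None,
    pval: float | None = None,
    ci_level: float = 0.95,
) -> tuple[float, float]:
    """Convert an odds ratio with CI (or p-value) to a log-odds beta and se.

    beta = ln(OR).  With a confidence interval, se = (ln(hi) - ln(lo)) / (2 z)
    where z is the two-sided normal quantile for ``ci_level``.  With only a
    p-value, se = |ln(OR)| / z_p with z_p the quantile matching the two-sided
    p-value.
    """
    if or_value <= 0:
        raise ValueError(f"odds ratio must be positive, got {or_value}")
    beta = math.log(or_value)
    if ci_low is not None and ci_high is not None:
        if not (0 < ci_low <= ci_high):
            raise ValueError("require 0 < ci_low <= ci_high")
        z = float(stats.norm.ppf(0.5 + ci_level / 2))
        se = (math.log(ci_high) - math.log(ci_low)) / (2 * z)
        if se <= 0:
            raise ValueError("degenerate confidence interval (zero width)")
        return beta, se
    if pval is not None:
        if not (0 < pval < 1):
            if pval == 1 and or_value != 1:
                raise ValueError("pval = 1 with OR != 1 is degenerate")
            raise ValueError(f"pval outside (0,1): {pval}")
        z_p = float(stats.norm.ppf(1 - pval / 2))
        if z_p <= 0:
            raise ValueError("pval too large to infer a standard error")
        return beta, abs(beta) / z_p
    raise ValueError("need either (ci_low, ci_high) or pval")


def _resolve_columns(header: Sequence[str], column_map: Mapping[str, str] | None) -> dict[str, str]:
    cmap = dict(column_map or {})
    resolved: dict[str, str] = {}
    for canon in COLUMNS + ["odds_ratio", "ci_low", "ci_high"]:
        src = cmap.get(canon, canon)
        if src in header:
            resolved[canon] = src
    return resolved


def read_sumstats(
    path: str | Path,
    trait_name: str,
    trait_unit: str = "",
    is_binary_outcome: bool = False,
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
    ci_level: float = 0.95,
) -> SumStats:
    """Read a summary-statistics table, validating every row.

    ``column_map`` maps canonical names (``snp_id``, ``beta``, ``odds_ratio``,
    ``ci_low`` ...) to the file's column names.  When both a marginal and a
    conditional effect column exist, map ``beta`` to the one to use (marginal
    by convention).  Rows violating invariants are collected in
    ``SumStats.rejects`` with their 1-based data line number and reason — they
    are reported, never silently dropped.  Betas are derived from odds ratios
    via :func:`or_to_beta` when no beta column is present.
    """
    raw = pd.read_csv(path, sep=sep, na_values=["NA"], dtype={0: str})
    cols = _resolve_columns(list(raw.columns), column_map)

    mandatory = ["snp_id", "effect_allele", "other_allele"]
    missing = [c for c in mandatory if c not in cols]
    has_beta = "beta" in cols
    has_or = "odds_ratio" in cols
    if not has_beta and not has_or:
        missing.append("beta (or odds_ratio)")
    if has_beta and "se" not in cols and "pval" not in cols:
        missing.append("se (or pval)")
    if missing:
        raise SumStatsError(f"{path}: missing mandatory column(s): {missing}")

    rows: list[dict] = []
    rejects: list[dict] = []
    for i, raw_row in raw.iterrows():
        line = int(i) + 1  # 1-based data line (header not counted)
        snp_id = str(raw_row[cols["snp_id"]])

        def _num(canon: str, line=line, snp_id=snp_id, raw_row=raw_row):
            if canon not in cols:
                return None
            v = raw_row[cols[canon]]
            if pd.isna(v):
                return None
            try:
                return float(v)
            except (TypeError, ValueError):
                raise SumStatsError(
                    f"unparsable numeric in column '{cols[canon]}' line {line} ({snp_id}): {v!r}"
                )

        try:
            beta, se = _num("beta"), _num("se")
            pval = _num("pval")
            if beta is None and has_or:
                orv = _num("odds_ratio")
                if orv is None:
                    raise SumStatsError("missing odds ratio")
                beta, se = or_to_beta(orv, _num("ci_low"), _num("ci_high"),
                                      pval=pval, ci_level=ci_level)
            if se is None and beta is not None and pval is not None and 0 < pval < 1:
                se = abs(beta) / float(stats.norm.ppf(1 - pval / 2))
            if pval is None and beta is not None and se is not None and se > 0:
                pval = float(2 * stats.norm.sf(abs(beta) / se))
                pval = max(pval, np.nextafter(0, 1))
        except (SumStatsError, ValueError) as exc:
            rejects.append({"line": line, "snp_id": snp_id, "reason": str(exc)})
            continue

        ea = str(raw_row.get(cols.get("effect_allele"), "")).upper()
        oa = str(raw_row.get(cols.get("other_allele"), "")).upper()
        eaf = _num("eaf")
        pos_v = _num("pos")
        pos = int(pos_v) if pos_v is not None else 0
        problems = validate_fields(ea, oa, beta, se, pval, eaf, pos if pos else None)
        if problems:
            rejects.append({"line": line, "snp_id": snp_id, "reason": "; ".join(problems)})
            continue
        n_v = _num("n")
        rows.append({
            "snp_id": snp_id,
            "chrom": str(raw_row[cols["chrom"]]) if "chrom" in cols else "NA",
            "pos": pos,
            "effect_allele": ea, "other_allele": oa,
            "eaf": np.nan if eaf is None else eaf,
            "beta": beta, "se": se, "pval": pval,
            "n": np.nan if n_v is None else n_v,
        })

    table = pd.DataFrame(rows, columns=COLUMNS)
    return SumStats(
        trait_name=trait_name, trait_unit=trait_unit,
        is_binary_outcome=is_binary_outcome, table=table,
        rejects=pd.DataFrame(rejects, columns=["line", "snp_id", "reason"]),
    )


def write_sumstats(s: SumStats, path: str | Path) -> None:
    """Write the canonical TSV dialect (header, NA for missing)."""
    out = s.table.copy()
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
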