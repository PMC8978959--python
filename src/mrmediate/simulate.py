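"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the statistical structure of the study design: a
polygenic exposure (BMI-like, hundreds of genome-wide-significant
instruments from a very large continuous-trait GWAS), a biomarker mediator
(CRP-like, instrumented by a handful of large-effect variants in a cis
gene region standing in for the IL-6 receptor locus), and a binary outcome
(MS-like, case/control log-odds associations), tied together by the
structural model

    mediator = alpha * exposure,   outcome = beta2 * exposure + beta1 * mediator

so the total exposure-outcome effect is beta2 + alpha*beta1 and the
proportion mediated is alpha*beta1 / (beta2 + alpha*beta1).  Optional
horizontal pleiotropy perturbs the instrument-outcome paths.  Block LD
(index variants with correlation-decaying companions), palindromic
variants, swapped allele orders, strand flips and missing outcome records
exercise the harmonization machinery.

Observed effects are truth plus normal noise with standard errors from
sample size and allele frequency: se = 1/sqrt(2 n f (1-f)) on the
standardized continuous scale, and the log-odds analogue
1/sqrt(2 f (1-f) n k (1-k)) (k the case fraction) for the binary outcome.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ld import IL6R_REGION, LDPanel, GeneRegion
from .sumstats import COLUMNS, SumStats, write_sumstats

__all__ = ["TruthRecord", "LDBlockSpec", "Study", "generate_study", "generate_outliers"]

_NONPAL_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PAL_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

_PVAL_FLOOR = 1e-300


@dataclass(frozen=True)
class LDBlockSpec:
    """Block-LD structure: each index variant may carry companion variants
    whose correlation decays geometrically with rank within the block."""

    companion_fraction: float = 0.05   # fraction of exposure instruments with companions
    n_companions: int = 2
    base_r: float = 0.95               # r at rank 1; rank i has base_r**i
    cis_companions: int = 2            # every cis variant gets companions


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth generator parameters (the study conditions).

    Defaults mirror the emulated data sources: 656 exposure instruments
    from a 681,275-individual continuous-trait GWAS, a 204,402-individual
    biomarker GWAS with a handful of cis instruments, and a binary-outcome
    GWAS of 14,802 cases / 26,703 controls.
    """

    alpha_true: float = 0.37     # exposure -> mediator
    beta1_true: float = 0.31     # mediator -> outcome, direct (log-odds)
    beta2_true: float = 0.15     # exposure -> outcome, direct (log-odds)
    pleiotropy_mode: str = "none"   # none | balanced | directional | inside_violating
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0    # mean shift (directional) or slope on gamma (inside_violating)
    n_instruments: int = 656
    n_cis: int = 8
    n_outcome_instruments: int = 50
    n_mhc: int = 0                  # exposure instruments placed inside the MHC
    n_exposure: int = 681_275
    n_mediator: int = 204_402
    n_cases: int = 14_802
    n_controls: int = 26_703
    gamma_sd: float = 0.02          # per-allele exposure effects, SD units
    cis_effect_mean: float = 0.06   # cis variant effect magnitude on the mediator
    cis_effect_sd: float = 0.02
    outcome_effect_min: float = 0.10  # outcome-specific disease variants (log-odds)
    outcome_effect_sd: float = 0.05
    palindromic_fraction: float = 0.10
    swap_fraction: float = 0.30     # outcome/mediator rows written with swapped alleles
    strand_flip_fraction: float = 0.10  # outcome rows written on the other strand
    missing_outcome_fraction: float = 0.02
    ld_block_spec: LDBlockSpec = field(default_factory=LDBlockSpec)
    seed: int = 0

    @property
    def true_effect_xy(self) -> float:
        """Total exposure -> outcome effect beta2 + alpha*beta1."""
        return self.beta2_true + self.alpha_true * self.beta1_true

    @property
    def true_proportion_mediated(self) -> float:
        return self.alpha_true * self.beta1_true / self.true_effect_xy

    def validate(self) -> None:
        for name in ("palindromic_fraction", "swap_fraction",
                     "strand_flip_fraction", "missing_outcome_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} outside [0,1]: {v}")
        if self.pleiotropy_mode not in ("none", "balanced", "directional",
                                        "inside_violating"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        for name in ("n_instruments", "n_exposure", "n_mediator",
                     "n_cases", "n_controls"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class Study:
    """One synthetic two-sample study plus its truth sidecar."""

    exposure: SumStats
    mediator: SumStats
    outcome: SumStats
    ld: LDPanel
    cis_region: GeneRegion
    truth: TruthRecord
    exposure_instruments: list[str]
    cis_instruments: list[str]
    outcome_instruments: list[str]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sumstats(self.exposure, outdir / "exposure.tsv")
        write_sumstats(self.mediator, outdir / "mediator.tsv")
        write_sumstats(self.outcome, outdir / "outcome.tsv")
        self.ld.write(outdir / "ld_pairs.tsv", outdir / "ld_variants.tsv")
        pd.DataFrame([dataclasses.asdict(self.cis_region)]).to_csv(
            outdir / "regions.tsv", sep="\t", index=False,
            columns=["name", "chrom", "start", "end", "assembly"])
        sidecar = dataclasses.asdict(self.truth)
        sidecar["exposure_instruments"] = self.exposure_instruments
        sidecar["cis_instruments"] = self.cis_instruments
        sidecar["outcome_instruments"] = self.outcome_instruments
        with open(outdir / "truth.json", "w") as fh:
            json.dump(sidecar, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _se_continuous(n: int, f: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2 * n * f * (1 - f))


def _se_binary(n_cases: int, n_controls: int, f: np.ndarray) -> np.ndarray:
    n = n_cases + n_controls
    k = n_cases / n
    return 1.0 / np.sqrt(2 * f * (1 - f) * n * k * (1 - k))


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, _PVAL_FLOOR, 1.0)


def generate_study(t: TruthRecord) -> Study:
    """Draw one full synthetic study under ``t``.

    Deterministic: the same TruthRecord (seed included) yields identical
    output, byte-for-byte once written.
    """
    t.validate()
    rng = np.random.default_rng(t.seed)
    spec = t.ld_block_spec

    # --- variant scaffold -------------------------------------------------
    rows: list[dict] = []     # per-variant: snp_id, chrom, pos, alleles, f, truth per trait
    ld_pairs: list[tuple[str, str, float]] = []
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"rs{counter[0]:06d}"

    def alleles(palindromic: bool) -> tuple[str, str]:
        pool = _PAL_PAIRS if palindromic else _NONPAL_PAIRS
        return pool[int(rng.integers(len(pool)))]

    chroms = [str(c) for c in range(2, 23) if c != 6]

    def add_variant(chrom, pos, bx, bm, by, palindromic=False) -> dict:
        ea, oa = alleles(palindromic)
        v = {
            "snp_id": new_id(), "chrom": chrom, "pos": int(pos),
            "effect_allele": ea, "other_allele": oa,
            "f": float(np.clip(rng.beta(2, 2), 0.01, 0.99)),
            "bx": bx, "bm": bm, "by": by,
        }
        rows.append(v)
        return v

    def add_companions(parent: dict, n: int) -> None:
        # companions hang off the index variant; corr(comp_i, comp_j) =
        # r_i * r_j (conditional independence given the index), a valid
        # decaying block structure
        members: list[tuple[str, float]] = [(parent["snp_id"], 1.0)]
        for i in range(1, n + 1):
            sign = 1.0 if rng.random() < 0.8 else -1.0
            ri = sign * spec.base_r ** i
            c = add_variant(parent["chrom"], parent["pos"] + 500 * i,
                            ri * parent["bx"], ri * parent["bm"],
                            ri * parent["by"], palindromic=False)
            for pid, rp in members:
                ld_pairs.append((pid, c["snp_id"], ri * rp))
            members.append((c["snp_id"], ri))

    # exposure instruments
    gam = rng.normal(0.0, t.gamma_sd, t.n_instruments)
    pleio = np.zeros(t.n_instruments)
    if t.pleiotropy_mode == "balanced":
        pleio = rng.normal(0.0, t.pleiotropy_sd, t.n_instruments)
    elif t.pleiotropy_mode == "directional":
        # directional means directional on the exposure-increasing allele
        # (the orientation Egger regression uses); a mean shift on randomly
        # oriented alleles would cancel out
        pleio = rng.normal(t.pleiotropy_mean, t.pleiotropy_sd, t.n_instruments) \
            * np.where(gam < 0, -1.0, 1.0)
    elif t.pleiotropy_mode == "inside_violating":
        pleio = t.pleiotropy_mean * gam + rng.normal(0.0, t.pleiotropy_sd,
                                                     t.n_instruments)

    n_pal = int(round(t.palindromic_fraction * t.n_instruments))
    pal_mask = np.zeros(t.n_instruments, bool)
    pal_mask[rng.choice(t.n_instruments, n_pal, replace=False)] = True

    exposure_ids: list[str] = []
    for j in range(t.n_instruments):
        if j < t.n_mhc:
            chrom, pos = "6", 25_000_000 + 100_000 * (j + 1)
        else:
            chrom = chroms[j % len(chroms)]
            pos = 1_000_000 + 400_000 * (j // len(chroms)) + int(rng.integers(0, 200_000))
        v = add_variant(chrom, pos, gam[j], t.alpha_true * gam[j],
                        t.true_effect_xy * gam[j] + pleio[j],
                        palindromic=bool(pal_mask[j]))
        exposure_ids.append(v["snp_id"])
        if rng.random() < spec.companion_fraction or pal_mask[j]:
            add_companions(v, spec.n_companions)

    # cis mediator instruments inside the designated gene region
    cis_region = IL6R_REGION
    span = cis_region.end - cis_region.start
    cis_ids: list[str] = []
    for j in range(t.n_cis):
        delta = float(np.sign(rng.standard_normal()) *
                      max(0.02, rng.normal(t.cis_effect_mean, t.cis_effect_sd)))
        pos = cis_region.start + (j + 1) * span // (t.n_cis + 1)
        v = add_variant(cis_region.chrom, pos, 0.0, delta, t.beta1_true * delta)
        cis_ids.append(v["snp_id"])
        if spec.cis_companions:
            add_companions(v, spec.cis_companions)

    # outcome-specific (disease) variants: direct outcome effects only
    outcome_ids: list[str] = []
    for j in range(t.n_outcome_instruments):
        b = float(np.sign(rng.standard_normal()) *
                  (t.outcome_effect_min + abs(rng.normal(0.0, t.outcome_effect_sd))))
        chrom = chroms[(j * 3) % len(chroms)]
        pos = 200_000_000 + 150_000 * j
        v = add_variant(chrom, pos, 0.0, 0.0, b)
        outcome_ids.append(v["snp_id"])

    var = pd.DataFrame(rows)
    f = var["f"].to_numpy()

    # --- observed datasets ------------------------------------------------
    def observe(true_beta: np.ndarray, se: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        beta_hat = rng.normal(true_beta, se)
        return beta_hat, _pvals(beta_hat, se)

    def dataset(true_col: str, se: np.ndarray, trait: str, unit: str,
                binary: bool, swap: bool, strand_flip: bool,
                drop_ids: set[str]) -> SumStats:
        beta_hat, pv = observe(var[true_col].to_numpy(), se)
        eaf_obs = np.clip(f + rng.normal(0, 0.003, len(f)), 0.001, 0.999)
        tab = pd.DataFrame({
            "snp_id": var["snp_id"], "chrom": var["chrom"], "pos": var["pos"],
            "effect_allele": var["effect_allele"], "other_allele": var["other_allele"],
            "eaf": eaf_obs, "beta": beta_hat, "se": se, "pval": pv,
            "n": (t.n_cases + t.n_controls) if binary else
                 (t.n_mediator if trait == "mediator" else t.n_exposure),
        })
        if swap:
            m = rng.random(len(tab)) < t.swap_fraction
            tab.loc[m, ["effect_allele", "other_allele"]] = \
                tab.loc[m, ["other_allele", "effect_allele"]].to_numpy()
            tab.loc[m, "beta"] = -tab.loc[m, "beta"]
            tab.loc[m, "eaf"] = 1 - tab.loc[m, "eaf"]
        if strand_flip:
            comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
            is_pal = tab.apply(
                lambda r: {r["effect_allele"], r["other_allele"]} in
                ({"A", "T"}, {"C", "G"}), axis=1)
            m = (rng.random(len(tab)) < t.strand_flip_fraction) & ~is_pal
            tab.loc[m, "effect_allele"] = tab.loc[m, "effect_allele"].map(comp)
            tab.loc[m, "other_allele"] = tab.loc[m, "other_allele"].map(comp)
        if drop_ids:
            tab = tab[~tab["snp_id"].isin(drop_ids)]
        return SumStats(trait_name=trait, trait_unit=unit,
                        is_binary_outcome=binary, table=tab.reset_index(drop=True))

    se_x = _se_continuous(t.n_exposure, f)
    se_m = _se_continuous(t.n_mediator, f)
    se_y = _se_binary(t.n_cases, t.n_controls, f)

    n_miss = int(round(t.missing_outcome_fraction * len(exposure_ids)))
    missing = set(rng.choice(exposure_ids, n_miss, replace=False)) if n_miss else set()

    exposure = dataset("bx", se_x, "exposure", "SD units", False,
                       swap=False, strand_flip=False, drop_ids=set())
    mediator = dataset("bm", se_m, "mediator", "ln biomarker units", False,
                       swap=True, strand_flip=False, drop_ids=set())
    outcome = dataset("by", se_y, "outcome", "log-odds", True,
                      swap=True, strand_flip=True, drop_ids=missing)

    panel = LDPanel(var[["snp_id", "chrom", "pos", "effect_allele",
                         "other_allele"]].copy(), ld_pairs)

    return Study(
        exposure=exposure, mediator=mediator, outcome=outcome, ld=panel,
        cis_region=cis_region, truth=t,
        exposure_instruments=exposure_ids, cis_instruments=cis_ids,
        outcome_instruments=outcome_ids,
    )


def generate_outliers(
    study: Study, k: int, displacement: float, seed: int = 0,
) -> tuple[Study, list[str]]:
    """Displace ``k`` exposure instruments' outcome betas by
    ``displacement`` times their se; returns (modified study, injected ids).
    """
    if k >= len(study.exposure_instruments):
        raise ValueError("k must be smaller than the instrument count")
    if k == 0:
        return study, []
    rng = np.random.default_rng(seed)
    targets = list(rng.choice(study.exposure_instruments, k, replace=False))
    tab = study.outcome.table.copy()
    m = tab["snp_id"].isin(targets)
    signs = np.where(rng.random(int(m.sum())) < 0.5, -1.0, 1.0)
    tab.loc[m, "beta"] = tab.loc[m, "beta"] + signs * displacement * tab.loc[m, "se"]
    new_outcome = SumStats(
        trait_name=study.outcome.trait_name, trait_unit=study.outcome.trait_unit,
        is_binary_outcome=study.outcome.is_binary_outcome, table=tab,
    )
    modified = Study(
        exposure=study.exposure, mediator=study.mediator, outcome=new_outcome,
        ld=study.ld, cis_region=study.cis_region, truth=study.truth,
        exposure_instruments=list(study.exposure_instruments),
        cis_instruments=list(study.cis_instruments),
        outcome_instruments=list(study.outcome_instruments),
    )
    return modified, targets
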