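# Methods

This note documents the statistical procedures implemented in
`mrmediate`, the assumptions behind them, the tunable parameters and
their defaults, what the synthetic-data generator does and does not
emulate, and the design choices made where more than one reasonable
convention exists.

## Two-sample MR model

All estimators consume per-variant summary pairs (γ̂ⱼ, se(γ̂ⱼ)) — the
SNP-exposure association — and (Γ̂ⱼ, se(Γ̂ⱼ)) — the SNP-outcome
association, taken from two non-overlapping GWAS samples and aligned to
the same effect allele. Under the instrumental-variable assumptions
(relevance, exchangeability, exclusion restriction), each ratio Γⱼ/γⱼ
estimates the same causal effect; the estimators differ in how they pool
ratios and which assumption violations they tolerate.

Binary outcomes enter on the log-odds scale. Inputs reporting odds
ratios are converted with β = ln(OR) and se = (ln CI_hi − ln CI_lo)/(2z),
z = 1.959964; when only a p-value accompanies the OR, se = |β|/z_p with
z_p the matching two-sided normal quantile.

### IVW (primary estimator)

Weighted regression of Γ̂ on γ̂ through the origin with weights
1/se(Γ̂ⱼ)². The multiplicative random-effects convention scales the
fixed-effect standard error by φ̂ = √(Q/(J−1)), the residual
overdispersion — equivalently, the standard error the weighted
regression itself reports. φ̂ is **not** floored at 1 by default: when
instruments are less heterogeneous than their sampling noise implies,
the standard error may fall below the fixed-effect value. This matches
the convention of regression-based MR tooling; a `mre_floor` flag
provides the floored alternative, which is also common. Inference uses
the normal reference by default (`use_t` for the t alternative).

Cochran's Q is computed on the ratio scale with first-order weights
γ̂ⱼ²/se(Γ̂ⱼ)², which makes it identical to the weighted residual sum of
squares of the origin regression; I² = max(0, (Q − df)/Q), stored as a
fraction.

### Sensitivity estimators

- **MR-Egger** adds an intercept after orienting every variant so
  γ̂ⱼ ≥ 0 (the exposure-increasing allele). The intercept estimates
  average directional pleiotropy; the slope remains consistent under the
  InSIDE assumption. Multiplicative scaling uses df = J−2.
- **Weighted median**: the 50% point of the weight-ordered ratio
  distribution (inverse-variance weights on the first-order ratio
  standard errors, cumulative weights sⱼ = Σ_{k≤j} w_k − wⱼ/2, linear
  interpolation at 0.5). Consistent when valid instruments contribute
  ≥ 50% of the weight. Standard error from a seeded parametric bootstrap
  (γ̂, Γ̂ redrawn from normals with their reported ses; 1,000 draws by
  default).
- **Mode estimators**: argmax of a normal-kernel smoothed density of the
  ratios, evaluated on a 512-point grid spanning the ratio range ± 3
  bandwidths. Bandwidth = φ × 0.9·min(sd, MAD/0.6745)·J^(−1/5) (modified
  Silverman; φ = 1 by default, computed from the unweighted ratios). The
  weighted variant weights the kernel sum by 1/se²(bⱼ). If all ratios
  coincide the common ratio is returned directly. Bootstrap standard
  errors as above.
- **Wald ratio** (single instrument): first-order delta standard error
  se(Γ̂)/|γ̂| by default; a second-order option adds the γ̂-uncertainty
  term. IVW with one instrument delegates here with a warning.

### Concordance verdict

An edge is labelled `causal-indicative` only when the IVW p-value is
below 0.05 **and** every available sensitivity estimator's point
estimate shares IVW's sign; no significance threshold is applied to the
sensitivity estimators themselves, which probe robustness rather than
test hypotheses.

## MR-PRESSO

The global test statistic is the sum over variants of the leave-one-out
weighted squared residual RSSⱼ = wⱼ(Γ̂ⱼ − b₍₋ⱼ₎γ̂ⱼ)², with b₍₋ⱼ₎ the IVW
slope excluding variant j. The null distribution is simulated: Γ*ⱼ ~
N(b₍₋ⱼ₎γ̂ⱼ, se(Γ̂ⱼ)) and γ*ⱼ ~ N(γ̂ⱼ, se(γ̂ⱼ)), the statistic recomputed
per replicate (1,000 by default; the analyses this package mirrors used
10,000 when the exposure was the polygenic trait, and `n_sim` is
per-analysis in the pipeline config). Empirical p-values use the
(r+1)/(n+1) continuity correction and so are never zero.

Per-variant outlier p-values compare RSSⱼ with its simulated
counterparts; a variant is flagged below the Bonferroni threshold
α/J (α = 0.05). If variants are flagged, IVW is re-estimated without
them, and a distortion test compares the resulting shift against the
null of removing a uniformly random subset of the same size (n_sim
draws; the originating method's resampling scheme is described only
loosely, so this concrete null is a documented package choice). A gross
outlier also drags the leave-one-out slopes of clean variants, so
neighbouring flags can accompany a large injected outlier; the test
suite asserts the injected variant is flagged and minimal in p-value
rather than flagged uniquely.

## Multivariable MR

With K exposures, the J×K matrix of SNP-exposure associations is
regressed against Γ̂ (no intercept, weights 1/se(Γ̂ⱼ)²); each coefficient
is a direct effect holding the other exposures fixed. Multiplicative
scaling uses df = J−K. Assembly of the joint instrument set — the union
of per-exposure instruments, re-clumped greedily with priority by the
minimum p-value across exposures, every retained variant required in
every exposure dataset and aligned to a common effect allele, outcome
harmonized exactly as in the univariable path — is not specified by
regression-based MVMR itself and materially affects results; the
procedure here is deliberate and documented.

Robust variants:

- **Egger**: intercept added after orienting rows so the first
  exposure's association is non-negative; df = J−K−1.
- **Median**: minimizes Σ wⱼ|Γ̂ⱼ − Xⱼβ| (weighted least absolute
  deviations, solved exactly as a linear program); parametric bootstrap
  standard errors (200 draws by default).
- **Robust**: Tukey-bisquare M-estimation (tuning constant 4.685) on the
  precision-weighted design.
- **Lasso**: per-SNP intercepts θⱼ penalized by L1. Walking λ from
  λ_max (all θ = 0) downward over a 50-point geometric path, the first λ
  whose zero-θ ("valid") subset passes a Cochran-Q heterogeneity test at
  the 95% chi-square quantile is selected, and plain MVMR-IVW runs on
  that subset. If no subset with ≥ K+1 variants passes, the method falls
  back, flagged, to full-set IVW.
- **Q(het)**: minimizes the generalized Q statistic
  Σⱼ (Γ̂ⱼ − Xⱼβ)² / (se(Γ̂ⱼ)² + Σ_k β_k² se(γ̂ⱼk)²), whose denominator
  propagates exposure-side uncertainty and therefore resists
  weak-instrument dilution. Nelder-Mead from the IVW solution plus
  perturbed starts (tolerance 1e-8); confidence intervals by parametric
  bootstrap (100 draws by default).

Conditional F-statistics for instrument strength are intentionally not
computed (out of scope); no sample-overlap correction is applied — when
exposure and outcome GWAS share participants the estimates can be
biased toward the observational association, and the package simply
reports what the summary data imply.

## Mediation

Product of coefficients: indirect = α̂·β̂₁ with delta-method variance
α̂²se(β̂₁)² + β̂₁²se(α̂)² (two-sample independence; covariance neglected);
proportion mediated = indirect/total with a delta-method CI on the
ratio. Both have seeded Monte-Carlo alternatives (100,000 draws) used as
cross-checks in the tests; the delta and Monte-Carlo intervals agree
closely only when the component ses are small relative to the
estimates, and the ratio CI in particular is approximate — which is why
the package does not claim any specific published interval for this
quantity. A proportion outside [−1, 1] is returned with a warning: it
can legitimately occur when the three separately-estimated components
are incoherent.

For binary outcomes the decomposition operates on log-odds, where
odds-ratio non-collapsibility can bias mediation estimates; the product
of coefficients lessens but does not remove this, and the caveat is
embedded in every mediation report. The additive check
total ≈ β₂ + α·β₁ is reported as a discrepancy but never enforced.

## Harmonization

Per instrument, against the outcome dataset: identical allele pairs are
copied; swapped pairs negate the outcome beta (flag `allele_flipped`);
non-palindromic pairs matching after strand complement are treated as
same-strand records. Palindromic variants (A/T, C/G) cannot be resolved
by letters: they are kept only when both datasets' effect-allele
frequencies fall outside the ambiguity band (0.42, 0.58) and agree on
orientation (flag `palindromic_inferred`); otherwise an LD proxy is
sought. Instruments absent from the outcome also go through proxy
search: the highest-r² non-palindromic panel neighbour with r² ≥ 0.9
present in the outcome, ties broken by base-pair distance then
lexicographic identifier (the tie-break is a package convention), with
the sign of r carrying the effect across the substitution. Everything
else becomes a recorded exclusion; |instruments| = |rows| + |exclusions|
always. The ambiguity band is a package convention — frequency-based
strand inference needs *some* threshold and none is canonical — and is
configurable.

Conventions: all genomic coordinates are 1-based and inclusive at both
ends (including cis windows; the gene-region TSV deviates deliberately
from 0-based half-open BED). The MHC exclusion region defaults to
chr6:25–35 Mb (GRCh37), configurable, since the locus is usually named
rather than delimited. Clumping thresholds differ by context: r² > 0.05
exclusion for genome-wide instruments, r² < 0.1 within cis windows; both
are exposed as parameters rather than reconciled, as is the cis window
(300 kb) itself. When a source reports both marginal and conditional
effects, the column map should point at the marginal column (the
package's convention for its own outputs). Variants absent from the LD
panel are kept during clumping but flagged — silently discarding them
would bias instrument counts.

## Synthetic-data generator

`TruthRecord` fixes the structural model of the mediation DAG:
per-variant exposure effects γⱼ ~ N(0, gamma_sd²); mediator effects
α·γⱼ plus cis-only instruments (effect magnitudes |N(cis_effect_mean,
cis_effect_sd²)|, sign random, placed inside an IL-6R-sized gene region
on chr1); outcome effects (β₂ + α·β₁)γⱼ + pⱼ with pleiotropy pⱼ by mode
(none; balanced zero-mean; directional, mean-shifted **on the
exposure-increasing allele** — the orientation the Egger intercept
detects, since a mean shift on randomly oriented alleles cancels; or
correlated with γⱼ, violating InSIDE). Outcome-specific disease
variants with direct log-odds effects support reverse-direction
analyses. Observed statistics are truth plus normal noise with
se = 1/√(2nf(1−f)) for continuous traits and the log-odds analogue
1/√(2f(1−f)·n·k(1−k)) for the case/control outcome.

Defaults are the emulated study's conditions: 656 exposure instruments,
exposure GWAS n = 681,275; mediator GWAS n = 204,402; outcome 14,802
cases / 26,703 controls; cis region = the IL-6R coordinates on GRCh37.
Realism choices where no value is dictated: gamma_sd = 0.02 (typical
polygenic per-allele effects in SD units), cis effects ~ 0.06, allele
frequencies Beta(2, 2), 10% palindromic variants, 30% swapped-allele and
10% strand-flipped rows in the outcome/mediator files, 2% of instruments
missing from the outcome (exercising proxies), and block LD built from
index variants with companions at geometrically decaying r (companion
pairs correlated as rᵢ·rⱼ, i.e. conditionally independent given the
index).

What the generator does **not** emulate: realistic genome-wide LD maps
(only block structure), sample overlap between datasets, population
stratification, winner's-curse in the discovery of instruments, INDELs
or multi-allelic variants. Passing recovery tests therefore demonstrate
estimator and pipeline correctness under the stated model, not
robustness to those artefacts of real data.

## Replicate experiments: design

The test suite runs several seeded replicate experiments; their settings
are part of the experimental design, chosen by power analysis:

- **Parameter recovery** (200 replicates; α = 0.37, β₁ = 0.31,
  β₂ = 0.15, 500 instruments, no pleiotropy) uses a strong-instrument
  regime on both sides: gamma_sd = 0.15, and 24 cis variants with
  magnitudes ~0.15 (large-effect biomarker cis variants, as at the CRP
  locus). Both follow the same analytic argument: regression-dilution
  bias from exposure-side measurement error scales as Σse²/Σγ̂²
  (univariable) and as J·σ_m²/Σδ² for the MVMR mediator coefficient
  (conditional instrument strength), and the experiment must keep those
  biases well inside the 3-Monte-Carlo-se acceptance band so that it
  measures estimator correctness, not instrument strength. For the same
  reason the recovery harness harmonizes the generator's designated
  instruments directly instead of re-selecting at p < 5e-8, which would
  add winner's-curse selection bias that is a property of the data
  regime, not of the estimators.
- **Type-I calibration** (1,000 null replicates, 100 instruments,
  balanced pleiotropy sd 0.003): multiplicative random-effects inference
  is exactly calibrated when heterogeneity scales with sampling
  variance; under *additive* heterogeneity with heteroscedastic ses the
  single multiplicative factor under-corrects, inflating rejection
  mildly and increasingly with the heterogeneity magnitude. The
  experiment uses a mild balanced-pleiotropy level accordingly, and
  this limitation of the estimator's convention is worth knowing when
  interpreting real-data p-values under strong heterogeneity.
- **Verdict-frequency experiments** (reverse-null, outlier power) run
  the sensitivity suite with reduced bootstrap draws: the concordance
  verdict depends only on point estimates and the IVW p-value, not on
  bootstrap standard errors.
- Problem sizes throughout (instrument counts, simulation and bootstrap
  draws) are chosen so each experiment completes in seconds to a couple
  of minutes while leaving its statistical conclusion unambiguous.

## Numerical details and degenerate inputs

- Seeds: everything stochastic (bootstraps, PRESSO simulations, the
  generator, Monte-Carlo propagation) takes an explicit seed; the
  pipeline splits one global seed per stage by CRC32 of the stage name,
  keeping every derived seed below 2³¹. Identical inputs and seeds give
  byte-identical outputs.
- Zero exposure effects: Wald ratio errors; IVW errors only if *all*
  γ̂ = 0; ratio-based estimators drop γ̂ = 0 rows with a warning.
- Exact proportionality (Q = 0): the unfloored multiplicative se
  degenerates toward zero; a tiny positive floor (1e-12 × fixed se)
  keeps downstream arithmetic finite.
- All-identical ratios: the mode estimators return the common ratio
  without density evaluation.
- Rank-deficient MVMR designs raise a collinearity error naming the
  exposures rather than returning unstable solutions.
- Empirical p-values are continuity-corrected; parametric p-values are
  floored at the smallest positive double when converted from extreme z.

## Known limitations

- LD is consumed as pairwise r from a local panel; no external LD
  services, no genotype-level data.
- No Steiger direction filtering, RAPS, or estimators beyond the suite
  described; no conditional-F diagnostics; no overlap correction.
- The proportion-mediated CI is approximate (delta or Monte-Carlo on a
  ratio); for weak total effects it can be badly behaved, and the
  package warns rather than truncates.
- The sensitivity-verdict rule is a transparent heuristic, not a
  decision procedure with controlled error rates.
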