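# Methods

This note documents the statistical models implemented in `mrkit`, the
assumptions they make, the synthetic-data generator used to verify them, and
the numerical choices made where the design was genuinely open.

## The two-sample MR model

A genetic variant j is a valid instrument for exposure X on outcome Y if it
(i) is associated with X, (ii) is independent of confounders of the X–Y
relationship, and (iii) affects Y only through X (no horizontal pleiotropy).
With summary statistics (β̂_Xj, σ_Xj) from one GWAS and (β̂_Yj, σ_Yj) from
another, each instrument supplies a Wald ratio θ̂_j = β̂_Yj/β̂_Xj estimating
the causal effect θ.

**IVW.** The inverse-variance-weighted estimate

θ̂ = Σ_j w_j β̂_Xj β̂_Yj / Σ_j w_j β̂_Xj²,  w_j = σ_Yj⁻²

is the weighted regression of outcome on exposure effects through the
origin, and is algebraically identical to the fixed-effect meta-analysis of
the Wald ratios (asserted to 1e-10 in the tests). The fixed-effect standard
error is (Σ_j w_j β̂_Xj²)^(-1/2). The default multiplicative random-effects
variant scales it by max(1, √(Q/(J−1))), Q being Cochran's statistic at the
fixed-effect estimate: balanced pleiotropy widens the interval but never
narrows it. Consequence worth stating plainly: under perfect homogeneity
the random-effects p-values are conservative, not uniform — exact null
calibration is a property of the fixed-effect variant only, and that is the
variant the calibration studies in `scripts/acceptance.py` assert on (the
random-effects rate is reported alongside as a bound). First-order Wald
ratio standard errors (σ_Yj/|β̂_Xj|) are used throughout; a second-order
option that adds the exposure-side delta-method term is available on
`wald_ratio`.

**MR-Egger.** Weighted regression β̂_Yj = a + θ β̂_Xj with weights w_j and a
free intercept. Under the InSIDE assumption (pleiotropic effects independent
of instrument strengths), the intercept a estimates the mean directional
pleiotropy and the slope remains consistent for θ. SNPs are first oriented
so every β̂_Xj ≥ 0; the fit is invariant to per-SNP sign flips, so this is
purely a convention, but it matters for interpreting the intercept's sign.
Both standard errors use multiplicative inflation max(1, √(Q′/(J−2))) and t
inference with J−2 df — at the J ≈ 7–15 instruments typical of single-trait
exposures the t and normal references differ materially. The regression is
performed by statsmodels WLS; the inflation floor is applied on top of its
scale estimate. One caveat the verification studies surface: the orientation
step flips the pleiotropy sign of any instrument whose *observed* exposure
effect is negative, so with instruments not bounded away from zero the
intercept is slightly attenuated. The pleiotropy studies therefore filter
instruments at genome-wide significance first — which is also what the
analysis pipeline itself does, and the regime in which Egger's relevance
assumption holds.

**Weighted median.** Per-SNP ratios θ̂_j weighted by β̂_Xj²/σ_Yj⁻²-scale
weights (the inverse first-order ratio variances), normalized to sum 1.
Ratios are sorted, cumulative midpoint positions p_j = Σ_{k≤j} w_k − w_j/2
computed, and the estimate linearly interpolates θ̂ across the two positions
bracketing 0.5; if 0.5 falls outside all midpoints the estimate clamps to
the extreme ratio (defined behaviour at tiny J). The estimator is consistent
when at least half the weight comes from valid instruments. Its standard
error is the standard deviation of the estimate over n_boot = 1000 (default)
parametric-bootstrap replicates drawing β̂*_Xj ~ N(β̂_Xj, σ_Xj²) and
β̂*_Yj ~ N(β̂_Yj, σ_Yj²) from a caller-supplied seed; nonparametric
resampling of SNPs would be invalid at small J. Instruments with β̂_Xj = 0
are excluded with a warning (their ratio is undefined).

All log-scale estimates are reported with OR = exp(β) and
CI = exp(β ± z_{1−α/2}·se), α = 0.05 by default.

## Diagnostics

**Cochran's Q / Rücker's Q′.** Q = Σ_j w_j (β̂_Yj − θ̂ β̂_Xj)² at the
fixed-effect IVW estimate (df J−1); Q′ is the analogous weighted RSS around
the Egger fit (df J−2). Because the Egger fit minimizes the same objective
over a strictly larger parameter space, Q′ ≤ Q always — asserted on every
random instance in the tests. Upper-tail chi-square p-values.

**Leave-one-out.** The default IVW estimate recomputed J times with each SNP
removed; entries whose reduced set cannot support the model are marked not
computable rather than erroring the whole panel.

**MR-PRESSO.** The observed residual sum of squares compares each SNP's
outcome effect with its leave-one-out fixed-effect IVW prediction:
RSS = Σ_j w_j (β̂_Yj − θ̂_(−j) β̂_Xj)². The global test simulates n_sim
(default 1000) datasets from the no-pleiotropy model
(β*_Xj ~ N(β̂_Xj, σ_Xj²), β*_Yj ~ N(θ̂_(−j) β̂_Xj, σ_Yj²)), fully re-analyses
each (leave-one-out predictions recomputed on the simulated data), and
reports the add-one-corrected empirical p-value, so p ∈ [1/(n_sim+1), 1] and
is never exactly zero. Per-SNP outlier p-values compare observed and
simulated squared residuals, Bonferroni-multiplied by J and capped at 1;
SNPs below the outlier α (default 0.05) are flagged. When outliers exist,
the corrected estimate is the fixed-effect IVW on the non-outlier set, and
the distortion p-value compares its displacement from the full-set estimate
against displacements under random removal of equally many SNPs. All draws
occur in snp_id-sorted order, making every diagnostic invariant to input row
order at a fixed seed. The minimum instrument count is 4, matching the
method's own requirement.

## Genetic risk scores

Individual-level: GRS_i = Σ_j β_j G_ij on 0/1/2 allele doses; missing doses
are imputed to 2·EAF when frequencies are available, otherwise the
individual's score is NaN (logged). Association is tested by OLS
(continuous outcome) or maximum-likelihood logistic regression (binary),
both via statsmodels; non-convergence (separation) raises a distinct error.
For a continuous outcome the exported "OR" column is exp(slope), kept only
for table-shape compatibility and labelled as such.

Summary-level: with weights w_j = β̂_Xj (score per exposure-increasing
allele effect), the score-outcome association collapses algebraically to
fixed-effect inverse-variance weighting:

α̂ = Σ_j w_j β̂_Yj/σ_Yj² / Σ_j w_j²/σ_Yj²,  se = (Σ_j w_j²/σ_Yj²)^(-1/2)

— identical to IVW to 1e-10, the module's master invariant. The score
heterogeneity statistic Q_rs = Σ_j (β̂_Yj − α̂ w_j)²/σ_Yj² uses df J−1 (one
fitted parameter).

## Power

The IVW estimate is asymptotically N(θ, 1/(n·R²·v)) with n the outcome
sample size, R² the exposure variance explained by the instruments, and
v = k(1−k) for a binary outcome with case fraction k (v = 1 continuous).
Two-sided power at level α is Φ(√(nR²v)·|θ| − z_{1−α/2}) +
Φ(−√(nR²v)·|θ| − z_{1−α/2}), which returns exactly α at θ = 0 and is
monotone in n, R², |θ|. Minimum n inverts the dominant term in closed form,
then verifies and adjusts by direct evaluation so the returned integer is
exactly minimal. The approximation treats instruments as strong (exposure
sampling error ignored); the verification grid holds the closed form within
0.04 of empirical IVW rejection rates across n ∈ {2000, 5000, 10000} and
θ ∈ {0.05, 0.1, 0.15} at 1000 replicates per cell.

## The synthetic generator

`simulate_two_sample` emulates the sampling structure two-sample MR assumes.
Per SNP: MAF p_j ~ Uniform(maf_range); true exposure effect
γ_j = |N(0, γ_sd²)| — oriented positive because GWAS instruments are
conventionally reported per exposure-increasing allele, and because with
sign-symmetric effects directional pleiotropy would induce no systematic
IVW bias, leaving nothing for robust estimators to be robust against;
pleiotropic outcome effect α_j drawn N(0, τ²) (balanced) or N(μ, τ²)
(directional) on a configurable invalid fraction, with optional gross
outliers of |α_j| = outlier_scale·σ_Yj. Standard errors follow the
standardized-trait approximation σ = 1/√(2np(1−p)·v), which makes
instrument strength controllable through n and γ_sd. Observed effects are
γ_j and θγ_j + α_j plus independent Gaussian noise in the two samples
(instrument effects drawn once — no winner's-curse modelling). Reporting
artifacts (allele swaps with negated beta and complemented frequencies,
strand flips, palindromic allele pairs) and compound-symmetric LD blocks
exercise harmonization and clumping. Truth, observation noise, allele
assignment, and artifacts consume separate child streams of the seed, so
switching artifacts on cannot change the underlying effects — the basis of
the bit-level invariance study.

Defaults mirror a serum-biomarker exposure GWAS (n = 39,883) against a
binary neurodegenerative-disease outcome GWAS (n = 54,162, 31.4% cases)
with ~10 instruments, 15% palindromic variants, and no true causal effect.
γ_sd = 0.15 was chosen once as a per-allele effect scale typical of a
strongly heritable biomarker, large enough that most candidate instruments
clear p < 5×10⁻⁸ at that exposure sample size.

What the generator does **not** emulate — and hence what passing studies do
not demonstrate about real data: realistic LD from a reference panel (blocks
are compound-symmetric), winner's curse from in-sample instrument discovery,
sample overlap between the two GWAS, population stratification, and
non-collapsibility of odds ratios for binary outcomes (outcome effects are
generated on a linear scale). The bidirectional pipeline also inherits the
design's known limitation that a strong forward effect contaminates the
reverse direction via mediated signal; no Steiger-type filtering is applied.

## Study conditions used for verification

The simulation studies in `scripts/acceptance.py` (shared by
`tests/test_acceptance.py`) use: null calibration J = 50,
n_X = n_Y = 100,000, 1000 replicates; recovery θ = 0.2, J = 30,
n_X = 500,000, n_Y = 100,000, 500 replicates (the large exposure GWAS keeps
weak-instrument dilution around 5×10⁻⁴ relative, far below Monte-Carlo
resolution); pleiotropy μ = 0.05, τ = 0.01, J = 30 with genome-wide
significance filtering, 200 replicates; MR-PRESSO detection with one
10-outcome-se outlier among J = 20 (100 replicates) and clean-null
calibration at θ = 0 (500 replicates); heterogeneity moments at J = 15 over
1000 replicates; artifact invariance over 20 seeds; and the 3×3 power grid
described above. Artifact fractions are zeroed in calibration studies where
the instrument count is prescribed. These sizes give each Monte-Carlo
quantity a standard error several times smaller than its acceptance band
while keeping the whole battery a sub-minute run.

## Numerical choices and edge cases

- Threshold comparisons follow the conventional strict forms: significance
  filter p < threshold, clump removal r² > threshold, proxy r² > threshold.
- Clumping visits candidates in (p-value, snp_id) order; the snp_id
  tie-break makes output invariant to input row order. The distance window
  is measured from the index SNP. Records lacking chrom/pos are treated as
  independent with a logged warning (estimation does not need positions;
  only the distance rule does).
- Variance explained uses the F-based identity r² = F/(F + n − 2) because
  allele frequencies may be absent; when EAF is present the 2β²p(1−p) value
  is logged for comparison.
- Palindrome policy defaults to drop. The frequency-rescue alternative
  orients A/T and C/G SNPs from allele frequencies when both are farther
  than 0.08 from 0.5; below that the strand call is too uncertain and the
  SNP is dropped.
- Harmonization drops indels/irreconcilable allele pairs as mismatches; the
  record model is biallelic-SNP only. Zero survivors raise an estimation
  error naming the largest drop category.
- Empirical p-values use the add-one correction; reported p-values are
  clamped into (0, 1].
- Missing-value tokens: "NA" on output; "NA", "", "." accepted on input.
  Floats are written with repr so file round-trips are exact.
- Human-readable exports round ORs/CIs/Q to 3 decimals and p-values to 3
  significant figures; `report.json` keeps full precision, and all
  stochastic stages derive their seeds from the run seed, making reruns
  byte-identical.
- Multiple outcomes are screened without multiple-testing correction;
  significance is flagged at p < 0.05 and the report header carries the
  caveat.
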