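# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `causalmr`, in the spirit of the model
documentation shipped by simulation and statistics packages.

## Two-sample summary-level MR

The package operates entirely on summary statistics: per-variant effect
sizes, standard errors, allele frequencies and p-values from one GWAS of
the exposure and an independent GWAS of the outcome. Effects are in SD
units for continuous traits and log-odds for case-control traits; odds
ratios reported for binary outcomes are per SD of a continuous exposure or
per unit log-odds of a binary exposure. The three instrumental-variable
assumptions (relevance, independence from confounders, no direct outcome
path) are addressed operationally: relevance by the p < 5×10⁻⁸ selection
and the F ≥ 10 weak-instrument rule; independence is untestable from
summary data; exclusion-restriction violations are probed by the Egger
intercept, heterogeneity statistics, MR-PRESSO, leave-out re-estimation
and user-supplied pleiotropic-variant exclusion lists.

### Instrument processing

- **Selection** keeps variants with p strictly below the threshold
  (boundary ties are vanishingly rare in practice; strictness makes the
  rule unambiguous). Per-SNP strength is F = (β̂ₓ/σₓ)² and variance
  explained R² = 2β̂ₓ²·EAF·(1−EAF); pooled R² is the sum, valid under the
  post-clumping independence assumption. Missing EAF yields a missing R²,
  never an imputed one.
- **Clumping** is the standard greedy algorithm: sort by p ascending,
  keep the best remaining SNP, discard SNPs with panel r² at or above the
  cutoff within the window (default 10,000 kb, r² 0.001). Variants on
  different chromosomes or lacking positions are compared on r² alone.
  LD panels are always supplied by the user or the simulator; the package
  never computes LD from genotypes or queries a reference service, which
  keeps every analysis deterministic and offline.
- **The F ≥ 10 filter is applied after clumping** in the pipeline (a
  post-clumping filter cannot resurrect pruned neighbours; applying it
  earlier would let a weak lead SNP shadow a strong one). The standalone
  `select_instruments` applies it directly unless told to defer.
- **Harmonization** aligns outcome rows to the exposure's effect allele:
  swapped alleles negate the outcome effect and flip its EAF; strand flips
  are resolved by complementing. Palindromic (A/T, C/G) variants cannot be
  resolved from alleles; the default `drop_ambiguous` policy drops them
  when either trait's EAF lies in [0.42, 0.58] (the established community
  band; configurable) and otherwise infers orientation from frequency
  agreement. `drop_all` is available for the conservative choice. Proxy
  substitution (r² > 0.8 from a user-supplied table) replaces only the
  outcome row; the exposure effect remains the original instrument's, and
  the proxy's alleles must still harmonize.

### Estimators

Formulas are given in the README. Numerical choices:

- IVW's default error model is *multiplicative floored*: the fixed-effect
  SE times max(1, √(Q/(k−1))). This follows common MR-package practice —
  under-dispersion never shrinks the interval below the fixed-effect one.
  The pure fixed-effect model is exposed as an option. With one instrument
  IVW degrades to the Wald ratio and says so in a note.
- MR-Egger orients each SNP so β̂ₓⱼ ≥ 0 (the fit is invariant to joint
  sign flips, and the intercept is only interpretable on this
  orientation), fits weighted least squares via statsmodels, and floors
  the residual scale at 1 exactly as IVW does. CIs and intercept tests use
  t(k−2); IVW/median/mode use normal quantiles — matching the conventions
  of each method's source publication.
- The weighted median interpolates the ordered ratios at cumulative-weight
  midpoint 0.5 with weights β̂ₓⱼ²/σᵧⱼ² (inverse first-order ratio
  variance). Its SE is the SD of the estimate over a seeded parametric
  bootstrap drawing β̂ₓⱼ* ~ N(β̂ₓⱼ, σₓⱼ), β̂ᵧⱼ* ~ N(β̂ᵧⱼ, σᵧⱼ); the default
  1000 replicates are recorded in the estimate metadata.
- The weighted mode (NOME-assumption variant only) maximizes the weighted
  Gaussian kernel density over a 10,001-point grid spanning
  [min θ − 3h, max θ + 3h] with bandwidth h = φ·0.9·min(sd, 1.4826·mad)·
  k^(−1/5) (MAD scaled for normal consistency, default φ = 1). Bootstrap
  replicates reuse the same machinery on a 1,001-point grid, ample for a
  standard deviation. If all ratios coincide the bandwidth is zero and the
  common ratio is returned directly. Simple and penalized mode variants
  are out of scope.
- All p-values are two-sided and floored at the smallest positive double.

### Diagnostics

Cochran's Q uses weights (β̂ₓⱼ/σᵧⱼ)² about the IVW estimate, df k−1,
I² = max(0, (Q−df)/Q)·100. Rucker's Q′ is the weighted residual sum about
the Egger fit on the oriented data, df k−2; Q′ ≤ Q always (nested models),
and Q′/Q near 1 says the intercept explains little of the heterogeneity.

MR-PRESSO follows the published residual-sum algorithm: the observed
statistic is Σⱼ σᵧⱼ⁻²(β̂ᵧⱼ − θ̂₍₋ⱼ₎β̂ₓⱼ)² with leave-one-out IVW
predictions; the null distribution comes from parametric replicates drawn
under the leave-one-out model, each evaluated with its *own* leave-one-out
predictions (fully vectorized). The global p is the exceedance proportion,
reported as "<1/n_sim" when nothing exceeds — an empirical p of exactly
zero is never printed. Per-SNP exceedance p-values are Bonferroni-adjusted
by k; the distortion test is deliberately not implemented — outlier-
corrected estimates are obtained by excluding flagged SNPs and
re-estimating, which keeps the correction explicit. Default n_sim = 1000,
configurable.

### Direction, power, multiplicity

The Steiger test compares pooled instrument R² in the two traits via
Fisher-z transformed correlations, z = (atanh r_x − atanh r_y) /
√(1/(n_x−3) + 1/(n_y−3)). For binary traits R² is computed on the observed
log-odds scale with the same 2β²·EAF(1−EAF) formula — an approximation,
flagged in the result. When outcome EAFs are unavailable the per-SNP
fallback r² = F/(F + n − 2) is used. Total (not effective) case-control n
is the default, configurable. Directionality requires a strict inequality,
so an exactly symmetric configuration reports `direction_ok = False`.

Binary-outcome power uses the normal approximation with noncentrality
NCP = n·R²·K(1−K)·(ln OR)²: power = Φ(√NCP − z₁₋α/₂). The detectable
effect at a target power is found by root bracketing on ln OR (tolerance
1e−10); risky and protective solutions are exact reciprocals because the
formula depends on |ln OR| only. The approximation is cross-validated in
the tests against an individual-level Monte-Carlo oracle (logistic score
tests on simulated cohorts at a down-scaled n with NCP preserved); the
agreement degrades for |ln OR| ≳ 0.6, where the logistic nonlinearity
bites, so the cross-check uses a moderate odds ratio.

The family-wise threshold is α/n_tests. With `n_tests: auto` the pipeline
counts exposure×outcome pairs times requested directions; a bidirectional
run triggers a warning noting that some studies nonetheless divide by the
one-way count, because the doubling convention is genuinely ambiguous in
the literature — the user can pin `n_tests` explicitly. Threshold display
truncates the mantissa (0.05/35 → "1.42 x 10^-3") to match the common
reporting convention.

### Multivariable IVW

Weighted least squares of the outcome effects on all exposure-effect
columns jointly, no intercept, weights σᵧⱼ⁻², with the same floored
residual inflation (df k−m). Instruments are pooled across the exposures'
clumped sets; a SNP missing from one exposure GWAS enters with effect 0
and that table's median SE, flagged in the output rather than dropped —
dropping would bias the pooled set toward SNPs shared by all GWAS arrays.
Collinear exposures are rejected at condition number 10⁸ with the
offending pair named. MVMR-Egger and instrument-strength Q statistics for
MVMR are out of scope.

## The synthetic generator

`synthetic.SimTruth` defaults describe the generator's reference scenario:
121 instruments explaining 5.75% of a continuous exposure measured in
~403k individuals, a case-control outcome of ~455k with 15.8% cases, and a
true effect of 0.175 log-odds (OR 1.19) — the scale of a well-powered
chronotype-versus-retinal-degeneration analysis. MAFs are uniform on
(0.05, 0.45); summary SEs use σₓ = 1/√(2·maf(1−maf)·n) and the
case-control analogue with an extra K(1−K) factor, rather than simulating
genotypes — summary-level fidelity at desk scale is the goal and an
individual-level generator is a non-goal.

Per-SNP variance-explained shares are lognormal with sigma
`effect_dispersion` (default 1.8). This matters: real instrument lists
combine a large pooled R² with a median F-statistic in the thirties and a
long right tail into the hundreds, which is only possible when the
effect-size distribution is strongly right-skewed. At the default scale
the simulated median per-SNP F lands in the high thirties while the mean
is near 190, reproducing that profile. Setting the dispersion to 0 gives
equal-strength instruments for clean calibration studies.

True exposure effects are oriented positive — the convention of reporting
instruments by their trait-increasing allele — so "directional" pleiotropy
(mean `pleiotropy_mean` added to the outcome path of a `pleiotropy_frac`
subset of instruments) is well-defined on the Egger orientation. Balanced
pleiotropy has mean zero. Pleiotropic effects are drawn independently of
instrument strength, so InSIDE holds by construction; an InSIDE-violating
mode is deliberately omitted (future work). A mean F below 10 triggers a
warning, not an error — the weak-instrument regime is a legitimate test
case.

What the generator does *not* emulate: LD between instruments (the block
panels are a separate fixture with constant within-block r²), sample
overlap between the two GWAS, population stratification, winner's-curse
bias in β̂ₓ of selected instruments, and real MAF spectra. Tests passing
on synthetic data therefore demonstrate the correctness and calibration of
the estimators under the stated model, not robustness to those real-data
pathologies.

The multi-exposure generator induces genetic correlation ρ through a
shared latent component of the true instrument effects, scales each
exposure column to the target pooled R², and builds the outcome from the
specified direct effects only — so a univariable analysis of a null
exposure is biased by construction while the multivariable model is not.
A common negative pairwise correlation is rejected for m > 2 (infeasible).

The ready-to-run fixture study (7 exposures × 5 outcomes, forward
direction, identity LD panels) uses desk-scale instrument counts (9–50 per
exposure, mean per-SNP F ≈ 45, mild dispersion 0.3) with GWAS-scale sample
sizes, so a full 35-pair run with diagnostics completes in well under a
minute; two exposure-outcome pairs carry true effects (0.175 and 0.12
log-odds), the other 33 are null.

## Test conditions and problem sizes

The statistical acceptance tests fix their own study conditions:

- *Calibration*: 30 equal-strength instruments, no effect, no pleiotropy,
  2000 replicates — IVW type-I error ~0.043 under the floored model
  (slightly conservative by design, inside the 5% ± 1.3% binomial band).
- *Recovery*: 50 instruments, pooled R² 10% at n = 100k (mean F ≈ 200,
  dispersion 0.8), true β 0.2, 200 replicates. The Egger estimator needs
  genuine spread in instrument strength to avoid dilution; this is what
  "strong instruments" means for that design.
- *Weighted-median consistency* uses a continuous biobank-scale outcome
  (n = 455k) so the per-ratio noise does not swamp the finite-sample
  quantile shift caused by the 30% invalid minority; with a case-control
  outcome at the same scale the finite-sample bias is roughly twice as
  large, a scale effect worth knowing about when interpreting real
  analyses with few, noisy instruments.
- *MR-PRESSO*: detection uses 20 instruments and a +10·SE outcome shift;
  calibration uses 10 instruments and 500 null simulations per replicate.

`scripts/acceptance.py` reruns all of the above from a single `--seed` and
additionally executes the full fixture study (bootstrap 200, PRESSO 500),
writing every measured quantity to JSON. Total runtime is well under a
minute on one CPU.

## Known limitations

- No LD-score-regression stage, no external database queries (expression
  or phenotype lookups enter only as user-supplied exclusion lists or
  groupings), no proxy search beyond a user-supplied table, no VCF input,
  no coordinate liftover.
- The Steiger binary-trait R² approximation and the total-n convention can
  misrank direction for very unbalanced case-control outcomes.
- The power formula is a normal approximation; it overstates power for
  odds ratios far from 1 (see the Monte-Carlo comparison in the tests).
- MR-RAPS, robust-regression variants, MVMR-Egger and the PRESSO
  distortion test are intentionally absent.
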