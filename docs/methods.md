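# Methods

This note records the statistical models implemented, the conventions and
numerical choices they depend on, and what the synthetic data used in testing
does and does not establish about behaviour on real data.

## Data contract and missing data

Input is a delimited table (comma, semicolon or tab) with mandatory columns
`Study`, `test.results` (continuous index test) and `disease` (0/1 reference
standard); all other columns are covariates. Study ids are assigned
sequentially by first appearance and never renumbered afterwards, so results
remain attributable across filtered subsets. Covariates are typed
automatically: non-numeric columns, and numeric columns with ≤ 10 distinct
values, are treated as categorical; the cutoff and per-column types are
overridable. Missing values (empty cells and `NA` by default) are handled by
per-variable complete-case analysis: a record missing a covariate is excluded
only from analyses using that covariate. Studies with a single disease class
are flagged and excluded from per-study accuracy computations rather than
failing the whole run.

## Dichotomization and per-study accuracy

Positivity is `test ≥ c` (higher values indicate disease); a global inversion
is achieved by negating the test. The closed-on-the-positive-side convention
matters for patients exactly at the threshold and is therefore fixed and
stated. Candidate cutpoints for threshold optimization are midpoints between
consecutive distinct pooled values plus −∞/+∞ sentinels, matching common ROC
practice; the Youden optimum maximizes `J = Se + Sp − 1` over these, and ties
are broken toward the smallest threshold by scanning candidates in ascending
order with strict (exact float) improvement — this makes the optimizer
provably consistent with an exhaustive search using the same arithmetic.

Interval families: Clopper–Pearson (exact binomial) for Se, Sp, PPV, NPV;
Wald intervals on the log scale for LR+, LR− (Simel variances) and the DOR
(Woolf variance). When any 2×2 cell is zero, 0.5 is added to all four cells
for the ratio measures only; proportions stay uncorrected. The per-study AUC
is the Mann–Whitney statistic (ties count ½) with DeLong's standard error,
equal by construction to the trapezoidal area under the empirical ROC.

## Bivariate summary model and HSROC form

The summary model is the two-stage normal approximation: study `i`
contributes `y_i = (logit Se_i, logit Sp_i)` with within-study variances
`1/TP + 1/FN` and `1/TN + 1/FP` (0.5 added to all cells of any study with a
zero cell), and `y_i ~ N(μ, Ψ + S_i)` with unstructured 2×2 between-study
covariance `Ψ`. `Ψ` is estimated by REML with the Nelder–Mead simplex on
`(log σ_A, log σ_B, atanh ρ)` (parameter tolerance 1e-8, up to 2000
iterations); between-study SDs are bounded below at 1e-5 and estimates at
the bound are reported as zero-variance boundary fits. The mean and its
covariance come from generalized least squares at the REML `Ψ`. An exact
binomial GLMM backend would be a natural extension; the normal approximation
is the supported method and is what the parameter-recovery simulations
calibrate.

The HSROC re-parameterization (accuracy Λ, threshold Θ, shape β, variances
σ²_α, σ²_θ) uses the standard one-to-one mapping from the bivariate
parameters; its inverse is implemented too, and the round trip is exact to
machine precision. The summary ROC curve is the induced line on the logit
plane, `logit TPR = Λ e^{−β/2} + e^{−β} logit FPR`, clipped by default to
the observed per-study FPR range to avoid extrapolation (full range on
request). It passes through the summary point identically; `β = 0` gives the
symmetric curve with constant log-DOR.

The confidence region for the summary point is the ellipse
`(μ̂ − μ)' C⁻¹ (μ̂ − μ) ≤ 2(k−1)/(k−2) · F_{0.95; 2, k−2}` on the logit
plane mapped pointwise to ROC space, where `C` is the GLS covariance of the
mean and `k` the number of studies. The Hotelling-type F calibration is used
instead of the χ²(2) quantile because the between-study covariance is
estimated: at `k = 15` the χ² region covers the true mean in only ≈ 90% of
simulated meta-analyses, while the F region attains ≈ 94–95%. For `k ≤ 3`
the F quantile is undefined and χ² is used as a fallback.

## AUC meta-analysis

Study AUCs are pooled by inverse variance; between-study variance uses the
DerSimonian–Laird moment estimator (REML optional), with
`I² = max(0, (Q − (k−1))/Q)`. Pooling defaults to the raw AUC scale to match
the generic inverse-variance convention, with confidence limits clipped to
[0, 1] (a warning notes the clip); the logit scale with delta-method SEs is
available for AUCs near the boundary. Studies with complete separation
(AUC exactly 0 or 1, DeLong SE 0) receive a half-pair continuity adjustment
`AUC' = 1 − 0.5/(n_D n_N̄)` and a Hanley–McNeil SE, and are flagged.

## Covariate-adjusted ROC

The adjusted ROC asks how the test separates groups once the covariate's
effect on the test in the healthy population is removed. The estimator is
frequentist semiparametric: OLS of the test on one covariate (indicator
coding for categorical levels) in the pooled nondiseased sample; residual
scale `σ̂` with denominator `n − p`; right-continuous ECDF `F̂` of the
standardized residuals; placement values `U = 1 − F̂((y − x'β̂)/σ̂)` for the
diseased; `AROC(t) = mean(U ≤ t)` and `AAUC = 1 − mean(U)`. The ECDF side
and the `n − p` denominator are binding conventions — the intercept-only
worked example (nondiseased {1, 2, 3}, diseased {2.5} → `U = 1/3`,
`AAUC = 2/3`) depends on both. The nondiseased regression needs
`n ≥ p + 2` (one residual degree of freedom for `σ̂` plus a non-degenerate
ECDF). The regression pools across studies with no study effects, mirroring
the one-covariate-at-a-time scope; a study-indicator option is a possible
extension. With a zero covariate effect the estimator reduces to the pooled
empirical ROC; under the null (diseased drawn from the nondiseased model)
the placement values are approximately uniform and AAUC ≈ 0.5. A Bayesian
nonparametric variant of this estimator exists in the literature and is
deliberately out of scope.

## Synthetic data generator

The generator emulates a hypothetical 15-study meta-analysis of one
continuous index test. Per study it draws a sample size in 50–120, a
prevalence in 0.25–0.55, a nondiseased mean in 0–1 (index-test units), and a
disease effect `Δ_i ~ N(1.5, 0.3²)`; subjects get
`y = μ0_i + 0.5·z_age + Δ_i·disease + ε`, `ε ~ N(0, 1)`, where `z_age`
standardizes an age-like covariate `N(55, 12²)`; a balanced binary `sex`
covariate carries no effect. These defaults put per-study AUCs around
0.75–0.9 with visible between-study heterogeneity and a real covariate
effect — the regime the analyses are designed for — and missingness is off
by default (the example dataset assumes complete data; rates are
configurable per column). Per-study substreams are spawned deterministically
from the seed, so extending the number of studies leaves earlier studies'
records unchanged.

The generator is binormal with a linear covariate effect and a shared
disease shift within study. It does not produce skewed or heavy-tailed test
distributions, threshold-dependent reporting, covariate-dependent disease
prevalence, informative missingness, or study-level confounding. Passing
tests therefore establish correctness of the estimators under their own
model assumptions and the algebraic/oracle identities that hold for any
data; they do not certify robustness to model misspecification on real IPD.

## Simulation scales and numerical conventions

Parameter-recovery checks use 500 simulated meta-analyses (k = 15, 100
diseased and 100 nondiseased per study) for the bivariate model — enough for
a Monte-Carlo SE of ≈ 0.007 on the mean-logit bias and ±2% on region
coverage — and 1000 replicates (k = 10) for DerSimonian–Laird τ² recovery;
the adjusted-ROC null and reduction simulations use n = 2000 subjects.
Oracle-equivalence checks run 200 random small studies against brute-force
enumeration. Ties in the Youden search are resolved as described above;
kernel densities use a Gaussian kernel with Silverman bandwidth, evaluated
on a grid extended four bandwidths past the data range so exported densities
integrate to ≈ 1; degenerate inputs (constant variables, single-class
studies, rank-deficient designs, all-zero tables) raise typed errors or are
flagged and skipped, as documented per function.

## Known limitations

- The bivariate fit is the normal-approximation two-stage model; sparse
  cells at extreme thresholds rely on the 0.5 correction rather than exact
  binomial likelihoods.
- The adjusted-ROC analysis supports one covariate at a time and pools the
  nondiseased regression across studies.
- Raw-scale AUC pooling can produce clipped confidence limits for very
  accurate tests; use the logit scale there.
- No prediction region is drawn on the SROC plot (confidence region only),
  and no publication-bias or small-study diagnostics are provided.
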