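# Methods

This note documents the statistical models implemented in `drugmr`, the
synthetic data-generating process used to validate them, the defaults and
why they were chosen, and the known limitations.

## Two-sample MR model

All estimators operate on harmonized per-variant summary pairs: exposure
effects `bx_j ± sx_j` (SD of expression/methylation/protein per effect
allele) and outcome effects `by_j ± sy_j` (log-odds per effect allele),
signed to the same allele. Under the instrumental-variable assumptions the
structural model is `by_j = β·bx_j (+ α_j)` where β is the causal effect of
one SD of exposure on the outcome log-odds and `α_j` is a per-variant direct
(pleiotropic) effect, zero under the exclusion restriction.

- **Wald ratio** (k = 1): `β̂ = by/bx`, first-order delta-method SE
  `sy/|bx|`. A second-order expansion adds a term in `sx`; the first-order
  form is the standard default and the exposure leg is strong by
  construction (F ≥ 10), so the correction is negligible here.
- **IVW, multiplicative random effects** (primary, k ≥ 2):
  origin-constrained WLS of `by` on `bx` with weights `1/sy²`. The residual
  overdispersion factor `max(1, sqrt(Q/(k−1)))` multiplies the fixed-effect
  SE; flooring at 1 means chance underdispersion never tightens the
  interval, which makes the test slightly conservative under the null
  (observed type-I error ≈ 0.035–0.045 at α = 0.05 with k = 5 — measured by
  the acceptance script, not asserted as 0.05).
- **MR-Egger** (k ≥ 3): WLS with intercept after orienting all exposure
  effects positive; the intercept estimates directional pleiotropy and its
  t-test (k − 2 df) is the pleiotropy diagnostic; the slope is the causal
  estimate with the same dispersion floor.
- **Weighted median / weighted mode** (k ≥ 3): order statistics of the
  per-variant Wald ratios with inverse-variance weights `(bx/sy)²`. The
  mode maximizes a Gaussian-kernel smoothed weighted density over the ratio
  points with Silverman-type bandwidth `0.9·k^(−1/5)·(weighted SD)`; exact
  density ties break toward the larger local weight, then the smaller
  absolute ratio. Both SEs come from a seeded parametric bootstrap
  (default 1,000 replicates) resampling `bx* ~ N(bx, sx)`, `by* ~ N(by, sy)`.
- **RAPS** (k ≥ 2): solves `Σ ψ(t_j) ∂t_j/∂β = 0` with
  `t_j = (by_j − β bx_j)/sqrt(sy_j² + β² sx_j²)`; ψ is the identity or a
  Huber clip at 1.345 (default). SE from the sandwich of the score. With
  exact exposure effects and identity ψ this reduces analytically to
  fixed-effect IVW, which the tests verify to 1e−6. Optional
  method-of-moments overdispersion adds a `τ²` to the denominator.
- **Profile maximum likelihood** (k ≥ 2): the per-variant true exposure
  effects are profiled out of the bivariate-normal likelihood, leaving
  `−2·logL(β) = Σ [(by_j − β bx_j)²/(sy_j² + β² sx_j²) + log(sy_j² + β² sx_j²)]`,
  minimized by Brent's method; SE from the numerical observed information.

Diagnostics: Cochran's Q (χ², k−1 df) with the IVW fit; leave-one-out IVW
refits flagging sign flips or excursions outside the fixed-effect CI (the
random-effects CI self-inflates under exactly the single-variant distortion
being hunted); Radial MR with modified second-order weights
`w_j = 1/(sy_j²/bx_j² + β² sx_j²/bx_j²)` iterated to convergence, each
`Q_j = w_j (ratio_j − β)²` referred to χ²₁ at α = 0.05 (no Bonferroni by
default, both knobs configurable); MR-PRESSO comparing the observed
leave-one-out weighted residual sum of squares against a parametric null
simulation (default 1,000 draws), with per-variant outlier p-values
Bonferroni-corrected over k. The simulation-based p uses the (r+1)/(n+1)
rank convention, so it is never exactly zero.

## Instruments, harmonization, filters

Cis windows are `[start − 100 kb, end + 100 kb]`, 1-based inclusive on both
ends. Instrument strength uses the PVE/F formulas above with k = 1 per
variant. The F < 10 exclusion is strict (F = 10 is retained). LD clumping is
greedy by ascending p-value within a 10,000 kb window at r² < 0.1; ties
break by (p, position, variant id), making the retained set invariant to
input row order. A per-gene BH FDR prefilter (α = 0.05, configurable off)
mirrors QTL sources distributed at FDR < 0.05; whether such a filter should
be per-gene or transcriptome-wide is a judgment call — per-gene is the
default and a switch, not a claim.

Harmonization keeps matching allele pairs, flips swapped pairs (negating
the outcome beta and replacing eaf by 1 − eaf), and drops anything else as
incompatible; every input variant leaves with an action code, so
kept + dropped always equals the intersection. Strand is assumed forward in
both studies; ambiguity is handled only through the palindrome rule:
A/T and C/G variants are dropped when MAF > 0.42 (strict) in either study, and
conservatively when a palindromic variant lacks a frequency. Steiger
filtering is a deterministic comparison of the PVE formula on both sides
(drop iff outcome PVE strictly exceeds exposure PVE); a z-test variant
requiring nominal significance of the difference is available by flag.

## Discovery gating

The discovery gene set is tested jointly: Bonferroni, BH step-up, and
q-values must all fall below 0.05 (an any-gate relaxation exists as
config). q-values use Storey's λ-grid {0.05, …, 0.95} with a cubic
polynomial smoother extrapolated to λ = 1, clipped to [1/m, 1], times the
BH step-up values — so q ≤ BH always. Direction consistency requires all
five auxiliary estimators to share the IVW sign; a beta of exactly zero
matches no sign, and a missing estimator fails the check in strict mode
(default). Replication IVW uses the same instruments against the second
cohort; the two IVW estimates are pooled fixed-effect when
I² = max(0, (Q−1)/Q)·100 < 50 (strict), else DerSimonian–Laird. The final
call additionally requires meta p < 0.05; requiring nominal replication
significance on its own is a config switch, off by default since the pooled
test is the stated criterion. Gene-level failures are isolated: a gene that
cannot be analysed gets a verdict row with a reason, never aborts the run.
MR-PRESSO can be enabled in the pipeline but does not gate verdicts; Radial
outlier removal precedes the headline fit (configurable off) and always
leaves at least one instrument.

## SMR, HEIDI and mediation

At the region's top QTL variant (largest |z|, lexicographic id tie-break —
p-values underflow to exact ties beyond |z| ≈ 38),

```
T_SMR = z_qtl² z_gwas² / (z_qtl² + z_gwas²) ~ χ²₁,
b_SMR = b_gwas/b_qtl,  se_SMR = |b_SMR|·sqrt(1/z_qtl² + 1/z_gwas²).
```

HEIDI tests whether per-variant SMR effects are consistent with a single
shared causal variant. Eligible variants have QTL p < 1.57×10⁻³ (z² > 10),
excluding the top variant, capped at the 20 strongest; fewer than 3 leaves
p undefined (treated as a conservative failure of the HEIDI gate by
default, pass-through by flag). Deviations `d_i = b_SMR(i) − b_SMR(top)`
get a delta-method covariance from the LD correlations of both the QTL and
GWAS estimation errors (independent samples, so no cross term); the sum of
squared standardized deviations is referred to its correlated-χ² null by
Satterthwaite moment matching on the eigenvalues of the standardized
covariance (an eigenvalue Monte Carlo tail is available via `method=`).
Measured calibration: single-shared-causal simulations reject at ~0.015–0.02
at the 0.01 level; regions driven by a distinct variant in weak LD give
median p below 10⁻⁴.

The three-step mediation analysis runs SMR+HEIDI for expression→outcome,
methylation→outcome, and methylation→expression; the verdict requires
p_SMR < 0.05 at every step, genome-wide significant top variants
(p < 5×10⁻⁸ on both legs of each step), and HEIDI p > 0.01 throughout. The
sign chain is consistent when sign(meth→expr)·sign(expr→outcome) equals
sign(meth→outcome). Protein/transcript direction consistency requires both
SMR records significant with passing HEIDI before comparing signs;
otherwise it is undefined and reported false with a log line. Exposures are
assumed standardized (effects per SD of methylation/expression) throughout.

## Phenome-wide scan

A fixed per-gene instrument set is harmonized against each trait GWAS and
fitted by IVW (Wald ratio at k = 1). Significance is Bonferroni at
α/m where m is the number of traits *requested* (strict mode, default,
mirroring a fixed phenome size); per-trait failures are isolated and, in
non-strict mode, reduce m. With a gene's disease-effect sign supplied,
significant traits are labelled: targeting the gene in its
disease-protective direction shifts the trait by −sign(disease β)·β_trait,
negative shifts (risk reduction) being beneficial, positive adverse. This
sign convention is recorded in output metadata rather than asserted as
universal.

## Synthetic data-generating process

Everything is simulated on the summary-statistic scale; no individual-level
genotypes. For a region of m variants with LD matrix R (block-diagonal
AR(1): r_ij = ρ^|i−j| within blocks, default ρ = 0.5), true joint effects
`b` yield true marginals `R·b`; estimated marginals add correlated noise
MVN(0, R/n) — the error structure LD induces, which HEIDI and Cochran's Q
depend on. Causal variants receive random-sign effects with magnitude
uniform on [0.4, 1.6]×`effect_sd`: QTL sources ascertain genes with
genuinely significant cis signals, so a simulated causal gene always
carries one. Default `effect_sd` = 0.25 SD per allele puts top-variant PVE
at roughly 4–9%, a realistic strong cis-eQTL at biobank-scale QTL sample
sizes.

Binary outcomes are generated directly on the log-odds scale: marginal
effect `β·(exposure true marginal) + R·a + noise`, where `a` are per-variant
direct effects (zero, balanced N(0, sd), or directional N(mean, sd)), and
the per-variant SE is `1/sqrt(n·φ(1−φ))` with case fraction φ = 0.035
(a population-register gout prevalence). Discovery and replication cohorts
are drawn independently (non-overlapping samples). Effect-allele
frequencies are uniform on (0.05, 0.95); a configurable fraction of
variants is forced palindromic with frequency near 0.5 to exercise the
ambiguity filter. Mediation regions chain methylation → expression →
outcome marginals exactly, with independent estimation noise per trait.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: realistic MAF spectra and MAF-dependent effect sizes,
imputation quality, sample overlap between exposure and outcome studies,
population stratification, strand misassignment beyond palindromes, winner's
curse in instrument selection, and case-control ascertainment effects beyond
the variance factor. Estimator calibration measured here is calibration
under correctly specified Gaussian summary noise.

## Numerical choices and degenerate inputs

Seeded `numpy` Generators everywhere; identical seeds give byte-identical
output tables. LD matrices must be symmetric (asymmetry < 1e−8 is averaged
away, more is an error), unit-diagonal, and PSD within 1e−8; MVN noise uses
the eigenvalue-clipped symmetric square root. HEIDI's covariance inverse is
avoided entirely (the statistic uses only variances plus an eigenvalue tail
approximation). Egger refuses designs with condition number above 1e12
(collinear exposure effects). RAPS brackets its root around the IVW start
and widens geometrically; no sign change is a diagnostics error rather than
a silent answer. Zero exposure effect makes the Wald ratio an error, and an
exactly-zero estimate counts as direction-inconsistent — boundary-safe and
conservative. The p-value/SE consistency check on input tables tolerates
10% relative deviation and skips magnitudes below double-precision reach.

## Problem sizes in the test and acceptance runs

Estimator recovery and type-I error use k = 5 instruments at
n = 50,000/50,000 over 500 and 1,000 replicates; HEIDI calibration uses
20-variant regions (ρ = 0.8, QTL n = 30,000, GWAS n = 300,000) over
400–500 replicates; the discovery truth table uses 51 genes (one causal,
β = 0.5, n = 100,000 per cohort, ~30 variants per region) over 10–20
seeded runs; the null phenome scan uses 100 traits. These sizes make the
whole suite run in a few minutes while keeping Monte-Carlo error well inside
the asserted bands.
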