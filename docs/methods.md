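# Methods

`repromr` implements the causal-inference toolkit used in genetics-based
studies of how obesity-related exposures (BMI, waist-to-hip ratio, WHR
adjusted for BMI) affect binary disease outcomes such as female reproductive
disorders: two-sample Mendelian randomisation (MR) on GWAS summary
statistics, multivariable and two-step mediation MR, stratified non-linear
MR on individual-level data, mixture-model clustering of per-SNP causal
estimates, and an observational logistic/fractional-polynomial arm.  This
note records the models, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Two-sample MR

For SNP j let (b_xj, s_xj) be its estimated effect on the exposure (SD
units) and (b_yj, s_yj) its effect on the outcome (log OR), taken from
non-overlapping GWAS samples and harmonised to a common effect allele.

* **Wald ratio** — b_yj / b_xj with first-order SE s_yj/|b_xj|; a
  second-order SE including exposure uncertainty is available behind a flag.
* **IVW** — weighted regression of b_y on b_x through the origin with
  weights 1/s_y²; fixed-effect by default (residual scale pinned at 1, so
  SE = 1/sqrt(Σ w b_x²)), with a multiplicative random-effects toggle that
  inflates the SE by sqrt(max(1, Q/df)).  Cochran's Q = Σ w (b_y − βb_x)²
  on n−1 df.
* **MR-Egger** — the same regression with a free intercept after orienting
  every SNP to a non-negative exposure effect; the intercept estimates
  average directional pleiotropy, Q′ is the weighted RSS on n−2 df.
* **Weighted median** — interpolated median of the per-SNP ratios at
  cumulative weight 0.5, weights 1/se(ratio)²; SE from a seeded parametric
  bootstrap (default 5,000 resamples).  Under fully directional pleiotropy
  the estimator retains a quantile-shift bias (the median of the mixture
  sits above the valid-instrument centre); it is near-unbiased at moderate
  invalid fractions and always far less biased than IVW — the tests assert
  exactly that, point recovery within 3 SE at 30% invalid weight and bias
  dominance over IVW at 40%.
* **Model selection (Rucker)** — IVW is kept unless its Q is significant
  (default α=0.05) *and* the Q−Q′ reduction on 1 df is significant *and*
  the Egger intercept is significant; the decision record keeps Q, Q′,
  Q′/Q and the intercept p so the reasoning is auditable.
* **Steiger directionality** — compares instrument variance explained in
  exposure vs outcome (2f(1−f)β² for continuous traits with known allele
  frequency, t²/(t²+n−2) otherwise) via Fisher-z.
* **Power** — normal-test approximation with SE(log OR) ≈
  1/sqrt(n·r²·φ(1−φ)); validated against a score-test Monte Carlo.

CIs are 95% throughout, ±1.96·SE on the log-OR scale, exponentiated for
reporting.  P-values are recomputed from beta/se everywhere; input p-value
columns are advisory.

## Harmonisation

Outcome records are aligned to the exposure's effect allele: direct match,
swap (negate, complement frequency), strand flip, or flip+swap.
Palindromic (A/T, C/G) SNPs cannot be resolved from alleles; under the
default `drop` policy they are dropped when either side's minor-allele
frequency is within `eaf_window` (default 0.08) of 0.5 or missing, and
otherwise strand is inferred by comparing which side of 0.5 the two
frequencies fall on.  The `infer-by-eaf` policy always infers when both
frequencies are present.  Every removal is recorded with a reason and
written to a JSON sidecar — nothing is silently dropped.  Instrument
selection defaults to p < 5×10⁻⁹ (densely imputed GWAS convention); LD
clumping is out of scope and instruments are assumed pre-pruned.

## Mediation

Two-step MR with the product of coefficients: a (exposure→mediator,
univariable IVW), b (mediator→outcome conditional on the exposure, from
multivariable MR over the combined instrument set), c (total effect).
Proportion mediated = a·b/c with the first-order delta SE treating a, b, c
as independent:

    se² = (b·se_a/c)² + (a·se_b/c)² + (a·b·se_c/c²)²

This three-term formula reproduces the printed worked-example interval
exactly, which is why it is the default.  CI bounds are truncated to [0,1]
only at the reporting layer.  Mediation is only computed for triples whose
total effect passes BH-FDR < 0.05 within its analysis family and whose a
and b paths are individually significant at p < 0.05; skipped triples are
recorded with reasons.

Multivariable MR is a weighted (1/s_y²) no-intercept regression of outcome
effects on the matrix of per-trait SNP effects with the residual scale
fixed at 1; collinear exposure columns are detected (condition number >
1e10) and named in the error.

## Non-linear MR

Individuals are ranked into q equal-count strata of the *IV-free exposure*
— the residual of the exposure on the genetic score and covariates — which
is independent of the instrument by construction and therefore avoids the
collider bias of raw-exposure stratification (demonstrated by a paired
simulation in the tests).  The localized average causal effect (LACE) in
stratum k is the stratum-specific logistic score-outcome coefficient
divided by the full-sample linear score-exposure coefficient, first-order
SE.  Strata without outcome variation are flagged unusable and excluded
with a warning rather than merged.  Defaults: q=10 for the piecewise-linear
curve, q=100 for the fractional-polynomial fit; the curve reference point
is the lowest stratum's mean exposure.

A stratum LACE estimates the *slope* of the causal log-OR curve h at the
stratum midpoint.  Candidate fractional polynomials h(x) = Σ β_j x^(p_j)
(powers from {−2,−1,−0.5,0,0.5,1,2,3}, 0 ≡ log, repeated powers adding a
log factor) are therefore fitted by regressing the LACE profile on the
*derivatives* of their terms with inverse-variance weights; the linear
curve corresponds to a constant LACE.  The non-linearity p-value tests the
weighted-RSS improvement of the best FP over the constant-LACE fit.
Because that statistic is a selection maximum over the power grid, its
null distribution is not chi-square; with stratum variances known the test
is calibrated by a seeded parametric Monte Carlo under the fitted null
(default 400 draws, vectorised through precomputed residual quadratic
forms; measured size 0.049-0.050 at nominal 0.05).  A chi-square(1)
analytic fallback (`mc_reps=0`) matches the convention of stratified
non-linear MR implementations and is mildly anticonservative (~0.065).
Heterogeneity across strata is tested with Cochran's Q and a
meta-regression trend test of LACE on stratum midpoint.

## SNP clustering

Per-SNP Wald ratios θ_i with SEs s_i are modelled as a mixture of a null
component N(0, s_i²), k substantial components N(μ_k, s_i²), and a junk
component N(0, s_i² + τ²).  Means and mixing proportions are estimated by
EM (tolerance 1e-8 on the log-likelihood, max 1,000 iterations, 10 starts:
one deterministic from quantiles of θ, the rest seeded draws); k is chosen
by BIC over 0..max_k (default 3).  τ² defaults to 10× the larger of the
largest s_i² and the sample variance of θ: tying the junk spread to the
spread of the estimates is what keeps an isolated extreme outlier in the
junk component — with an SE-only junk variance a dedicated singleton
"substantial" cluster always wins the BIC comparison, which would defeat
the component's purpose.  Substantial-cluster membership is reported at
posterior probability ≥ 0.80 with the cluster's effect sign.

## Observational arm

Exposures are residualised on covariates and rank-based inverse-normal
transformed with the Blom offset 0.375 (Φ⁻¹((r−0.375)/(n+0.25)), average
ranks for ties), making per-SD logistic odds ratios comparable across
exposures.  Non-linearity is assessed by fractional-polynomial logistic
regression with the closed test procedure: best FP2 vs null on 4 df
(overall association), vs linear on 3 df (non-linearity), vs best FP1 on
2 df (degree), each estimated power counting one df; model fits are also
compared by AIC.

## Synthetic data

The generator emulates the study's two-sample design with known ground
truth: unlinked biallelic SNPs (frequencies uniform on a configurable
range, default 0.05-0.5), a continuous exposure with genetic variance h²
(default 0.04, matching instrument strength typical of anthropometric
GWAS), an optional mediator (unit variance, path a from the exposure plus
its own SNPs explaining h²_mediator), and a logistic outcome with direct
effect θ_direct, mediator effect b, optional quadratic/threshold
non-linearity, and direct (pleiotropic) SNP effects on a configurable
fraction of invalid instruments.  The intercept is solved numerically for
the target prevalence (default 0.05, the floor used for stratified
analyses of common outcomes).  Effect alleles are oriented
exposure-increasing, as GWAS index SNPs are reported — without this,
directional pleiotropy averages out across random orientations and biases
nothing.  Summary statistics are computed on disjoint halves (two-sample)
by per-SNP OLS for continuous traits and one-step logistic score
regression for the binary outcome (exact per-SNP ML behind a flag); the
default 200-SNP instrument mirrors typical anthropometric instruments.

What the benchmarks do not emulate: LD between instruments, ancestry
structure and relatedness, genotyping error, sample overlap between
exposure and outcome GWAS, winner's curse in instrument selection, and
case-control ascertainment.  Passing tests therefore demonstrate the
estimators' statistical behaviour under the stated generative model, not
robustness to those real-data complications.

### Benchmark problem sizes

Named scenarios fix the study conditions (null; linear θ=0.25; 30% invalid
with directional pleiotropy; mediation with φ=0.5; U-shape).  The
replicate-heavy checks run at sizes chosen for stable Monte Carlo
behaviour: single-realisation estimator recovery uses the full n=100,000 /
200-SNP configuration; Egger-intercept and FP-non-linearity calibration
use 2,000 summary-level / stratum-level replicates; mediation recovery
uses 200 cohorts of n=50,000 with 100 exposure + 50 mediator SNPs,
h²=0.15 each and prevalence 0.10 — sized so the total-effect z-ratio is
near 10, keeping the ratio estimator a·b/c well-behaved (at weaker
instruments the near-zero denominator makes its mean unstable); cluster
recovery uses 50 replicates of 40 SNPs at 5-SE separation.

## Known limitations

* The Wald/IVW/Egger machinery treats exposure-side error as negligible;
  weak instruments attenuate estimates toward the null (visible in the
  synthetic two-sample benchmarks at low h²).
* The delta-method CI for the proportion mediated assumes independent
  a, b, c; with shared instruments it is mildly conservative (measured
  coverage ~0.94 at nominal 0.95 in the benchmark).
* log-OR mediation effects are only approximately collapsible; direct +
  indirect ≈ total holds for rare outcomes and is asserted only there.
* The mixture model assumes known per-SNP variances and normal components;
  BIC with a free junk component can absorb small genuine clusters when
  separation is below ~3 average SEs.
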