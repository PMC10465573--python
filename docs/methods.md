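# Methods

This note records the statistical model the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer would want
spelled out.

## Causal model and assumptions

Two-sample MR treats genetic variants as instrumental variables for a
modifiable exposure. Valid inference needs the three IV assumptions:
(i) relevance — the variant is associated with the exposure; (ii)
independence — no confounder of the variant–outcome relation; (iii)
exclusion — the variant affects the outcome only through the exposure.
All estimators consume per-SNP summary pairs (β̂_Xj, σ_Xj, β̂_Yj, σ_Yj)
from two non-overlapping GWAS samples; binary-trait effects are log odds
ratios, continuous-trait effects standardized units.

The mediation model is linear on that effect scale: with exposure → 
mediator effect a, mediator → outcome direct effect b, and exposure → 
outcome direct effect c′, the total effect is θ = c′ + Σ_k a_k b_k. The
two-step procedure estimates a by univariable IVW (step 1) and b by
multivariable IVW conditioning on the exposure (step 2); the indirect
effect is the product a·b ("product of coefficients") with first-order
delta-method SE √(a²se_b² + b²se_a²) — the cross term se_a²·se_b² is
omitted, which is conservative only in sign-definite cases and matters
little when both z-scores exceed ~3 (checked against a parametric
bootstrap in the tests). The mediation proportion a·b/θ is reported as a
point estimate only; the indirect-effect CI is the inferential object.
The total effect is taken from the univariable exposure→outcome analysis,
not re-derived as c′ + a·b (the two agree asymptotically; a test asserts
the convergence).

## Instrument pipeline

Published thresholds are applied as strict inequalities throughout:

| step | rule | default |
|---|---|---|
| significance screen | p < threshold | 5e-8 |
| LD clumping | drop r² ≥ threshold to a lower-p index within window | r² 0.001, window 10,000 kb |
| proxy search | best outcome-present SNP with r² > threshold | 0.8 |
| palindromic SNPs | drop when minor-allele frequency > cutoff in either table | 0.3 |
| instrument strength | keep per-SNP F = (β̂/σ)² > cutoff | 10 |
| Steiger | drop SNPs with r²_outcome > r²_exposure | — |

Clumping is greedy on ascending p (ties broken by variant id for
determinism). Variants absent from the LD reference are kept as
independent by default (`missing_ld_policy="keep"`, logged); a `drop`
policy is available. A pair absent from the reference is treated as
r² = 0.

Harmonization aligns the outcome record to the exposure's effect allele:
identical or strand-complementary allele pairs are kept, label-swapped
pairs have the outcome beta negated and EAF complemented, and palindromic
(A/T, C/G) variants — where strand cannot be resolved from alleles — are
dropped at intermediate frequency and otherwise aligned by EAF
concordance (effect-allele frequencies on opposite sides of 0.5 imply a
strand flip). Proxies substitute the outcome record of the best-LD
variant; pair lists store r² without sign, so the LD correlation sign is
assumed positive and the proxy is oriented by EAF concordance with the
target (logged; proxies without EAF on both sides are dropped). Every
dropped variant carries a machine-readable reason, and kept + dropped
counts always equal the input count.

Variance explained uses 2·EAF·(1−EAF)·β² for continuous traits with EAF
(standardized-trait approximation) and the z-based fallback
r² = z²/(z²+n) otherwise — a logistic-scale pseudo-r² for binary traits
rather than a liability-scale conversion, which would need prevalence
inputs the summary tables do not carry. The per-SNP F statistic is the
single-IV approximation (β̂/σ)², which matches (n−2)r²/(1−r²) to a few
percent at GWAS sample sizes. Steiger filtering also reports a set-level
directionality p from the Fisher-z comparison of the aggregated
correlations r = √(Σ r²) with variance 1/(n_exp−3) + 1/(n_out−3)
(two-sided).

Binary-outcome power uses the normal approximation with non-centrality
ν = |ln OR|·√(n·R²·k(1−k)), where R² is the summed instrument variance
explained and k the case fraction; this matches the Monte-Carlo rejection
rate of the IVW z-test under the generator's own sampling model within
±0.03.

## Estimators: numerical decisions

* **IVW** uses first-order weights 1/σ²_Yj (exposure uncertainty ignored
  in the weights, matching the convention of the standard primary
  analysis); random effects are multiplicative with the dispersion
  floored at 1, so the random-effects SE is never narrower than the
  fixed-effect SE. A single instrument degenerates exactly to the Wald
  ratio.
* **MR-Egger** orients instruments so β̂_Xj ≥ 0 (required for intercept
  identifiability), solves the weighted normal equations in closed form,
  and scales both SEs by the same floored multiplicative dispersion
  √max(1, Q′/(L−2)). The *intercept* SE additionally takes the maximum of
  the model-based and heteroskedasticity-robust (sandwich) values: with
  additive balanced pleiotropy and varying weights the multiplicative
  model understates the intercept variance by a few percent, enough to
  push the pleiotropy test's type-I error to ~0.07 at nominal 0.05; the
  robust floor restores calibration (measured 0.057 over 1000 null
  replicates) while leaving exact-fit and homogeneous cases untouched.
  I²_GX = (Q_GX − (L−1))/Q_GX quantifies exposure measurement error
  (NOME); values below 0.9 trigger SIMEX in the pipeline.
* **SIMEX** perturbs β̂_Xj with noise of variance λσ²_Xj over
  λ ∈ {0, 0.5, 1, 1.5, 2} (B = 1000 replicates per λ, seeded), fits a
  quadratic in λ to the mean slopes and extrapolates to λ = −1. The SE
  combines the quadratic extrapolation of the per-λ empirical slope
  variances (clipped at zero) with the λ = 0 model variance. Severe
  attenuation (narrow instrument-strength range) is only partly
  corrected — a property of the quadratic extrapolant, demonstrated in
  the tests, and the reason the IVW remains the primary estimate.
* **Weighted median** sorts ratios with normalized weights
  β̂²_Xj/σ²_Yj, interpolates at cumulative midpoint 0.5, and takes its SE
  from n_boot = 1000 seeded parametric-bootstrap resamples.
* **MR-PRESSO** computes leave-one-out IVW residuals, a weighted RSS
  (weights 1/σ²_Yj; the unweighted original is available behind a flag),
  Monte-Carlo p-values with the (1 + exceedances)/(n_sim + 1) convention
  (never 0, never > 1; n_sim default 1000, seed required in the
  pipeline), Bonferroni outlier calls at 0.05, and a two-sided distortion
  test against random same-size removals. The pipeline presents the
  outlier-corrected IVW row whenever outliers are found but marks it
  "adopted" only when both global and distortion tests are significant.
* **Multivariable MR** solves the weighted normal equations without
  intercept; SEs carry √max(1, Q_resid/(L−K)). The Egger variant adds an
  intercept after orienting rows to a non-negative effect on the primary
  exposure (the first exposure in the configuration). Joint instrument
  assembly unions each exposure's significant variants, clumps them with
  the minimum p across exposures as ranking key, drops variants missing
  from any table (zero-imputation would bias toward the null), applies
  the same palindrome rules, and excludes — with a named warning — any
  exposure left without a contributed instrument.
* Step-1 mediation gate: mediators enter step 2 only when the
  exposure→mediator IVW is significant at α = 0.05; when none passes, the
  analysis returns an explicit "no mediation pathway" status rather than
  an error.
* All CIs are normal-theory 95%; p-values two-sided normal (χ² upper tail
  for Q statistics). Human-readable reports round to 3 decimals
  (scientific notation below 0.001) and recompute OR columns as exp(β) at
  format time; machine outputs keep full precision.

## Synthetic-data generator

The generator works on the summary scale only — no individual genotypes —
because two-sample MR consumes nothing else. Per variant it draws MAF ~
U(0.05, 0.5), assigns non-palindromic allele pairs (a palindromic
fraction is available), true effects per the causal diagram, and observed
estimates β̂ ~ N(truth, σ²) with the GWAS standard-error scaling
σ = 1/√(2·MAF(1−MAF)·n) for continuous traits and
σ = 1/√(2·MAF(1−MAF)·n·k(1−k)) on the log-OR scale for binary traits.
Exposure, mediator, and outcome noise are independent (no sample
overlap, the design the analysis assumes). Defaults mirror a large
psychiatric two-sample design: 146 exposure instruments, binary exposure
GWAS of 130,644 (case fraction 0.409), binary outcome GWAS of 143,265
(case fraction 0.318), continuous mediator GWAS of 462,464.

Instrument effects are drawn as sign·(γ_min + |N(0, σ_γ²)|) with
γ_min = 0.08, σ_γ = 0.03: the panel emulates a published instrument list,
which is *ascertained* at genome-wide significance, so nearly all 146
variants survive the p < 5e-8 screen at the default sample sizes (a pure
centred normal would leave most instruments sub-threshold and the
pipeline operating on a panel unlike any real instrument set). Setting
γ_min = 0 recovers a plain normal effect distribution. Mediator-specific
instruments (default 30 per mediator) follow the same scheme so the
multivariable step is identified.

Pleiotropy α_j ~ N(μ_α, σ_α²) is drawn in the frame where each
instrument is oriented to its exposure-raising allele — the frame in
which "directional" is meaningful — and mapped back by the effect sign;
`inside_rho` correlates pleiotropy with instrument strength (|effect|),
violating InSIDE. Reverse-causal variants receive a primary outcome
effect (twice the instrument scale) and an induced exposure effect half
its size, giving Steiger filtering something real to remove.
LD is block-diagonal: blocks of configurable size share a configurable
r², variants 1 kb apart within a block, blocks 20 Mb apart (defaults: no
LD, so instrument counts are exact).

What the generator does **not** emulate: realistic LD decay (blocks are
exchangeable, not distance-decaying), allele-frequency differences
between samples, liability-scale binary architecture, winner's-curse
inflation of the exposure betas beyond the ascertainment floor, sample
overlap, and population stratification. Passing tests therefore certify
the estimators and pipeline logic under the stated sampling model, not
robustness to those additional real-data features.

## Test and report problem sizes

Calibration tests run 1000 null replicates at L = 150; coverage runs 500
replicates at L = 146; mediation recovery averages 10 full two-step
replicates; PRESSO detection uses 100 seeded runs at L = 50 with
n_sim = 1000; SIMEX behaviour is demonstrated at L = 200 with 200
replicates. These sizes keep the whole suite to a few minutes on one
core while leaving the Monte-Carlo error of each asserted rate a small
fraction of its tolerance band.

## Known limitations

* No conditional F statistics for multivariable MR (weak-instrument
  diagnostics there are limited to the univariable F of each variant).
* No mode-based, robust, or penalized IVW variants; no MVMR
  median/LASSO.
* The proxy LD-sign assumption (positive correlation) is a convention,
  logged but not verifiable from an unsigned pair list.
* The SIMEX quadratic extrapolant under-corrects severe attenuation;
  I²_GX well below ~0.6 should be read as "Egger uninformative" rather
  than "SIMEX fixed it".
* Mediation proportions are point estimates; inference should rest on
  the indirect-effect CI.
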