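# Methods

## Setting

A cohort of n unrelated individuals is fully phenotyped for an approximately
normal quantitative trait but only a fraction (default 50%) can be sequenced.
`qtdesign` evaluates how the choice of that fraction — at random, from the
phenotype extremes, or with phenotype-dependent probabilities — affects
association inference for a common variant and for a rare-variant burden
score within a single gene.

## Trait preparation

The analysis outcome is the OLS residual of the trait on intercept, age, sex,
and smoking, computed once per replicate over the **full cohort** before any
selection. Residualizing first (rather than adjusting inside the association
model) keeps each association fit a two-parameter regression and ensures the
sampling designs and the analysis see the same trait scale. The sample median
uses the even-n midpoint convention. Distances are d_i = |Y_i − Y_med| with
d_max = max(Y_max − Y_med, Y_med − Y_min); a constant residual vector gives
d_max = 0 and the probability designs refuse to run.

## Sampling designs

* **D1** keeps everyone (p_i = w_i = 1).
* **D2** draws a fixed-size SRS of round(f·n) individuals; p_i = f, w_i = 1/f.
* **D3/D4** are systematic: D3 takes the lowest and highest round(0.25n)
  residuals; D4 takes round(0.20n) per tail plus the round(0.10n) individuals
  nearest the median *by rank*. Rounding is round-half-to-even throughout, so
  n = 321 at f = 0.5 yields exactly 160 selected under both. Ties are broken
  by original order (stable sort), making the designs deterministic and
  idempotent. They are analyzed unweighted, deliberately ignoring the
  ascertainment — that is the behavior under study.
* **D5_1/D5_2** assign p_i = min{1, c·(ε + d_i/d_max)^k} with k = 1 or 2 and
  draw individuals independently (Poisson sampling), so the realized size is
  random with expectation f·n. c is calibrated by bisection on the
  cap-and-redistribute map Σ min(1, c·s_i) = f·n to absolute tolerance 1e-6
  (bisection runs to machine precision). Sampled individuals carry
  w_i = 1/p_i.

### Why (ε + d/d_max)^k rather than ε + (d/d_max)^k

The algebraic form of the published probability rules is not recoverable from
the available text; only their properties are: every individual keeps a
nonzero probability, probabilities are scaled by the maximum distance from
the median, and the squared variant favors extremes more strongly. Both
families above satisfy the first two, but only the compound form satisfies
the third after calibration: the ratio of k = 2 to k = 1 probabilities,
(c₂/c₁)(ε + d/d_max), is increasing in d, and since both designs share one
expected sample size the squared design must assign strictly less probability
near the median and at least as much at the extremes. With the additive-floor
family the calibration constant rises with k and the floor probability
c·ε rises with it, reversing the intended behavior near the median.

The floor default ε = 0.1 bounds the weights (w ≤ 1/(c·ε^k)); the much
smaller effective floor under k = 2 (ε² = 0.01) widens the weight range,
reproducing the known instability of design-based variance estimation when
extremes are sampled very aggressively.

## Variant handling

Monomorphic SNPs are dropped. MAF is folded to ≤ 0.5 by complementation, and
dosages are re-oriented to count minor alleles, so input coding does not
matter. SNPs with MAF strictly below 3% are rare; the burden score is the
per-individual total count of minor alleles over **all** rare SNPs (an
analyst does not know which are functional). The common SNP analyzed
separately is the common variant with the largest MAF.

## Association models

Forward linear fits solve the (weighted) normal equations for intercept +
genetic predictor. Weights are probability weights: they enter the estimating
equations but never act as a sample size. Classical variance is
σ̂²(X′WX)⁻¹ with σ̂² = Σw_ie_i²/(n−2); the design-based variance is the
with-replacement linearization (X′WX)⁻¹(Σw_i²e_i²x_ix_i′)(X′WX)⁻¹, the
standard survey default (an unweighted call reduces it to HC0). Exact
joint-inclusion-probability variances are out of scope.

Reverse GLMs (logistic for a carrier indicator — equivalent to additive
coding when no minor-allele homozygotes exist, and safer in general; Poisson
for the burden count) are fit by IRLS with the canonical link, convergence
when the largest coefficient change is below 1e-8 within 100 iterations, the
linear predictor clipped at ±30 against overflow. Complete separation
surfaces as `converged=False`; such fits are excluded from summaries with
counts reported. Reverse fits ignore the sampling weights under every design
because they condition on the trait value.

Wald tests divide the coefficient by its SE and use Student t with n−2 df for
linear models and the standard normal for GLMs — the combination that
reproduces printed (statistic, p) pairs such as (5.18, 3.9e-7) at 319 df and
(5.59, 2.3e-8). A zero SE returns an infinite statistic with p = 0.

## Synthetic cohort generator

The generator emulates an Asian-subpopulation-sized exome cohort: n = 321,
18 rare SNPs (MAFs spread over 0.25–2.75%, 6 flagged functional), one common
SNP at MAF 8.72% constrained to heterozygotes (dosage-2 draws are redrawn),
genotypes sampled under Hardy–Weinberg equilibrium with independent SNPs.
Covariates default to age ~ Uniform(30, 70), sex ~ Bernoulli(0.5), smoking ~
Bernoulli(0.3) with trait coefficients (0.01, 0.2, 0.3) — arbitrary but
explicit, since residualization removes them downstream. Genetic effects are
additive per allele; the default magnitudes, 0.44 trait units per rare allele
and 1.00 per common allele with residual SD 1.0, anchor the alternative trait
to full-cohort estimates of that size. The original generating model behind
those estimates is unpublished, so these are reconstructions chosen for
plausibility, not published parameters. The null trait zeroes all genetic
effects and keeps the covariates.

A deterministic `reference_cohort()` reproduces the published rare-score
spectrum exactly — burden scores 0/1/2/3 carried by 252/54/11/4 of 321
individuals — by explicit allele placement (round-robin over SNPs, multi-
allele carriers at distinct SNPs) rather than sampling, with the common SNP
at 56 heterozygotes.

What the generator does **not** model: linkage disequilibrium, population
structure, relatedness, sequencing error, or genotype–covariate correlation.
Passing simulations therefore show correctness of the design and estimation
machinery under a clean additive model, not robustness to confounded or
structured real data.

## Simulation harness

Genotypes and covariates are fixed across replicates; the trait (hence its
residual) is redrawn per replicate, and every random design redraws its
sample per replicate. Sub-seeds derive from
`SeedSequence((master_seed, replicate, design_index))`, so adding a design or
replicate never perturbs other cells and the whole study is bit-reproducible
from one master seed. Any cell whose fit raises is recorded as missing and
excluded with a count, never fatal.

Summaries per design × model × target: mean coefficient, empirical SD
(divisor R−1), mean estimated SE, rejection rate at the nominal level using
strict p < α, MRT = mean over replicates of |t_D1|/|t_design| (absolute
values; pairs with |t_design| < 1e-12 are skipped), and RE = 100 × var of the
full-cohort coefficients over var of the design's (reported unrounded;
conventionally printed as an integer). With R = 200 replicates, the Monte
Carlo 95% band around a 5% rejection rate is ±1.96·√(0.05·0.95/200) ≈ 0.03.

Default problem sizes (n = 321, R = 200, six designs, both variant targets)
run in a few seconds; all tests and the acceptance script use these defaults.

## Known limitations

* Poisson-sampled D5 sizes vary around f·n; no fixed-size unequal-probability
  scheme (e.g. Sampford) is provided.
* The sandwich variance is first-order; it is known to underestimate under
  very uneven weights (visible as elevated type I error for D5_2's forward
  linear fit).
* IPW forward estimates under the alternative are attenuated in finite
  samples relative to the full cohort; the reverse GLMs are the robust route.
* Single-gene scope; no weighted burden scores, variance-component tests, or
  multiple-testing control.
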