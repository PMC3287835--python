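# qtdesign

Tools for designing and evaluating **quantitative-trait-dependent sampling**
in sequencing association studies. When sequencing a whole phenotyped cohort
is too expensive, one can sequence only a fraction — but *which* fraction?
`qtdesign` implements and compares, by replicate simulation, six designs for
sequencing 50% of a cohort of unrelated individuals:

| design | selection rule |
|--------|----------------|
| D1 | entire cohort (reference, 100%) |
| D2 | 50% simple random sample |
| D3 | all individuals in each 25% tail of the trait distribution |
| D4 | all individuals in each 20% tail plus the central 10% |
| D5_1 | probability sampling, p_i increasing with distance from the trait median |
| D5_2 | as D5_1 with a squared distance score, favoring extremes more strongly |

The package is aimed at statistical geneticists and biostatisticians planning
sequencing sub-studies of an existing cohort, or studying the inferential
consequences (bias, type I error, power, efficiency) of phenotype-dependent
ascertainment.

## Model and methods

The quantitative trait is residualized on age, sex, and smoking by OLS over
the full cohort; all selection and analysis operate on the residual
*Y<sub>i</sub>*. Distance-based designs use

> d<sub>i</sub> = |Y<sub>i</sub> − Y<sub>med</sub>|,  d<sub>max</sub> = max(Y<sub>max</sub> − Y<sub>med</sub>, Y<sub>med</sub> − Y<sub>min</sub>)

and the probability designs draw each individual independently (Poisson
sampling) with

> p<sub>i</sub> = min{1, c · (ε + d<sub>i</sub>/d<sub>max</sub>)<sup>k</sup>},  k = 1 (D5_1) or 2 (D5_2),

where ε > 0 keeps every inclusion probability positive and c is calibrated by
bisection so that Σ p<sub>i</sub> equals the target sample size. Sampled
individuals carry the inverse-probability weight w<sub>i</sub> = 1/p<sub>i</sub>
(Horvitz–Thompson), so weighted estimators remain unbiased for cohort-level
quantities.

Association is tested two ways per variant class:

* **forward**: linear regression of *Y* on the genetic predictor — the
  minor-allele dosage of a common SNP, or the **rare-variant burden score**
  (total count of minor alleles across SNPs with MAF < 3%). Under D5 the fit
  is inverse-probability weighted with the design-based sandwich variance
  (X′WX)⁻¹(Σ w²e²xx′)(X′WX)⁻¹.
* **reverse**: logistic regression of a carrier indicator, or Poisson
  regression of the burden count, on *Y*. Conditioning on the trait makes
  these fits robust to trait-dependent ascertainment, so they run unweighted
  under every design.

Wald tests use a t reference (df = n − 2) for linear models and a standard
normal for the GLMs. The simulation harness summarizes, per design × model:
mean coefficient, empirical SD, mean estimated SE, rejection rate (type I
error under a null trait, power under an alternative), the mean ratio of the
full-cohort test statistic to the design's (MRT), and relative efficiency
(RE = 100 × variance ratio of the full-cohort coefficient to the design's).

## Worked example

Analyze replicate 1 of the packaged 321-individual reference cohort (18 rare
SNPs yielding burden scores 0–3 with frequencies 252/54/11/4; alternative
trait with 0.44 trait units per rare allele):

```python
import pandas as pd
import qtdesign as qd

c = qd.reference_cohort(trait_kind="alternative", n_replicates=1)
geno = pd.DataFrame(c.genotypes, columns=c.snp_ids)
panel = qd.filter_and_classify(geno)
score = qd.rare_variant_score(geno, panel)
y = qd.residualize(c.traits[:, 0], c.covariates)
rt = qd.median_distance(y)
for d in qd.DESIGN_IDS:
    sel = qd.make_selection(d, rt, seed=1)
    i = sel.indices
    if d.startswith("D5"):
        fit = qd.fit_linear(y[i], score[i], weights=sel.w[i],
                            variance_mode="design_sandwich")
    else:
        fit = qd.fit_linear(y[i], score[i])
    print(d, f"{fit.coefficient:.2f} {fit.se:.2f} {fit.statistic:.2f} {fit.p_value:.1e}")
```

prints

```
D1   0.48 0.10 4.91 1.4e-06
D2   0.35 0.16 2.20 2.9e-02
D3   0.83 0.18 4.71 5.4e-06
D4   0.69 0.16 4.27 3.3e-05
D5_1 0.70 0.19 3.60 4.2e-04
D5_2 0.67 0.20 3.42 7.9e-04
```

The full cohort estimates the generating slope (≈0.44) with the strongest
signal; the 50% SRS halves the information; the extreme-phenotype designs
D3/D4 keep a strong test statistic but visibly *inflate* the coefficient
(0.83, 0.69), because selecting by the outcome violates the linear-model
assumptions. The reverse Poisson fit (`qd.fit_glm_reverse(score[i], y[i],
"poisson")`) stays near the full-cohort value under every design — the
recommended analysis when sampling depends on the trait.

The same study runs from the shell:

```bash
qtdesign fixtures --out-dir data --trait-kind alternative
qtdesign select --phenotype data/phenotype.csv --design D5_1 --seed 1 --out sel.tsv
qtdesign fit --phenotype data/phenotype.csv --genotypes data/genotypes.csv \
         --selection sel.tsv --model linear
qtdesign evaluate --config config.yaml --out-dir results/
```

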