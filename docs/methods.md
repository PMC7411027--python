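# Methods

## The generative model

The simulator produces a cohort of `n_unrelated` singleton offspring (the
training pool) and `n_families` sibships of `n_sibs_per_family` full
siblings (the test set), each child of its own founder parent pair.
Founders never enter analysis cohorts — they exist to create realistic
sibling correlations and to carry the nurture confound.

**Genotypes.** Each of `n_variants` biallelic SNPs gets an ancestral
frequency drawn uniform on `[maf_low, maf_high]` (default 0.05–0.5). With
stratification (`fst > 0`), two subpopulations draw their own frequencies
from the Balding–Nichols distribution `Beta(f(1−F)/F, (1−f)(1−F)/F)`
(mean f, variance F·f(1−f)); families never span subpopulations, and
families alternate labels so both halves of the cohort are balanced.
Founder haplotypes are Bernoulli draws; offspring inherit one uniformly
chosen haplotype allele from each parent, independently per variant.
Loci are unlinked by design: every between-sibling statistic in scope
depends on the expected kinship of 0.5, not on genome-wide sharing
variance, so a recombination map would add cost without changing any
tested quantity. Consequences: no LD structure, so predictor sparsity
patterns are cleaner than on real genotypes, and no variation in realized
relatedness between sibling pairs.

**Phenotypes.** `n_causal` variants get standard-normal effect sizes,
rescaled so the cohort variance of the additive genetic value g equals
`h2` exactly. The (liability or trait) value is

```
y = g + e_fam + w·(g_father + g_mother)/2 + d·1[subpop B] + e
```

with `e_fam` shared within a family (variance `c2`), `w = w_nurture` the
genetic-nurture coefficient, `d = env_offset` in phenotype SD units, and
`e` sized so the confound-free total variance is 1. Quantitative traits
are z-scored on the cohort; disease traits threshold the z-scored
liability at the (1−K) normal quantile, so realized prevalence tracks K
even when confounds inflate variance. Nurture uses the same causal
effect vector applied to mean parental genotype — a one-parameter
realization of parental genotype acting through the rearing environment.

A master seed splits into named substreams (frequencies, effects,
founders, transmission, environment), so cohorts are bit-reproducible and
components independently so. Families are generated in fixed-size blocks;
the block size is a private constant, part of the deterministic layout.

What the simulator does *not* emulate: linkage and LD (so external-panel
scoring and clumping questions are out of reach), assortative mating,
dominance/epistasis, X chromosome, age/sex structure, genotyping error and
missingness (except as injected at I/O time), and realistic sibship-size
distributions (fixed-size sibships only). Tests passing here show the
*statistics* behave as the theory of the sibling design predicts; they do
not certify performance on real biobank genotypes.

## Predictor construction

Training uses only individuals without a sibling. Per ensemble member:

1. **Association scan.** Per-variant OLS of phenotype on dosage over the
   member's training split (binary y enters as 0/1 — the pipeline is
   linear throughout, matching the score's additive form). Closed-form
   slope/SE/t with a t(n−2) two-sided p-value; monomorphic variants get
   an undefined p and rank last.
2. **Preselection.** The `k` smallest p-values, ties broken by variant id.
   `k` defaults to 50,000 for biobank-scale inputs; the desk-scale runs in
   `analysis/` and the test suite use k of 100–1,000 against p of
   300–10,000, keeping the selected fraction comparable.
3. **LASSO path.** On column-standardized X and centered y,
   `O(λ,β) = ½‖y−Xβ‖² + nλ‖β‖₁` is minimized along a geometric grid of
   100 penalties from `λ_max = max_j |x_jᵀy|/n` (where the solution is
   exactly zero) down to `10⁻³·λ_max`, via scikit-learn's
   coordinate-descent `lasso_path` (duality-gap tolerance 1e-8, 2,000
   iterations — at the smallest penalties on large dense problems the
   solver may stop short of the gap target; those path points sit far
   from the selected penalty). KKT conditions and the univariate
   soft-threshold closed form are asserted in the test suite.
4. **Penalty selection.** Every path point is scored on the member's
   holdout; the λ maximizing AUC (binary) or Pearson correlation
   (quantitative) wins, ties going to the larger λ (sparser model). An
   all-zero coefficient vector scores AUC 0.5 (all ties) and correlation
   0 by convention.

Holdouts are five non-overlapping sets (500 cases + 500 controls, or
1,000 individuals, by default; smaller cohorts use proportionally smaller
holdouts, e.g. 150+150 at desk scale). Standardization statistics come
from the training split only and are frozen into the predictor; stored
weights are back-transformed to the raw dosage scale so scoring is a
plain weighted allele count, `PRS_i = Σ_j X_ij β_j`. Scores are z-scored
per predictor against the sibling test cohort (population-SD convention);
the ensemble score is the mean of the five z-scored member scores.

## Validation statistics

* **Call rate** (discordant pairs): fraction where the case outscores its
  partner; exact score ties count ½ (Mann–Whitney convention). Reported
  as the ensemble mean with the SD over the five predictors.
* **High-risk identification:** pairs where one member's ensemble-mean
  z-score is strictly above `hi_z` and the other's strictly below
  `normal_z = 1.0`; the statistic is the fraction where the outlier is
  the case. In the swept version the per-predictor spread comes from
  re-defining the outlier subset with each member score.
* **Errors:** every fraction carries both a Wald SD `√(p(1−p)/n)`
  (the tables' parenthetical convention) and a 68% central
  Clopper–Pearson half-width (larger one-sided deviation; fractional
  success counts from ties are rounded for the exact interval); curve
  errors take max(ensemble SD, CP half-width). An entry is flagged
  low-statistics when the combined error exceeds 10% of its value.
  Empty subsets are reported undefined; swept/binned curves leave points
  with fewer than 5 members undefined rather than plotted.
* **Prevalence curves:** affected fraction among individuals with score
  below (or above) each threshold, against the cohort prevalence
  baseline; the model prediction uses only the six moment-matched
  parameters of the two-Gaussian case/control score mixture. The ASP
  variant restricts to individuals with an affected sibling (controls
  need ≥1 affected sibling; cases need ≥1 *other* affected sibling — the
  restriction is idempotent and counts siblings' statuses from the full
  table, not the restricted subset).
* **Quantitative pairs:** within-pair member order is randomized once per
  pair (seeded) so signed differences have symmetric marginals;
  ρ(ΔPGS, Δy) is an ordinary Pearson correlation, invariant to the
  ordering up to mean-centering terms. Rank-call fractions count
  sign agreement of ΔPGS and Δy with ties at ½; the gap-thresholded
  version retains pairs by the *actual* phenotype difference
  |Δy| > threshold and then evaluates each of the five predictors on that
  fixed subset. Under joint normality the expected fraction is
  ½ + arcsin(ρ)/π, used as an independent oracle in the tests.
* **Randomized baselines** draw case–control (or unconstrained) pairs
  from the same sibling test cohort, never joining two members of one
  family, sampling without replacement within a draw.
* Multi-sibling families contribute all C(s,2) pairs by default;
  `one_pair_per_family` gives the conservative alternative when error
  bars must assume independent pairs. Trios are all 3-subsets of a
  sibship; trio calling credits the case (or top phenotype) being the
  top score, ties sharing credit equally.

## Theory oracles

`sibprs.theory` predicts pair statistics from the model rather than the
pipeline: the high-risk pair probability for independent members is a
ratio of Gaussian tail products, and the sibling/random call-rate pair
comes from Monte-Carlo draws of the 4-variate Gaussian
(s₁, s₂, y₁, y₂) with corr(s, g) measured on held-out data, sibling
correlation ½ for every genotype-linear quantity, and liability sibling
correlation h²/2. These let end-to-end tests separate the expected
kinship-induced sibling/random gap from genuine confound-driven
attenuation.

## Problem sizes

The analysis drivers and the acceptance script run at desk scale chosen
to keep every statistic's sampling error well below the effects under
study: 12,000–20,000 training individuals, 1,000–2,000 sibling pairs,
2,000–10,000 variants with 50–100 causal, preselection k of 400–1,000 and
60–100 path points. At these sizes the fitted ensemble recovers the
simulated genetic value with corr(PGS, gv) ≈ 0.9, so disease AUCs land
near the model ceiling (≈ 0.87 at h² = 0.5, K = 0.1) rather than at the
0.6-ish values typical of current real-data predictors, whose training
data support far weaker per-SNP signal.

## Known limitations

Binary traits are modeled linearly end to end (no logistic LASSO), and no
covariates (age, sex, principal components) enter the models — the object
of study is genetic predictive power alone. The two-subpopulation
stratification is a minimal confound mechanism, not a model of continuous
ancestry gradients. Clopper–Pearson intervals treat tie half-counts by
rounding. The PLINK codec handles the standard SNP-major BED layout only.
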