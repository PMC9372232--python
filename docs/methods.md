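# Methods

## The model

Age at disease onset is treated as a time-to-event outcome. For subject `i`
with effect-allele counts `x_i` the hazard is proportional:

```
h(t | x_i) = h0(t) · exp(Σ_j β_j x_ij + Σ_k γ_k PC_ik)
```

Cases contribute events at diagnosis age; controls are censored at last
follow-up. The SNP weights are estimated by maximizing the weighted Breslow
partial log-likelihood penalized by `λ · Σ_j |β_j|`; the four ancestry
principal components carry no penalty (they are confounder adjustments —
shrinking them to zero would defeat their purpose). The polygenic hazard
score of a subject is the SNP part of the fitted linear predictor,
`PHS = Σ_j β_j x_j` over the SNPs with nonzero coefficients.

### Partial likelihood and solver

Ties in event age share a single Breslow risk-set denominator; per-subject
sample weights multiply both the event terms and the risk-set contributions,
so unit weights recover the classical partial likelihood. The objective
minimized at each path point is `-(1/n)·pll(β) + λ·Σ pf_j|β_j|` with
predictors standardized internally and coefficients reported on the
allele-count scale; weights are normalized to mean one so λ is comparable
across weighting schemes.

The solver is the standard iteratively-reweighted-least-squares scheme:
each outer step builds the quadratic expansion of the partial likelihood in
the linear predictor (gradient and diagonal Hessian via prefix sums over
risk sets, O(n log n) after one sort), and cyclic coordinate descent with
soft thresholding solves it. Two numerical safeguards matter in practice:
the working residual is periodically refreshed from the stored working
response (incremental updates accumulate float drift that can stall
convergence below ~1e-9), and when the active set is ill-conditioned
(strongly correlated predictors) the restricted quadratic is solved exactly
by a Newton step with a sign-crossing line search. λ_max is computed from
the score at the unpenalized-covariates-only fit and nudged up by 1e-6
relative so the first path point is exactly sparse. The default path has
100 points log-spaced down to `1e-4·λ_max`; coefficient-change tolerance
1e-8. Large simulation studies in the test suite use a 30–40 point path to
`1e-2·λ_max` and tolerance 1e-6/1e-7 — selection behavior is unchanged at
these sizes.

### Cross-validation

λ is chosen to minimize the mean k-fold (default 10) cross-validated
partial-likelihood deviance in the Verweij–van Houwelingen form:
`dev_f = -2·[pll_all(β_-f) − pll_train(β_-f)]`, the held-out fold's
contribution to the partial likelihood of the model fitted without it.
This is the natural out-of-fold deviance for Cox models, where per-subject
likelihood contributions do not decompose. Folds are seeded; every training
complement must contain an event, and each held-out fold must too whenever
there are at least k events (with k > #events, e.g. leave-one-out,
censored-only folds are accepted — their deviance is still defined). The
minimum-mean rule is used, not the one-standard-error rule.

### Unpenalized fits

Evaluation-stage Cox fits (univariable SNP screening, PHS and
family-history models) use a dense Newton–Raphson solver on the same
likelihood with step halving. A coefficient exceeding 10 per predictor
standard deviation is treated as monotone-likelihood divergence and raised
as an error rather than returned; the observed information at the optimum
supplies Wald standard errors. `lifelines` and `scikit-survival` serve as
independent oracles for this solver in the test suite, never as the
implementation.

## Percentiles, hazard ratios, weights

Centile thresholds (20/30/70/80/95) are inverted-empirical-CDF (type-1)
quantiles of the PHS among training-set controls younger than 70 — young
controls approximate the unaffected population the score should rank. The
"middle 40%" band is percentiles 30–70 (the centered band around the
median; the alternative 40–60 reading is configurable at call sites by
building a custom reference). Band means `m_20, m_50, m_80, m_95` are
computed on the same reference, so `HR_A/B = exp(β·(m_A − m_B))` is
comparable across testing sets and `HR_80/20 = HR_80/50 / HR_20/50` holds
as an exact identity in every bootstrap replicate.

Case-enriched testing sets are corrected by inverse-probability weights:
controls weight 1, cases `(π/(1−π))·(N_ctrl/N_case)` so the weighted case
fraction equals the population prevalence π (default 0.12 lifetime risk;
the synthetic generator carries its realized prevalence alongside each
cohort). Bootstrap CIs resample cases and controls separately (preserving
the design ratio) with 2.5–97.5 percentile intervals; the reported point
estimate is the replicate mean, with the plug-in estimate also emitted for
the PPV.

The clinically-significant endpoint treats non-significant cases as
censored at their diagnosis age; fatal analysis places events at death age
and censors everyone else at last contact. The family-history comparison is
restricted to subjects with known family history, compares
`Cox(endpoint ~ FH + PHS)` against `Cox(endpoint ~ FH)` by a 1-df
likelihood-ratio test at α = 0.01, reports the PHS hazard ratio as
HR_80/20 and the family-history one as `exp(β_FH)`, and truncates reported
p-values at 1e-16.

## The synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes —
not any real population:

- **Genotypes**: `Binomial(2, f_j)` per SNP (Hardy–Weinberg), frequencies
  drawn U(0.05, 0.5) unless supplied. Near-duplicate pairs copy each of the
  partner's two alleles with probability 0.99 (configurable in (0.95, 1]),
  giving genotypic r² ≈ fidelity² ≈ 0.98.
- **Onset**: Weibull baseline with shape 4.5 and scale 116 years — shape
  well above 1 mimics the steeply rising incidence of a late-onset cancer,
  and the scale puts the realized case fraction near the 0.12–0.15 lifetime
  risk under the default censoring window, U(55, 90) years of last
  follow-up. Onset is sampled by the closed-form inverse CDF under the
  proportional-hazards model with the centered true burden as linear
  predictor. Default effects: 20 causal SNPs with |β| spanning 0.15–0.45 and
  alternating sign, chosen so the implied top-vs-bottom-quintile hazard
  ratio is of order 10, the regime the evaluation machinery is meant to
  resolve.
- **Clinical significance**: each case draws a full diagnostic record
  (Gleason, PSA, stage, nodes, metastases) consistent with a Bernoulli
  significance indicator (default p = 0.36 given case, the value implied by
  an overall screening PPV of ~0.12 at a 1:2 case:control ratio), and the
  flag is produced by the classifier itself, so the rule
  "Gleason ≥ 7 / PSA ≥ 10 / T3–T4 / N1 / M1" is exercised on every draw.
- **Fatal outcomes**: significant cases die of the disease with
  probability 0.25, at diagnosis age plus an Exponential(mean 5 years)
  survival time.
- **Family history**: logistic in the true burden,
  `P(FH) = expit(−2.2 + 0.5·lp)`, giving ~10% positive rates among the
  ~75% of subjects with non-missing family history (missingness is
  completely at random) — within the 7–18% positive and 43–89% availability
  ranges the pipeline should tolerate.
- **Ancestry PCs**: first four left singular vectors of the column-centered
  genotype matrix, augmented with 200 background markers before the SVD.
  Real ancestry axes are computed genome-wide, so candidate SNPs contribute
  negligibly to them; computing PCs from the candidate matrix alone would
  make the covariates exactly collinear with the predictors. In this
  homogeneous simulated population the PCs are effectively null covariates.
- **Screening**: every case is PSA-positive; screen-positive controls are
  drawn to hold a 1:2 case:control ratio among PSA-positives; biopsy equals
  significance for cases and is negative for controls.

What the generator does **not** emulate: chromosome-scale LD structure,
ancestry admixture or stratification, genotyping error or imputation
uncertainty, PSA as a continuous marker, informative censoring, or
competing mortality. Passing tests therefore demonstrate correctness of the
estimation machinery under its own assumptions, not performance on real
consortium data.

## Problem sizes in the test suite

Distributional checks run at sizes chosen once for statistical
interpretability: selection recovery at n = 20,000 with 50 SNPs over 20
seeded replicates; bootstrap-CI coverage on 50 cohorts of n = 5,000 with
250 bootstrap replicates; the null size of the family-history LRT over 500
replicates on a 2,500-subject cohort; PPV consistency with a PSA-positive
pool of ~32,000 so that the ±0.03 tolerance on the top-5% band is a
~3-sigma statement (a pool of 3,000 leaves that band with ~150 subjects and
a sampling sd of ~0.037, too noisy to bound at 0.03). The acceptance script
runs the full pipeline on a 30,000-subject population with 120 candidate
SNPs (25 causal, 8 near-duplicate pairs), a 40-point path and 1,000
bootstrap replicates.

## Degenerate inputs and tie-breaks

- Pruning processes flagged pairs in ascending order of the within-pair
  minimum p-value (id-based tie-break), and an eliminated SNP cannot trigger
  further removals; the outcome is invariant to column order when p-values
  are distinct.
- Equal p-values in a pruned pair keep the lexicographically smaller id.
- Percentile references warn (rather than fail) on degenerate or small
  (< 100) reference populations; band HRs on a degenerate reference are 1
  with a warning.
- Adjusted incidence above 1 is clipped to 1 with a warning; the exact
  transform `1 − (1 − F)^HR` is emitted alongside the literal product for
  comparison, since the product is a rare-disease approximation that the
  direct multiplication convention implies.
- Missing genotypes are mean-imputed (2 × effect-allele frequency) for
  scoring and fitting; a weight-table allele matching the genotype's other
  allele flips the count to 2 − x; any other mismatch is an error.

## Known limitations

- Only Breslow tie handling is implemented; with continuous simulated ages
  ties are measure-zero, but heavily discretized real ages would make the
  Efron approximation preferable.
- The LASSO solver assumes standardizable (non-constant) predictors and
  raises on monomorphic SNPs; filter before fitting.
- Bootstrap percentile CIs are slightly anticonservative at moderate n
  (coverage ~90–93% at n = 5,000 in the suite's own coverage study).
- The sample-weighting scheme is one defensible inverse-probability
  construction; other weighting conventions would change HR point estimates
  for strongly enriched designs.
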