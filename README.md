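# polyhaz

Development and evaluation of **polygenic hazard scores (PHS)** for
age-at-onset risk stratification, modelled on the prostate-cancer screening
setting: which men carry enough common-variant risk that a positive PSA test
is likely to mean clinically significant disease, and at what age?

A PHS is the Cox linear predictor

```
PHS_i = Σ_j β_j · x_ij
```

where `x_ij` is the effect-allele count of SNP `j` in subject `i` and the
weights `β_j` are per-allele log-hazard ratios estimated by an
L1-regularized (LASSO) Cox proportional hazards model of age at diagnosis,
with the penalty chosen by 10-fold cross-validated partial-likelihood
deviance. The package covers the full workflow:

- **Synthetic cohorts** (`polyhaz.simulate`) — Hardy–Weinberg genotypes with
  near-duplicate SNP pairs, Weibull proportional-hazards onset ages, control
  censoring at last follow-up, case oversampling, a clinical-significance
  sub-phenotype (Gleason ≥ 7, PSA ≥ 10 ng/mL, stage T3–T4, nodal or distant
  metastasis), disease deaths, family history linked to true genetic burden,
  and a PSA-screening layer with a 1:2 case:control ratio.
- **Candidate pruning** (`polyhaz.pruning`) — of each SNP pair with
  genotypic r² > 0.95, the member with the larger univariable Cox p-value
  is dropped.
- **Penalized Cox fitting** (`polyhaz.lasso_cox`) — an authored
  coordinate-descent solver for the weighted Breslow partial likelihood
  with a penalty mask (SNPs penalized, ancestry principal components not),
  exposed as the scikit-learn-style estimator `LassoCoxPHS`.
- **Scoring and percentiles** (`polyhaz.scoring`) — PHS computation with
  allele flipping and frequency imputation; centile thresholds and band
  means defined once, on training-set controls younger than 70.
- **Risk stratification** (`polyhaz.stratify`) — sample-weight-corrected
  hazard ratios between percentile bands, `HR_A/B = exp(β·(m_A − m_B))`,
  with stratified-bootstrap CIs; multivariable comparison of family history
  plus PHS against family history alone (likelihood-ratio test, α = 0.01).
- **Screening PPV** (`polyhaz.ppv`) — bootstrap positive predictive value
  of PSA testing for clinically significant disease, overall and within the
  top 20% / top 5% of the PHS.
- **Incidence curves** (`polyhaz.incidence`) — population age-specific
  cumulative incidence split into significant / non-significant components
  and scaled by the mean HR of the top risk bands.

## Worked example

```python
import numpy as np
import polyhaz as ph

# training cohort: case-enriched, 60 candidate SNPs of which 12 causal
cfg = ph.SimulationConfig(n_subjects=6000, n_snps=60, n_causal=12,
                          ld_dup_pairs=4, seed=11)
g, phen = ph.simulate_cohort(cfg)
train = ph.apply_case_control_sampling(phen, cfg)
g_train = g.select_subjects(train["subject_id"])

pruned, report = ph.prune(g_train, train, threshold=0.95)

X = np.column_stack([pruned.counts,
                     train[["pc1", "pc2", "pc3", "pc4"]].to_numpy()])
est = ph.LassoCoxPHS(cv=10, n_lambda=40, lambda_min_ratio=1e-2,
                     random_state=5)
est.fit(X, ((train.status == "case").to_numpy(),
            train.event_age.to_numpy()),
        penalty_free=[pruned.n_snps + i for i in range(4)],
        feature_names=pruned.snp_ids + ["pc1", "pc2", "pc3", "pc4"])
print(est.n_nonzero_snps_)          # 13  SNPs kept by the LASSO

weights = ph.export_weights(est.to_fitted_model(), pruned.snp_meta)
scores = ph.compute_phs(g_train, weights)
ref = ph.build_percentile_reference(scores, train, max_age=70)

# a screening-trial-style testing cohort (1:2 case:control, biopsy data)
cfg_t = ph.SimulationConfig(n_subjects=6000, n_snps=60, n_causal=12,
                            ld_dup_pairs=4, seed=77,
                            sampled_case_control_ratio=0.5)
g_t, phen_t = ph.simulate_cohort(cfg_t)
test = ph.simulate_screening(ph.apply_case_control_sampling(phen_t, cfg_t),
                             cfg_t)
s_test = ph.compute_phs(g_t.select_subjects(test["subject_id"]), weights)

hr = ph.hr_report(s_test, test, ref, "any",
                  phen_t.attrs["population_prevalence"],
                  n_boot=50, seed=3)
print(hr.hrs["hr_80_20"])           # (7.02, 5.27, 8.63)

ppv = ph.ppv_bootstrap(test, s_test, ref, n_boot=200, seed=4)
print(ppv.ppv)                      # ppv_overall (0.124, 0.114, 0.136)
                                    # ppv_80      (0.178, 0.158, 0.202)
                                    # ppv_95      (0.208, 0.175, 0.248)
```

The hazard ratio of ~7 between the top and bottom PHS quintile says that
men in the top fifth of genetic risk develop the disease at a given age at
about seven times the rate of men in the bottom fifth; the rising PPVs show
that restricting PSA screening follow-up to high-PHS men raises the yield
of clinically significant diagnoses per positive test from 12% to ~21%.

The same workflow is available from the shell:

```sh
polyhaz simulate --config cfg.yaml --out-prefix train --sample
polyhaz prune --vcf train.vcf --phen train.phen.tsv --out-vcf pruned.vcf
polyhaz fit --vcf pruned.vcf --phen train.phen.tsv --folds 10 \
            --seed 2 --out weights.tsv --model model.json
polyhaz score / reference / evaluate / fh-compare / ppv / incidence ...
```

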