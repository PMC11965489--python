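# fieldsig

Epigenetic field-defect signatures for mouse DNA-methylation cohorts:
a tested pipeline for deriving and scoring four methylation biomarkers of
carcinogen exposure in surrogate tissues, and relating them to tumor-free
survival.

## The problem

Hormone-driven carcinogenesis (e.g. synthetic-progesterone/DMBA exposure in
mice) leaves genome-wide methylation marks not only in the at-risk organ
but in easily sampled surrogate tissues — a *field-defect* readout of
systemic cancer risk. This package implements the four biomarkers such a
study derives from Illumina mouse-array beta values (methylation fractions
in [0, 1]):

1. **Carcinogen signature.** In a discovery cohort, CpGs are ranked per
   tissue by the difference in mean beta between exposed (P/D+) and
   unexposed animals; tissue rankings are combined by geometric mean into a
   pan-tissue ranking. The signature score of a sample is
   `mean(beta over top-1000 hyper CpGs) − mean(beta over top-1000 hypo CpGs)`,
   linearly scaled to mean 0 / SD 1 in healthy mammary-gland discovery
   samples, with that scale frozen for later cohorts.
2. **Cell-type composition.** Reference-based deconvolution of bulk betas
   against marker panels (non-negative least squares, renormalized to the
   simplex), flat and hierarchical (immune or mammary-epithelial subtypes
   inside a parent fraction). Panels are built by ranking CpGs per cell
   type on |mean-beta difference| and Wilcoxon rank-sum p, combined by the
   geometric mean of the two ranks (top 100/50/100 per type). Sequencing
   (WGBS/RRBS) references are harmonized onto the array scale by the
   linear transform mapping the sequencing beta modes (exactly 0 and 1)
   onto the array modes (0.017, 0.955): `beta_adj = 0.938·beta + 0.017`.
3. **Mitotic clock.** Mean beta over CpGs within ±200 bp of
   polycomb-group-target gene TSSs (human list mapped to mouse homologs)
   that have <10 % mean methylation in fetal brain/intestine/limb/liver —
   promoter methylation there accumulates with cell divisions.
4. **PRBS score.** Mean beta over CpGs inside progesterone-receptor
   ChIP-seq binding peaks (BED, 0-based half-open vs 1-based CpG
   positions).

Around these sit the array QC cascade (median log2 intensity < 9.5 removes
a sample; detection p > 0.01 marks a probe failed; samples with > 10 %
failures, then probes with > 10 % failures are removed; top-1000
most-variable-probe PCA checked against technical covariates) and the
survival layer (Kaplan-Meier, log-rank, single-covariate Cox with Efron
ties, median-split high/low strata with ties to low).

A synthetic-data module generates every input with the structure the
analysis assumes — bimodal array betas, binomial read sampling for
WGBS/RRBS, planted exposure effects, Dirichlet cell mixtures, annotation
tables, and exponential tumor latencies with administrative censoring — so
the whole pipeline is testable without any downloads.

## Worked example

```python
import fieldsig as fs

cfg = fs.ScenarioConfig(seed=1, n_cpgs=2000,
                        tissues=("mammary_gland", "cervix", "liver"),
                        n_per_group=5, n_affected_hyper=200,
                        n_affected_hypo=200, noise_sd=0.02)
beta, sheet, truth = fs.simulate_discovery_cohort(cfg)
sig = fs.define_carcinogen_signature(beta, sheet, k=100)
scores = fs.score_carcinogen(beta, sig)           # scaled units
healthy = sheet.index[(sheet.tissue == "mammary_gland")
                      & (sheet.exposure == "P/D-")]
print(round(scores[healthy].mean(), 12), round(scores[healthy].std(ddof=1), 6))
print(len(set(sig.hyper_cpgs) & set(truth["hyper_cpgs"])) / 100)
```

prints

```
0.0 1.0
1.0
```

healthy mammary scores are standardized exactly by construction, and with
a 0.2 beta-shift at planted CpGs and noise SD 0.02 the top-100 hyper set
recovers 100 % of the planted ground truth.

The full study flow lives in `analysis/` as numbered drivers
(`01_simulate_cohorts.py` … `06_intervention_survival.py`): simulate the
discovery and intervention cohorts, run QC, build the three reference
panels from mixed-platform references, benchmark deconvolution (per-type
RMSE ≤ 0.004 at noise SD 0.02), derive the signature, and fit the
4-tissue × 4-signature median-split survival grid. Tables land in
`results/`. A thin `fieldsig` CLI exposes the same stages
(`fieldsig simulate`, `qc`, `build-panel`, `deconvolve`,
`discover-signature`, `score`, `clock-def`, `prbs-def`, `survival`,
`run-discovery`, `run-intervention`).

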