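# Methods

## Scope and design

`fieldsig` implements a four-biomarker methylation pipeline for mouse
exposure studies — carcinogen signature, reference-based cell-type
deconvolution, PCGT mitotic clock, PRBS methylation score — together with
array QC and tumor-free survival analysis, exercised end to end on
synthetic data. All statistics operate on beta values (methylation
fractions in [0, 1]); nothing here parses raw array intensities, and
background/dye correction and BMIQ normalization are assumed to have
happened upstream (the pipeline consumes normalized betas).

## QC cascade (`fieldsig.qc`)

Samples with median methylated *or* unmethylated log2 intensity < 9.5 are
removed (log2 is the customary scale at which 9.5 is a meaningful array
cutoff; the threshold is configurable). A probe measurement with detection
p > 0.01, or a missing beta, counts as failed. The cascade then removes
samples with a failed fraction > 0.10, recomputes probe failure fractions
over the retained samples, and removes probes > 0.10. All comparisons are
strict, so values exactly at a threshold are retained. The order —
probes-marked-failed → samples → probes — is fixed and tested: the source
rules are stated in one sentence without an ordering, and recomputing
probe fractions after sample removal is the choice that makes the cascade
idempotent. The PCA check selects the 1,000 most variable probes by sample
SD (ddof = 1, ties broken by CpG id), computes up to 10 principal
components over samples, and tests each against each covariate — Pearson's
two-sided test for numeric covariates, Kruskal-Wallis for categorical. No
multiplicity correction is applied; the table is for inspection, and
constant covariates are skipped with a warning.

## Cross-platform harmonization (`fieldsig.refpanel`)

Array betas are bimodal with modes strictly inside (0, 1) because of
background intensity (0.017 and 0.955 for this array); sequencing betas
are exact read fractions with modes at 0 and 1. Modes are located as the
two argmaxes of a Gaussian KDE on a 2,001-point grid, one per side of 0.5;
grid endpoints count as modes when density falls away from them (that is
how exact-0/1 sequencing modes are found), densities below 10⁻³ of the
maximum are ignored as numerically flat tails, and unimodal input is an
error. The harmonizing map is the unique line through the two mode pairs —
for (0, 1) → (0.017, 0.955), slope 0.938 and intercept 0.017 — applied
elementwise with clamping to [0, 1] (a no-op for any transform mapping the
unit interval into itself; it guards user-supplied lines). Cross-platform
CpG filtering keeps CpGs on the array universe, observed in every RRBS
dataset, and missing in ≤ 10 % of pooled samples (strict >).

## Marker ranking and panels

For a target cell type, each CpG gets Δ = mean beta(target) − mean
beta(rest) (complete-case) and a two-sided Wilcoxon rank-sum p comparing
the two groups — exact enumeration when min(n) ≤ 8 with no ties, normal
approximation with tie and continuity correction otherwise. CpGs are
ranked by |Δ| (descending) and by p (ascending) with 1-based average ranks
for ties; the combined rank is the geometric mean of the two, selection
takes the lowest combined ranks with ties broken by larger |Δ| then CpG
id. Panels are the union of per-type top lists (defaults 100 primary, 50
immune-subtype, 100 epithelial-subtype per type; duplicates collapse), and
entries are per-type complete-case mean betas. The builder takes any
labeled sample collection; it does not hard-code the provenance sample
counts of any particular reference compendium, and the immune type list is
caller-specified rather than fixed at any specific number of subtypes.

## Deconvolution (`fieldsig.deconv`)

Fractions are the non-negative least-squares fit of a sample's betas at
the panel CpGs onto the panel columns, renormalized to sum to 1; values
below 10⁻⁶ are snapped to 0 (then renormalized) for stable downstream
ratios. Constrained projection was chosen over robust partial-correlation
variants because it is exactly testable by mixture recovery; a robust mode
could be added without changing the contract. Rank-deficient panels and
samples covering < 80 % of panel CpGs (configurable) are errors.
Hierarchical mode fits a subtype panel separately and rescales its
fractions to sum to the parent type's primary fraction, so the expanded
vector stays on the simplex; a parent fraction of 0 zeroes all its
subtypes. The granulocyte/lymphocyte ratio sums configurable class members
(default granulocytes: neutrophil + MDSC when present; lymphocytes: B, NK,
CD4 T, CD8 T) and returns +inf when the lymphocyte sum is 0. Note that
when bulk contains substantial signal from types absent from a subtype
panel, subtype fits absorb part of it; subtype panels are meant for
samples dominated by the parent lineage (e.g. immune subtypes in blood).

## Carcinogen signature (`fieldsig.signatures`)

Per tissue (≥ 2 samples per exposure group; tumor samples excluded by
caller contract), CpGs are ranked by the signed exposed-minus-unexposed
difference in mean beta, yielding a hyper ranking (descending) and a hypo
ranking (ascending) — two signed rankings rather than |difference|,
because the end product is separate top-k hyper- and hypo-methylated
lists. Each ranking is combined across tissues by the per-CpG geometric
mean of ranks and re-ranked ascending. The top k = 1,000 of each become
the signature sets. After geometric-mean combination the two sets can in
principle intersect; overlapping CpGs are removed from both and each set
refilled from the next ranks until disjoint (logged). The raw score is
mean(hyper betas) − mean(hypo betas); scaling subtracts the mean and
divides by the sample SD (ddof = 1) of raw scores over unexposed
mammary-gland discovery samples, and a frozen signature reuses those
parameters on any later cohort — no re-fitting. Scoring requires ≥ 80 %
of signature CpGs present per sample.

## Mitotic clock and PRBS score

Clock CpGs lie within ±200 bp (inclusive both ends) of the TSS of a mouse
homolog of a human polycomb-group-target gene and have mean beta < 0.10 in
every listed fetal tissue; the homolog map, TSS table, CpG positions, and
fetal reference are inputs, not embedded resources, so the published CpG
counts for the real annotation are provenance facts rather than outputs
this package reproduces. PRBS CpGs are those whose 1-based position falls
inside a progesterone-receptor ChIP-seq peak, with BED intervals read as
0-based half-open (position p overlaps [start, end) iff start < p ≤ end).
Both scores are plain means over present CpGs with the same 80 % coverage
floor.

## Survival (`fieldsig.surv`)

Time is days from pellet implantation; an event is the first caliper
measurement of a tumor, and sacrifice without a measured tumor (including
tumors found only at necropsy, by caller contract) is censoring.
Kaplan-Meier and two-group log-rank are standard; the Cox model has a
single covariate, maximized by Newton iteration with the Efron tie
correction (appropriate for small rodent cohorts with shared measurement
days), Wald CI exp(β ± 1.96·SE). These fits are backed by lifelines;
tests verify the coefficient against a hand-written partial-likelihood
grid oracle. Monotone likelihood (complete separation) is flagged
`converged=False`, reporting a weakly penalized fit rather than a runaway
coefficient. Median splits send ties and the median itself to "low" —
deterministic and conservative for the high-vs-low hazard ratio.

## Synthetic data (`fieldsig.sim`)

The generator emulates the study's structure, not its measured effect
sizes — exposure effects on individual CpGs are free parameters, not
estimates of real data.

- **Biology vs measurement.** True methylomes put background CpGs at
  exactly 0/1 (half and half); the array reports them at the modes
  (0.017, 0.955) plus truncated Gaussian noise on the beta scale (clamped
  to [0, 1]; noise is Gaussian on the beta scale, not logit, because every
  downstream statistic operates on betas). Sequencing platforms draw
  per-CpG Binomial(depth = 30) reads, which yields exact 0/1 modes; RRBS
  covers 8 % of CpGs by default, WGBS 95 %.
- **Cell types.** Each type owns a disjoint block of marker CpGs
  (default 100/type) at 0.5 ± marker_delta/2 with alternating direction,
  so the target-vs-rest difference is exactly marker_delta.
- **Cohorts.** Defaults mirror the study design: nine surrogate tissues
  with 9 animals per exposure arm in Discovery; each animal contributes
  one sample per tissue (shared `animal_id`). Exposure shifts 1,500
  planted hyper CpGs by +0.2 and 1,500 hypo CpGs by −0.2 (defaults;
  planted CpGs get mid-range baselines so the shift is never clipped).
  Mifepristone attenuates the exposure effect by a configurable factor
  (default 0.6) in the intervention arms. The planted ground truth is
  shared between the discovery and intervention cohorts of one scenario
  seed, so frozen signatures transfer; only measurement noise is
  cohort-specific.
- **Mixtures.** Bulk = fraction-weighted average of cell-type methylomes
  plus clamped Gaussian noise; fractions come from a symmetric Dirichlet
  (configurable concentration) and are always returned as ground truth.
- **Survival.** Exponential latency with hazard
  h₀·exp(log HR·score), administrative censoring at the follow-up horizon
  (default 161 d ≈ the 23-week sacrifice age).
- **Determinism.** One scenario seed fans out to fixed per-stage child
  streams (SeedSequence with stage offsets), so identical seeds give
  byte-identical outputs and each stage is independently reproducible.

What the synthetic data does **not** model: probe chemistry and bisulfite
conversion error, spatially correlated CpGs, tissue-specific baseline
methylomes, realistic effect-size distributions, or informative censoring.
Passing tests therefore demonstrate correctness of the procedures and
recoverability under the stated generative model, not performance on real
cohorts.

## Problem sizes and numerical choices

The test suite runs the signature construction at the full default scale
(10,000 CpGs, nine tissues, 9 + 9 animals per tissue) and the calibration
checks at 100 replicates (Cox CI coverage at n = 200) and 200 replicates
(type-I error of the null signature test and of the log-rank test, judged
against an exact binomial test of the 5 % nominal rate). The null
signature check scores an *independent* null cohort with the trained
signature: scoring the training replicate itself would be
anti-conservative, since the top-k sets are selected on the very contrast
being tested. Fraction estimates use `scipy.optimize.nnls`; PCA uses the
full SVD solver for determinism; all rankings use average ranks for ties
with lexicographic CpG-id tie-breaks so results are order-invariant.

## Known limitations

- The deconvolution contract is plain NNLS; no robust variant is shipped.
- `estimate_beta_modes` needs ≥ 100 values spanning both tails and a
  0.5 split point between modes; distributions with both modes on one
  side of 0.5 are rejected rather than guessed.
- The Cox layer is single-covariate by design — no multivariable models,
  proportional-hazards diagnostics, or competing risks.
- The CLI is a thin convenience layer; programmatic use via
  `fieldsig.pipeline` is the primary interface.
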