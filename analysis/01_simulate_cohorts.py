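#!/usr/bin/env python
"""Simulate the Discovery and Intervention cohorts and write them to disk.

Discovery: nine surrogate tissues, 9 exposed (P/D+) vs 9 healthy animals,
with 1,500 planted hyper- and 1,500 hypo-methylated CpGs (beta shift 0.2).
Intervention: four surrogate tissues, all four P/D x mifepristone arms.
"""

import json

import fieldsig as fs
from scenario import DATA, DISCOVERY, INTERVENTION, RESULTS, ensure_dirs


def main() -> None:
    ensure_dirs()
    beta_d, sheet_d, truth = fs.simulate_discovery_cohort(DISCOVERY)
    fs.io.write_beta_matrix(beta_d, DATA / "discovery_beta.tsv.gz")
    fs.io.write_sample_sheet(sheet_d, DATA / "discovery_samples.csv")
    (DATA / "ground_truth.json").write_text(json.dumps(truth))

    beta_i, sheet_i, _ = fs.simulate_intervention_cohort(INTERVENTION)
    fs.io.write_beta_matrix(beta_i, DATA / "intervention_beta.tsv.gz")
    fs.io.write_sample_sheet(sheet_i, DATA / "intervention_samples.csv")

    summary = (
        sheet_d.assign(cohort="discovery")
        .pipe(lambda d: d.groupby(["cohort", "tissue", "exposure"]).size())
        .rename("n_samples")
        .reset_index()
    )
    summary.to_csv(RESULTS / "cohort_summary.csv", index=False)
    print(f"discovery: {beta_d.shape[0]} CpGs x {beta_d.shape[1]} samples "
          f"({len(truth['hyper_cpgs'])} hyper / {len(truth['hypo_cpgs'])} hypo planted)")
    print(f"intervention: {beta_i.shape[0]} CpGs x {beta_i.shape[1]} samples, "
          f"{sheet_i.animal_id.nunique()} animals in {sheet_i.intervention.nunique() * 2} arms")


if __name__ == "__main__":
    main()
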