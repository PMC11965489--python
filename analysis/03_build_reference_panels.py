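#!/usr/bin/env python
"""Build the three cell-type reference panels from mixed-platform references.

Simulates labeled reference methylomes on array, WGBS, and RRBS platforms,
rescales sequencing betas onto the array's bimodal scale with the
mode-matching linear transform, keeps CpGs usable across platforms, and
builds the primary (4-type), immune-subtype, and mammary-epithelial
subtype marker panels.
"""

import numpy as np
import pandas as pd

import fieldsig as fs
from scenario import (
    CELL_MODEL, EPITHELIAL_SUBTYPES, IMMUNE_SUBTYPES, RESULTS, SEED, ensure_dirs,
)


def main() -> None:
    ensure_dirs()
    arr_beta, arr_sheet = fs.simulate_reference_methylomes(CELL_MODEL, 8, "array", seed=SEED)
    wgbs_beta, wgbs_sheet = fs.simulate_reference_methylomes(CELL_MODEL, 4, "WGBS", seed=SEED + 1)
    rrbs_beta, rrbs_sheet = fs.simulate_reference_methylomes(CELL_MODEL, 3, "RRBS", seed=SEED + 2)

    arr_modes = fs.estimate_beta_modes(arr_beta.to_numpy().ravel())
    seq = np.concatenate([b.to_numpy().ravel() for b in (wgbs_beta, rrbs_beta)])
    seq_modes = fs.estimate_beta_modes(seq[np.isfinite(seq)])
    transform = fs.derive_mode_matching_transform(seq_modes, arr_modes)
    print(f"array modes {tuple(round(m, 3) for m in arr_modes)}, sequencing modes "
          f"{seq_modes} -> slope {transform.slope:.3f}, intercept {transform.intercept:.3f}")

    wgbs_beta = fs.harmonize_sequencing_betas(wgbs_beta, transform)
    rrbs_beta = fs.harmonize_sequencing_betas(rrbs_beta, transform)

    keep = fs.filter_cross_platform_cpgs(
        {"array": (arr_beta, "array"), "wgbs": (wgbs_beta, "WGBS"), "rrbs": (rrbs_beta, "RRBS")}
    )
    beta = pd.concat([b.loc[keep] for b in (arr_beta, wgbs_beta, rrbs_beta)], axis=1)
    labels = pd.concat([s["cell_type"] for s in (arr_sheet, wgbs_sheet, rrbs_sheet)])
    print(f"{len(keep)} of {CELL_MODEL.n_cpgs} CpGs usable across platforms")

    primary = fs.build_panel(beta, labels, list(CELL_MODEL.cell_types), 100, level="primary")
    primary.write(RESULTS / "panel_primary.tsv")

    immune_model = fs.CellTypeModel(
        cell_types=IMMUNE_SUBTYPES, n_cpgs=2000, markers_per_type=50, marker_delta=0.5
    )
    ib, ish = fs.simulate_reference_methylomes(immune_model, 6, "array", seed=SEED + 3)
    immune = fs.build_panel(ib, ish["cell_type"], list(IMMUNE_SUBTYPES), 50, level="immune_subtype")
    immune.write(RESULTS / "panel_immune.tsv")

    epi_model = fs.CellTypeModel(
        cell_types=EPITHELIAL_SUBTYPES, n_cpgs=2000, markers_per_type=100, marker_delta=0.5
    )
    eb, esh = fs.simulate_reference_methylomes(epi_model, 8, "array", seed=SEED + 4)
    epithelial = fs.build_panel(
        eb, esh["cell_type"], list(EPITHELIAL_SUBTYPES), 100, level="epithelial_subtype"
    )
    epithelial.write(RESULTS / "panel_epithelial.tsv")

    for name, panel in [("primary", primary), ("immune", immune), ("epithelial", epithelial)]:
        print(f"{name} panel: {panel.betas.shape[0]} unique marker CpGs x "
              f"{len(panel.cell_types)} cell types")


if __name__ == "__main__":
    main()
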