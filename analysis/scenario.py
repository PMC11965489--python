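"""Shared study scenario for the numbered analysis drivers.

One global seed; cohort sizes mirror the study design (nine surrogate
tissues with 9 exposed / 9 unexposed animals in Discovery; four surrogate
tissues in the Intervention arm).  Simulated inputs are written under
scratch/data, derived tables under results/.
"""

from pathlib import Path

import fieldsig as fs

SEED = 20260927

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"

DISCOVERY = fs.ScenarioConfig(seed=SEED)  # defaults: 10,000 CpGs, 9 tissues, 9/group

INTERVENTION = fs.ScenarioConfig(
    seed=SEED,
    n_cpgs=10_000,
    tissues=("mammary_gland", "cervix", "oviduct", "blood"),
    n_per_group=9,  # 4 arms x 9 animals
    noise_sd=0.02,
    baseline_hazard=0.005,
    log_hr_per_unit_signature=1.0,
)

CELL_MODEL = fs.CellTypeModel(
    cell_types=("epithelial", "fibroblast", "fat", "immune"),
    n_cpgs=4000,
    markers_per_type=100,
    marker_delta=0.6,
)

IMMUNE_SUBTYPES = ("b_cell", "nk", "cd4_t", "cd8_t", "monocyte", "neutrophil")
EPITHELIAL_SUBTYPES = ("basal", "luminal_progenitor", "mature_luminal")


def ensure_dirs() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
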