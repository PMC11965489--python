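"""Synthetic methylation cohorts with the structure the pipeline assumes.

Generates every input the analysis consumes: cell-type reference methylomes
on array/WGBS/RRBS platforms, bulk mixtures with known fractions, a
multi-tissue discovery cohort with planted exposure effects, an intervention
cohort with four treatment arms, and censored tumor-latency outcomes linked
to a per-animal score.

Beta values are methylation fractions in [0, 1].  Array-like data are
bimodal with modes at ``ARRAY_BETA_MODES``; sequencing platforms draw
per-CpG binomial read counts, so their pooled betas have modes at exactly
0 and 1.  Noise is Gaussian on the beta scale, clamped to [0, 1].

A single scenario seed fans out to fixed per-stage child seeds so each
stage is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Modes of the bimodal array beta distribution (unmethylated, methylated).
ARRAY_BETA_MODES = (0.017, 0.955)

#: Fraction of the CpG universe covered by each sequencing platform.
PLATFORM_COVERAGE = {"array": 1.0, "WGBS": 0.95, "RRBS": 0.08}

EXPOSED, UNEXPOSED = "P/D+", "P/D-"
TREATED, UNTREATED = "M+", "M-"

#: Discovery-set surrogate tissues (nine, mammary gland first).
DEFAULT_TISSUES = (
    "mammary_gland",
    "cervix",
    "oviduct",
    "uterus",
    "ovary",
    "spleen",
    "liver",
    "lung",
    "blood",
)

# Fixed offsets fanning the scenario seed out to per-stage child streams.
_STAGE = {
    "reference": 11,
    "mixtures": 23,
    "discovery": 37,
    "intervention": 41,
    "survival": 53,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child generator for a named pipeline stage of a global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE[stage]]))


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a simulated exposure study.

    ``n_per_group`` animals are drawn for every (tissue, exposure,
    intervention) cell.  Exposure shifts ``n_affected_hyper`` planted CpGs
    up by ``effect_size_hyper`` and ``n_affected_hypo`` down by
    ``effect_size_hypo``, consistently across tissues.  Survival follows an
    exponential latency with hazard
    ``baseline_hazard * exp(log_hr_per_unit_signature * score)`` and
    administrative censoring at ``followup_days`` (default 161 d = 23 wk).
    """

    seed: int
    n_cpgs: int = 10_000
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_per_group: int = 9
    effect_size_hyper: float = 0.2
    effect_size_hypo: float = 0.2
    n_affected_hyper: int = 1_500
    n_affected_hypo: int = 1_500
    noise_sd: float = 0.02
    followup_days: float = 161.0
    baseline_hazard: float = 0.01
    log_hr_per_unit_signature: float = 1.1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("effect_size_hyper", "effect_size_hypo", "noise_sd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_cpgs", "n_per_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_affected_hyper + self.n_affected_hypo > self.n_cpgs:
            raise ValueError("planted CpG counts exceed n_cpgs")
        if self.followup_days < 0:
            raise ValueError("followup_days must be non-negative")


@dataclass(frozen=True)
class CellTypeModel:
    """Generative model of cell-type-specific methylomes.

    Each cell type owns a disjoint block of ``markers_per_type`` marker
    CpGs at which it differs from every other type by ``marker_delta``
    (alternating direction).  All remaining CpGs sit at one of the two
    ``background_modes``, shared across types.
    """

    cell_types: tuple[str, ...]
    n_cpgs: int = 2_000
    markers_per_type: int = 100
    marker_delta: float = 0.6
    background_modes: tuple[float, float] = ARRAY_BETA_MODES

    def __post_init__(self) -> None:
        lo, hi = self.background_modes
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("background_modes must be strictly ordered in (0, 1)")
        if not 0.0 < self.marker_delta <= 1.0:
            raise ValueError("marker_delta must be in (0, 1]")
        if self.markers_per_type * len(self.cell_types) > self.n_cpgs:
            raise ValueError("marker sets exceed n_cpgs")

    @property
    def marker_cpgs(self) -> dict[str, list[str]]:
        """Planted marker CpG ids per cell type (disjoint blocks)."""
        m = self.markers_per_type
        return {
            t: [_cpg_id(i) for i in range(k * m, (k + 1) * m)]
            for k, t in enumerate(self.cell_types)
        }


def _cpg_id(i: int) -> str:
    return f"cpg{i:06d}"


def _cpg_index(n: int) -> pd.Index:
    return pd.Index([_cpg_id(i) for i in range(n)], name="cpg_id")


def true_methylomes(model: CellTypeModel, seed: int) -> pd.DataFrame:
    """Noise-free biological CpG x cell-type beta matrix implied by the model.

    Background CpGs are fully unmethylated (0) or methylated (1); the
    array's attenuated background modes are a measurement property applied
    in :func:`simulate_reference_methylomes`, not part of the biology.
    """
    rng = stage_rng(seed, "reference")
    state = rng.random(model.n_cpgs) < 0.5
    base = np.where(state, 1.0, 0.0)
    beta = np.tile(base[:, None], (1, len(model.cell_types))).astype(float)
    m = model.markers_per_type
    for k in range(len(model.cell_types)):
        rows = slice(k * m, (k + 1) * m)
        # alternate marker direction; |target - rest| == marker_delta exactly
        sign = np.where(np.arange(m) % 2 == 0, 1.0, -1.0)
        beta[rows, :] = (0.5 - sign[:, None] * model.marker_delta / 2.0)
        beta[rows, k] = 0.5 + sign * model.marker_delta / 2.0
    return pd.DataFrame(beta, index=_cpg_index(model.n_cpgs), columns=list(model.cell_types))


def _clip01(a: np.ndarray) -> np.ndarray:
    return np.clip(a, 0.0, 1.0)


def simulate_reference_methylomes(
    model: CellTypeModel,
    n_samples_per_type: int,
    platform: str,
    seed: int,
    noise_sd: float = 0.02,
    read_depth: int = 30,
    coverage_fraction: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a labeled reference dataset on one platform.

    Array samples add truncated Gaussian noise to the true methylome;
    WGBS/RRBS samples draw ``Binomial(read_depth, beta)/read_depth``, which
    puts the pooled modes at exactly 0 and 1.  Sequencing platforms cover
    only ``coverage_fraction`` of CpGs (platform default otherwise); the
    rest are missing.

    Returns (beta matrix, sample sheet).
    """
    if platform not in PLATFORM_COVERAGE:
        raise ValueError(f"unknown platform {platform!r}; expected one of {sorted(PLATFORM_COVERAGE)}")
    if n_samples_per_type < 1:
        raise ValueError("n_samples_per_type must be >= 1")
    truth = true_methylomes(model, seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE["reference"], 7]))
    cover = PLATFORM_COVERAGE[platform] if coverage_fraction is None else coverage_fraction

    lo, hi = model.background_modes
    cols, data, rows = [], [], []
    for t in model.cell_types:
        mu = truth[t].to_numpy()
        if platform == "array":
            # array background intensity attenuates the extremes: fully
            # unmethylated/methylated CpGs read at the array modes
            mu = np.where(mu == 0.0, lo, np.where(mu == 1.0, hi, mu))
        for i in range(n_samples_per_type):
            if platform == "array":
                x = _clip01(mu + rng.normal(0.0, noise_sd, size=mu.shape)) if noise_sd > 0 else mu.copy()
            else:
                x = rng.binomial(read_depth, mu) / read_depth
            sid = f"{t}_{platform}_{i:02d}"
            cols.append(sid)
            data.append(x)
            rows.append({"sample_id": sid, "cell_type": t, "platform": platform, "tissue": "reference"})
    beta = pd.DataFrame(np.column_stack(data), index=truth.index, columns=cols)
    if cover < 1.0:
        covered = rng.random(model.n_cpgs) < cover
        beta.loc[~covered, :] = np.nan
    sheet = pd.DataFrame(rows).set_index("sample_id")
    return beta, sheet


def dirichlet_fractions(
    n_samples: int,
    cell_types: list[str] | tuple[str, ...],
    concentration: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample-by-type fraction matrix drawn from a symmetric Dirichlet."""
    rng = stage_rng(seed, "mixtures")
    f = rng.dirichlet([concentration] * len(cell_types), size=n_samples)
    idx = pd.Index([f"mix_{i:03d}" for i in range(n_samples)], name="sample_id")
    return pd.DataFrame(f, index=idx, columns=list(cell_types))


def simulate_bulk_mixtures(
    methylomes: pd.DataFrame,
    fractions: pd.DataFrame,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Bulk betas as fraction-weighted averages of cell-type methylomes.

    ``methylomes`` is CpG x type, ``fractions`` sample x type on the
    simplex.  Truncated Gaussian noise is added and values clamped to
    [0, 1].  Ground-truth fractions are the caller's ``fractions``.
    """
    f = fractions[methylomes.columns].to_numpy()
    if (f < -1e-12).any() or not np.allclose(f.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("fraction vectors must be non-negative and sum to 1")
    bulk = methylomes.to_numpy() @ f.T
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE["mixtures"], 3]))
        bulk = bulk + rng.normal(0.0, noise_sd, size=bulk.shape)
    return pd.DataFrame(_clip01(bulk), index=methylomes.index, columns=fractions.index)


def _baseline_betas(config: ScenarioConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-CpG baseline and the signed planted effect vector.

    Planted CpGs get mid-range baselines so the shift is not clipped;
    background CpGs sit at the array modes.
    """
    lo, hi = ARRAY_BETA_MODES
    base = np.where(rng.random(config.n_cpgs) < 0.5, hi, lo).astype(float)
    planted = rng.choice(
        config.n_cpgs, size=config.n_affected_hyper + config.n_affected_hypo, replace=False
    )
    hyper, hypo = planted[: config.n_affected_hyper], planted[config.n_affected_hyper:]
    base[hyper] = rng.uniform(0.1, max(0.1, 0.9 - config.effect_size_hyper), size=hyper.size)
    base[hypo] = rng.uniform(min(0.9, 0.1 + config.effect_size_hypo), 0.9, size=hypo.size)
    effect = np.zeros(config.n_cpgs)
    effect[hyper] = config.effect_size_hyper
    effect[hypo] = -config.effect_size_hypo
    return base, effect


def _simulate_cohort(
    config: ScenarioConfig,
    arms: list[tuple[str, str]],
    stage: str,
    attenuation: float,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    if len(config.tissues) < 2:
        raise ValueError("at least 2 tissues required")
    if config.n_per_group < 2:
        raise ValueError("need >= 2 samples per group for rank statistics")
    # ground truth (baseline + planted effects) is shared across cohorts of
    # one scenario; only the measurement noise is cohort-specific
    base, effect = _baseline_betas(config, stage_rng(config.seed, "discovery"))
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), _STAGE[stage], 1]))
    cols, data, rows = [], [], []
    for exposure, intervention in arms:
        dose = float(exposure == EXPOSED) * (1.0 - attenuation * float(intervention == TREATED))
        arm_tag = f"{'PDp' if exposure == EXPOSED else 'PDm'}{'Mp' if intervention == TREATED else 'Mm'}"
        for i in range(config.n_per_group):
            animal = f"m_{arm_tag}_{i:02d}"
            mu = base + dose * effect
            for tissue in config.tissues:
                x = mu if config.noise_sd == 0 else mu + rng.normal(0.0, config.noise_sd, size=mu.shape)
                sid = f"{animal}_{tissue}"
                cols.append(sid)
                data.append(_clip01(x))
                rows.append(
                    {
                        "sample_id": sid,
                        "animal_id": animal,
                        "tissue": tissue,
                        "exposure": exposure,
                        "intervention": intervention,
                        "platform": "array",
                    }
                )
    beta = pd.DataFrame(np.column_stack(data), index=_cpg_index(config.n_cpgs), columns=cols)
    sheet = pd.DataFrame(rows).set_index("sample_id")
    truth = {
        "hyper_cpgs": [_cpg_id(i) for i in np.flatnonzero(effect > 0)],
        "hypo_cpgs": [_cpg_id(i) for i in np.flatnonzero(effect < 0)],
    }
    return beta, sheet, truth


def simulate_discovery_cohort(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Discovery cohort: exposed (P/D+) vs healthy (P/D-) animals, no drug.

    Exposure shifts planted hyper CpGs up and planted hypo CpGs down,
    consistently across all tissues.  Returns (beta, sample sheet, ground
    truth with the planted CpG ids).
    """
    arms = [(UNEXPOSED, UNTREATED), (EXPOSED, UNTREATED)]
    return _simulate_cohort(config, arms, "discovery", attenuation=0.0)


def simulate_intervention_cohort(
    config: ScenarioConfig, mifepristone_attenuation: float = 0.6
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Intervention cohort with all four P/D+- x M+- arms.

    Mifepristone (M+) attenuates the exposure effect by the given factor
    in exposed animals and does nothing in unexposed ones.
    """
    arms = [(e, m) for e in (UNEXPOSED, EXPOSED) for m in (UNTREATED, TREATED)]
    return _simulate_cohort(config, arms, "intervention", attenuation=mifepristone_attenuation)


def simulate_annotation_resources(
    n_cpgs: int,
    seed: int,
    chroms: tuple[str, ...] = ("chr1", "chr2", "chr3"),
    n_genes: int = 60,
    n_pcgt: int = 25,
    n_peaks: int = 40,
    peak_width: tuple[int, int] = (200, 2000),
    chrom_length: int = 500_000,
) -> dict:
    """Genome-annotation inputs for the clock and PRBS selections.

    Produces a CpG position table (1-based), a gene TSS table, a
    human->mouse homolog map covering all genes, a human PCGT gene list,
    and a BED-convention peak table (0-based half-open).  All structure is
    synthetic but coordinate conventions match the real inputs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 97]))
    chrom = rng.choice(chroms, size=n_cpgs)
    pos = np.sort(rng.integers(1, chrom_length, size=n_cpgs))
    cpg_annotation = pd.DataFrame(
        {"chrom": chrom, "pos": pos}, index=_cpg_index(n_cpgs)
    )
    genes = [f"Gene{i:03d}" for i in range(n_genes)]
    tss_annotation = pd.DataFrame(
        {
            "gene": genes,
            "chrom": rng.choice(chroms, size=n_genes),
            "tss": rng.integers(1, chrom_length, size=n_genes),
        }
    )
    homolog_map = pd.DataFrame(
        {"human_gene": [g.upper() for g in genes], "mouse_gene": genes}
    )
    pcgt = rng.choice(homolog_map["human_gene"], size=n_pcgt, replace=False).tolist()
    starts = rng.integers(0, chrom_length - peak_width[1], size=n_peaks)
    widths = rng.integers(peak_width[0], peak_width[1], size=n_peaks)
    peaks = pd.DataFrame(
        {"chrom": rng.choice(chroms, size=n_peaks), "start": starts, "end": starts + widths}
    ).sort_values(["chrom", "start"], ignore_index=True)
    return {
        "cpg_annotation": cpg_annotation,
        "tss_annotation": tss_annotation,
        "homolog_map": homolog_map,
        "pcgt_genes": pcgt,
        "peaks": peaks,
    }


def simulate_fetal_betas(
    cpg_ids: pd.Index,
    seed: int,
    tissues: tuple[str, ...] = ("fetal_brain", "fetal_intestine", "fetal_limb", "fetal_liver"),
    n_per_tissue: int = 3,
    frac_high: float = 0.3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Fetal-tissue reference betas for the mitotic-clock fetal filter.

    Most CpGs are unmethylated in all fetal tissues (mean beta ~0.03); a
    ``frac_high`` subset is methylated (~0.5) and should be filtered out.
    Returns (beta matrix, sample -> tissue labels).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    n = len(cpg_ids)
    high = rng.random(n) < frac_high
    mu = np.where(high, 0.5, 0.03)
    cols, data, tlab = [], [], []
    for t in tissues:
        for i in range(n_per_tissue):
            cols.append(f"{t}_{i}")
            tlab.append(t)
            data.append(_clip01(mu + rng.normal(0, 0.01, size=n)))
    beta = pd.DataFrame(np.column_stack(data), index=cpg_ids, columns=cols)
    return beta, pd.Series(tlab, index=cols, name="tissue")


def simulate_survival(
    scores: pd.Series | np.ndarray,
    config: ScenarioConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Tumor-latency outcomes driven by a per-animal signature score.

    Latency is exponential with hazard
    ``baseline_hazard * exp(log_hr_per_unit_signature * score)``;
    observation stops at ``followup_days`` (event=0, censored).
    """
    s = pd.Series(scores).astype(float)
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("scores must be finite")
    if config.baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be > 0")
    rng = stage_rng(config.seed if seed is None else seed, "survival")
    hazard = config.baseline_hazard * np.exp(config.log_hr_per_unit_signature * s.to_numpy())
    latency = rng.exponential(1.0 / hazard)
    event = latency < config.followup_days
    time = np.minimum(latency, config.followup_days)
    return pd.DataFrame({"time": time, "event": event.astype(int)}, index=s.index)
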