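"""End-to-end drivers for the two experiments.

``run_discovery`` takes a discovery cohort (betas + sample sheet), applies
the QC cascade where QC inputs are given, and derives the pan-tissue
carcinogen signature with its frozen healthy-mammary scaling.

``run_intervention`` scores an intervention cohort with previously frozen
definitions (carcinogen signature, mitotic clock, PRBS set, optional
cell-composition metric) and runs the tissue x signature grid of
median-split Kaplan-Meier / log-rank / Cox analyses on per-animal
tumor-free survival records.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import deconv, qc, surv
from .refpanel import ReferencePanel
from .signatures import (
    CarcinogenSignature,
    CpGSetScoreDefinition,
    define_carcinogen_signature,
    score_carcinogen,
    score_cpg_set,
)

log = logging.getLogger(__name__)

SIGNATURE_COLUMNS = ("carcinogen", "composition", "mitotic_clock", "prbs")

#: How the composition signature is computed per tissue:
#: metric -> one of luminal_progenitor | epithelial | gl_ratio
DEFAULT_COMPOSITION_METRICS = {
    "mammary_gland": "luminal_progenitor",
    "cervix": "epithelial",
    "oviduct": "epithelial",
    "blood": "gl_ratio",
}


@dataclass
class DiscoveryResult:
    signature: CarcinogenSignature
    qc_report: qc.QcReport
    counts: dict = field(default_factory=dict)


@dataclass
class InterventionResult:
    """Per-sample score table and the tissue x signature survival grid."""

    scores: pd.DataFrame
    grid: dict  # (tissue, signature) -> dict(cox, logrank, km_high, km_low, n)
    summary: pd.DataFrame


def run_discovery(
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    k: int = 1000,
    detection_p: pd.DataFrame | None = None,
    median_meth: pd.Series | None = None,
    median_unmeth: pd.Series | None = None,
    thresholds: qc.QcThresholds = qc.QcThresholds(),
    scaling_tissue: str = "mammary_gland",
) -> DiscoveryResult:
    """QC cascade -> per-tissue rankings -> pan-tissue carcinogen signature.

    Samples flagged in an ``is_tumor`` sample-sheet column are excluded
    before ranking (signatures are built from normal surrogate tissue).
    """
    if "exposure" not in samples.columns or "tissue" not in samples.columns:
        raise ValueError("sample sheet must provide 'tissue' and 'exposure' columns")
    counts = {"input_samples": beta.shape[1], "input_cpgs": beta.shape[0]}
    report = qc.QcReport()

    if "is_tumor" in samples.columns:
        tumors = samples.index[samples["is_tumor"].astype(bool)]
        beta = beta.drop(columns=[c for c in tumors if c in beta.columns])
        counts["tumor_samples_excluded"] = int(len(tumors))

    if median_meth is not None and median_unmeth is not None:
        retained, frag = qc.filter_low_intensity_samples(
            median_meth.loc[beta.columns], median_unmeth.loc[beta.columns], thresholds
        )
        report.removed_samples.update(frag.removed_samples)
        beta = beta[retained]
        if detection_p is not None:
            detection_p = detection_p[retained]
    if detection_p is not None:
        beta, frag = qc.apply_failure_cascade(beta, detection_p.loc[beta.index], thresholds)
        report.removed_samples.update(frag.removed_samples)
        report.removed_probes = frag.removed_probes
        report.failure_mask = frag.failure_mask
        # ranking needs complete rows; drop probes still carrying failures
        beta = beta.dropna(axis=0)
    counts["qc_removed_samples"] = len(report.removed_samples)
    counts["qc_removed_probes"] = len(report.removed_probes)
    counts["retained_samples"] = beta.shape[1]
    counts["retained_cpgs"] = beta.shape[0]
    log.info("discovery QC: %s", counts)

    sig = define_carcinogen_signature(
        beta, samples.loc[beta.columns], k=k, scaling_tissue=scaling_tissue
    )
    return DiscoveryResult(signature=sig, qc_report=report, counts=counts)


def _composition_scores(
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    metrics: dict[str, str],
    primary_panel: ReferencePanel | None,
    immune_panel: ReferencePanel | None,
    epithelial_panel: ReferencePanel | None,
) -> pd.Series:
    out = pd.Series(np.nan, index=beta.columns, name="composition")
    if primary_panel is None:
        return out
    for tissue, metric in metrics.items():
        cols = samples.index[samples["tissue"] == tissue].intersection(beta.columns)
        if cols.empty:
            continue
        bulk = beta[cols]
        try:
            if metric == "luminal_progenitor" and epithelial_panel is not None:
                est = deconv.hierarchical_deconvolve(
                    bulk, primary_panel, epithelial_panel, parent_type="epithelial"
                )
                out.loc[cols] = est.fractions["luminal_progenitor"]
            elif metric == "epithelial":
                est = deconv.deconvolve(bulk, primary_panel)
                out.loc[cols] = est.fractions["epithelial"]
            elif metric == "gl_ratio" and immune_panel is not None:
                est = deconv.hierarchical_deconvolve(
                    bulk, primary_panel, immune_panel, parent_type="immune"
                )
                sub = est.fractions[immune_panel.cell_types]
                out.loc[cols] = deconv.granulocyte_lymphocyte_ratio(sub)
        except ValueError as err:
            warnings.warn(f"composition for tissue {tissue!r} skipped: {err}")
    return out


def run_intervention(
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    survival_records: pd.DataFrame,
    signature: CarcinogenSignature,
    clock_def: CpGSetScoreDefinition,
    prbs_def: CpGSetScoreDefinition,
    primary_panel: ReferencePanel | None = None,
    immune_panel: ReferencePanel | None = None,
    epithelial_panel: ReferencePanel | None = None,
    composition: pd.Series | None = None,
    composition_metrics: dict[str, str] = DEFAULT_COMPOSITION_METRICS,
    min_subjects: int = 4,
) -> InterventionResult:
    """Score every intervention sample and fit the survival grid.

    ``survival_records`` (time, event) is indexed by animal id; the sample
    sheet's ``animal_id`` column links tissue samples to animals.  For each
    tissue with at least ``min_subjects`` animals and each of the four
    signatures, animals are median-split and compared by Kaplan-Meier,
    log-rank, and a single-covariate Cox model (high=1 vs low=0).
    ``composition`` may be supplied precomputed; otherwise it is derived by
    deconvolution when panels are given, and left missing when not.
    """
    samples = samples.loc[beta.columns]
    scores = samples[["animal_id", "tissue", "exposure", "intervention"]].copy()
    scores["carcinogen"] = score_carcinogen(beta, signature, scaled=True)
    scores["mitotic_clock"] = score_cpg_set(beta, clock_def)
    scores["prbs"] = score_cpg_set(beta, prbs_def)
    if composition is not None:
        scores["composition"] = composition.reindex(beta.columns)
    else:
        scores["composition"] = _composition_scores(
            beta, samples, composition_metrics, primary_panel, immune_panel, epithelial_panel
        )

    grid: dict = {}
    rows = []
    for tissue in sorted(samples["tissue"].unique()):
        sub = scores[scores["tissue"] == tissue].set_index("animal_id")
        sub = sub.loc[sub.index.intersection(survival_records.index)]
        if len(sub) < min_subjects:
            warnings.warn(f"tissue {tissue!r} has {len(sub)} subjects (<{min_subjects}); skipped")
            continue
        rec = survival_records.loc[sub.index]
        for sig_name in SIGNATURE_COLUMNS:
            vals = sub[sig_name].replace([np.inf, -np.inf], np.nan).dropna()
            if len(vals) < min_subjects or vals.nunique() < 2:
                warnings.warn(f"signature {sig_name!r} in tissue {tissue!r} not usable; skipped")
                continue
            strata = surv.median_split(vals)
            high = (strata == "high").astype(float)
            r = rec.loc[vals.index]
            fit = surv.cox_single(r, high)
            stat, lr_p = surv.logrank_test(r, strata)
            km = {
                lev: surv.km_estimate(r[(strata == lev).to_numpy()]) for lev in ("high", "low")
            }
            grid[(tissue, sig_name)] = {
                "cox": fit,
                "logrank": (stat, lr_p),
                "km_high": km["high"],
                "km_low": km["low"],
                "n": len(vals),
            }
            rows.append(
                {
                    "tissue": tissue,
                    "signature": sig_name,
                    "n": len(vals),
                    "n_events": fit.n_events,
                    "hr_high_vs_low": fit.hazard_ratio,
                    "ci_low": fit.ci_low,
                    "ci_high": fit.ci_high,
                    "cox_p": fit.p,
                    "logrank_p": lr_p,
                }
            )
    summary = pd.DataFrame(
        rows,
        columns=[
            "tissue",
            "signature",
            "n",
            "n_events",
            "hr_high_vs_low",
            "ci_low",
            "ci_high",
            "cox_p",
            "logrank_p",
        ],
    )
    return InterventionResult(scores=scores, grid=grid, summary=summary)
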