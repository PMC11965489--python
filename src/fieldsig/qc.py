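"""Sample/probe quality control and the PCA covariate-association check.

The cascade mirrors standard methylation-array QC: samples whose median
methylated or unmethylated log2 intensity falls below a cutoff are dropped;
probes with a detection p-value above threshold are marked failed; samples
with too many failed probes are removed; finally probes failing in too
large a fraction of the retained samples are removed.  All comparisons are
strict, so values exactly at a threshold are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA


@dataclass(frozen=True)
class QcThresholds:
    """Cutoffs of the QC cascade and PCA check.

    ``min_median_log_intensity`` is on the log2 intensity scale, the
    customary scale at which 9.5 is a meaningful array cutoff.
    """

    min_median_log_intensity: float = 9.5
    detection_p_max: float = 0.01
    max_sample_failed_fraction: float = 0.10
    max_probe_failed_fraction: float = 0.10
    n_variable_probes: int = 1000
    n_pcs: int = 10

    def __post_init__(self) -> None:
        for name in ("max_sample_failed_fraction", "max_probe_failed_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.n_variable_probes <= 0 or self.n_pcs <= 0:
            raise ValueError("counts must be positive")


@dataclass
class QcReport:
    """What the cascade removed and why, plus the PC association table."""

    removed_samples: dict[str, str] = field(default_factory=dict)
    removed_probes: list[str] = field(default_factory=list)
    failure_mask: pd.DataFrame | None = None
    pc_association_table: pd.DataFrame | None = None


def filter_low_intensity_samples(
    median_meth: pd.Series,
    median_unmeth: pd.Series,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[list[str], QcReport]:
    """Drop samples whose median log2 intensity is below cutoff in either channel."""
    if median_meth.isna().any() or median_unmeth.isna().any():
        raise ValueError("median intensities must be present for every sample")
    if not median_meth.index.equals(median_unmeth.index):
        raise ValueError("intensity series must share the sample index")
    cut = thresholds.min_median_log_intensity
    report = QcReport()
    retained = []
    for sid in median_meth.index:
        m, u = median_meth[sid], median_unmeth[sid]
        if m < cut or u < cut:
            report.removed_samples[sid] = (
                f"median intensity below {cut} (meth={m:g}, unmeth={u:g})"
            )
        else:
            retained.append(sid)
    return retained, report


def apply_failure_cascade(
    beta: pd.DataFrame,
    detection_p: pd.DataFrame,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[pd.DataFrame, QcReport]:
    """Detection-p failure cascade: mark probes failed, drop samples, drop probes.

    A probe measurement with detection p > ``detection_p_max`` (or a missing
    beta) counts as failed and its beta is set missing.  Samples with a
    failed fraction > ``max_sample_failed_fraction`` are removed first;
    probe failure fractions are then recomputed over the retained samples
    and probes above ``max_probe_failed_fraction`` removed.
    """
    if not (beta.index.equals(detection_p.index) and beta.columns.equals(detection_p.columns)):
        raise ValueError("beta and detection_p dimensions must match")
    failed = (detection_p > thresholds.detection_p_max) | beta.isna()
    report = QcReport(failure_mask=failed)
    masked = beta.mask(failed)

    sample_frac = failed.mean(axis=0)
    bad_samples = sample_frac[sample_frac > thresholds.max_sample_failed_fraction].index
    for sid in bad_samples:
        report.removed_samples[sid] = (
            f"failed-probe fraction {sample_frac[sid]:.3f} > {thresholds.max_sample_failed_fraction}"
        )
    keep_samples = [c for c in beta.columns if c not in set(bad_samples)]

    probe_frac = failed[keep_samples].mean(axis=1)
    bad_probes = probe_frac[probe_frac > thresholds.max_probe_failed_fraction].index
    report.removed_probes = list(bad_probes)
    keep_probes = beta.index.difference(bad_probes, sort=False)
    return masked.loc[keep_probes, keep_samples], report


def most_variable_probes(beta: pd.DataFrame, n: int) -> pd.Index:
    """Top-n probes by sample standard deviation (ddof=1); ties by CpG id."""
    sd = beta.std(axis=1, ddof=1)
    order = sd.to_frame("sd").reset_index()
    idc = order.columns[0]
    order = order.sort_values(["sd", idc], ascending=[False, True], kind="mergesort")
    if n > len(order):
        warnings.warn(f"requested {n} variable probes but only {len(order)} available; using all")
        n = len(order)
    return pd.Index(order[idc].head(n))


def pc_covariate_check(
    beta: pd.DataFrame,
    covariates: pd.DataFrame,
    thresholds: QcThresholds = QcThresholds(),
) -> pd.DataFrame:
    """Test top principal components against technical covariates.

    PCA is run over samples on the ``n_variable_probes`` most variable
    probes (complete cases only).  Numeric covariates are tested with the
    two-sided test of zero Pearson correlation, categorical ones with
    Kruskal-Wallis.  Returns rows (covariate, pc, test, p).  Constant
    covariates are skipped with a warning.  No multiplicity correction is
    applied; the table is for inspection.
    """
    if beta.shape[1] < 2:
        raise ValueError("need >= 2 samples for PCA")
    complete = beta.dropna(axis=0)
    sel = most_variable_probes(complete, thresholds.n_variable_probes)
    x = complete.loc[sel].T.to_numpy()  # samples x probes
    n_pcs = min(thresholds.n_pcs, x.shape[0] - 1, x.shape[1])
    pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(x)

    rows = []
    for cov in covariates.columns:
        v = covariates.loc[beta.columns, cov]
        if v.nunique(dropna=True) < 2:
            warnings.warn(f"covariate {cov!r} is constant; skipped")
            continue
        numeric = pd.api.types.is_numeric_dtype(v)
        for j in range(n_pcs):
            pc = pcs[:, j]
            if numeric:
                ok = v.notna().to_numpy()
                _, p = stats.pearsonr(v.to_numpy()[ok].astype(float), pc[ok])
                test = "pearson"
            else:
                groups = [pc[(v == lev).to_numpy()] for lev in v.dropna().unique()]
                groups = [g for g in groups if len(g) > 0]
                _, p = stats.kruskal(*groups)
                test = "kruskal-wallis"
            rows.append({"covariate": cov, "pc": j + 1, "test": test, "p": p})
    return pd.DataFrame(rows, columns=["covariate", "pc", "test", "p"])
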