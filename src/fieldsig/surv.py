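"""Tumor-free survival: Kaplan-Meier, log-rank, and single-covariate Cox.

Records carry the days from pellet implantation to the first caliper
measurement of a tumor (event=1) or to sacrifice without a measured tumor
(event=0, censored).  Cox fits use the Efron approximation for tied event
times, appropriate for small rodent cohorts.  Median splits assign ties
(and the median itself) to the low stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import logrank_test as _ll_logrank


@dataclass(frozen=True)
class KmCurve:
    """Product-limit survival step function with at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


@dataclass(frozen=True)
class CoxFit:
    """Single-covariate proportional-hazards fit (Wald inference)."""

    coef: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float
    n_events: int
    converged: bool = True

    def __post_init__(self) -> None:
        if not np.isclose(self.hazard_ratio, np.exp(self.coef), rtol=1e-8):
            raise ValueError("hazard_ratio must equal exp(coef)")


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise ValueError("need at least one record")
    if (records["time"] < 0).any():
        raise ValueError("times must be non-negative")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event must be 0/1")
    return records


def km_estimate(records: pd.DataFrame) -> KmCurve:
    """Kaplan-Meier estimate from columns ``time`` and ``event``.

    Censored times reduce the risk set without producing a step.
    """
    records = _check_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    tl = kmf.event_table
    return KmCurve(
        times=tl.index.to_numpy(dtype=float),
        survival=kmf.survival_function_["KM_estimate"].to_numpy(),
        at_risk=tl["at_risk"].to_numpy(),
    )


def median_split(scores: pd.Series) -> pd.Series:
    """Label scores 'high' (> median) or 'low' (<= median, ties to low)."""
    s = scores.dropna()
    if len(s) < 2:
        raise ValueError("need >= 2 subjects to split")
    if s.nunique() == 1:
        raise ValueError("all scores identical; no median split possible")
    med = s.median()
    return pd.Series(np.where(s > med, "high", "low"), index=s.index, name="stratum")


def cox_single(records: pd.DataFrame, covariate: pd.Series) -> CoxFit:
    """Cox proportional-hazards fit with one (binary or continuous) covariate.

    Partial likelihood is maximized by Newton iteration with the Efron tie
    correction; the CI is the Wald interval exp(coef +- 1.96*SE).  Complete
    separation (monotone likelihood) is flagged via ``converged=False``
    with the coefficient reported at the iteration cap.
    """
    records = _check_records(records)
    if records["event"].sum() < 1:
        raise ValueError("need at least one event")
    cov = covariate.loc[records.index]
    if pd.Series(cov).nunique() < 2:
        raise ValueError("covariate is constant")
    x = pd.to_numeric(pd.Series(cov), errors="coerce")
    if x.isna().any():  # binary labels such as high/low
        levels = sorted(pd.Series(cov).unique())
        if len(levels) != 2:
            raise ValueError("non-numeric covariate must be binary")
        x = pd.Series(cov).map({levels[0]: 0.0, levels[1]: 1.0})
    df = pd.DataFrame({"time": records["time"], "event": records["event"], "x": x})
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceError:
            # monotone likelihood (complete separation): report a weakly
            # penalized fit, flagged as non-converged
            converged = False
            cph = CoxPHFitter(penalizer=0.01)
            cph.fit(df, duration_col="time", event_col="event")
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    s = cph.summary.loc["x"]
    return CoxFit(
        coef=float(s["coef"]),
        hazard_ratio=float(np.exp(s["coef"])),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
        p=float(s["p"]),
        n_events=int(records["event"].sum()),
        converged=converged,
    )


def logrank_test(records: pd.DataFrame, groups: pd.Series) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    records = _check_records(records)
    g = groups.loc[records.index]
    levels = g.unique()
    if len(levels) != 2:
        raise ValueError("log-rank test requires exactly 2 groups")
    if records["event"].sum() == 0:
        return 0.0, 1.0
    a = records[g == levels[0]]
    b = records[g == levels[1]]
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)
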