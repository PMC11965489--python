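"""Cell-type reference panels from heterogeneous array/WGBS/RRBS sources.

Array betas are bimodal with modes strictly inside (0, 1) because of
background intensity; sequencing betas (read fractions) have modes at
exactly 0 and 1.  Harmonization estimates both pairs of modes and applies
the unique linear map taking the sequencing modes onto the array modes
(for array modes 0.017/0.955 this is beta_adjusted = 0.938*beta + 0.017).

Markers are ranked per cell type by combining the |mean-beta difference|
ranking and the Wilcoxon rank-sum p-value ranking through their geometric
mean; the union of per-type top lists forms the reference panel of mean
betas used for deconvolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats


@dataclass(frozen=True)
class LinearTransform:
    """beta -> slope*beta + intercept, mapping [0,1] into [0,1]."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        lo, hi = self.intercept, self.slope + self.intercept
        if not (-1e-12 <= lo and hi <= 1 + 1e-12):
            raise ValueError("transform must map [0,1] into [0,1]")

    def __call__(self, beta):
        return self.slope * beta + self.intercept


@dataclass
class ReferencePanel:
    """Marker-CpG x cell-type matrix of mean betas.

    ``level`` distinguishes the primary panel from subtype panels used in
    hierarchical deconvolution.  ``markers`` records which CpGs were
    selected for which type (provenance; rows are their union).
    """

    betas: pd.DataFrame
    level: str = "primary"
    n_top_per_type: int | None = None
    markers: dict[str, list[str]] | None = None

    @property
    def cell_types(self) -> list[str]:
        return list(self.betas.columns)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.betas.to_csv(path, sep="\t")
        side = {"level": self.level, "n_top_per_type": self.n_top_per_type, "markers": self.markers}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(side, indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "ReferencePanel":
        path = Path(path)
        betas = pd.read_csv(path, sep="\t", index_col=0)
        side_path = path.with_suffix(path.suffix + ".json")
        side = json.loads(side_path.read_text()) if side_path.exists() else {}
        return cls(
            betas,
            level=side.get("level", "primary"),
            n_top_per_type=side.get("n_top_per_type"),
            markers=side.get("markers"),
        )


def estimate_beta_modes(values, grid_size: int = 2001) -> tuple[float, float]:
    """Locate the two modes of a bimodal beta distribution by KDE.

    Returns (lower mode in [0, 0.5), upper mode in [0.5, 1]).  Raises if
    the kernel density has no local maximum on one side (unimodal input).
    Grid endpoints count as modes when the density falls away from them,
    which is how exact-0/1 sequencing modes are found.
    """
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if v.size < 100:
        raise ValueError("need >= 100 values to estimate modes")
    kde = stats.gaussian_kde(v)
    grid = np.linspace(0.0, 1.0, grid_size)
    dens = kde(grid)
    floor = dens.max() * 1e-3  # ignore numerically-flat tails
    idx = list(signal.find_peaks(dens, height=floor)[0])
    if dens[0] >= dens[1] and dens[0] > floor:
        idx.append(0)
    if dens[-1] >= dens[-2] and dens[-1] > floor:
        idx.append(grid_size - 1)
    idx = np.array(sorted(idx), dtype=int)
    peaks = grid[idx]
    peak_dens = dens[idx]
    lower = peaks[peaks < 0.5]
    upper = peaks[peaks >= 0.5]
    if lower.size == 0 or upper.size == 0:
        raise ValueError("distribution is not bimodal: no mode on one side of 0.5")
    lo = lower[np.argmax(peak_dens[peaks < 0.5])]
    hi = upper[np.argmax(peak_dens[peaks >= 0.5])]
    return float(lo), float(hi)


def derive_mode_matching_transform(
    source_modes: tuple[float, float], target_modes: tuple[float, float]
) -> LinearTransform:
    """Unique linear map sending the source mode pair onto the target pair.

    With sequencing modes (0, 1) and array modes (0.017, 0.955) the result
    is slope 0.938, intercept 0.017.
    """
    s_lo, s_hi = source_modes
    t_lo, t_hi = target_modes
    if s_lo == s_hi:
        raise ValueError("source modes coincide; transform undefined")
    if not t_lo < t_hi:
        raise ValueError("target modes must be ordered")
    slope = (t_hi - t_lo) / (s_hi - s_lo)
    return LinearTransform(slope=slope, intercept=t_lo - slope * s_lo)


def harmonize_sequencing_betas(beta: pd.DataFrame, transform: LinearTransform) -> pd.DataFrame:
    """Apply the mode-matching transform elementwise, clamped to [0, 1].

    Missing entries stay missing.  Clamping is a no-op for any transform
    mapping [0,1] into itself; it guards user-supplied lines.
    """
    return (transform.slope * beta + transform.intercept).clip(0.0, 1.0)


def filter_cross_platform_cpgs(
    datasets: dict[str, tuple[pd.DataFrame, str]],
    max_missing_fraction: float = 0.10,
) -> pd.Index:
    """CpGs usable across all platforms.

    ``datasets`` maps name -> (beta matrix, platform tag).  Keeps CpGs that
    are on the array universe (union of array datasets), observed in every
    RRBS dataset, and missing in <= ``max_missing_fraction`` of all samples
    pooled (strict ">" excludes).
    """
    array_sets = [b for b, p in datasets.values() if p == "array"]
    if not array_sets:
        raise ValueError("at least one array dataset must define the CpG universe")
    universe = array_sets[0].index
    for b in array_sets[1:]:
        universe = universe.union(b.index)

    keep = pd.Series(True, index=universe)
    for beta, platform in datasets.values():
        if platform == "RRBS":
            observed = beta.notna().any(axis=1)
            present = observed[observed].index
            keep &= universe.isin(present)

    n_total = sum(b.shape[1] for b, _ in datasets.values())
    n_missing = pd.Series(0.0, index=universe)
    for beta, _ in datasets.values():
        miss = beta.reindex(universe).isna().sum(axis=1)
        n_missing += miss
    keep &= (n_missing / n_total) <= max_missing_fraction

    retained = universe[keep.to_numpy()]
    if retained.empty:
        raise ValueError("no CpGs survive cross-platform filtering")
    return retained


def wilcoxon_rank_sum(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when min(n) <= 8 and there are no ties; otherwise the
    normal approximation with tie and continuity correction.
    """
    a = np.asarray(pd.Series(group_a).dropna(), dtype=float)
    b = np.asarray(pd.Series(group_b).dropna(), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must contain values")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def _group_delta_p(
    betas: pd.DataFrame, labels: pd.Series, target: str
) -> tuple[pd.Series, pd.Series]:
    """Per-CpG mean difference (target - rest) and Wilcoxon p, complete-case."""
    labels = labels.loc[betas.columns]
    in_t = (labels == target).to_numpy()
    if in_t.sum() < 2 or (~in_t).sum() < 2:
        raise ValueError(f"need >= 2 samples inside and outside cell type {target!r}")
    x = betas.to_numpy()
    at, ar = x[:, in_t], x[:, ~in_t]
    delta = pd.Series(np.nanmean(at, axis=1) - np.nanmean(ar, axis=1), index=betas.index)

    # vectorize: exact rows (no ties, small n, no missing) in one call, rest asymptotic
    nt, nr = at.shape[1], ar.shape[1]
    finite = np.isfinite(at).all(axis=1) & np.isfinite(ar.astype(float)).all(axis=1)
    pooled = np.concatenate([at, ar], axis=1)
    tie_free = np.array(
        [np.unique(row[np.isfinite(row)]).size == np.isfinite(row).sum() for row in pooled]
    )
    exact_rows = finite & tie_free & (min(nt, nr) <= 8)
    p = np.empty(betas.shape[0])
    if exact_rows.any():
        p[exact_rows] = stats.mannwhitneyu(
            at[exact_rows], ar[exact_rows], alternative="two-sided", method="exact", axis=1
        ).pvalue
    rest = ~exact_rows
    for i in np.flatnonzero(rest):
        ra = at[i][np.isfinite(at[i])]
        rb = ar[i][np.isfinite(ar[i])]
        p[i] = wilcoxon_rank_sum(ra, rb)
    return delta, pd.Series(p, index=betas.index)


def rank_markers(
    betas: pd.DataFrame,
    labels: pd.Series,
    target: str,
    n_top: int,
) -> tuple[pd.DataFrame, list[str]]:
    """Rank CpGs as markers of ``target`` and select the top ``n_top``.

    Ranks by |delta| (descending) and by p (ascending) are combined via
    their geometric mean (1-based average ranks for ties).  Selection takes
    the lowest combined ranks, ties broken by larger |delta| then CpG id.
    Returns (ranking table, selected CpG ids).
    """
    if n_top > betas.shape[0]:
        raise ValueError("n_top exceeds available CpGs")
    delta, p = _group_delta_p(betas, labels, target)
    rank_delta = (-delta.abs()).rank(method="average")
    rank_p = p.rank(method="average")
    combined = np.sqrt(rank_delta * rank_p)
    table = pd.DataFrame(
        {
            "delta": delta,
            "p": p,
            "rank_delta": rank_delta,
            "rank_p": rank_p,
            "combined_rank": combined,
        }
    )
    order = table.assign(_absd=table.delta.abs(), _id=table.index).sort_values(
        ["combined_rank", "_absd", "_id"], ascending=[True, False, True], kind="mergesort"
    )
    return table, list(order.index[:n_top])


def build_panel(
    betas: pd.DataFrame,
    labels: pd.Series,
    types: list[str],
    n_top_per_type: int = 100,
    level: str = "primary",
) -> ReferencePanel:
    """Union of per-type marker selections with per-type mean betas.

    Duplicate markers across types are collapsed, so the panel has at most
    ``len(types) * n_top_per_type`` rows.  Group means are complete-case
    per CpG.
    """
    labels = labels.loc[betas.columns]
    markers: dict[str, list[str]] = {}
    for t in types:
        if (labels == t).sum() == 0:
            raise ValueError(f"cell type {t!r} has no samples")
        _, sel = rank_markers(betas, labels, t, n_top_per_type)
        markers[t] = sel
    union = pd.Index(sorted(set().union(*markers.values())))
    means = {
        t: betas.loc[union, (labels == t).to_numpy()].mean(axis=1, skipna=True) for t in types
    }
    return ReferencePanel(
        betas=pd.DataFrame(means, index=union),
        level=level,
        n_top_per_type=n_top_per_type,
        markers=markers,
    )
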