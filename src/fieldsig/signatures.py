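"""Carcinogen signature, mitotic clock, and PRBS methylation score.

The carcinogen signature ranks CpGs per tissue by the exposed-minus-
unexposed difference in mean beta, combines tissue rankings through a
geometric mean into one pan-tissue ranking, and takes the top-k hyper- and
hypo-methylated CpG sets.  The raw score of a sample is
mean(beta, hyper set) - mean(beta, hypo set); it is linearly scaled to
zero mean and unit SD in healthy mammary-gland discovery samples, and that
scale is frozen for any later cohort.

The mitotic clock is the mean beta over CpGs near polycomb-group-target
gene promoters that are unmethylated in fetal tissues (methylation there
accumulates with cell divisions).  The PRBS score is the mean beta over
CpGs inside progesterone-receptor ChIP-seq binding peaks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from scipy.stats import gmean

log = logging.getLogger(__name__)

DEFAULT_K = 1000
DEFAULT_COVERAGE_FLOOR = 0.8
DEFAULT_TSS_WINDOW = 200
DEFAULT_MAX_FETAL_MEAN = 0.10


@dataclass(frozen=True)
class TissueRanking:
    """Signed per-CpG exposure effect and its two rank orders in one tissue."""

    tissue: str
    difference: pd.Series  # mean beta (exposed) - mean beta (unexposed)
    hyper_rank: pd.Series  # 1 = most hyper-methylated on exposure
    hypo_rank: pd.Series  # 1 = most hypo-methylated on exposure


@dataclass
class CarcinogenSignature:
    """Top-k hyper/hypo CpG sets plus the frozen scaling parameters."""

    hyper_cpgs: list[str]
    hypo_cpgs: list[str]
    scale_location: float
    scale_spread: float
    k: int = DEFAULT_K

    def __post_init__(self) -> None:
        if set(self.hyper_cpgs) & set(self.hypo_cpgs):
            raise ValueError("hyper and hypo sets must be disjoint")
        if self.scale_spread <= 0:
            raise ValueError("scale_spread must be > 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "hyper_cpgs": self.hyper_cpgs,
                    "hypo_cpgs": self.hypo_cpgs,
                    "scale_location": self.scale_location,
                    "scale_spread": self.scale_spread,
                    "k": self.k,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CarcinogenSignature":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class CpGSetScoreDefinition:
    """A flat CpG set whose mean beta is the score (clock or PRBS)."""

    cpg_ids: tuple[str, ...]
    label: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.cpg_ids) == 0:
            raise ValueError("CpG set must be non-empty")
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ValueError("CpG ids must be unique")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"cpg_ids": list(self.cpg_ids), "label": self.label, "provenance": self.provenance}
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CpGSetScoreDefinition":
        d = json.loads(Path(path).read_text())
        return cls(cpg_ids=tuple(d["cpg_ids"]), label=d["label"], provenance=d.get("provenance", {}))


def rank_tissue_cpgs(betas: pd.DataFrame, exposed: pd.Series, tissue: str = "") -> TissueRanking:
    """Rank CpGs of one tissue by the exposed-unexposed mean-beta difference.

    ``exposed`` is a boolean per-sample series over the beta columns.
    Average ranks for ties.  Tumor samples must not be included (caller
    contract: signatures are derived from normal surrogate tissue only).
    """
    exposed = exposed.loc[betas.columns].astype(bool)
    if exposed.sum() < 2 or (~exposed).sum() < 2:
        raise ValueError(f"need >= 2 samples per exposure group in tissue {tissue or '?'}")
    diff = betas.loc[:, exposed.to_numpy()].mean(axis=1) - betas.loc[:, (~exposed).to_numpy()].mean(axis=1)
    return TissueRanking(
        tissue=tissue,
        difference=diff,
        hyper_rank=(-diff).rank(method="average"),
        hypo_rank=diff.rank(method="average"),
    )


def combine_rankings_geometric(rankings: list[pd.Series]) -> pd.DataFrame:
    """Combine per-tissue rank vectors into a pan-tissue ranking.

    Returns a frame with the per-CpG geometric mean of tissue ranks
    (``geo_mean``) and its ascending re-ranking (``rank``, average ties;
    rank 1 = most consistently extreme).
    """
    universe = rankings[0].index
    for r in rankings[1:]:
        if not r.index.equals(universe):
            if set(r.index) != set(universe):
                raise ValueError("rank vectors must share one CpG universe")
            r = r.loc[universe]
    stacked = np.column_stack([r.loc[universe].to_numpy() for r in rankings])
    gm = pd.Series(gmean(stacked, axis=1), index=universe, name="geo_mean")
    return pd.DataFrame({"geo_mean": gm, "rank": gm.rank(method="average")})


def _top_k(combined: pd.DataFrame, k: int, exclude: set[str]) -> list[str]:
    df = combined.drop(index=list(exclude), errors="ignore")
    # deterministic tie-break inside equal geo_mean by CpG id
    order = df.assign(_id=df.index).sort_values(["geo_mean", "_id"], kind="mergesort")
    return list(order.index[:k])


def define_carcinogen_signature(
    betas: pd.DataFrame,
    samples: pd.DataFrame,
    k: int = DEFAULT_K,
    exposure_col: str = "exposure",
    exposed_value: str = "P/D+",
    tissue_col: str = "tissue",
    scaling_tissue: str = "mammary_gland",
) -> CarcinogenSignature:
    """Derive the pan-tissue carcinogen signature from a discovery cohort.

    Per tissue, CpGs are ranked by the exposure difference; hyper and hypo
    rankings are combined across tissues by geometric mean, and the top-k
    of each become the signature sets.  If the two sets overlap, the
    overlapping CpGs are removed from both and each set refilled from the
    next ranks until disjoint (logged).  Scaling uses mean and sample SD of
    raw scores over unexposed ``scaling_tissue`` samples.
    """
    if betas.shape[0] < 2 * k:
        raise ValueError(f"need >= {2 * k} CpGs to take two disjoint top-{k} sets")
    samples = samples.loc[betas.columns]
    tissues = sorted(samples[tissue_col].unique())
    hyper_ranks, hypo_ranks = [], []
    for t in tissues:
        cols = samples.index[samples[tissue_col] == t]
        exposed = samples.loc[cols, exposure_col] == exposed_value
        r = rank_tissue_cpgs(betas[cols], exposed, tissue=t)
        hyper_ranks.append(r.hyper_rank)
        hypo_ranks.append(r.hypo_rank)
    hyper_comb = combine_rankings_geometric(hyper_ranks)
    hypo_comb = combine_rankings_geometric(hypo_ranks)

    banned: set[str] = set()
    while True:
        hyper = _top_k(hyper_comb, k, banned)
        hypo = _top_k(hypo_comb, k, banned)
        overlap = set(hyper) & set(hypo)
        if not overlap:
            break
        log.info("hyper/hypo overlap of %d CpGs removed from both sets and refilled", len(overlap))
        banned |= overlap

    healthy = samples.index[
        (samples[tissue_col] == scaling_tissue) & (samples[exposure_col] != exposed_value)
    ]
    if len(healthy) < 2:
        raise ValueError(f"need >= 2 unexposed {scaling_tissue!r} samples for scaling")
    sig = CarcinogenSignature(hyper, hypo, scale_location=0.0, scale_spread=1.0, k=k)
    raw = score_carcinogen(betas[healthy], sig, scaled=False)
    return CarcinogenSignature(
        hyper, hypo, scale_location=float(raw.mean()), scale_spread=float(raw.std(ddof=1)), k=k
    )


def _mean_over_set(betas: pd.DataFrame, cpgs: list[str], floor: float, what: str) -> pd.Series:
    present = betas.index.intersection(pd.Index(cpgs))
    sub = betas.loc[present]
    covered = sub.notna().sum(axis=0) / len(cpgs)
    low = covered[covered < floor]
    if len(present) / len(cpgs) < floor or not low.empty:
        worst = low.index[0] if not low.empty else "(all)"
        raise ValueError(
            f"{what}: coverage below the {floor:.0%} floor (e.g. sample {worst!r}; "
            f"{len(present)}/{len(cpgs)} CpGs present)"
        )
    return sub.mean(axis=0, skipna=True)


def score_carcinogen(
    betas: pd.DataFrame,
    signature: CarcinogenSignature,
    scaled: bool = True,
    coverage_floor: float = DEFAULT_COVERAGE_FLOOR,
) -> pd.Series:
    """Per-sample carcinogen score: mean(hyper betas) - mean(hypo betas).

    With ``scaled`` the frozen discovery scaling is applied
    ((raw - location) / spread); raw scores are on the beta scale.
    """
    raw = _mean_over_set(betas, signature.hyper_cpgs, coverage_floor, "hyper set") - _mean_over_set(
        betas, signature.hypo_cpgs, coverage_floor, "hypo set"
    )
    raw.name = "carcinogen_score"
    if not scaled:
        return raw
    return (raw - signature.scale_location) / signature.scale_spread


def score_cpg_set(
    betas: pd.DataFrame,
    definition: CpGSetScoreDefinition,
    coverage_floor: float = DEFAULT_COVERAGE_FLOOR,
) -> pd.Series:
    """Mean beta over the definition's CpGs (clock or PRBS score)."""
    s = _mean_over_set(betas, list(definition.cpg_ids), coverage_floor, definition.label)
    n_missing = len(definition.cpg_ids) - len(betas.index.intersection(pd.Index(definition.cpg_ids)))
    if n_missing:
        log.info("%s: %d of %d CpGs absent from the matrix", definition.label, n_missing, len(definition.cpg_ids))
    s.name = definition.label
    return s


def select_mitotic_clock_cpgs(
    pcgt_genes: list[str],
    homolog_map: pd.DataFrame,
    tss_annotation: pd.DataFrame,
    cpg_annotation: pd.DataFrame,
    fetal_betas: pd.DataFrame,
    fetal_tissues: pd.Series,
    window: int = DEFAULT_TSS_WINDOW,
    max_fetal_mean: float = DEFAULT_MAX_FETAL_MEAN,
) -> CpGSetScoreDefinition:
    """CpGs near polycomb-target TSSs that are unmethylated in fetal tissue.

    Human PCGT genes are mapped to mouse homologs (``homolog_map`` columns
    ``human_gene``/``mouse_gene``); candidate CpGs lie within ``window`` bp
    of a mapped gene's TSS (inclusive both ends, |CpG - TSS| <= window,
    same chromosome); candidates must have mean beta < ``max_fetal_mean``
    in every fetal tissue of ``fetal_tissues`` (sample -> tissue).
    """
    mouse = homolog_map.loc[
        homolog_map["human_gene"].isin(pcgt_genes), "mouse_gene"
    ].unique()
    if mouse.size == 0:
        raise ValueError("homolog map covers none of the PCGT genes")
    tss = tss_annotation[tss_annotation["gene"].isin(mouse)]
    near = set()
    for chrom, sub in tss.groupby("chrom"):
        cp = cpg_annotation[cpg_annotation["chrom"] == chrom]
        pos = cp["pos"].to_numpy()
        hit = np.zeros(len(cp), dtype=bool)
        for t in sub["tss"].to_numpy():
            hit |= np.abs(pos - t) <= window
        near.update(cp.index[hit])
    candidates = [c for c in cpg_annotation.index if c in near and c in fetal_betas.index]

    fetal_tissues = fetal_tissues.loc[fetal_betas.columns]
    keep = []
    for c in candidates:
        means = fetal_betas.loc[c].groupby(fetal_tissues).mean()
        if (means < max_fetal_mean).all():
            keep.append(c)
    if not keep:
        raise ValueError("no CpGs pass the TSS-window and fetal-methylation filters")
    return CpGSetScoreDefinition(
        cpg_ids=tuple(keep),
        label="mitotic_clock",
        provenance={
            "n_pcgt_genes": len(pcgt_genes),
            "n_mouse_genes": int(mouse.size),
            "window_bp": window,
            "max_fetal_mean": max_fetal_mean,
            "n_tss_candidates": len(candidates),
        },
    )


def read_bed3(path: str | Path) -> pd.DataFrame:
    """Parse a BED3+ file (0-based half-open intervals).

    Malformed lines are reported with their 1-based line numbers.
    """
    rows, bad = [], []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        try:
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start < 0 or end < start:
                raise ValueError
        except (IndexError, ValueError):
            bad.append(i)
            continue
        rows.append({"chrom": chrom, "start": start, "end": end})
    if bad:
        raise ValueError(f"malformed BED lines: {bad}")
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def select_prbs_cpgs(
    peaks: pd.DataFrame | str | Path,
    cpg_annotation: pd.DataFrame,
) -> CpGSetScoreDefinition:
    """CpGs falling inside progesterone-receptor binding peaks.

    ``peaks`` is a BED3 frame or path (0-based half-open); CpG positions
    are 1-based, so position p overlaps [start, end) iff start < p <= end.
    """
    if not isinstance(peaks, pd.DataFrame):
        peaks = read_bed3(peaks)
    hit_ids = []
    for chrom, sub in peaks.groupby("chrom"):
        cp = cpg_annotation[cpg_annotation["chrom"] == chrom]
        if cp.empty:
            continue
        pos = cp["pos"].to_numpy()
        hit = np.zeros(len(cp), dtype=bool)
        for start, end in sub[["start", "end"]].to_numpy():
            hit |= (pos > start) & (pos <= end)
        hit_ids.extend(cp.index[hit])
    if not hit_ids:
        raise ValueError("no CpGs overlap the peak set")
    order = [c for c in cpg_annotation.index if c in set(hit_ids)]
    return CpGSetScoreDefinition(
        cpg_ids=tuple(order),
        label="prbs",
        provenance={"n_peaks": int(len(peaks)), "n_overlapping_cpgs": len(order)},
    )
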