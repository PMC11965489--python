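"""Reference-based cell-type deconvolution of bulk methylation profiles.

The bulk beta vector at the panel CpGs is modeled as a non-negative
combination of the cell-type mean methylomes; fractions are estimated by
non-negative least squares and renormalized to the simplex.  A two-level
(hierarchical) mode refines one parent type into subtypes using a second
panel, rescaling subtype fractions to sum to the parent's share.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .refpanel import ReferencePanel

#: Fractions smaller than this after renormalization are snapped to zero.
ZERO_SNAP = 1e-6

DEFAULT_GRANULOCYTES = ("neutrophil", "mdsc")
DEFAULT_LYMPHOCYTES = ("b_cell", "nk", "cd4_t", "cd8_t")


@dataclass
class FractionEstimate:
    """Per-sample cell-type fractions plus fit residuals."""

    fractions: pd.DataFrame  # samples x types, rows on the simplex
    residual_norm: pd.Series
    panel_level: str

    def __post_init__(self) -> None:
        f = self.fractions.to_numpy()
        if (f < 0).any():
            raise ValueError("fractions must be non-negative")


def deconvolve(
    bulk: pd.DataFrame,
    panel: ReferencePanel,
    min_overlap: float = 0.8,
) -> FractionEstimate:
    """Estimate cell-type fractions for each bulk sample (CpG x sample).

    Missing CpGs are dropped per sample; a sample must still cover at least
    ``min_overlap`` of the panel's CpGs.  The non-negative least-squares
    solution is renormalized to sum to 1, with near-zero entries snapped
    to exactly 0.
    """
    a_full = panel.betas
    if np.linalg.matrix_rank(a_full.to_numpy()) < a_full.shape[1]:
        raise ValueError("panel is rank-deficient (collinear cell-type columns)")
    common = bulk.index.intersection(a_full.index)
    if len(common) / len(a_full.index) < min_overlap:
        raise ValueError(
            f"bulk covers {len(common)}/{len(a_full.index)} panel CpGs, "
            f"below the {min_overlap:.0%} floor"
        )
    rows, resids = [], []
    for sid in bulk.columns:
        y = bulk.loc[common, sid]
        ok = y.notna()
        if ok.sum() / len(a_full.index) < min_overlap:
            raise ValueError(
                f"sample {sid!r} covers {int(ok.sum())}/{len(a_full.index)} panel CpGs, "
                f"below the {min_overlap:.0%} floor"
            )
        a = a_full.loc[common[ok.to_numpy()]].to_numpy()
        w, rnorm = nnls(a, y[ok].to_numpy())
        total = w.sum()
        if total <= 0:
            raise ValueError(f"degenerate fit for sample {sid!r}: all fractions zero")
        w = w / total
        w[w < ZERO_SNAP] = 0.0
        w = w / w.sum()
        rows.append(w)
        resids.append(rnorm)
    fractions = pd.DataFrame(rows, index=bulk.columns, columns=a_full.columns)
    return FractionEstimate(
        fractions=fractions,
        residual_norm=pd.Series(resids, index=bulk.columns),
        panel_level=panel.level,
    )


def hierarchical_deconvolve(
    bulk: pd.DataFrame,
    primary_panel: ReferencePanel,
    subtype_panel: ReferencePanel,
    parent_type: str,
    min_overlap: float = 0.8,
) -> FractionEstimate:
    """Refine one primary cell type into its subtypes.

    Flat fractions come from the primary panel; subtype fractions from the
    subtype panel are rescaled to sum to the parent's primary fraction, so
    the expanded vector still sums to 1.  When the parent fraction is 0,
    all its subtypes are 0.
    """
    if parent_type not in primary_panel.betas.columns:
        raise ValueError(f"{parent_type!r} is not a column of the primary panel")
    flat = deconvolve(bulk, primary_panel, min_overlap=min_overlap)
    try:
        sub = deconvolve(bulk, subtype_panel, min_overlap=min_overlap)
    except ValueError as err:
        raise ValueError(f"subtype fit failed for panel {subtype_panel.level!r}: {err}") from err
    others = [t for t in flat.fractions.columns if t != parent_type]
    parent = flat.fractions[parent_type]
    scaled_sub = sub.fractions.mul(parent, axis=0)
    out = pd.concat([flat.fractions[others], scaled_sub], axis=1)
    return FractionEstimate(
        fractions=out,
        residual_norm=flat.residual_norm,
        panel_level=f"{primary_panel.level}+{subtype_panel.level}",
    )


def granulocyte_lymphocyte_ratio(
    fractions: pd.DataFrame,
    granulocytes: tuple[str, ...] = DEFAULT_GRANULOCYTES,
    lymphocytes: tuple[str, ...] = DEFAULT_LYMPHOCYTES,
) -> pd.Series:
    """Per-sample ratio of summed granulocyte to summed lymphocyte fractions.

    A zero lymphocyte sum yields +inf (flagged undefined).  Class
    membership is configurable; defaults treat neutrophils (and MDSCs when
    present) as granulocytes and B/NK/CD4 T/CD8 T as lymphocytes.
    """
    g_cols = [c for c in fractions.columns if c in granulocytes]
    l_cols = [c for c in fractions.columns if c in lymphocytes]
    if not g_cols or not l_cols:
        raise ValueError("fractions must include at least one granulocyte and one lymphocyte type")
    g = fractions[g_cols].sum(axis=1).to_numpy()
    l = fractions[l_cols].sum(axis=1).to_numpy()
    ratio = np.where(l > 0, g / np.where(l > 0, l, 1.0), np.inf)
    return pd.Series(ratio, index=fractions.index, name="granulocyte_lymphocyte_ratio")
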