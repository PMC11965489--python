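"""Reading and writing the pipeline's tabular formats.

Beta matrices are TSV/CSV with CpG ids in the first column and one column
per sample (gzip transparently supported via the ``.gz`` suffix); sample
sheets are CSV indexed by sample id; annotation tables are tab-separated
with required named columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml


def _sep_for(path: Path) -> str:
    name = path.name.removesuffix(".gz")
    return "," if name.endswith(".csv") else "\t"


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    """Read a CpG x sample beta matrix, validating ids and value range."""
    path = Path(path)
    beta = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    beta.index.name = "cpg_id"
    if beta.index.duplicated().any():
        dup = beta.index[beta.index.duplicated()][:5].tolist()
        raise ValueError(f"duplicate CpG ids: {dup}")
    vals = beta.to_numpy(dtype=float)
    bad = np.nonzero((vals < 0) | (vals > 1))
    if bad[0].size:
        i, j = bad[0][0], bad[1][0]
        raise ValueError(
            f"beta out of [0,1]: CpG {beta.index[i]!r}, sample {beta.columns[j]!r}, "
            f"value {vals[i, j]!r}"
        )
    return beta.astype(float)


def write_beta_matrix(beta: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    beta.to_csv(path, sep=_sep_for(path))


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path)


def read_table(path: str | Path, required: tuple[str, ...], index_col=None) -> pd.DataFrame:
    """Tab-separated table with a required-column contract."""
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_cpg_annotation(path: str | Path) -> pd.DataFrame:
    """CpG annotation indexed by cpg_id with chrom and 1-based pos."""
    return read_table(path, required=("chrom", "pos"), index_col=0)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: YAML config must be a mapping")
    return cfg
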