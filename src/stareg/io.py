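"""Reading paired p-value tables and writing annotated result tables.

Input is a plain delimited text table (TSV or CSV, header required) with a
gene-identifier column and one p-value column per study; nothing
platform-specific is assumed, since the method consumes only p-values.
Result tables carry run metadata in ``#``-prefixed header lines above the
column header.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import PairedPValues

__all__ = ["ReadError", "read_paired_pvalues", "build_result_table",
           "write_result_table", "read_result_table"]

logger = logging.getLogger("stareg")

#: values this far outside [0,1] are treated as float slop and clipped;
#: anything further out is a hard error
_RANGE_SLOP = 1e-8


class ReadError(ValueError):
    """Raised for malformed input tables (missing columns, duplicate ids,
    out-of-range p-values, unparseable files)."""


def _delimiter(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_paired_pvalues(path, gene_col: str = "gene", p1_col: str = "p1",
                        p2_col: str = "p2", sep: str | None = None) -> PairedPValues:
    """Load a gene/p1/p2 table; rows with missing p-values are dropped with
    a logged warning, duplicate gene ids and out-of-range p-values error."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_delimiter(path, sep), comment="#")
    except Exception as exc:
        raise ReadError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in (gene_col, p1_col, p2_col) if c not in df.columns]
    if missing:
        raise ReadError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    for col in (p1_col, p2_col):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    n_before = len(df)
    df = df.dropna(subset=[gene_col, p1_col, p2_col])
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with missing values", path, n_dropped)
    if len(df) == 0:
        raise ReadError(f"{path}: no usable rows")
    if df[gene_col].duplicated().any():
        dup = df.loc[df[gene_col].duplicated(), gene_col].iloc[0]
        raise ReadError(f"{path}: duplicate gene id {dup!r}")
    for col in (p1_col, p2_col):
        vals = df[col].to_numpy(dtype=float)
        bad = (vals < -_RANGE_SLOP) | (vals > 1.0 + _RANGE_SLOP)
        if bad.any():
            row = df.index[np.argmax(bad)]
            raise ReadError(
                f"{path}: {col} outside [0, 1] at row {row} (value {vals[bad][0]!r})")
        df[col] = np.clip(vals, 0.0, 1.0)
    return PairedPValues(gene_ids=df[gene_col].to_numpy(),
                         p1=df[p1_col].to_numpy(),
                         p2=df[p2_col].to_numpy())


def build_result_table(data, lfdr_result, decision, rank_order,
                       rank_scores) -> pd.DataFrame:
    """Per-gene result table in original input order."""
    rank_score = np.empty(data.m)
    rank_score[rank_order] = rank_scores
    return pd.DataFrame({
        "gene_id": data.gene_ids,
        "p1": data.p1,
        "p2": data.p2,
        "lfdr": lfdr_result.lfdr,
        "rejected": decision.rejected,
        "rank_score": rank_score,
    })


def write_result_table(path, table: pd.DataFrame, metadata: dict,
                       sep: str | None = None) -> None:
    """Write a result table with ``# key: value`` metadata header lines;
    floats keep 12 significant digits so a round trip is faithful."""
    path = Path(path)
    delim = _delimiter(path, sep)
    with open(path, "w") as fh:
        for key, value in metadata.items():
            fh.write(f"# {key}: {value}\n")
        table.to_csv(fh, sep=delim, index=False, float_format="%.12g")


def read_result_table(path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_delimiter(path, sep), comment="#")
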