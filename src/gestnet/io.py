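"""Readers and writers for the pipeline's plain-text formats.

Matrices travel as labelled TSV (first row and first column are node
labels) plus an interoperable long-format CSV (from, to, value); tables as
ordinary CSV.  Matrix round-trips preserve labels exactly and values to at
least 12 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .matrices import DyadMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_table",
    "write_table",
    "load_config",
    "write_json",
]


def write_matrix(matrix: DyadMatrix, path, long_csv: bool = True) -> None:
    """Labelled TSV; also writes ``<stem>.long.csv`` unless disabled."""
    path = Path(path)
    frame = matrix.to_frame()
    frame.to_csv(path, sep="\t", float_format="%.17g", index_label="")
    if long_csv:
        matrix.to_long().to_csv(
            path.with_suffix(".long.csv"), index=False, float_format="%.17g"
        )


def read_matrix(path, name: str | None = None, zero_diagonal: bool = False) -> DyadMatrix:
    """Read a labelled TSV matrix.

    Row labels must equal column labels in order.  A nonzero diagonal is an
    error unless ``zero_diagonal`` is set, in which case it is zeroed.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(c) for c in frame.columns]
    row_labels = [str(r) for r in frame.index]
    if labels != row_labels:
        raise ValueError(
            f"{path}: row labels do not match column labels "
            f"({row_labels[:3]}... vs {labels[:3]}...)"
        )
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate node labels")
    values = frame.to_numpy(dtype=float)
    if np.any(np.diag(values) != 0):
        if not zero_diagonal:
            raise ValueError(f"{path}: nonzero diagonal (pass zero_diagonal=True)")
        np.fill_diagonal(values, 0.0)
    return DyadMatrix(labels, values, name=name or path.stem)


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"mother_id": "string"} , keep_default_na=True)


def load_config(path) -> dict:
    """Structured key: value config (YAML, of which plain key: value is a subset)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return cfg


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
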