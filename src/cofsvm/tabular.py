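"""CSV/TSV plumbing shared by the command-line interface.

Feature files: one row per sample, numeric columns only (optional header,
optional group column for per-video style aggregation).  Label files: binary
indicator columns named ``label_1 .. label_z`` (header required so the
schema is explicit).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_feature_table",
    "read_label_table",
    "write_feature_table",
    "write_label_table",
]


class SchemaError(ValueError):
    """A table does not match the expected column layout."""


def _has_header(path: Path, sep: str) -> bool:
    with open(path) as fh:
        first = fh.readline().strip()
    for tok in first.split(sep):
        try:
            float(tok)
        except ValueError:
            return True
    return False


def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","


def read_feature_table(path, group_column: str | None = None):
    """Load a feature table.

    Returns ``(X, groups)`` where ``groups`` is None unless ``group_column``
    was requested (it is removed from the numeric block).
    """
    path = Path(path)
    sep = _sep_for(path)
    header = 0 if _has_header(path, sep) else None
    df = pd.read_csv(path, sep=sep, header=header)
    groups = None
    if group_column is not None:
        if header is None:
            raise SchemaError("a group column requires a header row")
        if group_column not in df.columns:
            raise SchemaError(f"feature table has no column {group_column!r}")
        groups = df[group_column].to_numpy()
        df = df.drop(columns=[group_column])
    try:
        X = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise SchemaError(f"non-numeric feature column: {exc}") from exc
    return X, groups


def read_label_table(path):
    """Load a binary indicator label table; returns ``(Y, label_names)``."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    names = [c for c in df.columns if str(c).startswith("label_")]
    if not names:
        raise SchemaError(
            "label table must contain indicator columns named label_1..label_z"
        )
    expected = [f"label_{i + 1}" for i in range(len(names))]
    if sorted(names) != sorted(expected):
        missing = set(expected) - set(names)
        raise SchemaError(f"missing label columns: {sorted(missing)}")
    Y = df[expected].to_numpy()
    if not np.isin(Y, (0, 1)).all():
        raise SchemaError("label columns must be binary indicators")
    return Y.astype(int), expected


def write_feature_table(path, X, group=None, group_column: str = "group") -> None:
    df = pd.DataFrame(np.asarray(X, dtype=float))
    df.columns = [f"f{i + 1}" for i in range(df.shape[1])]
    if group is not None:
        df.insert(0, group_column, group)
    df.to_csv(path, sep=_sep_for(Path(path)), index=False)


def write_label_table(path, Y) -> None:
    Y = np.asarray(Y, dtype=int)
    df = pd.DataFrame(Y, columns=[f"label_{i + 1}" for i in range(Y.shape[1])])
    df.to_csv(path, sep=_sep_for(Path(path)), index=False)
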