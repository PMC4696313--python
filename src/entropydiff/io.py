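"""Reading expression matrices and writing result tables.

Matrices are plain tab- or comma-delimited text: one label column (default
the first), one column per sample, optional header line.  Recognized NA
tokens are ``NA``, ``NaN``, ``nan`` and the empty cell; anything else
non-numeric is a parse error reported with its line and column.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .exceptions import MatrixParseError

__all__ = ["read_matrix", "write_matrix", "write_result", "load_demo_pair"]

NA_TOKENS = {"", "NA", "NaN", "nan", "na"}

_DELIMITERS = {"tab": "\t", "comma": ","}


def _resolve_sep(path: Path, delimiter: str) -> str:
    if delimiter in _DELIMITERS:
        return _DELIMITERS[delimiter]
    if delimiter != "auto":
        raise ValueError(
            f"delimiter must be 'tab', 'comma' or 'auto', got {delimiter!r}"
        )
    with open(path, "rt") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_matrix(
    path: Union[str, Path],
    delimiter: str = "auto",
    header: bool = True,
    label_column: int = 0,
) -> pd.DataFrame:
    """Parse a delimited text file into a row-labeled numeric matrix.

    Returns a DataFrame indexed by the label column, one float column per
    sample.  Raises :class:`MatrixParseError` for non-numeric cells (with
    1-based line/column coordinates) and for duplicate row labels.
    """
    path = Path(path)
    sep = _resolve_sep(path, delimiter)
    raw = pd.read_csv(
        path,
        sep=sep,
        header=0 if header else None,
        dtype=str,
        keep_default_na=False,
        skip_blank_lines=True,
    )
    if raw.shape[1] < 2:
        raise MatrixParseError(
            f"{path}: expected a label column plus >= 1 sample column, "
            f"found {raw.shape[1]} column(s) (delimiter {sep!r})"
        )
    if not 0 <= label_column < raw.shape[1]:
        raise ValueError(
            f"label_column {label_column} out of range for "
            f"{raw.shape[1]} columns"
        )
    labels = raw.iloc[:, label_column].str.strip()
    if labels.duplicated().any():
        dup = labels[labels.duplicated()].iloc[0]
        raise MatrixParseError(f"{path}: duplicate row label {dup!r}")
    body = raw.drop(columns=raw.columns[label_column])
    values = body.apply(lambda col: pd.to_numeric(col.str.strip(), errors="coerce"))
    bad = values.isna() & ~body.apply(
        lambda col: col.str.strip().isin(NA_TOKENS)
    )
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        line = r + 2 if header else r + 1  # 1-based, counting the header
        col_pos = list(raw.columns).index(body.columns[c]) + 1
        raise MatrixParseError(
            f"{path}: non-numeric value {body.iloc[r, c]!r} at line {line}, "
            f"column {col_pos}"
        )
    out = values.astype(float)
    out.index = pd.Index(labels, name=labels.name or "feature")
    if not header:
        out.columns = [f"s{i + 1}" for i in range(out.shape[1])]
    return out


def _atomic_to_csv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    # write to a sibling temp file and rename, so a failure never leaves a
    # partial result behind
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            df.to_csv(fh, **kwargs)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_matrix(
    matrix: pd.DataFrame, path: Union[str, Path], format: Optional[str] = None
) -> None:
    """Write a row-labeled matrix as TSV (default) or CSV."""
    path = Path(path)
    sep = _format_sep(path, format)
    _atomic_to_csv(
        matrix, path, sep=sep, na_rep="NA", index_label=matrix.index.name or "feature"
    )


def write_result(
    table: pd.DataFrame, path: Union[str, Path], format: Optional[str] = None
) -> None:
    """Write a result table with floats at 6 significant digits, NA as "NA".

    ``format`` is ``"tsv"`` or ``"csv"``; if omitted it is inferred from
    the file extension (``.csv`` -> CSV, anything else -> TSV).
    """
    path = Path(path)
    sep = _format_sep(path, format)
    _atomic_to_csv(
        table,
        path,
        sep=sep,
        na_rep="NA",
        float_format="%.6g",
        index_label=table.index.name or "feature",
    )


def _format_sep(path: Path, format: Optional[str]) -> str:
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "tsv"
    try:
        return {"tsv": "\t", "csv": ","}[format.lower()]
    except KeyError:
        raise ValueError(f"format must be 'tsv' or 'csv', got {format!r}") from None


def load_demo_pair():
    """The packaged 10-feature, 4+4-sample demo case/control pair."""
    from importlib import resources

    base = resources.files("entropydiff") / "data"
    with resources.as_file(base / "demo_case.tsv") as p:
        case = read_matrix(p, delimiter="tab")
    with resources.as_file(base / "demo_control.tsv") as p:
        control = read_matrix(p, delimiter="tab")
    return case, control
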