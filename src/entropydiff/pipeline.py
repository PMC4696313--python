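"""Single-call case/control analysis over row-matched expression matrices.

The tool surface: takes two row-labeled positive matrices (rows = features,
columns = samples), resolves optional additive shifts, validates alignment
and positivity, computes the requested differential metric and p-values for
every row, adjusts for multiplicity, sorts and truncates to the top rows.

The heavy lifting is delegated to
:class:`entropydiff.estimator.DifferentialVariability`; this module handles
matrix-level validation and the output-table schema.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from .estimator import STAT_LABELS, DifferentialVariability
from .exceptions import AlignmentError, PositivityError
from .metrics import VALID_METRICS, resolve_shift

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "OTYPES", "validate_and_align", "run_analysis"]

#: output types -> (number of columns, sort key)
OTYPES = {
    "v": (2, "diff"),     # the two per-condition statistics, sorted by diff
    "bv": (3, "diff"),    # both statistics + difference, sorted by diff
    "p": (5, "p_raw"),    # stats, diff, raw and adjusted p, sorted by raw p
    "pa": (5, "p_adj"),   # same columns, sorted by adjusted p
    "bp": (5, "diff"),    # same columns, sorted by diff
    "bpa": (5, "diff"),   # same columns, sorted by diff
}

ShiftSpec = Tuple[Union[float, str], Union[float, str]]


@dataclasses.dataclass
class AnalysisConfig:
    """Configuration of one analysis run.

    shift is a pair of per-matrix additive biases, each a number >= 0 or
    "auto" (derived from the least non-positive entry).  ntop=None keeps
    all rows.  seed governs every permutation stream.
    """

    metric: str = "dse"
    otype: str = "bv"
    ntop: Optional[int] = None
    nperm: int = 1000
    shift: ShiftSpec = (0.0, 0.0)
    padjust: str = "bh"
    seed: Optional[int] = None
    bias_corrected: bool = False

    def __post_init__(self):
        if self.metric not in VALID_METRICS:
            raise ValueError(
                f"metric must be one of {VALID_METRICS}, got {self.metric!r}"
            )
        if self.otype not in OTYPES:
            raise ValueError(
                f"otype must be one of {sorted(OTYPES)}, got {self.otype!r}"
            )
        if self.ntop is not None and int(self.ntop) < 1:
            raise ValueError("ntop must be a positive integer or None")
        if int(self.nperm) < 1:
            raise ValueError("nperm must be >= 1")
        if len(tuple(self.shift)) != 2:
            raise ValueError("shift must be a pair (shift1, shift2)")


def _as_matrix(m, name: str) -> pd.DataFrame:
    if not isinstance(m, pd.DataFrame):
        raise TypeError(
            f"{name} must be a pandas DataFrame with row labels as index"
        )
    if m.shape[0] < 1 or m.shape[1] < 2:
        raise ValueError(
            f"{name} must have >= 1 row and >= 2 sample columns, "
            f"got shape {m.shape}"
        )
    if m.index.has_duplicates:
        dup = m.index[m.index.duplicated()][0]
        raise ValueError(f"{name} has duplicate row label {dup!r}")
    return m.astype(float)


def validate_and_align(
    m1: pd.DataFrame, m2: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Check that the matrices are row-matched and strictly positive.

    The two row-label sequences must be identical (same labels, same
    order); every finite entry must be > 0.  Returns the validated pair.
    """
    m1 = _as_matrix(m1, "matrix 1")
    m2 = _as_matrix(m2, "matrix 2")
    if len(m1.index) != len(m2.index) or not (m1.index == m2.index).all():
        n = min(len(m1.index), len(m2.index))
        for i in range(n):
            if m1.index[i] != m2.index[i]:
                raise AlignmentError(
                    f"row labels diverge at position {i}: "
                    f"{m1.index[i]!r} vs {m2.index[i]!r}"
                )
        raise AlignmentError(
            f"matrices have different numbers of rows "
            f"({len(m1.index)} vs {len(m2.index)})"
        )
    for name, m in (("matrix 1", m1), ("matrix 2", m2)):
        vals = m.to_numpy()
        bad = np.isfinite(vals) & (vals <= 0)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise PositivityError(
                f"{name} contains non-positive entry {vals[r, c]} at row "
                f"{m.index[r]!r}, column {m.columns[c]!r}; use the shift "
                "argument to add a positive bias"
            )
    return m1, m2


def run_analysis(
    m1: pd.DataFrame,
    m2: pd.DataFrame,
    config: Optional[AnalysisConfig] = None,
    **overrides,
) -> pd.DataFrame:
    """Full analysis of a case/control matrix pair.

    Keyword overrides (``metric=``, ``otype=``, ``ntop=``, ``nperm=``,
    ``shift=``, ``padjust=``, ``seed=``) update ``config`` field-wise.
    Returns the sorted, truncated result table: a DataFrame indexed by row
    label whose columns follow the requested output type (for metric dse:
    ``SE1, SE2`` for otype ``v``; ``+ DSE`` for ``bv``; ``+ p_raw, p_adj``
    for the five-column types).  Rows where a condition has fewer than two
    finite values carry NA and sort last.
    """
    cfg = config or AnalysisConfig()
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)

    m1 = _as_matrix(m1, "matrix 1")
    m2 = _as_matrix(m2, "matrix 2")
    s1 = resolve_shift(m1.to_numpy(), cfg.shift[0])
    s2 = resolve_shift(m2.to_numpy(), cfg.shift[1])
    if s1:
        logger.info("adding shift %g to matrix 1", s1)
        m1 = m1 + s1
    if s2:
        logger.info("adding shift %g to matrix 2", s2)
        m2 = m2 + s2
    m1, m2 = validate_and_align(m1, m2)

    n_cols, sort_key = OTYPES[cfg.otype]
    est = DifferentialVariability(
        metric=cfg.metric,
        compute_pvalues=n_cols == 5,
        n_permutations=int(cfg.nperm),
        adjust_method=cfg.padjust,
        bias_corrected_permutation=cfg.bias_corrected,
        random_state=cfg.seed,
    )
    X = np.vstack([m1.to_numpy().T, m2.to_numpy().T])
    y = np.concatenate(
        [np.zeros(m1.shape[1], dtype=int), np.ones(m2.shape[1], dtype=int)]
    )
    est.fit(pd.DataFrame(X, columns=m1.index), y)

    table = est.results_
    stem = STAT_LABELS[cfg.metric]
    if n_cols == 2:
        table = table[[f"{stem}1", f"{stem}2"]]
        sort_col, ascending = est.results_[cfg.metric.upper()], False
    elif n_cols == 3:
        sort_col, ascending = table[cfg.metric.upper()], False
    else:
        col = {"diff": cfg.metric.upper(), "p_raw": "p_raw", "p_adj": "p_adj"}[
            sort_key
        ]
        # descending for the value sorts, ascending for the p sorts
        sort_col, ascending = table[col], sort_key != "diff"

    order = _sort_order(sort_col, ascending)
    table = table.iloc[order]
    if cfg.ntop is not None:
        table = table.iloc[: int(cfg.ntop)]
    return table


def _sort_order(key: pd.Series, ascending: bool) -> np.ndarray:
    """Stable order by key (NaN last), ties broken by row label."""
    frame = pd.DataFrame(
        {"key": key.to_numpy(), "label": key.index.astype(str)}
    )
    frame = frame.sort_values("label", kind="stable")
    frame = frame.sort_values(
        "key", ascending=ascending, kind="stable", na_position="last"
    )
    return frame.index.to_numpy()
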