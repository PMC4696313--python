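"""Per-feature dispersion statistics.

For a list of *n* strictly positive numbers ``x_1 .. x_n`` with sum ``x``,
the normalized Shannon entropy is

    SE = -sum_i (x_i / x) * log2(x_i / x) / log2(n)

which lies in [0, 1]: 1 for a perfectly uniform list, approaching 0 as a
single value dominates.  Under this convention *lower* SE means *more*
variability.  The coefficient of variation is the sample standard deviation
(n - 1 denominator) over the absolute mean, CV = s / |x̄|, in [0, inf).

Given a feature measured in two conditions, the differential metrics are
the absolute differences DSE = |SE1 - SE2|, DCV = |CV1 - CV2| and
DE = |x̄1 - x̄2|.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence, Union

import numpy as np

from .exceptions import PositivityError

__all__ = [
    "MetricTriple",
    "VALID_METRICS",
    "shannon_entropy",
    "coefficient_of_variation",
    "row_mean",
    "diff_metric",
    "resolve_shift",
]

VALID_METRICS = ("dse", "dcv", "de")

#: Additive-shift specification component: a nonnegative number, or "auto".
ShiftComponent = Union[float, str]


class MetricTriple(NamedTuple):
    """Per-condition statistics and their absolute difference."""

    stat1: float
    stat2: float
    diff: float


def _as_1d(values, label=None, min_size=2) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    where = f" (row {label!r})" if label is not None else ""
    if arr.size < min_size:
        raise ValueError(
            f"need at least {min_size} values{where}, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"values contain non-finite entries{where}")
    return arr


def _check_positive(arr: np.ndarray, label=None) -> None:
    if np.any(arr <= 0):
        where = f" in row {label!r}" if label is not None else ""
        bad = float(arr[arr <= 0][0])
        raise PositivityError(
            f"all values must be strictly positive{where}; found {bad}"
        )


def shannon_entropy(values: Sequence[float], label=None) -> float:
    """Normalized base-2 Shannon entropy of the value proportions.

    Parameters
    ----------
    values : sequence of float
        At least two strictly positive, finite numbers.
    label : optional
        Row identifier used in error messages.

    Returns
    -------
    float in [0, 1]; exactly 1.0 when all values are equal.
    """
    arr = _as_1d(values, label)
    _check_positive(arr, label)
    if np.all(arr == arr[0]):
        # uniform proportions: normalization forces exactly 1, independent
        # of float rounding in x_i / sum
        return 1.0
    p = arr / arr.sum()
    se = float(-(p * np.log2(p)).sum() / np.log2(arr.size))
    return min(max(se, 0.0), 1.0)


def coefficient_of_variation(values: Sequence[float], label=None) -> float:
    """Sample standard deviation (n-1 denominator) over the absolute mean."""
    arr = _as_1d(values, label)
    mean = arr.mean()
    if mean == 0:
        where = f" (row {label!r})" if label is not None else ""
        raise ValueError(f"coefficient of variation undefined: zero mean{where}")
    return float(arr.std(ddof=1) / abs(mean))


def row_mean(values: Sequence[float], label=None) -> float:
    """Arithmetic mean of a non-empty value list."""
    arr = _as_1d(values, label, min_size=1)
    return float(arr.mean())


_STAT_FUNCS = {
    "dse": shannon_entropy,
    "dcv": coefficient_of_variation,
    "de": row_mean,
}


def diff_metric(list1, list2, metric: str, label=None) -> MetricTriple:
    """Per-condition statistic for each list plus their absolute difference.

    ``metric`` selects the statistic: ``"dse"`` (normalized Shannon
    entropy), ``"dcv"`` (coefficient of variation) or ``"de"`` (mean).
    The two lists may have different lengths.
    """
    try:
        func = _STAT_FUNCS[metric]
    except KeyError:
        raise ValueError(
            f"unknown metric {metric!r}; expected one of {VALID_METRICS}"
        ) from None
    s1 = func(list1, label)
    s2 = func(list2, label)
    return MetricTriple(s1, s2, abs(s1 - s2))


def resolve_shift(matrix, shift: ShiftComponent = "auto") -> float:
    """Resolve one component of an additive-shift specification.

    A numeric ``shift`` is returned unchanged (must be >= 0).  ``"auto"``
    inspects the matrix: if the minimum finite entry ``m`` is positive the
    shift is 0; otherwise it is ``|m| + d`` where ``d`` is the smallest
    strictly positive entry (1 if none exists), which guarantees a strictly
    positive post-shift matrix with a data-scaled margin.
    """
    data = np.asarray(matrix, dtype=float)
    finite = data[np.isfinite(data)]
    if finite.size == 0:
        raise ValueError("matrix has no finite entries")
    if not (isinstance(shift, str) and shift == "auto"):
        if isinstance(shift, str):
            raise ValueError(f"shift must be a number or 'auto', got {shift!r}")
        value = float(shift)
        if value < 0:
            raise ValueError(f"shift must be >= 0, got {value}")
        return value
    lowest = float(finite.min())
    if lowest > 0:
        return 0.0
    positive = finite[finite > 0]
    margin = float(positive.min()) if positive.size else 1.0
    value = abs(lowest) + margin
    # a margin far below one ulp of |lowest| can be absorbed by rounding;
    # bump until the post-shift minimum is genuinely positive
    while lowest + value <= 0:
        value = np.nextafter(value, np.inf)
    return value


# ---------------------------------------------------------------------------
# Vectorized, NaN-aware row-wise variants used by the estimator.  Rows with
# fewer than 2 finite values yield NaN; positivity is the caller's contract.


def row_entropies(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    mask = np.isfinite(X)
    n = mask.sum(axis=1)
    Xz = np.where(mask, X, 0.0)
    total = Xz.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(mask, Xz / total, 1.0)  # placeholder 1 -> plogp term 0
        se = -(p * np.log2(p)).sum(axis=1) / np.log2(
            np.where(n > 1, n, 2).astype(float)
        )
    se = np.clip(se, 0.0, 1.0)
    # exact 1.0 on constant rows (see shannon_entropy)
    hi = np.where(mask, X, -np.inf).max(axis=1)
    lo = np.where(mask, X, np.inf).min(axis=1)
    se[(hi == lo) & (n >= 2)] = 1.0
    se[n < 2] = np.nan
    return se


def row_cvs(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    mask = np.isfinite(X)
    n = mask.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, np.where(mask, X, 0.0).sum(1) / n, np.nan)
        ss = np.where(mask, (X - mean[:, None]) ** 2, 0.0).sum(1)
        sd = np.sqrt(ss / np.where(n > 1, n - 1, 1))
        cv = sd / np.abs(mean)
    cv[(n < 2) | (mean == 0)] = np.nan
    return cv


def row_means(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    mask = np.isfinite(X)
    n = mask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.where(mask, X, 0.0).sum(1) / n, np.nan)
    # row-level NA policy: a variability row needs >= 2 finite values; means
    # follow the same rule so every metric marks the same rows NA
    mean[n < 2] = np.nan
    return mean


ROW_STAT_FUNCS = {"dse": row_entropies, "dcv": row_cvs, "de": row_means}
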