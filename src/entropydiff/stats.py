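"""P-value machinery for the three differential metrics.

* DSE — pooled-permutation test.  No standard reference distribution fits
  differential Shannon entropy, so the null is built by pooling the
  n1 + n2 values, repeatedly permuting the pool, splitting it back into
  groups of sizes n1 and n2, and recomputing DSE.  The p-value is the
  proportion of permuted DSEs at least as extreme as the observed one.
* DCV — Fligner-Killeen rank test of homogeneity of variances applied to
  the log-transformed data (robust to non-normality; asymptotically
  chi-square with 1 df for two groups).
* DE — two-sided Welch (unequal-variance) two-sample t-test.

plus multiple-testing adjustment (Bonferroni, Holm, Hochberg, BH, BY).
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
from scipy import stats as sps

from .exceptions import PositivityError
from .metrics import _as_1d, _check_positive

__all__ = [
    "TestResult",
    "dse_permutation_pvalue",
    "fligner_killeen_pvalue",
    "de_ttest_pvalue",
    "adjust_pvalues",
    "ADJUST_METHODS",
]

# Recomputing DSE on a resampled split that happens to reproduce the observed
# one can differ from the observed DSE by ~1e-16 (summation order), which
# would wrongly drop an exact tie from the ">= observed" count.  Ties are
# what make the test valid at small n, so comparisons allow this margin.
_TIE_TOLERANCE = 1e-9


class TestResult(NamedTuple):
    """A test statistic (the observed DSE for the permutation test) and its
    raw p-value."""

    statistic: float
    p_raw: float


def _norm_entropy_2d(M: np.ndarray) -> np.ndarray:
    """Normalized Shannon entropy of each row of a positive 2-D array."""
    p = M / M.sum(axis=1, keepdims=True)
    return -(p * np.log2(p)).sum(axis=1) / np.log2(M.shape[1])


def dse_permutation_pvalue(
    list1: Sequence[float],
    list2: Sequence[float],
    n_permutations: int = 1000,
    seed: Union[int, np.random.Generator, None] = None,
    bias_corrected: bool = False,
) -> TestResult:
    """Pooled-permutation p-value for the differential Shannon entropy.

    The observed DSE is computed on the original split.  All n1 + n2 values
    are pooled, and for each of ``n_permutations`` iterations the pool is
    randomly permuted and re-split by group size; the p-value is the
    proportion of permuted DSEs >= the observed DSE.

    With ``bias_corrected=True`` the estimator (count + 1)/(nperm + 1) is
    used instead, which can never return 0.

    Deterministic for a fixed integer ``seed``.  The null splits depend on
    the pooled values and group sizes only, so the p-value is invariant to
    swapping the two lists.
    """
    if n_permutations < 1:
        raise ValueError(f"n_permutations must be >= 1, got {n_permutations}")
    a = _as_1d(list1)
    b = _as_1d(list2)
    _check_positive(a)
    _check_positive(b)

    obs = float(abs(_norm_entropy_2d(a[None, :]) - _norm_entropy_2d(b[None, :]))[0])

    pool = np.sort(np.concatenate([a, b]))
    n_small = min(a.size, b.size)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    perms = rng.permuted(np.tile(pool, (n_permutations, 1)), axis=1)
    dse = np.abs(
        _norm_entropy_2d(perms[:, :n_small]) - _norm_entropy_2d(perms[:, n_small:])
    )
    count = int((dse >= obs - _TIE_TOLERANCE).sum())
    if bias_corrected:
        p = (count + 1) / (n_permutations + 1)
    else:
        p = count / n_permutations
    return TestResult(obs, float(p))


def fligner_killeen_pvalue(
    list1: Sequence[float], list2: Sequence[float]
) -> TestResult:
    """Fligner-Killeen homogeneity-of-variances p-value on log data.

    Both lists are natural-log-transformed (the statistic is invariant to
    the base: changing base shifts every log by a common factor that drops
    out of the median-centered ranks).  Absolute deviations from each group
    median are ranked over the pooled sample, mapped to one-sided normal
    scores, and compared between groups via a chi-square statistic with
    1 degree of freedom.
    """
    a = _as_1d(list1)
    b = _as_1d(list2)
    _check_positive(a)
    _check_positive(b)
    la, lb = np.log(a), np.log(b)
    dev = np.concatenate([np.abs(la - np.median(la)), np.abs(lb - np.median(lb))])
    if np.all(dev == 0):
        warnings.warn(
            "all median-centered deviations are zero; "
            "variance homogeneity is vacuous (p = 1)",
            RuntimeWarning,
            stacklevel=2,
        )
        return TestResult(0.0, 1.0)
    # the statistic is symmetric in the groups, but the float rounding of
    # the pooled grand mean is not; canonicalize the order so that swapping
    # the two lists returns bit-identical results
    ga, gb = np.sort(la), np.sort(lb)
    if (gb.size, tuple(gb)) < (ga.size, tuple(ga)):
        ga, gb = gb, ga
    statistic, p = sps.fligner(ga, gb)
    return TestResult(float(statistic), float(p))


def de_ttest_pvalue(list1: Sequence[float], list2: Sequence[float]) -> TestResult:
    """Two-sided Welch two-sample t-test p-value for the mean difference."""
    a = _as_1d(list1)
    b = _as_1d(list2)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        equal = a.mean() == b.mean()
        warnings.warn(
            "both groups are constant; t statistic undefined "
            f"(p = {1.0 if equal else 0.0})",
            RuntimeWarning,
            stacklevel=2,
        )
        return TestResult(np.nan, 1.0 if equal else 0.0)
    statistic, p = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(statistic), float(p))


ADJUST_METHODS = ("bonferroni", "holm", "hochberg", "bh", "by")


def adjust_pvalues(
    p_raw: Sequence[float], method: str = "bh"
) -> np.ndarray:
    """Multiplicity-adjusted p-values, order-preserving, clipped to <= 1.

    ``method`` is one of ``bonferroni``, ``holm`` (step-down), ``hochberg``
    (step-up), ``bh`` (Benjamini-Hochberg FDR) or ``by``
    (Benjamini-Yekutieli).  The family size m is the length of ``p_raw``:
    adjust over every tested hypothesis, not just the displayed ones.
    Values match R's ``p.adjust`` for the same method names.
    """
    key = str(method).lower()
    if key not in ADJUST_METHODS:
        raise ValueError(
            f"unknown adjustment method {method!r}; "
            f"valid methods: {sorted(ADJUST_METHODS)}"
        )
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("p_raw must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("raw p-values must all lie in [0, 1]")
    m = p.size
    if key == "bonferroni":
        return np.minimum(p * m, 1.0)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    i = np.arange(1, m + 1)
    if key == "holm":
        adj = np.maximum.accumulate((m - i + 1) * ranked)
    elif key == "hochberg":
        adj = np.minimum.accumulate(((m - i + 1) * ranked)[::-1])[::-1]
    else:  # bh / by step-up
        scale = np.sum(1.0 / i) if key == "by" else 1.0
        adj = np.minimum.accumulate((scale * m / i * ranked)[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
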