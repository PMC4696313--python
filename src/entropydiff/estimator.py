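"""Scikit-learn style estimator for two-group differential variability.

``DifferentialVariability`` scores every feature of a samples x features
matrix ``X`` against a binary condition vector ``y``, computing the chosen
per-condition statistic (normalized Shannon entropy, coefficient of
variation, or mean), its absolute between-condition difference, and raw plus
multiplicity-adjusted p-values.  It behaves like a univariate feature
selector: ``transform`` keeps the ``n_top`` features with the largest
differential, so the estimator composes with sklearn pipelines and model
selection.
"""

from __future__ import annotations

import logging
from typing import Optional, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import metrics, stats
from .exceptions import PositivityError
from .metrics import ROW_STAT_FUNCS, VALID_METRICS

logger = logging.getLogger(__name__)

#: column-label stems for each metric
STAT_LABELS = {"dse": "SE", "dcv": "CV", "de": "mean"}


def _row_rng(base: np.random.SeedSequence, row: int) -> np.random.Generator:
    # substream keyed on (seed, row index): reproducible regardless of the
    # order in which rows are evaluated
    return np.random.default_rng(
        np.random.SeedSequence(entropy=base.entropy, spawn_key=(row,))
    )


class DifferentialVariability(TransformerMixin, BaseEstimator):
    """Per-feature differential variability/expression between two groups.

    Parameters
    ----------
    metric : {"dse", "dcv", "de"}, default "dse"
        Differential metric: absolute difference of normalized Shannon
        entropies, of coefficients of variation, or of means.
    n_top : int or None, default None
        Number of features ``transform`` keeps (largest difference first,
        ties broken by feature name).  None keeps all features.
    compute_pvalues : bool, default True
        Whether ``fit`` computes raw and adjusted p-values (pooled
        permutation test for dse, Fligner-Killeen on logs for dcv, Welch
        t-test for de).
    n_permutations : int, default 1000
        Permutations per feature for the dse test.
    adjust_method : {"bonferroni","holm","hochberg","bh","by"}, default "bh"
        Multiple-testing adjustment, applied across all features with a
        computable raw p.
    bias_corrected_permutation : bool, default False
        Use the (count + 1)/(nperm + 1) permutation p estimator instead of
        the plain proportion.
    random_state : int or None, default None
        Seed for the permutation streams.  Each feature gets an independent
        substream derived from (random_state, feature index).

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted group labels; ``classes_[0]`` is condition 1.
    stat1_, stat2_ : ndarray of shape (n_features,)
        Per-condition statistic (NaN where a group has < 2 finite values).
    diff_ : ndarray of shape (n_features,)
        ``|stat1_ - stat2_|``.
    p_values_, p_values_adjusted_ : ndarray of shape (n_features,)
        Raw and adjusted p-values (only when ``compute_pvalues``).
    results_ : pandas.DataFrame
        One row per feature with the columns above, indexed by feature name.
    """

    def __init__(
        self,
        metric: str = "dse",
        n_top: Optional[int] = None,
        compute_pvalues: bool = True,
        n_permutations: int = 1000,
        adjust_method: str = "bh",
        bias_corrected_permutation: bool = False,
        random_state: Optional[int] = None,
    ):
        self.metric = metric
        self.n_top = n_top
        self.compute_pvalues = compute_pvalues
        self.n_permutations = n_permutations
        self.adjust_method = adjust_method
        self.bias_corrected_permutation = bias_corrected_permutation
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def _validate_params_(self):
        if self.metric not in VALID_METRICS:
            raise ValueError(
                f"metric must be one of {VALID_METRICS}, got {self.metric!r}"
            )
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.n_top is not None and self.n_top < 1:
            raise ValueError("n_top must be a positive integer or None")
        if str(self.adjust_method).lower() not in stats.ADJUST_METHODS:
            raise ValueError(
                f"unknown adjustment method {self.adjust_method!r}; "
                f"valid methods: {sorted(stats.ADJUST_METHODS)}"
            )

    def fit(self, X, y):
        """Compute per-feature statistics, differences and p-values.

        ``X`` is samples x features (NaN allowed: non-finite entries are
        dropped per feature per group); ``y`` holds exactly two distinct
        group labels.  Strictly positive data are required for ``dse``
        always, and for ``dcv`` when p-values are computed.
        """
        self._validate_params_()
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            if Xv.ndim != 2:
                raise ValueError(f"X must be 2-D, got shape {Xv.shape}")
            self.feature_names_in_ = None
        y = np.asarray(y).ravel()
        if y.shape[0] != Xv.shape[0]:
            raise ValueError(
                f"X has {Xv.shape[0]} samples but y has {y.shape[0]} labels"
            )
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"y must contain exactly 2 group labels, got {self.classes_.size}"
            )
        g1 = Xv[y == self.classes_[0]].T  # features x samples
        g2 = Xv[y == self.classes_[1]].T
        if g1.shape[1] < 2 or g2.shape[1] < 2:
            raise ValueError("each group needs at least 2 samples")
        self.n_features_in_ = Xv.shape[1]

        needs_positive = self.metric == "dse" or (
            self.metric == "dcv" and self.compute_pvalues
        )
        if needs_positive:
            self._check_positive_matrix(g1, "condition 1")
            self._check_positive_matrix(g2, "condition 2")

        rows = self._feature_index()
        stat_func = ROW_STAT_FUNCS[self.metric]
        self.stat1_ = stat_func(g1)
        self.stat2_ = stat_func(g2)
        # a feature with < 2 finite values in either condition is NA in full
        incomplete = np.isnan(self.stat1_) | np.isnan(self.stat2_)
        self.stat1_[incomplete] = np.nan
        self.stat2_[incomplete] = np.nan
        self.diff_ = np.abs(self.stat1_ - self.stat2_)

        n_bad = int(incomplete.sum())
        if n_bad:
            logger.warning(
                "%d feature(s) have fewer than 2 finite values in a "
                "condition; their outputs are reported as NA",
                n_bad,
            )

        if self.compute_pvalues:
            self.p_values_ = self._raw_pvalues(g1, g2)
            self.p_values_adjusted_ = np.full_like(self.p_values_, np.nan)
            ok = np.isfinite(self.p_values_)
            if ok.any():
                self.p_values_adjusted_[ok] = stats.adjust_pvalues(
                    self.p_values_[ok], self.adjust_method
                )

        stem = STAT_LABELS[self.metric]
        data = {
            f"{stem}1": self.stat1_,
            f"{stem}2": self.stat2_,
            self.metric.upper(): self.diff_,
        }
        if self.compute_pvalues:
            data["p_raw"] = self.p_values_
            data["p_adj"] = self.p_values_adjusted_
        self.results_ = pd.DataFrame(data, index=rows)
        return self

    def _feature_index(self) -> pd.Index:
        if self.feature_names_in_ is not None:
            return pd.Index(self.feature_names_in_)
        width = len(str(max(self.n_features_in_ - 1, 0)))
        return pd.Index([f"f{i:0{width}d}" for i in range(self.n_features_in_)])

    def _check_positive_matrix(self, g: np.ndarray, which: str) -> None:
        bad = np.isfinite(g) & (g <= 0)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            name = (
                self.feature_names_in_[r]
                if self.feature_names_in_ is not None
                else f"index {r}"
            )
            raise PositivityError(
                f"{which} contains a non-positive entry ({g[r, c]}) in "
                f"feature {name}, sample column {c}; the {self.metric} "
                "metric requires strictly positive data (consider an "
                "additive shift)"
            )

    def _raw_pvalues(self, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
        base = np.random.SeedSequence(self.random_state)
        out = np.full(g1.shape[0], np.nan)
        for i in range(g1.shape[0]):
            v1 = g1[i][np.isfinite(g1[i])]
            v2 = g2[i][np.isfinite(g2[i])]
            if v1.size < 2 or v2.size < 2:
                continue
            if self.metric == "dse":
                out[i] = stats.dse_permutation_pvalue(
                    v1,
                    v2,
                    n_permutations=self.n_permutations,
                    seed=_row_rng(base, i),
                    bias_corrected=self.bias_corrected_permutation,
                ).p_raw
            elif self.metric == "dcv":
                out[i] = stats.fligner_killeen_pvalue(v1, v2).p_raw
            else:
                out[i] = stats.de_ttest_pvalue(v1, v2).p_raw
        return out

    # ------------------------------------------------------------ transform

    def get_support(self, indices: bool = False):
        """Boolean mask (or integer indices) of the features ``transform``
        keeps: the ``n_top`` largest differences, NaN rows never selected,
        ties broken by feature name."""
        self._check_fitted()
        order = self._ranking()
        k = self.n_features_in_ if self.n_top is None else min(
            self.n_top, self.n_features_in_
        )
        chosen = order[:k]
        chosen = chosen[np.isfinite(self.diff_[chosen])]
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[chosen] = True
        return np.flatnonzero(mask) if indices else mask

    def _ranking(self) -> np.ndarray:
        names = self._feature_index().astype(str)
        frame = pd.DataFrame({"diff": self.diff_, "name": names})
        frame = frame.sort_values("name", kind="stable")
        frame = frame.sort_values(
            "diff", ascending=False, kind="stable", na_position="last"
        )
        return frame.index.to_numpy()

    def transform(self, X):
        """Select the top differential-variability features from ``X``."""
        self._check_fitted()
        mask = self.get_support()
        if isinstance(X, pd.DataFrame):
            if X.shape[1] != self.n_features_in_:
                raise ValueError(
                    f"X has {X.shape[1]} features, expected {self.n_features_in_}"
                )
            return X.loc[:, mask]
        Xv = np.asarray(X)
        if Xv.ndim != 2 or Xv.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has shape {Xv.shape}, expected (*, {self.n_features_in_})"
            )
        return Xv[:, mask]

    def fit_transform(self, X, y=None, **fit_params):
        if y is None:
            raise ValueError("y with two group labels is required")
        return self.fit(X, y, **fit_params).transform(X)

    def _check_fitted(self):
        if not hasattr(self, "diff_"):
            raise AttributeError(
                "this DifferentialVariability instance is not fitted yet; "
                "call fit(X, y) first"
            )
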