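"""Label-blind feature subset selection via condition-capped pivoted QR.

With ~56 candidate features and only ~60 patients, multicollinearity makes
logistic-regression coefficients unstable.  Before any model is fit, each
task's feature matrix is standardized ((x - mean)/mean per column), reordered
by Householder QR with column pivoting — whose greedy pivot rule places a
maximally linearly independent set of columns first, with non-increasing
|diag(R)| — and truncated to the longest column prefix whose 2-norm condition
number (ratio of extreme singular values) does not exceed a cap, 15 by
default, a compromise within the commonly recommended 10-20 range.  Outcome
labels are never an input, so both prediction outcomes share the subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .features import FeatureMatrix

__all__ = [
    "SubsetSelectionResult",
    "ConditionCappedQRSelector",
    "standardize",
    "pivoted_qr_order",
    "choose_subset",
    "select_subset",
]

MEAN_RATIO = "mean_ratio"
ZSCORE = "zscore"
NONE = "none"


def standardize(
    X: np.ndarray, method: str = MEAN_RATIO, feature_names=None
) -> np.ndarray:
    """Standardize columns by (x - mean)/mean (default) or z-scoring.

    The mean-ratio form expresses every feature as a fractional deviation
    from its cohort mean; it is undefined for zero-mean columns, which raise
    an error naming the feature and pointing to the z-score option.
    ``method="none"`` returns the columns untouched (for use on matrices
    that are already scaled).
    """
    X = np.asarray(X, dtype=float)
    if method == NONE:
        return X.copy()
    mu = X.mean(axis=0)
    if method == MEAN_RATIO:
        bad = np.abs(mu) < 1e-12
        if bad.any():
            j = int(np.flatnonzero(bad)[0])
            name = feature_names[j] if feature_names is not None else f"column {j}"
            raise ValueError(
                f"feature {name!r} has zero mean; mean-ratio standardization is "
                "undefined for it (use standardization='zscore')"
            )
        return (X - mu) / mu
    if method == ZSCORE:
        sd = X.std(axis=0, ddof=1)
        bad = sd < 1e-12
        if bad.any():
            j = int(np.flatnonzero(bad)[0])
            name = feature_names[j] if feature_names is not None else f"column {j}"
            raise ValueError(f"feature {name!r} is constant; cannot z-score")
        return (X - mu) / sd
    raise ValueError(f"unknown standardization method {method!r}")


@dataclass
class SubsetSelectionResult:
    """Outcome of pivoted-QR subset selection on one feature group.

    ``pivot_order`` is the column permutation from pivoted QR, ``r_diag`` the
    |diag(R)| magnitudes (non-increasing), ``prefix_cond[k-1]`` the condition
    number of the first k standardized pivot columns, and ``chosen_k`` the
    largest k with ``prefix_cond <= cond_cap``.
    """

    feature_names: list[str]
    pivot_order: np.ndarray
    r_diag: np.ndarray
    prefix_cond: np.ndarray
    cond_cap: float = 15.0
    chosen_k: int | None = None
    rank: int | None = None

    @property
    def chosen_features(self) -> list[str]:
        if self.chosen_k is None:
            raise ValueError("chosen_k not set; run choose_subset first")
        return [self.feature_names[j] for j in self.pivot_order[: self.chosen_k]]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "pivot_rank": np.arange(1, len(self.pivot_order) + 1),
                "feature": [self.feature_names[j] for j in self.pivot_order],
                "r_diag": self.r_diag,
                "prefix_cond": self.prefix_cond,
                "selected": np.arange(1, len(self.pivot_order) + 1)
                <= (self.chosen_k or 0),
            }
        )


class ConditionCappedQRSelector(TransformerMixin, BaseEstimator):
    """Select a maximally linearly independent feature subset, capped by
    condition number.

    A scikit-learn transformer: ``fit`` ignores ``y`` entirely (selection is
    blinded to class labels by construction), standardizes the columns,
    computes the column-pivoted QR permutation, and keeps the longest pivot
    prefix with 2-norm condition number <= ``cond_cap``; ``transform``
    returns the chosen columns (original, unstandardized values) in pivot
    order.

    Parameters
    ----------
    cond_cap : float, default 15.0
        Maximum allowed condition number of the selected standardized prefix.
    standardization : {"mean_ratio", "zscore"}, default "mean_ratio"
        Column standardization applied before QR and conditioning.

    Attributes
    ----------
    pivot_order_ : ndarray of int
        Feature indices in pivot order.
    r_diag_ : ndarray
        |diag(R)|, non-increasing.
    prefix_cond_ : ndarray
        Condition number of each standardized pivot prefix.
    chosen_k_ : int
        Size of the selected subset.
    rank_ : int
        Numerical rank of the standardized matrix; trailing pivots beyond it
        are degenerate to machine precision.
    support_ : ndarray of bool
        Mask over input features of the selected subset.
    """

    def __init__(self, cond_cap: float = 15.0, standardization: str = MEAN_RATIO):
        self.cond_cap = cond_cap
        self.standardization = standardization

    def fit(self, X, y=None, feature_names=None):
        X = check_array(X, dtype=float, ensure_min_samples=2)
        n, m = X.shape
        if n <= m:
            warnings.warn(
                f"subset selection with {n} patients and {m} features: more "
                "patients than features is recommended",
                stacklevel=2,
            )
        self.n_features_in_ = m
        if feature_names is not None:
            self.feature_names_in_ = np.asarray(feature_names, dtype=object)
        Xs = standardize(X, self.standardization, feature_names)
        _, R, piv = scipy.linalg.qr(Xs, mode="economic", pivoting=True)
        r_diag = np.abs(np.diag(R))[: min(n, m)]
        if r_diag.size < m:  # fewer rows than columns: trailing pivots unresolved
            r_diag = np.concatenate([r_diag, np.zeros(m - r_diag.size)])
        tol = max(n, m) * np.finfo(float).eps * (r_diag[0] if r_diag.size else 0.0)
        rank = int(np.sum(r_diag > tol))

        prefix_cond = np.empty(m)
        for k in range(1, m + 1):
            s = scipy.linalg.svdvals(Xs[:, piv[:k]])
            prefix_cond[k - 1] = np.inf if s[-1] == 0 else s[0] / s[-1]

        ok = np.flatnonzero(prefix_cond <= self.cond_cap)
        if ok.size == 0:
            warnings.warn(
                "no pivot prefix satisfies the condition-number cap "
                f"{self.cond_cap:g}; keeping a single feature",
                stacklevel=2,
            )
            chosen_k = 1
        else:
            # largest satisfying k (scan from m downward)
            chosen_k = int(ok[-1]) + 1

        self.pivot_order_ = np.asarray(piv, dtype=int)
        self.r_diag_ = r_diag
        self.prefix_cond_ = prefix_cond
        self.rank_ = rank
        self.chosen_k_ = chosen_k
        self.support_ = np.zeros(m, dtype=bool)
        self.support_[self.pivot_order_[:chosen_k]] = True
        return self

    def transform(self, X):
        check_is_fitted(self, "chosen_k_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; selector was fit on "
                f"{self.n_features_in_}"
            )
        return X[:, self.pivot_order_[: self.chosen_k_]]

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return self.pivot_order_[: self.chosen_k_] if indices else self.support_

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "chosen_k_")
        if input_features is None:
            input_features = getattr(
                self.feature_names_in_ if hasattr(self, "feature_names_in_") else None,
                "tolist",
                lambda: [f"x{i}" for i in range(self.n_features_in_)],
            )()
        return np.asarray(
            [input_features[j] for j in self.pivot_order_[: self.chosen_k_]],
            dtype=object,
        )

    def result_(self, feature_names=None) -> SubsetSelectionResult:
        """Package the fitted attributes as a SubsetSelectionResult."""
        check_is_fitted(self, "chosen_k_")
        if feature_names is None:
            if hasattr(self, "feature_names_in_"):
                feature_names = list(self.feature_names_in_)
            else:
                feature_names = [f"x{i}" for i in range(self.n_features_in_)]
        return SubsetSelectionResult(
            feature_names=list(feature_names),
            pivot_order=self.pivot_order_,
            r_diag=self.r_diag_,
            prefix_cond=self.prefix_cond_,
            cond_cap=self.cond_cap,
            chosen_k=self.chosen_k_,
            rank=self.rank_,
        )


def pivoted_qr_order(
    matrix: FeatureMatrix | np.ndarray,
    feature_names=None,
    standardization: str = MEAN_RATIO,
) -> SubsetSelectionResult:
    """Pivot order + |diag(R)| + prefix condition numbers (no cap applied).

    Accepts a FeatureMatrix (standardizes its values) or an ndarray.
    """
    if isinstance(matrix, FeatureMatrix):
        X, feature_names = matrix.values, matrix.feature_names
    else:
        X = np.asarray(matrix, dtype=float)
    sel = ConditionCappedQRSelector(cond_cap=np.inf, standardization=standardization)
    sel.fit(X, feature_names=feature_names)
    res = sel.result_(feature_names)
    res.chosen_k = None  # cap not applied yet
    return res


def choose_subset(
    result: SubsetSelectionResult, cond_cap: float = 15.0
) -> SubsetSelectionResult:
    """Fill chosen_k/chosen_features: the largest prefix with condition
    number <= cond_cap, scanning from the full width downward."""
    ok = np.flatnonzero(result.prefix_cond <= cond_cap)
    if ok.size == 0:
        warnings.warn(
            f"no pivot prefix satisfies the condition-number cap {cond_cap:g}; "
            "keeping a single feature",
            stacklevel=2,
        )
        result.chosen_k = 1
    else:
        result.chosen_k = int(ok[-1]) + 1
    result.cond_cap = cond_cap
    return result


def select_subset(
    matrix: FeatureMatrix | np.ndarray,
    cond_cap: float = 15.0,
    feature_names=None,
    standardization: str = MEAN_RATIO,
) -> SubsetSelectionResult:
    """Standardize, pivot and cap in one call."""
    res = pivoted_qr_order(matrix, feature_names, standardization)
    return choose_subset(res, cond_cap)
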