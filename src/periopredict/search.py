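"""Exhaustive logistic-regression model search under leave-one-out CV.

Every nonempty combination of up to five features from the selected subset is
fit as a logistic-regression classifier.  Each patient's predicted outcome
probability comes from a model trained on all other patients (leave-one-out
cross-validation, LOOCV); the pooled score vector yields the combination's
AUC.  Multivariate odds ratios and Wald P-values come from the full-data fit
on raw (unstandardized) feature values, so ORs are per physical unit (e.g.
per mmHg·min of exposure area).  The five-feature cap limits the
feature-to-case ratio at cohort sizes of ~60 with ~11-13 events.

Fitting is plain maximum-likelihood Newton/IRLS; on non-convergence or
detected separation (|coefficient| > 15) the model is refit with a tiny L2
penalty (1e-6) and flagged.  The LOOCV fits for one combination are advanced
simultaneously as a batch of Newton iterations warm-started at the full-data
solution, which is algebraically identical to n independent fits.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.special import expit, ndtr
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .evaluation import auc as _auc
from .features import FeatureMatrix

__all__ = [
    "LogisticFit",
    "ClassifierResult",
    "TaskSpec",
    "count_combinations",
    "enumerate_combinations",
    "fit_logistic",
    "loocv_scores",
    "ExhaustiveLogisticSearch",
    "run_task",
]

_ETA_CLIP = 35.0
SEPARATION_COEF = 15.0


class FitCounter:
    """Counts individual logistic-model fits (one per training set)."""

    def __init__(self) -> None:
        self.count = 0

    def add(self, n: int = 1) -> None:
        self.count += n

    def reset(self) -> None:
        self.count = 0


FIT_COUNTER = FitCounter()


def count_combinations(pool_size: int, max_k: int = 5, include_empty: bool = False) -> int:
    """Number of feature combinations of size <= max_k: sum_k C(pool, k)."""
    if pool_size < 1 or max_k < 1:
        raise ValueError("pool_size and max_k must be >= 1")
    total = sum(math.comb(pool_size, k) for k in range(1, min(max_k, pool_size) + 1))
    return total + (1 if include_empty else 0)


def enumerate_combinations(
    pool_size: int, max_k: int = 5, include_empty: bool = False
) -> Iterator[tuple[int, ...]]:
    """Yield every subset of indices of size <= max_k, size-major then
    lexicographic; deterministic.  The empty (intercept-only) model is
    excluded by default."""
    if pool_size < 1 or max_k < 1:
        raise ValueError("pool_size and max_k must be >= 1")
    if include_empty:
        yield ()
    for k in range(1, min(max_k, pool_size) + 1):
        yield from itertools.combinations(range(pool_size), k)


# ---------------------------------------------------------------------------
# Newton/IRLS core
# ---------------------------------------------------------------------------


def _loglik(A: np.ndarray, y: np.ndarray, beta: np.ndarray, pen: float) -> float:
    eta = np.clip(A @ beta, -_ETA_CLIP, _ETA_CLIP)
    return float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * pen * beta @ beta)


def _newton(
    A: np.ndarray,
    y: np.ndarray,
    pen: float = 0.0,
    beta0: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, float, bool, int]:
    """Newton-Raphson with step halving on the (optionally L2-penalized)
    Bernoulli log-likelihood.  Returns (beta, loglik, converged, n_iter)."""
    n, m = A.shape
    beta = np.zeros(m) if beta0 is None else np.array(beta0, dtype=float)
    ll = _loglik(A, y, beta, pen)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(A @ beta, -_ETA_CLIP, _ETA_CLIP)
        p = expit(eta)
        g = A.T @ (y - p) - pen * beta
        w = p * (1.0 - p)
        H = (A * w[:, None]).T @ A
        if pen:
            H = H + pen * np.eye(m)
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, g, rcond=None)[0]
        step = 1.0
        new_ll = _loglik(A, y, beta + delta, pen)
        while new_ll < ll - 1e-10 and step > 1e-6:  # step-halving safeguard
            step *= 0.5
            new_ll = _loglik(A, y, beta + step * delta, pen)
        beta = beta + step * delta
        if abs(new_ll - ll) < tol * (abs(ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    return beta, ll, converged, it


def _wald(A: np.ndarray, beta: np.ndarray, pen: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    eta = np.clip(A @ beta, -_ETA_CLIP, _ETA_CLIP)
    p = expit(eta)
    w = p * (1.0 - p)
    H = (A * w[:, None]).T @ A
    if pen:
        H = H + pen * np.eye(A.shape[1])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate design
        se = np.full(A.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * (1.0 - ndtr(np.abs(z)))
    return se, z, pvals


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald statistics.

    ``coef[0]`` is the intercept; remaining entries are log-odds per original
    feature unit.
    """

    coef: np.ndarray
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    loglik: float
    converged: bool
    ridge_fallback: bool
    n_iter: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        A = np.column_stack([np.ones(len(X)), np.asarray(X, dtype=float)])
        return expit(np.clip(A @ self.coef, -_ETA_CLIP, _ETA_CLIP))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge_lambda: float = 1e-6,
    max_iter: int = 100,
    tol: float = 1e-8,
    beta0: np.ndarray | None = None,
    _allow_single_class: bool = False,
) -> LogisticFit:
    """Fit logistic regression with intercept on raw feature values.

    On non-convergence or separation (any |coefficient| > 15), refits with an
    L2 penalty ``ridge_lambda`` on all coefficients and sets
    ``ridge_fallback``.  Requires both classes in ``y`` (single-class labels
    are tolerated only internally, for leave-one-out training folds, where
    the ridge fallback keeps the fit finite).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.atleast_1d(y)) == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y have incompatible shapes")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("labels must be binary 0/1")
    if classes.size < 2 and not _allow_single_class:
        raise ValueError("both classes must be present in the labels")

    A = np.column_stack([np.ones(y.size), X])
    FIT_COUNTER.add()
    ridge_fallback = False
    if classes.size < 2:
        beta, ll, conv, it = _newton(A, y, ridge_lambda, beta0, max_iter, tol)
        ridge_fallback = True
        pen = ridge_lambda
    else:
        beta, ll, conv, it = _newton(A, y, 0.0, beta0, max_iter, tol)
        pen = 0.0
        if not conv or np.abs(beta).max() > SEPARATION_COEF:
            beta, ll, conv, it = _newton(A, y, ridge_lambda, beta0, max_iter, tol)
            ridge_fallback = True
            pen = ridge_lambda
    se, z, p = _wald(A, beta, pen)
    return LogisticFit(beta, se, z, p, ll, conv, ridge_fallback, it)


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------


def _loocv_loop(
    X: np.ndarray,
    y: np.ndarray,
    folds: Iterable[int],
    ridge_lambda: float,
    beta0: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Reference implementation: one independent fit per held-out patient."""
    folds = list(folds)
    scores = np.empty(len(folds))
    fallback = np.zeros(len(folds), dtype=bool)
    idx = np.arange(y.size)
    for j, i in enumerate(folds):
        keep = idx != i
        fit = fit_logistic(
            X[keep],
            y[keep],
            ridge_lambda=ridge_lambda,
            beta0=beta0,
            _allow_single_class=True,
        )
        scores[j] = fit.predict_proba(X[i : i + 1])[0]
        fallback[j] = fit.ridge_fallback
    return scores, fallback


def _loocv_batched(
    A: np.ndarray,
    y: np.ndarray,
    beta_full: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """All n leave-one-out Newton fits advanced simultaneously.

    Fold f maximizes the unpenalized likelihood over all rows except f,
    warm-started at the full-data solution.  Returns (B, converged_mask);
    folds that fail (non-convergence, separation, singular Hessian) are the
    caller's responsibility to refit individually.
    """
    n, m = A.shape
    B = np.tile(beta_full, (n, 1))
    mask = 1.0 - np.eye(n)
    prev_ll = np.full(n, -np.inf)
    active = np.ones(n, dtype=bool)
    converged = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        eta = np.clip(A @ B.T, -_ETA_CLIP, _ETA_CLIP)  # (rows, folds)
        P = expit(eta)
        llm = (y[:, None] * eta - np.logaddexp(0.0, eta)) * mask
        ll = llm.sum(axis=0)
        done = active & (np.abs(ll - prev_ll) < tol * (np.abs(ll) + 1.0))
        converged |= done
        active &= ~done
        prev_ll = ll
        if not active.any():
            break
        R = (y[:, None] - P) * mask
        G = A.T @ R[:, active]  # (m, n_active)
        W = (P * (1.0 - P)) * mask
        H = np.einsum("if,ip,iq->fpq", W[:, active], A, A, optimize=True)
        try:
            delta = np.linalg.solve(H, G.T[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            break  # leave remaining folds unconverged for individual refit
        B[active] += delta
    return B, converged


def loocv_scores(
    X: np.ndarray,
    y: np.ndarray,
    ridge_lambda: float = 1e-6,
    method: str = "batched",
    full_fit: LogisticFit | None = None,
) -> np.ndarray:
    """Per-patient LOOCV predicted probabilities, each from a model not
    trained on that patient.  Deterministic given the data; independent of
    patient ordering (each score travels with its patient).

    ``method="loop"`` fits every fold independently (reference path);
    ``method="batched"`` advances all folds as one batched Newton iteration,
    falling back to individual (ridge-penalized) refits for folds that do not
    converge cleanly — e.g. separable or single-class training folds.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present in the labels")
    if full_fit is None:
        full_fit = fit_logistic(X, y, ridge_lambda=ridge_lambda)

    if method == "loop":
        scores, _ = _loocv_loop(X, y, range(n), ridge_lambda, full_fit.coef)
        return np.clip(scores, 1e-12, 1.0 - 1e-12)
    if method != "batched":
        raise ValueError(f"unknown LOOCV method {method!r}")

    A = np.column_stack([np.ones(n), X])
    if full_fit.ridge_fallback:
        # whole problem is separable/ill-posed: take the reference path
        scores, _ = _loocv_loop(X, y, range(n), ridge_lambda, full_fit.coef)
        return np.clip(scores, 1e-12, 1.0 - 1e-12)

    B, converged = _loocv_batched(A, y, full_fit.coef)
    FIT_COUNTER.add(n)
    bad = ~converged | (np.abs(B).max(axis=1) > SEPARATION_COEF)
    scores = expit(np.clip(np.einsum("ij,ij->i", A, B), -_ETA_CLIP, _ETA_CLIP))
    if bad.any():
        folds = np.flatnonzero(bad)
        FIT_COUNTER.add(-folds.size)  # re-counted by the individual fits
        redo, _ = _loocv_loop(X, y, folds, ridge_lambda, full_fit.coef)
        scores[folds] = redo
    return np.clip(scores, 1e-12, 1.0 - 1e-12)


# ---------------------------------------------------------------------------
# Results and the exhaustive search estimator
# ---------------------------------------------------------------------------


@dataclass
class ClassifierResult:
    """One feature combination's LOOCV performance and full-data fit."""

    feature_names: tuple[str, ...]
    feature_idx: tuple[int, ...]
    loocv_scores: np.ndarray
    auc: float
    coef: np.ndarray  # intercept first, raw-unit log-odds
    se: np.ndarray
    pvalues: np.ndarray  # aligned with coef (intercept first)
    converged: bool
    ridge_fallback: bool

    @property
    def intercept(self) -> float:
        return float(self.coef[0])

    @property
    def odds_ratios(self) -> np.ndarray:
        """exp(coef) per feature, in inverse original units."""
        return np.exp(self.coef[1:])

    @property
    def or_ci(self) -> tuple[np.ndarray, np.ndarray]:
        """95% Wald confidence bounds on the odds ratios."""
        lo = np.exp(self.coef[1:] - 1.959963984540054 * self.se[1:])
        hi = np.exp(self.coef[1:] + 1.959963984540054 * self.se[1:])
        return lo, hi

    @property
    def wald_p(self) -> np.ndarray:
        """Per-feature Wald P-values from the full-data multivariate fit."""
        return self.pvalues[1:]


@dataclass
class TaskSpec:
    """One prediction task: outcome x feature group."""

    outcome: str  # "mortality" | "arf"
    feature_group: str  # preop_only | intraop_only | combined | nonhemo_only
    max_features: int = 5


class ExhaustiveLogisticSearch(BaseEstimator):
    """Exhaustive <=k-feature logistic-regression search scored by LOOCV AUC.

    ``fit(X, y)`` enumerates every nonempty combination of at most
    ``max_features`` columns of X, computes each combination's pooled LOOCV
    score vector and AUC, and the full-data multivariate fit (odds ratios,
    Wald P).  Results are sorted by AUC descending, ties broken by fewer
    features then lexicographic feature names.  Combinations are independent,
    so any execution order yields identical results.

    Attributes
    ----------
    results_ : list of ClassifierResult, sorted best-first.
    best_result_ : ClassifierResult
    n_fits_ : int
        Individual logistic fits performed: n_combinations * (n + 1).
    """

    def __init__(
        self,
        max_features: int = 5,
        ridge_lambda: float = 1e-6,
        include_empty: bool = False,
        loocv_method: str = "batched",
    ):
        self.max_features = max_features
        self.ridge_lambda = ridge_lambda
        self.include_empty = include_empty
        self.loocv_method = loocv_method

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if np.unique(y).size < 2:
            raise ValueError("both classes must be present in the labels")
        n, m = X.shape
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(m)]
        self.feature_names_in_ = list(feature_names)
        start = FIT_COUNTER.count
        results: list[ClassifierResult] = []
        for combo in enumerate_combinations(m, self.max_features, self.include_empty):
            Xc = X[:, combo] if combo else np.empty((n, 0))
            full = fit_logistic(Xc, y, ridge_lambda=self.ridge_lambda)
            scores = loocv_scores(
                Xc,
                y,
                ridge_lambda=self.ridge_lambda,
                method=self.loocv_method,
                full_fit=full,
            )
            results.append(
                ClassifierResult(
                    feature_names=tuple(feature_names[j] for j in combo),
                    feature_idx=tuple(combo),
                    loocv_scores=scores,
                    auc=_auc(scores, y),
                    coef=full.coef,
                    se=full.se,
                    pvalues=full.pvalues,
                    converged=full.converged,
                    ridge_fallback=full.ridge_fallback,
                )
            )
        results.sort(key=lambda r: (-r.auc, len(r.feature_names), r.feature_names))
        self.results_ = results
        self.best_result_ = results[0]
        self.n_fits_ = FIT_COUNTER.count - start
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "best_result_")
        X = check_array(X, dtype=float)
        best = self.best_result_
        A = np.column_stack([np.ones(len(X)), X[:, list(best.feature_idx)]])
        p1 = expit(np.clip(A @ best.coef, -_ETA_CLIP, _ETA_CLIP))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def to_frame(self, top_n: int | None = None):
        """Tabulate results: one row per classifier with AUC, ORs, CIs, P."""
        import pandas as pd

        check_is_fitted(self, "results_")
        rows = []
        for r in self.results_[: top_n or len(self.results_)]:
            lo, hi = r.or_ci
            rows.append(
                {
                    "features": "+".join(r.feature_names) or "(intercept only)",
                    "n_features": len(r.feature_names),
                    "auc": r.auc,
                    "odds_ratios": ";".join(f"{v:.6g}" for v in r.odds_ratios),
                    "or_ci_low": ";".join(f"{v:.6g}" for v in lo),
                    "or_ci_high": ";".join(f"{v:.6g}" for v in hi),
                    "wald_p": ";".join(f"{v:.4g}" for v in r.wald_p),
                    "converged": r.converged,
                    "ridge_fallback": r.ridge_fallback,
                }
            )
        return pd.DataFrame(rows)


def run_task(
    task: TaskSpec,
    matrix: FeatureMatrix,
    labels: np.ndarray,
    ridge_lambda: float = 1e-6,
    loocv_method: str = "batched",
) -> list[ClassifierResult]:
    """Run one task's exhaustive search on a matrix already restricted to the
    task's selected feature subset."""
    search = ExhaustiveLogisticSearch(
        max_features=task.max_features,
        ridge_lambda=ridge_lambda,
        loocv_method=loocv_method,
    )
    search.fit(matrix.values, labels, feature_names=matrix.feature_names)
    return search.results_
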