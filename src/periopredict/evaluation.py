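"""ROC/AUC evaluation: Mann-Whitney AUC, BCa bootstrap intervals, DeLong
paired comparisons and the feature-inclusion-frequency summary.

The AUC is computed as the normalized Mann-Whitney U statistic
(#concordant case-control pairs + half-ties) / (n1*n0), equivalent to the
trapezoidal area under the ROC curve over all distinct score thresholds.
Confidence intervals resample the fixed per-patient LOOCV (score, label)
pairs with replacement and apply the bias-corrected-and-accelerated (BCa)
adjustment with 1,000 replicates by default.  Best-per-task AUCs on the same
patients are compared with the DeLong test for correlated ROC curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

__all__ = [
    "RocResult",
    "DeLongResult",
    "auc",
    "bca_ci",
    "delong_test",
    "inclusion_frequency",
    "compare_tasks",
    "prevalence",
]


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if s.size != y.size:
        raise ValueError("scores and labels must have equal length")
    if not np.all(np.isin(np.unique(y), (0.0, 1.0))):
        raise ValueError("labels must be binary 0/1")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    return s, y


def prevalence(labels) -> float:
    """Fraction of positive labels."""
    y = np.asarray(labels, dtype=float).ravel()
    return float(y.mean())


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Equals (#pairs where a case outscores a control + 0.5 * #ties) / (n1*n0).
    """
    s, y = _check_scores_labels(scores, labels)
    r = rankdata(s)
    n1 = int(y.sum())
    n0 = y.size - n1
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _auc_rows(S: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Row-wise AUC for a batch of (scores, labels) resamples.

    Rows with a single class yield NaN.
    """
    r = rankdata(S, axis=1)
    n = S.shape[1]
    n1 = L.sum(axis=1)
    n0 = n - n1
    with np.errstate(invalid="ignore", divide="ignore"):
        out = ((r * L).sum(axis=1) - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    out[(n1 == 0) | (n0 == 0)] = np.nan
    return out


@dataclass
class RocResult:
    """Point AUC with a 95% BCa bootstrap confidence interval."""

    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n_redrawn: int = 0  # single-class bootstrap replicates that were redrawn


def bca_ci(
    scores,
    labels,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> RocResult:
    """95% (by default) BCa bootstrap CI for the AUC of a score vector.

    Patients — (score, label) pairs — are resampled with replacement;
    replicates that draw a single class are redrawn and counted.  The bias
    correction z0 comes from the fraction of bootstrap AUCs below the point
    estimate and the acceleration from jackknife skewness; both shift the
    percentile endpoints in the usual way.  Deterministic given ``seed``.
    """
    s, y = _check_scores_labels(scores, labels)
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for stable BCa endpoints")
    n = s.size
    rng = np.random.default_rng(seed)
    theta = auc(s, y)

    boots = np.empty(n_boot)
    filled = 0
    n_redrawn = 0
    while filled < n_boot:
        need = n_boot - filled
        idx = rng.integers(0, n, size=(need, n))
        vals = _auc_rows(s[idx], y[idx])
        good = ~np.isnan(vals)
        n_redrawn += int((~good).sum())
        k = int(good.sum())
        boots[filled : filled + k] = vals[good]
        filled += k
    if n_redrawn:
        warnings.warn(
            f"{n_redrawn} single-class bootstrap replicates redrawn", stacklevel=2
        )

    # bias correction: proportion of replicates below the point estimate
    prop = np.mean(boots < theta)
    prop = min(max(prop, 0.5 / n_boot), 1.0 - 0.5 / n_boot)
    z0 = ndtri(prop)

    # acceleration from the jackknife distribution of the AUC
    jack = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        yi = y[keep]
        jack[i] = auc(s[keep], yi) if 0 < yi.sum() < yi.size else theta
        keep[i] = True
    d = jack.mean() - jack
    denom = (d**2).sum() ** 1.5
    a = (d**3).sum() / (6.0 * denom) if denom > 0 else 0.0

    z_lo, z_hi = ndtri(alpha / 2.0), ndtri(1.0 - alpha / 2.0)
    a1 = ndtr(z0 + (z0 + z_lo) / (1.0 - a * (z0 + z_lo)))
    a2 = ndtr(z0 + (z0 + z_hi) / (1.0 - a * (z0 + z_hi)))
    lo, hi = np.quantile(boots, [a1, a2])
    return RocResult(theta, float(lo), float(hi), n_boot, seed, n_redrawn)


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------


def _placements(s: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-case and per-control placement values V10, V01 and the AUC."""
    cases = s[y == 1]
    ctrls = s[y == 0]
    cmp = (cases[:, None] > ctrls[None, :]) + 0.5 * (cases[:, None] == ctrls[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0), float(cmp.mean())


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    z: float
    p_value: float
    var_diff: float
    degenerate: bool = False  # identical scores / zero variance


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """DeLong paired comparison of two AUCs measured on the same patients.

    The variance of the AUC difference is built from the empirical
    covariances of the per-case and per-control placement values of the two
    score vectors; the two-sided P comes from a normal reference.  Identical
    score vectors (zero variance of the difference) return P = 1, flagged.
    """
    sa, y = _check_scores_labels(scores_a, labels)
    sb, y2 = _check_scores_labels(scores_b, labels)
    if not np.array_equal(y, y2):
        raise ValueError("paired design requires identical labels")
    n1 = int(y.sum())
    n0 = y.size - n1
    v10a, v01a, auc_a = _placements(sa, y)
    v10b, v01b, auc_b = _placements(sb, y)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n0
    if var <= 0 or np.isclose(var, 0.0):
        return DeLongResult(auc_a, auc_b, 0.0, 1.0, max(var, 0.0), degenerate=True)
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * (1.0 - ndtr(abs(z)))
    return DeLongResult(auc_a, auc_b, float(z), float(p), float(var))


def delong_variance(scores, labels) -> float:
    """DeLong variance of a single AUC (placement-value form)."""
    s, y = _check_scores_labels(scores, labels)
    n1 = int(y.sum())
    n0 = y.size - n1
    v10, v01, _ = _placements(s, y)
    return float(np.var(v10, ddof=1) / n1 + np.var(v01, ddof=1) / n0)


# ---------------------------------------------------------------------------
# Inclusion frequency and task comparison
# ---------------------------------------------------------------------------


def inclusion_frequency(
    results: Sequence,
    auc_threshold: float = 0.7,
    p_threshold: float = 0.05,
    all_features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """How often each feature enters high-performing classifiers significantly.

    Counts, over classifiers with AUC > ``auc_threshold``, the ones that
    include each feature with full-fit Wald P < ``p_threshold``, split by the
    direction of the odds ratio.  Features never included at significance are
    listed with zero.  Rows sorted by count descending.
    """
    counts: dict[str, list[int]] = {}
    pool = set(all_features or [])
    n_high = 0
    for r in results:
        pool.update(r.feature_names)
        if r.auc <= auc_threshold:
            continue
        n_high += 1
        for name, orat, p in zip(r.feature_names, r.odds_ratios, r.wald_p):
            if p < p_threshold:
                c = counts.setdefault(name, [0, 0])
                c[0 if orat > 1.0 else 1] += 1
    if n_high == 0:
        warnings.warn(
            f"no classifier exceeds AUC {auc_threshold:g}; inclusion-frequency "
            "table is empty",
            stacklevel=2,
        )
    rows = []
    for name in sorted(pool):
        gt, lt = counts.get(name, (0, 0))
        tot = gt + lt
        rows.append(
            {
                "feature": name,
                "n_high_performers": tot,
                "frac_or_gt_1": gt / tot if tot else 0.0,
                "frac_or_lt_1": lt / tot if tot else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            ["n_high_performers", "feature"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


def compare_tasks(
    best_scores: Mapping[str, np.ndarray],
    labels,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise DeLong comparisons of the best classifiers across tasks.

    ``best_scores`` maps task name -> that task's best LOOCV score vector on
    the shared patient set.  Returns one row per unordered task pair.
    """
    y = np.asarray(labels, dtype=float).ravel()
    names = list(best_scores)
    for name in names:
        if len(np.asarray(best_scores[name]).ravel()) != y.size:
            raise ValueError(
                f"task {name!r}: score vector length does not match the labels "
                "(tasks must share one patient set)"
            )
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = delong_test(best_scores[names[i]], best_scores[names[j]], y)
            rows.append(
                {
                    "task_a": names[i],
                    "task_b": names[j],
                    "auc_a": res.auc_a,
                    "auc_b": res.auc_b,
                    "z": res.z,
                    "p_value": res.p_value,
                    "significant": res.p_value < alpha,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["task_a", "task_b", "auc_a", "auc_b", "z", "p_value", "significant"],
    )
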