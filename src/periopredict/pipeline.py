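"""End-to-end analysis: filters -> features -> subset selection -> exhaustive
search -> evaluation, for one outcome across the four feature-group tasks.

Subset selection runs once per feature group on all records with complete
features, irrespective of outcome labels, so both outcomes share the same
subsets; prediction then uses the records that additionally carry the
requested outcome label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import PatientRecord, apply_inclusion_filters, write_exclusion_log
from .evaluation import RocResult, bca_ci, compare_tasks, inclusion_frequency
from .features import GROUPS, build_feature_matrix
from .search import ClassifierResult, ExhaustiveLogisticSearch, TaskSpec, run_task
from .selection import SubsetSelectionResult, select_subset

__all__ = ["GROUP_MAP", "TaskReport", "run_outcome_analysis", "derive_seed"]

#: Feature groups entering each of the four prediction tasks.
GROUP_MAP: dict[str, tuple[str, ...]] = {
    "preop_only": ("preoperative",),
    "intraop_only": ("hemodynamic", "nonhemodynamic"),
    "combined": GROUPS,
    "nonhemo_only": ("nonhemodynamic",),
}


def derive_seed(seed: int, *keys) -> int:
    """Deterministic child seed from a top-level seed and operation keys."""
    ent = [int(seed)] + [
        int.from_bytes(str(k).encode(), "little") % (2**32) for k in keys
    ]
    return int(np.random.SeedSequence(ent).generate_state(1)[0] % (2**31))


@dataclass
class TaskReport:
    """Ranked classifiers and inference for one outcome across tasks."""

    outcome: str
    n_patients: int
    labels: np.ndarray
    selections: dict[str, SubsetSelectionResult]
    results: dict[str, list[ClassifierResult]]  # top_n per task, best-first
    best: dict[str, ClassifierResult]
    best_ci: dict[str, RocResult]
    pairwise: pd.DataFrame
    inclusion: dict[str, pd.DataFrame]
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    def best_table(self) -> pd.DataFrame:
        """Best classifier per task: AUC with CI, features, ORs, Wald P."""
        rows = []
        for task, r in self.best.items():
            ci = self.best_ci[task]
            lo, hi = r.or_ci
            for name, orat, l, h, p in zip(
                r.feature_names, r.odds_ratios, lo, hi, r.wald_p
            ):
                rows.append(
                    {
                        "task": task,
                        "best_auc": r.auc,
                        "auc_ci_low": ci.ci_low,
                        "auc_ci_high": ci.ci_high,
                        "feature": name,
                        "odds_ratio": orat,
                        "or_ci_low": l,
                        "or_ci_high": h,
                        "wald_p": p,
                    }
                )
        return pd.DataFrame(rows)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.best_table().to_csv(out / f"{self.outcome}_best_classifiers.csv", index=False)
        self.pairwise.to_csv(out / f"{self.outcome}_pairwise_delong.csv", index=False)
        for task, df in self.inclusion.items():
            df.to_csv(out / f"{self.outcome}_{task}_inclusion_frequency.csv", index=False)
        for task, sel in self.selections.items():
            sel.to_frame().to_csv(out / f"{self.outcome}_{task}_subset.csv", index=False)
        if self.exclusion_log:
            write_exclusion_log(self.exclusion_log, out / f"{self.outcome}_exclusions.csv")


def run_outcome_analysis(
    records: Sequence[PatientRecord],
    outcome: str,
    tasks: Iterable[str] = tuple(GROUP_MAP),
    cond_cap: float = 15.0,
    max_features: int = 5,
    n_boot: int = 1000,
    seed: int = 0,
    signals: Sequence[str] | None = None,
    min_signal_minutes: float = 180.0,
    top_n: int = 100,
    auc_threshold: float = 0.7,
    loocv_method: str = "batched",
) -> TaskReport:
    """Run the full prediction analysis for one outcome.

    Returns a TaskReport with, per task: the label-blind selected subset,
    the ranked classifiers (top ``top_n`` retained with score vectors), the
    best classifier's BCa AUC interval, pairwise DeLong comparisons of best
    AUCs, and the feature-inclusion-frequency tables.
    """
    tasks = list(tasks)
    unknown = set(tasks) - set(GROUP_MAP)
    if unknown:
        raise ValueError(f"unknown tasks: {sorted(unknown)}")

    # label-blind set for subset selection; labelled set for prediction
    sel_records, _ = apply_inclusion_filters(
        records, None, min_signal_minutes, required_signals=signals
    )
    pred_records, excl = apply_inclusion_filters(
        records, outcome, min_signal_minutes, required_signals=signals
    )
    labels = np.array([r.outcomes[outcome] for r in pred_records], dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError(f"outcome {outcome!r}: both classes required for prediction")

    selections: dict[str, SubsetSelectionResult] = {}
    results: dict[str, list[ClassifierResult]] = {}
    best: dict[str, ClassifierResult] = {}
    best_ci: dict[str, RocResult] = {}
    inclusion: dict[str, pd.DataFrame] = {}

    for task in tasks:
        groups = GROUP_MAP[task]
        sel_matrix = build_feature_matrix(sel_records, groups, signals=signals)
        sel = select_subset(sel_matrix, cond_cap=cond_cap)
        selections[task] = sel

        pred_matrix = build_feature_matrix(pred_records, groups, signals=signals)
        pool = pred_matrix.select(sel.chosen_features)
        task_results = run_task(
            TaskSpec(outcome, task, max_features), pool, labels, loocv_method=loocv_method
        )
        best[task] = task_results[0]
        best_ci[task] = bca_ci(
            task_results[0].loocv_scores,
            labels,
            n_boot=n_boot,
            seed=derive_seed(seed, "bca", outcome, task),
        )
        inclusion[task] = inclusion_frequency(
            task_results, auc_threshold=auc_threshold, all_features=pool.feature_names
        )
        results[task] = task_results[:top_n]

    pairwise = compare_tasks(
        {t: best[t].loocv_scores for t in tasks}, labels
    )
    return TaskReport(
        outcome=outcome,
        n_patients=len(pred_records),
        labels=labels,
        selections=selections,
        results=results,
        best=best,
        best_ci=best_ci,
        pairwise=pairwise,
        inclusion=inclusion,
        exclusion_log=excl,
    )
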