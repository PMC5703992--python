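"""Waveform feature extraction and feature-matrix assembly.

From every hemodynamic signal a median is extracted; from the ten continuous
signals additionally the median absolute deviation (MAD, unscaled) and the
time-integrated exposure area beyond the signal's normal threshold, in
signal-unit·minutes.  Together with 15 preoperative features and 5
non-hemodynamic intraoperative features (four blood-product volumes in mL/kg
and surgery duration in minutes) this yields the full 56-column feature
matrix: 15 preoperative + 36 hemodynamic (16 medians + 10 MADs + 10 areas)
+ 5 non-hemodynamic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .signals import (
    CONTINUOUS,
    SIGNALS,
    ThresholdSpec,
    WaveformSignal,
    area_feature_name,
    sample_intervals_minutes,
)

__all__ = [
    "PREOP_FEATURES",
    "NONHEMO_FEATURES",
    "GROUPS",
    "FeatureMatrix",
    "feature_columns",
    "extract_median",
    "extract_mad",
    "extract_exposure_area",
    "build_feature_matrix",
    "normalize_to_body_mass",
]

#: Preoperative clinical features (registry order = column order).
PREOP_FEATURES: list[str] = [
    "age",
    "male",
    "bmi",
    "diabetes",
    "hypertension",
    "smoking",
    "asa_class",
    "meld",
    "marginal_donor",
    "piggyback",
    "inr",
    "direct_bilirubin",
    "total_bilirubin",
    "albumin",
    "creatinine",
]

BINARY_PREOP: frozenset[str] = frozenset(
    ["male", "diabetes", "hypertension", "smoking", "marginal_donor", "piggyback"]
)

#: Non-hemodynamic intraoperative features: blood-product volumes per kg
#: body mass and overall surgery duration.
NONHEMO_FEATURES: list[str] = [
    "whole_blood_ml_kg",
    "ffp_ml_kg",
    "platelets_ml_kg",
    "rbc_ml_kg",
    "surgery_duration_min",
]

BLOOD_PRODUCT_FEATURES: list[str] = NONHEMO_FEATURES[:4]

PREOPERATIVE = "preoperative"
HEMODYNAMIC = "hemodynamic"
NONHEMODYNAMIC = "nonhemodynamic"
GROUPS: tuple[str, ...] = (PREOPERATIVE, HEMODYNAMIC, NONHEMODYNAMIC)


def feature_columns(
    groups: Iterable[str] = GROUPS,
    thresholds: Mapping[str, ThresholdSpec] | None = None,
    signals: Iterable[str] | None = None,
) -> list[tuple[str, str]]:
    """Canonical ``(feature_name, group_tag)`` columns for the requested groups.

    Hemodynamic columns follow signal-registry order, per signal: median,
    then (continuous only) MAD and exposure area.  ``thresholds`` may
    override the registry threshold for individual signals (this changes the
    area feature's name accordingly).  ``signals`` restricts the hemodynamic
    block to a subset of the registry (default: all 16 signals, giving the
    full 56-column matrix when all groups are requested).
    """
    groups = set(groups)
    unknown = groups - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown feature groups: {sorted(unknown)}")
    use_signals = set(SIGNALS if signals is None else signals)
    cols: list[tuple[str, str]] = []
    if PREOPERATIVE in groups:
        cols += [(f, PREOPERATIVE) for f in PREOP_FEATURES]
    if HEMODYNAMIC in groups:
        for sid, sdef in SIGNALS.items():
            if sid not in use_signals:
                continue
            cols.append((f"median_{sid}", HEMODYNAMIC))
            if sdef.kind == CONTINUOUS:
                spec = (thresholds or {}).get(sid, sdef.threshold)
                cols.append((f"mad_{sid}", HEMODYNAMIC))
                cols.append((area_feature_name(sid, spec), HEMODYNAMIC))
    if NONHEMODYNAMIC in groups:
        cols += [(f, NONHEMODYNAMIC) for f in NONHEMO_FEATURES]
    return cols


def extract_median(signal: WaveformSignal) -> float:
    """Sample median of the signal values (mean of the central pair for even n)."""
    if signal.n_samples == 0:
        raise ValueError(f"signal {signal.signal_id}: cannot take median of empty series")
    return float(np.median(signal.values))


def extract_mad(signal: WaveformSignal) -> float:
    """Median absolute deviation, median(|x - median(x)|), without any
    normal-consistency scaling.  Defined only for continuous signals."""
    if signal.kind != CONTINUOUS:
        raise ValueError(
            f"signal {signal.signal_id}: MAD is defined only for continuous signals"
        )
    if signal.n_samples == 0:
        raise ValueError(f"signal {signal.signal_id}: cannot take MAD of empty series")
    med = np.median(signal.values)
    return float(np.median(np.abs(signal.values - med)))


def extract_exposure_area(
    signal: WaveformSignal,
    spec: ThresholdSpec | None = None,
    max_gap_s: float = 60.0,
) -> float:
    """Time-integrated exposure beyond the normal threshold, in unit·minutes.

    Each sample contributes a rectangle ``max(0, s*(value - threshold)) * dt``
    where ``s`` is +1 for harmful-above and -1 for harmful-below thresholds
    and ``dt`` is the gap-capped holding time of the sample in minutes (the
    monitors emit step-held values; the last sample is held for the median
    inter-sample interval).  Always >= 0.
    """
    if signal.kind != CONTINUOUS:
        raise ValueError(
            f"signal {signal.signal_id}: exposure area requires a continuous signal"
        )
    if signal.n_samples < 2:
        raise ValueError(
            f"signal {signal.signal_id}: exposure area requires >= 2 samples"
        )
    if spec is None:
        spec = signal.threshold
    if spec is None:
        raise ValueError(f"signal {signal.signal_id}: no threshold specification")
    gaps = np.diff(signal.times)
    if np.all(gaps > max_gap_s):
        warnings.warn(
            f"signal {signal.signal_id}: every inter-sample gap exceeds the "
            f"{max_gap_s:g} s cap; area computed from capped intervals only",
            stacklevel=2,
        )
    dt_min = sample_intervals_minutes(signal.times, max_gap_s)
    excess = np.maximum(0.0, spec.sign * (signal.values - spec.threshold))
    return float(np.sum(excess * dt_min))


def normalize_to_body_mass(volume_ml: float, weight_kg: float) -> float:
    """Convert a raw administered volume in mL to mL/kg body mass."""
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    return volume_ml / weight_kg


@dataclass
class FeatureMatrix:
    """Patients x named-features grid with per-feature group tags.

    Constructed only from records that passed the inclusion filters, so it
    carries no missing cells.
    """

    patient_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # shape (n_patients, n_features)
    group_tags: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patient_ids), len(self.feature_names)):
            raise ValueError("values shape does not match ids/names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite cells")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        """Sub-matrix with the given columns, in the given order."""
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            list(self.patient_ids),
            list(names),
            self.values[:, idx].copy(),
            {n: self.group_tags[n] for n in names},
        )

    def restrict_groups(self, groups: Iterable[str]) -> "FeatureMatrix":
        groups = set(groups)
        names = [n for n in self.feature_names if self.group_tags[n] in groups]
        return self.select(names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.patient_ids, name="patient_id"),
            columns=self.feature_names,
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def build_feature_matrix(
    records: Sequence,
    groups: Iterable[str] = GROUPS,
    thresholds: Mapping[str, ThresholdSpec] | None = None,
    max_gap_s: float = 60.0,
    signals: Iterable[str] | None = None,
) -> FeatureMatrix:
    """Assemble the feature matrix for records that passed inclusion filtering.

    Columns are exactly the canonical features of the requested groups in
    deterministic order.  A required feature missing from any record is a
    contract violation (the record should have been excluded) and raises.
    """
    cols = feature_columns(groups, thresholds, signals)
    use_signals = set(SIGNALS if signals is None else signals)
    groups = set(groups)
    ids = [r.patient_id for r in records]
    out = np.full((len(ids), len(cols)), np.nan)

    for i, rec in enumerate(records):
        row: dict[str, float] = {}
        if PREOPERATIVE in groups:
            for f in PREOP_FEATURES:
                v = rec.preop.get(f)
                if v is None:
                    raise ValueError(
                        f"patient {rec.patient_id}: preoperative feature {f!r} "
                        "missing; records must pass inclusion filters first"
                    )
                row[f] = float(v)
        if NONHEMODYNAMIC in groups:
            for f in NONHEMO_FEATURES:
                v = rec.nonhemo.get(f)
                if v is None:
                    raise ValueError(
                        f"patient {rec.patient_id}: feature {f!r} missing; "
                        "records must pass inclusion filters first"
                    )
                row[f] = float(v)
        if HEMODYNAMIC in groups:
            for sid, sdef in SIGNALS.items():
                if sid not in use_signals:
                    continue
                sig = rec.waveforms.get(sid)
                if sig is None:
                    raise ValueError(
                        f"patient {rec.patient_id}: signal {sid} missing; "
                        "records must pass inclusion filters first"
                    )
                row[f"median_{sid}"] = extract_median(sig)
                if sdef.kind == CONTINUOUS:
                    spec = (thresholds or {}).get(sid, sdef.threshold)
                    row[f"mad_{sid}"] = extract_mad(sig)
                    row[area_feature_name(sid, spec)] = extract_exposure_area(
                        sig, spec, max_gap_s
                    )
        out[i] = [row[name] for name, _ in cols]

    return FeatureMatrix(ids, [n for n, _ in cols], out, dict(cols))
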