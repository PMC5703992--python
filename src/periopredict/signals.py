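"""Registry of intraoperative hemodynamic signals and their "normal" thresholds.

Sixteen variables are recorded by the bedside monitors during orthotopic liver
transplantation.  Ten are continuous time series (arterial pressure, CVP, heart
rate, SpO2, contractility, pulse-contour cardiac index, dynamic fluid-
responsiveness indices, stroke-volume and resistance indices); six are computed
only intermittently by the transpulmonary-thermodilution monitor.  Each
continuous signal carries a device "normal" threshold and a harmful direction
(e.g. CVP above 5 mmHg, SBP below 100 mmHg) used by the exposure-area feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ThresholdSpec",
    "WaveformSignal",
    "SignalDef",
    "SIGNALS",
    "CONTINUOUS_SIGNALS",
    "INTERMITTENT_SIGNALS",
    "area_feature_name",
    "sample_intervals_minutes",
    "covered_minutes",
]

CONTINUOUS = "continuous"
INTERMITTENT = "intermittent"


@dataclass(frozen=True)
class ThresholdSpec:
    """A normal threshold and the side of it considered harmful."""

    threshold: float
    direction: str  # "above" or "below": the harmful side

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise ValueError(
                f"direction must be 'above' or 'below', got {self.direction!r}"
            )

    @property
    def sign(self) -> float:
        """+1 if exposure accrues above the threshold, -1 if below."""
        return 1.0 if self.direction == "above" else -1.0


@dataclass
class WaveformSignal:
    """One patient's time-stamped series for one hemodynamic variable.

    Parameters
    ----------
    signal_id : str
        Lower-case signal name from the registry (e.g. ``"cvp"``).
    times : array-like
        Seconds from surgery start, strictly increasing.
    values : array-like
        Signal values in the registry unit, finite.
    kind : {"continuous", "intermittent"}
    threshold : ThresholdSpec, optional
        Required for continuous signals, forbidden for intermittent ones
        (the monitors define no normal threshold for the intermittent
        indices and only a median is extracted from them).
    """

    signal_id: str
    times: np.ndarray
    values: np.ndarray
    kind: str = CONTINUOUS
    threshold: ThresholdSpec | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError(f"signal {self.signal_id}: times/values must be 1-D")
        if self.times.shape != self.values.shape:
            raise ValueError(
                f"signal {self.signal_id}: times and values length mismatch"
            )
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError(
                f"signal {self.signal_id}: timestamps must be strictly increasing"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"signal {self.signal_id}: values must be finite")
        if self.kind not in (CONTINUOUS, INTERMITTENT):
            raise ValueError(f"signal {self.signal_id}: unknown kind {self.kind!r}")
        if self.kind == CONTINUOUS and self.threshold is None:
            raise ValueError(
                f"signal {self.signal_id}: continuous signals require a ThresholdSpec"
            )
        if self.kind == INTERMITTENT and self.threshold is not None:
            raise ValueError(
                f"signal {self.signal_id}: intermittent signals carry no threshold"
            )

    @property
    def n_samples(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class SignalDef:
    """Registry entry: unit, kind and threshold for one monitored variable."""

    signal_id: str
    unit: str
    kind: str
    threshold: ThresholdSpec | None = None


# Registry order is the canonical (alphabetical-by-abbreviation) column order
# used when assembling the hemodynamic block of the feature matrix.
SIGNALS: dict[str, SignalDef] = {
    d.signal_id: d
    for d in [
        SignalDef("sbp", "mmHg", CONTINUOUS, ThresholdSpec(100.0, "below")),
        SignalDef("cvp", "mmHg", CONTINUOUS, ThresholdSpec(5.0, "above")),
        SignalDef("hr", "bpm", CONTINUOUS, ThresholdSpec(100.0, "above")),
        SignalDef("spo2", "%", CONTINUOUS, ThresholdSpec(90.0, "below")),
        SignalDef("cfi", "1/min", INTERMITTENT),
        SignalDef("dpmx", "mmHg/s", CONTINUOUS, ThresholdSpec(642.0, "below")),
        SignalDef("elwi", "mL/kg", INTERMITTENT),
        SignalDef("gedi", "mL/m2", INTERMITTENT),
        SignalDef("gef", "%", INTERMITTENT),
        SignalDef("itbi", "mL/min/m2", INTERMITTENT),
        SignalDef("pcci", "L/min/m2", CONTINUOUS, ThresholdSpec(3.0, "below")),
        SignalDef("ppv", "%", CONTINUOUS, ThresholdSpec(10.0, "above")),
        SignalDef("pvpi", "", INTERMITTENT),
        # SVI: exposure to reduced stroke volume, i.e. below 40 mL/m2.
        SignalDef("svi", "mL/m2", CONTINUOUS, ThresholdSpec(40.0, "below")),
        SignalDef("svri", "dyn.s.cm-5.m2", CONTINUOUS, ThresholdSpec(1700.0, "below")),
        SignalDef("svv", "%", CONTINUOUS, ThresholdSpec(10.0, "above")),
    ]
}

CONTINUOUS_SIGNALS: list[str] = [s for s, d in SIGNALS.items() if d.kind == CONTINUOUS]
INTERMITTENT_SIGNALS: list[str] = [
    s for s, d in SIGNALS.items() if d.kind == INTERMITTENT
]


def area_feature_name(signal_id: str, spec: ThresholdSpec) -> str:
    """Machine name for an exposure-area feature, e.g. ``area_cvp_gt_5``."""
    op = "gt" if spec.direction == "above" else "lt"
    thr = spec.threshold
    thr_s = str(int(thr)) if float(thr).is_integer() else str(thr).replace(".", "p")
    return f"area_{signal_id}_{op}_{thr_s}"


def sample_intervals_minutes(times: np.ndarray, max_gap_s: float = 60.0) -> np.ndarray:
    """Per-sample holding times in minutes under the gap-capping rule.

    Each sample is held until the next one, with the holding time capped at
    ``max_gap_s`` so that monitor dropouts do not accrue exposure; the last
    sample is held for the (capped) median inter-sample interval.  For a
    series sampled regularly every ``d`` seconds this sums to ``n*d`` seconds.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return np.empty(0)
    if times.size == 1:
        return np.zeros(1)
    gaps = np.diff(times)
    cap = float(max_gap_s)
    dt = np.minimum(gaps, cap)
    last = min(float(np.median(gaps)), cap)
    return np.concatenate([dt, [last]]) / 60.0


def covered_minutes(times: np.ndarray, max_gap_s: float = 60.0) -> float:
    """Total recording coverage in minutes, gap-capped (not last-minus-first)."""
    return float(sample_intervals_minutes(times, max_gap_s).sum())
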