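"""Cohort and waveform I/O plus record-inclusion filtering.

File contract
-------------
Cohort table: CSV, one row per patient; columns ``patient_id``, the 15
preoperative features, the 5 non-hemodynamic features and one column per
outcome (``mortality``, ``arf``).  Missing values are empty cells and are
carried as missing, never imputed.

Waveforms: long-format CSV with header ``patient_id,signal,time_s,value``,
one row per sample, timestamps in seconds from surgery start.

A record enters an analysis only if all preoperative features and all
blood-product volumes are present, every continuous hemodynamic signal
carries at least 180 minutes of gap-capped coverage (intermittent indices
need only one sample), and the requested outcome label is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import (
    BINARY_PREOP,
    BLOOD_PRODUCT_FEATURES,
    NONHEMO_FEATURES,
    PREOP_FEATURES,
)
from .signals import CONTINUOUS, SIGNALS, WaveformSignal, covered_minutes

__all__ = [
    "PatientRecord",
    "ParseError",
    "OUTCOMES",
    "load_cohort",
    "write_cohort",
    "apply_inclusion_filters",
    "write_exclusion_log",
]

OUTCOMES: tuple[str, ...] = ("mortality", "arf")


class ParseError(ValueError):
    """Raised when an input file violates the documented column contract."""


@dataclass
class PatientRecord:
    """All data for one patient: preoperative features, non-hemodynamic
    intraoperative features, binary outcomes and hemodynamic waveforms.

    Missing scalar values are represented by absent keys (or ``None``).
    """

    patient_id: str
    preop: dict[str, float] = field(default_factory=dict)
    nonhemo: dict[str, float] = field(default_factory=dict)
    outcomes: dict[str, int] = field(default_factory=dict)
    waveforms: dict[str, WaveformSignal] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        for f in BINARY_PREOP & self.preop.keys():
            if self.preop[f] not in (0, 1):
                raise ValueError(
                    f"patient {self.patient_id}: binary feature {f!r} must be 0/1, "
                    f"got {self.preop[f]!r}"
                )
        for f in BLOOD_PRODUCT_FEATURES:
            v = self.nonhemo.get(f)
            if v is not None and v < 0:
                raise ValueError(
                    f"patient {self.patient_id}: blood-product volume {f!r} "
                    f"must be >= 0, got {v}"
                )
        dur = self.nonhemo.get("surgery_duration_min")
        if dur is not None and dur <= 0:
            raise ValueError(
                f"patient {self.patient_id}: surgery duration must be > 0, got {dur}"
            )
        for name, v in self.outcomes.items():
            if v not in (0, 1):
                raise ValueError(
                    f"patient {self.patient_id}: outcome {name!r} must be 0/1, got {v!r}"
                )


def _clean_row(row: pd.Series, fields: Sequence[str]) -> dict[str, float]:
    out: dict[str, float] = {}
    for f in fields:
        if f in row.index and pd.notna(row[f]):
            out[f] = float(row[f])
    return out


def load_cohort(
    cohort_path, waveform_path=None, schema: Mapping[str, str] | None = None
) -> list[PatientRecord]:
    """Read cohort and waveform files into validated PatientRecords.

    ``schema`` optionally maps canonical column names to the names used in
    the files.  Unknown signal names, duplicate samples, and non-monotone
    timestamps are rejected with errors naming the offending patient/signal.
    """
    rename = {v: k for k, v in (schema or {}).items()}
    try:
        cohort = pd.read_csv(cohort_path, dtype={"patient_id": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse cohort file {cohort_path}: {exc}") from exc
    cohort = cohort.rename(columns=rename)
    if "patient_id" not in cohort.columns:
        raise ParseError(f"cohort file {cohort_path} lacks a 'patient_id' column")
    if cohort["patient_id"].duplicated().any():
        dup = cohort.loc[cohort["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ParseError(f"duplicate patient_id {dup!r} in cohort file")

    records: dict[str, PatientRecord] = {}
    known = set(PREOP_FEATURES) | set(NONHEMO_FEATURES) | set(OUTCOMES)
    meta_cols = [c for c in cohort.columns if c != "patient_id" and c not in known]
    for _, row in cohort.iterrows():
        rec = PatientRecord(
            patient_id=str(row["patient_id"]),
            preop=_clean_row(row, PREOP_FEATURES),
            nonhemo=_clean_row(row, NONHEMO_FEATURES),
            outcomes={k: int(v) for k, v in _clean_row(row, OUTCOMES).items()},
            meta={c: row[c] for c in meta_cols if pd.notna(row[c])},
        )
        rec.validate()
        records[rec.patient_id] = rec

    if waveform_path is not None:
        _attach_waveforms(records, waveform_path)
    return list(records.values())


def _attach_waveforms(records: dict[str, PatientRecord], waveform_path) -> None:
    try:
        wf = pd.read_csv(
            waveform_path, dtype={"patient_id": str, "signal": str}
        )
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"cannot parse waveform file {waveform_path}: {exc}") from exc
    required = {"patient_id", "signal", "time_s", "value"}
    if not required.issubset(wf.columns):
        raise ParseError(
            f"waveform file {waveform_path} must have columns "
            "patient_id,signal,time_s,value"
        )
    for (pid, sid), grp in wf.groupby(["patient_id", "signal"], sort=False):
        if sid not in SIGNALS:
            raise ParseError(f"patient {pid}: unknown signal name {sid!r}")
        if pid not in records:
            raise ParseError(f"waveform file references unknown patient {pid!r}")
        times = grp["time_s"].to_numpy(float)
        if pd.Series(times).duplicated().any():
            raise ParseError(f"patient {pid}: duplicate timestamp in signal {sid}")
        if np.any(np.diff(times) < 0):
            raise ParseError(
                f"patient {pid}: non-monotone timestamps in signal {sid}"
            )
        sdef = SIGNALS[sid]
        records[pid].waveforms[sid] = WaveformSignal(
            sid, times, grp["value"].to_numpy(float), sdef.kind, sdef.threshold
        )


def write_cohort(
    records: Iterable[PatientRecord], cohort_path, waveform_path=None
) -> None:
    """Write records back to the CSV contract (round-trips with load_cohort)."""
    records = list(records)
    rows = []
    for r in records:
        row: dict = {"patient_id": r.patient_id}
        row.update(r.preop)
        row.update(r.nonhemo)
        row.update(r.outcomes)
        row.update(r.meta)
        rows.append(row)
    cols = ["patient_id"] + PREOP_FEATURES + NONHEMO_FEATURES + list(OUTCOMES)
    extra = sorted({k for row in rows for k in row} - set(cols))
    pd.DataFrame(rows).reindex(columns=cols + extra).to_csv(cohort_path, index=False)

    if waveform_path is not None:
        parts = []
        for r in records:
            for sid, sig in r.waveforms.items():
                parts.append(
                    pd.DataFrame(
                        {
                            "patient_id": r.patient_id,
                            "signal": sid,
                            "time_s": sig.times,
                            "value": sig.values,
                        }
                    )
                )
        if parts:
            pd.concat(parts, ignore_index=True).to_csv(waveform_path, index=False)
        else:  # still emit a valid header
            pd.DataFrame(columns=["patient_id", "signal", "time_s", "value"]).to_csv(
                waveform_path, index=False
            )


def _first_exclusion_reason(
    rec: PatientRecord,
    outcome: str | None,
    min_signal_minutes: float,
    max_gap_s: float,
    required_signals: Iterable[str],
) -> str | None:
    for f in PREOP_FEATURES:
        if rec.preop.get(f) is None:
            return f"preoperative feature {f} missing"
    for f in BLOOD_PRODUCT_FEATURES:
        if rec.nonhemo.get(f) is None:
            return f"blood product {f} missing"
    if rec.nonhemo.get("surgery_duration_min") is None:
        return "surgery duration missing"
    for sid in required_signals:
        sdef = SIGNALS[sid]
        sig = rec.waveforms.get(sid)
        if sig is None or sig.n_samples == 0:
            return f"signal {sid} missing"
        if sdef.kind == CONTINUOUS:
            cov = covered_minutes(sig.times, max_gap_s)
            if cov < min_signal_minutes:
                return f"signal {sid} < {min_signal_minutes:g} min"
    if outcome is not None and rec.outcomes.get(outcome) is None:
        return f"outcome {outcome} missing"
    return None


def apply_inclusion_filters(
    records: Sequence[PatientRecord],
    outcome: str | None = None,
    min_signal_minutes: float = 180.0,
    max_gap_s: float = 60.0,
    required_signals: Iterable[str] | None = None,
) -> tuple[list[PatientRecord], list[tuple[str, str]]]:
    """Split records into (included, exclusion_log) for one prediction task.

    Inclusion requires complete preoperative features, complete blood-product
    volumes and surgery duration, >= ``min_signal_minutes`` of gap-capped
    coverage for every continuous hemodynamic signal (>= 1 sample for the
    intermittently computed indices), and — when ``outcome`` is given — a
    present outcome label.  ``outcome=None`` filters on feature completeness
    only (the label-blind set used for subset selection).  Each excluded
    record is logged with its first failing reason.  ``required_signals``
    defaults to the full 16-signal registry.
    """
    if outcome is not None and outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    req = list(SIGNALS if required_signals is None else required_signals)
    included: list[PatientRecord] = []
    log: list[tuple[str, str]] = []
    for rec in records:
        reason = _first_exclusion_reason(
            rec, outcome, min_signal_minutes, max_gap_s, req
        )
        if reason is None:
            included.append(rec)
        else:
            log.append((rec.patient_id, reason))
    if records and not included:
        raise ValueError(
            "no records pass the inclusion filters; check completeness of the "
            "cohort file and waveform coverage"
        )
    return included, log


def write_exclusion_log(log: Sequence[tuple[str, str]], path) -> None:
    pd.DataFrame(log, columns=["patient_id", "reason"]).to_csv(path, index=False)
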