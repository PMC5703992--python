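import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import periopredict as pp
from periopredict.signals import SIGNALS, ThresholdSpec, WaveformSignal

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_signal(signal_id, values, interval_s=10.0, times=None):
    """Build a WaveformSignal from values at a regular interval (registry
    kind/threshold attached)."""
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(values.size) * interval_s
    sdef = SIGNALS[signal_id]
    return WaveformSignal(signal_id, times, values, sdef.kind, sdef.threshold)


def make_complete_record(patient_id="P001", n_minutes=200.0, interval_s=10.0,
                         outcomes=None):
    """Hand-built record with every preoperative feature, product volume and
    all 16 signals present at constant physiological values."""
    levels = {
        "sbp": 115.0, "cvp": 7.0, "hr": 82.0, "spo2": 98.0, "dpmx": 900.0,
        "pcci": 3.4, "ppv": 8.0, "svi": 45.0, "svri": 1900.0, "svv": 8.0,
        "cfi": 4.5, "elwi": 8.0, "gedi": 700.0, "gef": 25.0, "itbi": 900.0,
        "pvpi": 2.0,
    }
    rec = pp.PatientRecord(
        patient_id=patient_id,
        preop={
            "age": 56.0, "male": 1.0, "bmi": 25.0, "diabetes": 0.0,
            "hypertension": 1.0, "smoking": 0.0, "asa_class": 3.0,
            "meld": 17.0, "marginal_donor": 0.0, "piggyback": 1.0,
            "inr": 1.5, "direct_bilirubin": 1.1, "total_bilirubin": 1.6,
            "albumin": 3.2, "creatinine": 0.9,
        },
        nonhemo={
            "whole_blood_ml_kg": 8.0, "ffp_ml_kg": 12.0,
            "platelets_ml_kg": 3.0, "rbc_ml_kg": 5.0,
            "surgery_duration_min": float(n_minutes),
        },
        outcomes=dict(
            outcomes if outcomes is not None else {"mortality": 0, "arf": 0}
        ),
    )
    n = int(n_minutes * 60 / interval_s)
    for sid, level in levels.items():
        if SIGNALS[sid].kind == "intermittent":
            times = np.arange(0.0, n_minutes * 60.0, 1800.0)
            vals = np.full(times.size, level)
            rec.waveforms[sid] = WaveformSignal(sid, times, vals, "intermittent")
        else:
            rec.waveforms[sid] = make_signal(sid, np.full(n, level), interval_s)
    return rec


@pytest.fixture
def complete_record():
    return make_complete_record()


@pytest.fixture(scope="session")
def small_cohort():
    """Simulated 80-patient reduced-panel cohort shared across tests."""
    cfg = pp.SimConfig.compact(80, seed=42)
    records, truth = pp.simulate_cohort(cfg)
    return cfg, records, truth
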