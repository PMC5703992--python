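"""Synthetic cohort generator: intraoperative waveforms, correlated
preoperative labs, blood-product volumes, and outcomes from a logistic link.

No clinical data ship with the package; every stage of the pipeline is
exercised on cohorts drawn here.  Continuous hemodynamic signals are
stationary AR(1) processes around patient-specific baselines (lag-1
correlation 0.97 at a 10 s sampling interval, so excursions across the
normal thresholds are sustained rather than white noise), clipped to
physiological ranges; the intermittently computed thermodilution indices are
emitted every 30 simulated minutes.  Preoperative labs are drawn through a
Gaussian copula so that severity measures (MELD, INR, bilirubin, creatinine,
albumin) are realistically inter-correlated and subset selection faces
genuine multicollinearity.  Binary outcomes are Bernoulli draws from a
logistic link on a chosen sparse set of true features; the intercept is
tuned by bisection so the cohort's expected prevalence hits a target
(default 18%, in line with 180-day mortality after liver transplantation).

The generator's parameters are non-clinical defaults chosen for test
utility, not physiological fidelity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.special import expit, logit

from .cohort import PatientRecord
from .features import (
    NONHEMO_FEATURES,
    PREOP_FEATURES,
    extract_exposure_area,
    extract_mad,
    extract_median,
)
from .signals import CONTINUOUS, SIGNALS, WaveformSignal, area_feature_name

__all__ = [
    "SignalModel",
    "DEFAULT_SIGNAL_MODELS",
    "SimConfig",
    "MissingnessConfig",
    "GroundTruth",
    "simulate_waveform",
    "simulate_cohort",
    "inject_missingness",
    "tune_intercept",
    "population_auc",
]


@dataclass(frozen=True)
class SignalModel:
    """AR(1) waveform model for one signal: patient baselines are drawn
    N(baseline_mean, baseline_sd); around the baseline the signal is a
    stationary AR(1) with the given marginal SD and lag-1 correlation,
    clipped to a physiological range."""

    baseline_mean: float
    baseline_sd: float
    marginal_sd: float
    rho: float = 0.97
    clip: tuple[float, float] = (-np.inf, np.inf)


DEFAULT_SIGNAL_MODELS: dict[str, SignalModel] = {
    "sbp": SignalModel(110.0, 12.0, 12.0, 0.97, (50.0, 220.0)),
    "cvp": SignalModel(7.0, 2.5, 2.5, 0.97, (0.0, 30.0)),
    "hr": SignalModel(85.0, 12.0, 10.0, 0.97, (30.0, 200.0)),
    # enough variability that transient desaturations below 90% occur
    "spo2": SignalModel(96.5, 1.5, 2.5, 0.97, (70.0, 100.0)),
    "dpmx": SignalModel(900.0, 200.0, 180.0, 0.97, (200.0, 2500.0)),
    "pcci": SignalModel(3.5, 0.7, 0.6, 0.97, (1.0, 8.0)),
    "ppv": SignalModel(9.0, 3.0, 4.0, 0.97, (0.0, 40.0)),
    "svi": SignalModel(42.0, 8.0, 7.0, 0.97, (10.0, 90.0)),
    "svri": SignalModel(1900.0, 400.0, 350.0, 0.97, (500.0, 4500.0)),
    "svv": SignalModel(9.0, 3.0, 4.0, 0.97, (0.0, 40.0)),
    # intermittent indices (median-only features): rho unused
    "cfi": SignalModel(4.5, 0.8, 0.4, 0.0, (1.0, 12.0)),
    "elwi": SignalModel(8.0, 2.0, 1.0, 0.0, (2.0, 25.0)),
    "gedi": SignalModel(700.0, 120.0, 60.0, 0.0, (300.0, 1400.0)),
    "gef": SignalModel(25.0, 5.0, 2.5, 0.0, (8.0, 50.0)),
    "itbi": SignalModel(900.0, 150.0, 75.0, 0.0, (400.0, 1800.0)),
    "pvpi": SignalModel(2.0, 0.5, 0.25, 0.0, (0.5, 6.0)),
}

# Preoperative marginals, loosely matching typical liver-transplant cohorts
# (age median ~56, MELD median ~17, INR ~1.5, albumin ~3.2 g/dL ...).
# kind: normal(mean, sd, lo, hi) | lognormal(median, sigma) | bernoulli(p)
#       | ordinal(values, probs)
_PREOP_MODELS: dict[str, tuple] = {
    "age": ("normal", 56.0, 8.0, 18.0, 75.0),
    "male": ("bernoulli", 0.74),
    "bmi": ("normal", 25.5, 3.0, 16.0, 42.0),
    "diabetes": ("bernoulli", 0.25),
    "hypertension": ("bernoulli", 0.30),
    "smoking": ("bernoulli", 0.27),
    "asa_class": ("ordinal", (1, 2, 3, 4), (0.02, 0.10, 0.75, 0.13)),
    "meld": ("lognormal", 17.0, 0.45),
    "marginal_donor": ("bernoulli", 0.45),
    "piggyback": ("bernoulli", 0.38),
    "inr": ("lognormal", 1.5, 0.25),
    "direct_bilirubin": ("lognormal", 1.1, 0.8),
    "total_bilirubin": ("lognormal", 1.5, 0.8),
    "albumin": ("normal", 3.2, 0.5, 1.5, 5.0),
    "creatinine": ("lognormal", 0.9, 0.35),
}

# Latent-normal (copula) correlations among preoperative features.
_PREOP_CORR_PAIRS: dict[tuple[str, str], float] = {
    ("meld", "inr"): 0.60,
    ("meld", "creatinine"): 0.50,
    ("meld", "total_bilirubin"): 0.60,
    ("meld", "direct_bilirubin"): 0.45,
    ("total_bilirubin", "direct_bilirubin"): 0.80,
    ("inr", "total_bilirubin"): 0.40,
    ("meld", "albumin"): -0.35,
    ("albumin", "total_bilirubin"): -0.30,
    ("age", "hypertension"): 0.30,
    ("bmi", "diabetes"): 0.30,
    ("meld", "asa_class"): 0.40,
}

# Blood products: lognormal mL/kg volumes sharing a per-patient severity
# latent, so transfusion volumes are mutually correlated: (median, sigma).
_PRODUCT_MODELS: dict[str, tuple[float, float]] = {
    "whole_blood_ml_kg": (8.0, 0.8),
    "ffp_ml_kg": (12.0, 0.7),
    "platelets_ml_kg": (3.0, 0.9),
    "rbc_ml_kg": (5.0, 0.8),
}


def _default_outcome_models() -> dict[str, dict[str, float]]:
    # Sparse truths mirroring the dominant clinical predictors: exposure to
    # elevated CVP and transfusion volume (plus creatinine for renal failure).
    return {
        "mortality": {"area_cvp_gt_5": 0.001, "whole_blood_ml_kg": 0.09},
        "arf": {
            "area_cvp_gt_5": 0.0008,
            "whole_blood_ml_kg": 0.08,
            "creatinine": 0.9,
        },
    }


def _default_prevalences() -> dict[str, float]:
    return {"mortality": 0.177, "arf": 0.21}


@dataclass
class SimConfig:
    """Study conditions for a simulated cohort.

    ``outcome_models`` map outcome -> {canonical feature name: true
    coefficient}; the intercept is tuned so the cohort's mean outcome
    probability matches ``prevalence_targets``.
    """

    n_patients: int = 62
    seed: int = 0
    duration_mean_min: float = 420.0
    duration_sd_min: float = 90.0
    duration_floor_min: float = 240.0
    sample_interval_s: float = 10.0
    intermittent_interval_min: float = 30.0
    signals: tuple[str, ...] = tuple(SIGNALS)
    signal_models: dict[str, SignalModel] = field(
        default_factory=lambda: dict(DEFAULT_SIGNAL_MODELS)
    )
    outcome_models: dict[str, dict[str, float]] = field(
        default_factory=_default_outcome_models
    )
    prevalence_targets: dict[str, float] = field(default_factory=_default_prevalences)

    def __post_init__(self) -> None:
        for sid in self.signals:
            if sid not in SIGNALS:
                raise ValueError(f"unknown signal {sid!r}")
        for sid, m in self.signal_models.items():
            if not 0.0 <= m.rho < 1.0:
                raise ValueError(f"signal {sid}: AR(1) correlation must be in [0, 1)")
        for name, p in self.prevalence_targets.items():
            if not 0.0 < p <= 0.5:
                raise ValueError(
                    f"outcome {name}: prevalence target must be in (0, 0.5]"
                )

    @classmethod
    def compact(
        cls, n_patients: int, seed: int, outcome: str = "mortality"
    ) -> "SimConfig":
        """Reduced signal panel (CVP, SVI, HR) and a two-feature truth, for
        fast end-to-end recovery experiments."""
        return cls(
            n_patients=n_patients,
            seed=seed,
            signals=("cvp", "svi", "hr"),
            outcome_models={
                outcome: {"area_cvp_gt_5": 0.0012, "whole_blood_ml_kg": 0.1}
            },
            prevalence_targets={outcome: 0.18},
        )


@dataclass
class GroundTruth:
    """Generating model and latent quantities, kept for recovery tests."""

    patient_ids: list[str]
    coefficients: dict[str, dict[str, float]]  # outcome -> feature -> beta
    intercepts: dict[str, float]
    eta: dict[str, np.ndarray]  # linear predictor (without intercept)
    prob: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]

    def to_frame(self):
        import pandas as pd

        data: dict = {"patient_id": self.patient_ids}
        for outcome in self.eta:
            data[f"eta_{outcome}"] = self.eta[outcome]
            data[f"prob_{outcome}"] = self.prob[outcome]
            data[f"label_{outcome}"] = self.labels[outcome]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def tune_intercept(eta: np.ndarray, target: float, tol: float = 1e-12) -> float:
    """Bisect the intercept c so that mean(expit(c + eta)) == target."""
    if not 0.0 < target < 1.0:
        raise ValueError("prevalence target must be in (0, 1)")
    eta = np.asarray(eta, dtype=float)
    lo, hi = -60.0, 60.0
    f = lambda c: float(np.mean(expit(c + eta))) - target
    if f(lo) > 0 or f(hi) < 0:  # pragma: no cover - eta magnitudes are finite
        raise ValueError("prevalence target unreachable under the coefficient config")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def population_auc(probs: np.ndarray) -> float:
    """AUC of the generating model itself.

    For outcomes drawn Bernoulli(p_i) and any score that orders patients
    like p, the large-sample AUC is
    sum_{i,j} p_i (1-p_j) [1(p_i > p_j) + 1/2(p_i = p_j)] / (sum p)(sum 1-p),
    evaluated here exactly over the supplied probability vector.
    """
    p = np.sort(np.asarray(probs, dtype=float))
    q = 1.0 - p
    cq = np.concatenate([[0.0], np.cumsum(q)])
    # group ties
    uniq, start = np.unique(p, return_index=True)
    end = np.concatenate([start[1:], [p.size]])
    num = 0.0
    for s, e in zip(start, end):
        p_grp = p[s:e].sum()
        q_below = cq[s]
        q_tie = cq[e] - cq[s]
        num += p_grp * (q_below + 0.5 * q_tie)
    den = p.sum() * q.sum()
    return float(num / den) if den > 0 else 0.5


def simulate_waveform(
    signal_id: str,
    baseline: float,
    duration_min: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> WaveformSignal:
    """One signal for one patient: stationary AR(1) around the baseline
    (continuous signals) or sparse draws every 30 minutes (intermittent)."""
    sdef = SIGNALS[signal_id]
    model = config.signal_models[signal_id]
    lo, hi = model.clip
    if sdef.kind == CONTINUOUS:
        times = np.arange(0.0, duration_min * 60.0, config.sample_interval_s)
        n = times.size
        rho, sd = model.rho, model.marginal_sd
        if sd == 0.0:
            x = np.zeros(n)
        else:
            innov = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), size=n)
            x0 = rng.normal(0.0, sd)
            x, _ = lfilter([1.0], [1.0, -rho], innov, zi=np.array([rho * x0]))
        values = np.clip(baseline + x, lo, hi)
    else:
        times = np.arange(0.0, duration_min * 60.0, config.intermittent_interval_min * 60.0)
        values = np.clip(
            rng.normal(baseline, model.marginal_sd, size=times.size), lo, hi
        )
    return WaveformSignal(signal_id, times, values, sdef.kind, sdef.threshold)


def _draw_preop(n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    names = PREOP_FEATURES
    m = len(names)
    C = np.eye(m)
    for (a, b), r in _PREOP_CORR_PAIRS.items():
        i, j = names.index(a), names.index(b)
        C[i, j] = C[j, i] = r
    # ensure positive definiteness of the hand-set correlation matrix
    w, V = np.linalg.eigh(C)
    C = (V * np.maximum(w, 1e-6)) @ V.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    Z = rng.standard_normal((n, m)) @ np.linalg.cholesky(C).T

    from scipy.special import ndtr

    out: dict[str, np.ndarray] = {}
    for j, name in enumerate(names):
        spec = _PREOP_MODELS[name]
        z = Z[:, j]
        kind = spec[0]
        if kind == "normal":
            _, mean, sd, lo, hi = spec
            out[name] = np.clip(mean + sd * z, lo, hi)
        elif kind == "lognormal":
            _, med, sigma = spec
            out[name] = np.exp(np.log(med) + sigma * z)
        elif kind == "bernoulli":
            _, p = spec
            out[name] = (ndtr(z) < p).astype(float)
        elif kind == "ordinal":
            _, values, probs = spec
            edges = np.cumsum(probs)[:-1]
            out[name] = np.asarray(values, dtype=float)[
                np.searchsorted(edges, ndtr(z))
            ]
        else:  # pragma: no cover
            raise ValueError(f"unknown marginal kind {kind!r}")
    return out


def _record_feature(rec: PatientRecord, name: str, max_gap_s: float = 60.0) -> float:
    """Evaluate any canonical feature by name from a simulated record."""
    if name in rec.preop:
        return rec.preop[name]
    if name in rec.nonhemo:
        return rec.nonhemo[name]
    for sid, sdef in SIGNALS.items():
        if name == f"median_{sid}" and sid in rec.waveforms:
            return extract_median(rec.waveforms[sid])
        if sdef.kind != CONTINUOUS or sid not in rec.waveforms:
            continue
        if name == f"mad_{sid}":
            return extract_mad(rec.waveforms[sid])
        if name == area_feature_name(sid, sdef.threshold):
            return extract_exposure_area(rec.waveforms[sid], max_gap_s=max_gap_s)
    raise ValueError(
        f"outcome model references feature {name!r} which the simulator did not "
        "produce for this configuration"
    )


def simulate_cohort(config: SimConfig) -> tuple[list[PatientRecord], GroundTruth]:
    """Draw a complete cohort and its generating truth.

    Fully reproducible from ``config.seed``: independent child generators
    are derived for preoperative features, blood products, durations,
    waveforms and outcome labels, so e.g. changing the signal list does not
    perturb the preoperative draws.
    """
    n = config.n_patients
    ss = np.random.SeedSequence(config.seed)
    rng_preop, rng_prod, rng_dur, rng_wave, rng_lab = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    preop = _draw_preop(n, rng_preop)

    severity = rng_prod.standard_normal(n)
    products: dict[str, np.ndarray] = {}
    for pname, (med, sigma) in _PRODUCT_MODELS.items():
        z = 0.6 * severity + 0.8 * rng_prod.standard_normal(n)
        products[pname] = np.exp(np.log(med) + sigma * z)

    durations = rng_dur.normal(config.duration_mean_min, config.duration_sd_min, n)
    bad = durations < config.duration_floor_min
    while bad.any():  # truncated normal by redraw
        durations[bad] = rng_dur.normal(
            config.duration_mean_min, config.duration_sd_min, int(bad.sum())
        )
        bad = durations < config.duration_floor_min

    width = max(3, len(str(n)))
    records: list[PatientRecord] = []
    for i in range(n):
        rec = PatientRecord(
            patient_id=f"P{i + 1:0{width}d}",
            preop={k: float(v[i]) for k, v in preop.items()},
            nonhemo={
                **{k: float(v[i]) for k, v in products.items()},
                "surgery_duration_min": float(durations[i]),
            },
        )
        for sid in config.signals:
            model = config.signal_models[sid]
            baseline = float(
                np.clip(
                    rng_wave.normal(model.baseline_mean, model.baseline_sd),
                    *model.clip,
                )
            )
            rec.waveforms[sid] = simulate_waveform(
                sid, baseline, durations[i], config, rng_wave
            )
        records.append(rec)

    truth = GroundTruth(
        patient_ids=[r.patient_id for r in records],
        coefficients={},
        intercepts={},
        eta={},
        prob={},
        labels={},
    )
    for outcome, model in config.outcome_models.items():
        eta = np.zeros(n)
        for fname, beta in model.items():
            eta += beta * np.array([_record_feature(r, fname) for r in records])
        c = tune_intercept(eta, config.prevalence_targets.get(outcome, 0.18))
        prob = expit(c + eta)
        labels = rng_lab.binomial(1, prob)
        for r, lab in zip(records, labels):
            r.outcomes[outcome] = int(lab)
        truth.coefficients[outcome] = dict(model)
        truth.intercepts[outcome] = c
        truth.eta[outcome] = eta
        truth.prob[outcome] = prob
        truth.labels[outcome] = labels
    return records, truth


@dataclass
class MissingnessConfig:
    """Completely-at-random dropout probabilities.

    ``preop_cell``: each preoperative value independently; ``waveform_truncate``:
    each continuous signal truncated to a random length under 180 min;
    ``product_missing``: each blood-product volume; ``outcome_missing``: each
    outcome label.
    """

    preop_cell: float = 0.0
    waveform_truncate: float = 0.0
    product_missing: float = 0.0
    outcome_missing: float = 0.0

    @classmethod
    def typical(cls) -> "MissingnessConfig":
        """Rates emulating retrospective intraoperative archives, in which
        roughly 38% of records end up unusable for prediction."""
        return cls(
            preop_cell=0.007,
            waveform_truncate=0.026,
            product_missing=0.037,
            outcome_missing=0.01,
        )


def inject_missingness(
    records: list[PatientRecord],
    config: MissingnessConfig,
    seed: int | np.random.Generator = 0,
) -> list[PatientRecord]:
    """Return copies of the records with values deleted completely at random."""
    for p in (
        config.preop_cell,
        config.waveform_truncate,
        config.product_missing,
        config.outcome_missing,
    ):
        if not 0.0 <= p <= 1.0:
            raise ValueError("dropout probabilities must be in [0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out: list[PatientRecord] = []
    for rec in records:
        preop = {
            k: v for k, v in rec.preop.items() if rng.random() >= config.preop_cell
        }
        nonhemo = dict(rec.nonhemo)
        for pname in _PRODUCT_MODELS:
            if pname in nonhemo and rng.random() < config.product_missing:
                del nonhemo[pname]
        outcomes = {
            k: v
            for k, v in rec.outcomes.items()
            if rng.random() >= config.outcome_missing
        }
        waveforms = {}
        for sid, sig in rec.waveforms.items():
            if (
                SIGNALS[sid].kind == CONTINUOUS
                and rng.random() < config.waveform_truncate
            ):
                cut_s = rng.uniform(20.0, 170.0) * 60.0
                keep = sig.times < cut_s
                if keep.sum() < 2:
                    keep[:2] = True
                waveforms[sid] = WaveformSignal(
                    sid, sig.times[keep], sig.values[keep], sig.kind, sig.threshold
                )
            else:
                waveforms[sid] = sig
        out.append(
            dataclasses.replace(
                rec, preop=preop, nonhemo=nonhemo, outcomes=outcomes, waveforms=waveforms
            )
        )
    return out
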