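"""Synthetic cohort generator: waveforms, copula labs, outcomes, missingness."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm

import periopredict as pp
from periopredict.simulate import tune_intercept

from conftest import make_complete_record


def _wave_config(**kw):
    return pp.SimConfig(n_patients=1, seed=0, **kw)


class TestSimulateWaveform:
    def test_zero_noise_gives_constant_baseline(self):
        cfg = _wave_config(
            signal_models={
                **pp.simulate.DEFAULT_SIGNAL_MODELS,
                "cvp": pp.simulate.SignalModel(7.0, 0.0, 0.0, 0.0, (0, 30)),
            }
        )
        rng = np.random.default_rng(0)
        sig = pp.simulate_waveform("cvp", 7.0, 60.0, cfg, rng)
        assert np.all(sig.values == 7.0)
        assert sig.times[0] == 0.0 and sig.n_samples == 360

    def test_lag1_autocorrelation_matches_config(self):
        cfg = _wave_config(
            signal_models={
                **pp.simulate.DEFAULT_SIGNAL_MODELS,
                # wide clip so clipping cannot bias the estimate
                "svri": pp.simulate.SignalModel(1900.0, 0.0, 300.0, 0.9, (-1e9, 1e9)),
            }
        )
        rng = np.random.default_rng(1)
        sig = pp.simulate_waveform("svri", 1900.0, 100_000 * 10 / 60.0, cfg, rng)
        x = sig.values - sig.values.mean()
        rho_hat = (x[:-1] @ x[1:]) / (x @ x)
        assert rho_hat == pytest.approx(0.9, abs=0.02)

    def test_marginal_sd_and_clipping(self):
        cfg = _wave_config()
        rng = np.random.default_rng(2)
        sig = pp.simulate_waveform("spo2", 97.5, 2000.0, cfg, rng)
        assert sig.values.max() <= 100.0

    def test_intermittent_every_30_minutes(self):
        cfg = _wave_config()
        rng = np.random.default_rng(3)
        sig = pp.simulate_waveform("cfi", 4.5, 240.0, cfg, rng)
        assert sig.kind == "intermittent"
        np.testing.assert_allclose(np.diff(sig.times), 1800.0)

    def test_mean_exposure_matches_rectified_normal(self):
        """Baseline CVP 8 above threshold 5: the per-minute exposure
        expectation is that of a rectified normal, sigma*phi(z) + mu*Phi(z)."""
        cfg = _wave_config()
        rng = np.random.default_rng(4)
        areas, minutes = [], 400.0
        for _ in range(30):
            sig = pp.simulate_waveform("cvp", 8.0, minutes, cfg, rng)
            areas.append(pp.extract_exposure_area(sig))
        mu, sd = 3.0, 2.5  # excess over threshold is N(3, 2.5), clipped at 0
        z = mu / sd
        expected = sd * norm.pdf(z) + mu * norm.cdf(z)
        got = np.mean(areas) / minutes
        assert got == pytest.approx(expected, rel=0.05)


class TestSimulateCohort:
    def test_same_seed_byte_identical_files(self, tmp_path):
        for d in ("a", "b"):
            cfg = pp.SimConfig.compact(12, seed=99)
            records, truth = pp.simulate_cohort(cfg)
            (tmp_path / d).mkdir()
            pp.write_cohort(records, tmp_path / d / "cohort.csv", tmp_path / d / "waves.csv")
            truth.to_csv(tmp_path / d / "truth.csv")
        for name in ("cohort.csv", "waves.csv", "truth.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_different_seeds_differ(self):
        a, _ = pp.simulate_cohort(pp.SimConfig.compact(10, seed=1))
        b, _ = pp.simulate_cohort(pp.SimConfig.compact(10, seed=2))
        assert a[0].preop["meld"] != b[0].preop["meld"]

    def test_null_model_prevalence(self):
        """All coefficients zero: empirical prevalence hits the target."""
        cfg = pp.SimConfig(
            n_patients=10_000,
            seed=5,
            signals=(),
            outcome_models={"mortality": {}},
            prevalence_targets={"mortality": 0.2},
        )
        records, truth = pp.simulate_cohort(cfg)
        assert truth.labels["mortality"].mean() == pytest.approx(0.2, abs=0.01)

    def test_intercept_tuning_hits_target(self):
        rng = np.random.default_rng(6)
        eta = rng.normal(0, 2, 500)
        c = tune_intercept(eta, 0.18)
        assert float(np.mean(expit(c + eta))) == pytest.approx(0.18, abs=1e-9)

    def test_unreachable_prevalence_rejected(self):
        with pytest.raises(ValueError):
            tune_intercept(np.zeros(5), 1.5)

    def test_unknown_model_feature_rejected(self):
        cfg = pp.SimConfig(
            n_patients=4,
            seed=0,
            signals=("cvp",),
            outcome_models={"mortality": {"area_svv_gt_10": 1.0}},
            duration_mean_min=240,
            duration_sd_min=0,
        )
        with pytest.raises(ValueError, match="area_svv_gt_10"):
            pp.simulate_cohort(cfg)

    def test_preop_copula_correlations(self):
        cfg = pp.SimConfig(n_patients=4000, seed=7, signals=(), outcome_models={})
        records, _ = pp.simulate_cohort(cfg)
        meld = np.array([r.preop["meld"] for r in records])
        inr = np.array([r.preop["inr"] for r in records])
        alb = np.array([r.preop["albumin"] for r in records])
        assert np.corrcoef(np.log(meld), np.log(inr))[0, 1] > 0.4
        assert np.corrcoef(np.log(meld), alb)[0, 1] < -0.2

    def test_roundtrip_preserves_extracted_features(self, tmp_path):
        """simulate -> write -> load -> extract: constant-free medians agree."""
        cfg = pp.SimConfig.compact(6, seed=8)
        records, _ = pp.simulate_cohort(cfg)
        pp.write_cohort(records, tmp_path / "c.csv", tmp_path / "w.csv")
        loaded = {r.patient_id: r for r in pp.load_cohort(tmp_path / "c.csv", tmp_path / "w.csv")}
        for rec in records:
            got = loaded[rec.patient_id]
            for sid in cfg.signals:
                assert pp.extract_median(got.waveforms[sid]) == pytest.approx(
                    pp.extract_median(rec.waveforms[sid])
                )


class TestPopulationAuc:
    def test_matches_quadratic_brute_force(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.01, 0.99, 80)
        p[10:14] = p[4]  # inject ties
        num = 0.0
        for i in range(80):
            for j in range(80):
                w = p[i] * (1 - p[j])
                num += w * (1.0 if p[i] > p[j] else (0.5 if p[i] == p[j] else 0.0))
        expected = num / (p.sum() * (1 - p).sum())
        assert pp.population_auc(p) == pytest.approx(expected, rel=1e-12)

    def test_constant_probabilities_give_half(self):
        assert pp.population_auc(np.full(50, 0.3)) == pytest.approx(0.5)


class TestInjectMissingness:
    def test_zero_probabilities_change_nothing(self):
        records, _ = pp.simulate_cohort(pp.SimConfig.compact(5, seed=10))
        out = pp.inject_missingness(records, pp.MissingnessConfig(), seed=1)
        for a, b in zip(records, out):
            assert a.preop == b.preop and a.nonhemo == b.nonhemo
            for sid in a.waveforms:
                assert b.waveforms[sid].n_samples == a.waveforms[sid].n_samples

    def test_truncation_probability_one_excludes_everyone(self):
        records, _ = pp.simulate_cohort(pp.SimConfig.compact(5, seed=11))
        out = pp.inject_missingness(
            records, pp.MissingnessConfig(waveform_truncate=1.0), seed=2
        )
        with pytest.raises(ValueError, match="inclusion"):
            pp.apply_inclusion_filters(out, "mortality", required_signals=("cvp", "svi", "hr"))

    def test_typical_rates_exclude_about_38_percent(self):
        """Full-panel records under typical archive dropout: roughly 38%
        become unusable (checked loosely over 400 records)."""
        records = [
            make_complete_record(f"P{i:03d}", n_minutes=200.0, interval_s=60.0)
            for i in range(400)
        ]
        out = pp.inject_missingness(records, pp.MissingnessConfig.typical(), seed=3)
        _, log = pp.apply_inclusion_filters(out, "mortality")
        rate = len(log) / 400
        assert 0.25 <= rate <= 0.52
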