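"""AUC, BCa bootstrap intervals, DeLong comparisons, inclusion frequency."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import periopredict as pp
from periopredict.evaluation import delong_variance


def brute_force_auc(scores, labels):
    """Independent oracle: enumerate all case-control pairs."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, float)
    cases, ctrls = s[y == 1], s[y == 0]
    num = 0.0
    for a in cases:
        for b in ctrls:
            num += 1.0 if a > b else (0.5 if a == b else 0.0)
    return num / (len(cases) * len(ctrls))


class TestAuc:
    def test_perfect_ordering(self):
        assert pp.auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert pp.auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_hand_set_with_tie_matches_pair_counting(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.35, 0.9, 0.6, 0.2]
        labels = [0, 0, 1, 1, 0, 1, 0, 0]
        assert pp.auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels)
        )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        s = rng.normal(size=200)
        y = rng.integers(0, 2, 200)
        y[0], y[1] = 0, 1
        assert pp.auc(s, y) == pytest.approx(roc_auc_score(y, s))

    @given(st.integers(0, 2**32 - 1))
    def test_complement_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=30)
        y = np.r_[np.ones(10), np.zeros(20)]
        assert pp.auc(s, y) + pp.auc(-s, y) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        s = rng.uniform(0.01, 0.99, 40)
        y = np.r_[np.ones(15), np.zeros(25)]
        a = pp.auc(s, y)
        assert pp.auc(np.log(s / (1 - s)), y) == pytest.approx(a)
        assert pp.auc(s**3, y) == pytest.approx(a)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            pp.auc([0.1, 0.9], [1, 1])


class TestBcaCi:
    @pytest.fixture(scope="class")
    def cohort62(self):
        rng = np.random.default_rng(5)
        y = np.r_[np.ones(11), np.zeros(51)]
        s = np.where(y == 1, rng.normal(1.2, 1, 62), rng.normal(0, 1, 62))
        return s, y

    def test_deterministic_given_seed(self, cohort62):
        s, y = cohort62
        a = pp.bca_ci(s, y, n_boot=1000, seed=7)
        b = pp.bca_ci(s, y, n_boot=1000, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        c = pp.bca_ci(s, y, n_boot=1000, seed=8)
        assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)

    def test_brackets_point_estimate(self, cohort62):
        s, y = cohort62
        res = pp.bca_ci(s, y, n_boot=1000, seed=7)
        assert 0.0 <= res.ci_low <= res.auc <= res.ci_high <= 1.0

    def test_reduces_to_percentile_when_unbiased_symmetric(self):
        """With z0 = 0 and a = 0 the BCa endpoints are plain percentiles."""
        from scipy.special import ndtri
        from periopredict.evaluation import bca_ci as _bca

        rng = np.random.default_rng(9)
        y = np.r_[np.ones(40), np.zeros(40)]
        s = np.where(y == 1, rng.normal(1, 1, 80), rng.normal(0, 1, 80))
        res = pp.bca_ci(s, y, n_boot=2000, seed=3)
        # recompute the same bootstrap distribution for plain percentiles
        rng2 = np.random.default_rng(3)
        boots = []
        while len(boots) < 2000:
            idx = rng2.integers(0, 80, (2000 - len(boots), 80))
            for row in idx:
                yy = y[row]
                if 0 < yy.sum() < 80:
                    boots.append(pp.auc(s[row], yy))
        lo, hi = np.quantile(boots, [0.025, 0.975])
        # symmetric near-unbiased case: BCa within a quantile-grid step
        assert res.ci_low == pytest.approx(lo, abs=0.03)
        assert res.ci_high == pytest.approx(hi, abs=0.03)

    def test_min_boot_enforced(self, cohort62):
        s, y = cohort62
        with pytest.raises(ValueError, match="200"):
            pp.bca_ci(s, y, n_boot=50, seed=1)


class TestDeLong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=30)
        y = np.r_[np.ones(10), np.zeros(20)]
        res = pp.delong_test(s, s, y)
        assert res.p_value == 1.0 and res.degenerate

    def test_variance_matches_placement_enumeration(self):
        """Single-AUC DeLong variance equals the explicit placement-value
        computation on a small example."""
        scores = np.array([0.9, 0.8, 0.7, 0.65, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1])
        labels = np.array([1, 1, 0, 1, 0, 0, 1, 0, 0, 0])
        cases = scores[labels == 1]
        ctrls = scores[labels == 0]
        v10 = np.array([np.mean([(a > b) + 0.5 * (a == b) for b in ctrls]) for a in cases])
        v01 = np.array([np.mean([(a > b) + 0.5 * (a == b) for a in cases]) for b in ctrls])
        expected = np.var(v10, ddof=1) / len(cases) + np.var(v01, ddof=1) / len(ctrls)
        assert delong_variance(scores, labels) == pytest.approx(expected)

    def test_matches_r_proc(self, tmp_path):
        """Cross-check z and P against the pROC reference implementation."""
        import shutil, subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(3)
        y = np.r_[np.ones(15), np.zeros(25)]
        sa = y * 0.8 + rng.normal(0, 1, 40)
        sb = y * 0.3 + rng.normal(0, 1, 40)
        res = pp.delong_test(sa, sb, y)
        script = tmp_path / "delong.R"
        script.write_text(
            "suppressMessages(library(pROC))\n"
            f"y <- c({','.join(str(int(v)) for v in y)})\n"
            f"sa <- c({','.join(f'{v:.17g}' for v in sa)})\n"
            f"sb <- c({','.join(f'{v:.17g}' for v in sb)})\n"
            "t <- roc.test(roc(y, sa, quiet=TRUE), roc(y, sb, quiet=TRUE),"
            " method='delong', paired=TRUE)\n"
            "cat(t$statistic, t$p.value, sep='\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        z_ref, p_ref = (float(v) for v in out.stdout.split())
        assert abs(res.z) == pytest.approx(abs(z_ref), abs=1e-6)
        assert res.p_value == pytest.approx(p_ref, abs=1e-6)

    def test_detects_true_difference(self):
        rng = np.random.default_rng(4)
        y = np.r_[np.ones(60), np.zeros(140)]
        strong = y * 2.0 + rng.normal(0, 1, 200)
        weak = rng.normal(0, 1, 200)
        res = pp.delong_test(strong, weak, y)
        assert res.auc_a > res.auc_b
        assert res.p_value < 0.001

    def test_mismatched_labels_rejected(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(ValueError, match="length|labels"):
            pp.delong_test(np.arange(10), np.arange(9), y)


class _FakeResult:
    def __init__(self, names, auc, ors, ps):
        self.feature_names = tuple(names)
        self.auc = auc
        self.odds_ratios = np.asarray(ors, float)
        self.wald_p = np.asarray(ps, float)


class TestInclusionFrequency:
    def test_single_significant_classifier(self):
        res = [_FakeResult(["cvp_area"], 0.8, [1.3], [0.01])]
        df = pp.inclusion_frequency(res)
        row = df.iloc[0]
        assert row.feature == "cvp_area"
        assert row.n_high_performers == 1
        assert row.frac_or_gt_1 == 1.0

    def test_fractions_partition(self):
        res = [
            _FakeResult(["a", "b"], 0.85, [1.5, 0.7], [0.01, 0.02]),
            _FakeResult(["a"], 0.75, [0.6], [0.03]),
            _FakeResult(["a"], 0.65, [2.0], [0.001]),  # below AUC threshold
            _FakeResult(["c"], 0.9, [3.0], [0.2]),  # not significant
        ]
        df = pp.inclusion_frequency(res).set_index("feature")
        assert df.loc["a", "n_high_performers"] == 2
        assert df.loc["a", "frac_or_gt_1"] + df.loc["a", "frac_or_lt_1"] == 1.0
        assert df.loc["c", "n_high_performers"] == 0
        assert list(df.index)[0] == "a"  # sorted by count descending

    def test_impossible_threshold_yields_empty_with_warning(self):
        res = [_FakeResult(["a"], 0.99, [1.2], [0.01])]
        with pytest.warns(UserWarning, match="no classifier"):
            df = pp.inclusion_frequency(res, auc_threshold=1.01)
        assert (df.n_high_performers == 0).all()


class TestCompareTasks:
    def test_self_comparison_p_one(self):
        rng = np.random.default_rng(6)
        y = np.r_[np.ones(10), np.zeros(20)]
        s = rng.normal(size=30)
        df = pp.compare_tasks({"a": s, "b": s.copy()}, y)
        assert df.loc[0, "p_value"] == 1.0

    def test_three_tasks_three_pairs(self):
        rng = np.random.default_rng(7)
        y = np.r_[np.ones(10), np.zeros(20)]
        scores = {k: rng.normal(size=30) for k in "abc"}
        df = pp.compare_tasks(scores, y)
        assert len(df) == 3

    def test_mismatched_patient_sets_rejected(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(ValueError, match="patient set"):
            pp.compare_tasks({"a": np.arange(10), "b": np.arange(8)}, y)
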