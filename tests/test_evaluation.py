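import numpy as np
import pandas as pd
import pytest
from scipy import stats

from irgpi.evaluation import (
    ConfusionSummary,
    classify_and_confuse,
    compare_survival,
    cox_binary_breslow,
    km_curve,
    median_survival,
    meta_fixed_effect,
    os_driven_cutpoint,
    roc_and_youden,
)
from irgpi.io_core import IrgpiError
from irgpi.screening import logrank_test
from conftest import make_survival


def _series(values, prefix="s"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))], dtype=float)


class TestRocAndYouden:
    def test_perfect_separation(self):
        scores = _series([-3, -2, -1, 1, 2, 3])
        labels = pd.Series([True] * 3 + [False] * 3, index=scores.index)
        roc = roc_and_youden(scores, labels)
        assert roc.auc == pytest.approx(1.0)
        assert roc.youden_j == pytest.approx(1.0)
        assert -1 < roc.youden_cutoff < 1

    def test_auc_equals_mann_whitney(self, rng):
        scores = _series(rng.normal(size=200))
        labels = pd.Series(rng.random(200) < 0.4, index=scores.index)
        roc = roc_and_youden(scores, labels)
        pos = scores[labels].to_numpy()
        neg = scores[~labels].to_numpy()
        # low scores predict positive: AUC = P(pos < neg), tie-corrected
        u = stats.mannwhitneyu(neg, pos, alternative="two-sided").statistic
        assert roc.auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_auc_with_tied_scores_still_matches_rank_statistic(self, rng):
        scores = _series(rng.integers(0, 5, 120).astype(float))
        labels = pd.Series(rng.random(120) < 0.5, index=scores.index)
        roc = roc_and_youden(scores, labels)
        pos, neg = scores[labels].to_numpy(), scores[~labels].to_numpy()
        u = stats.mannwhitneyu(neg, pos).statistic
        assert roc.auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_label_inversion_flips_auc(self, rng):
        scores = _series(rng.normal(size=100))
        labels = pd.Series(rng.random(100) < 0.5, index=scores.index)
        a = roc_and_youden(scores, labels).auc
        b = roc_and_youden(scores, ~labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_direction_complement_without_ties(self, rng):
        scores = _series(rng.normal(size=80))
        labels = pd.Series(rng.random(80) < 0.5, index=scores.index)
        a = roc_and_youden(scores, labels, direction="low_is_positive").auc
        b = roc_and_youden(-scores, labels, direction="low_is_positive").auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_errors(self):
        scores = _series([1, 2, 3])
        with pytest.raises(IrgpiError):
            roc_and_youden(scores, pd.Series([True, True, True], index=scores.index))


class TestClassifyAndConfuse:
    def test_printed_discovery_counts(self):
        c = ConfusionSummary.from_counts(tp=38, fn=15, tn=61, fp=6)
        assert c.sensitivity == 71.7
        assert c.specificity == 91.0
        assert c.accuracy == 82.5

    @pytest.mark.parametrize("correct,total,expected", [(31, 42, 73.8), (40, 55, 72.7)])
    def test_validation_cohort_accuracy_arithmetic(self, correct, total, expected):
        tn = correct // 2
        tp = correct - tn
        fn = (total - correct) // 2
        fp = total - correct - fn
        c = ConfusionSummary.from_counts(tp=tp, fn=fn, tn=tn, fp=fp)
        assert c.accuracy == expected

    def test_all_predicted_positive(self):
        scores = _series([-1, -2, -3, -4])
        labels = pd.Series([True, True, False, False], index=scores.index)
        c = classify_and_confuse(scores, cutoff=0.0, labels=labels)
        assert c.sensitivity == 100.0
        assert c.specificity == 0.0

    def test_youden_cutoff_reproduces_j(self, rng):
        scores = _series(rng.normal(size=150))
        labels = pd.Series(rng.random(150) < 0.45, index=scores.index)
        roc = roc_and_youden(scores, labels)
        c = classify_and_confuse(scores, roc.youden_cutoff, labels)
        j = c.tp / (c.tp + c.fn) + c.tn / (c.tn + c.fp) - 1
        assert j == pytest.approx(roc.youden_j, abs=1e-12)

    def test_orr_by_group_computed_from_split(self):
        scores = _series([-2, -1, 1, 2])
        labels = pd.Series([True, False, True, False], index=scores.index)
        c = classify_and_confuse(scores, 0.0, labels)
        assert c.orr_low == pytest.approx(0.5)
        assert c.orr_high == pytest.approx(0.5)


class TestKmCurve:
    def test_three_deaths_product_limit(self):
        curve = km_curve([1, 2, 3], [1, 1, 1])
        assert np.allclose(curve["survival"], [2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat_at_one(self):
        curve = km_curve([5, 6, 7], [0, 0, 0])
        assert (curve["survival"] == 1.0).all()

    def test_tied_events_single_step_hand_fixture(self):
        # times (2,2,3,4,5), events (1,1,0,1,0): S(2)=3/5, S(4)=3/5 * 1/2
        curve = km_curve([2, 2, 3, 4, 5], [1, 1, 0, 1, 0])
        by_time = curve.set_index("time")
        assert by_time.loc[2.0, "n_events"] == 2
        assert by_time.loc[2.0, "survival"] == pytest.approx(3 / 5)
        assert by_time.loc[4.0, "survival"] == pytest.approx(3 / 10)

    def test_median_undefined_when_curve_stays_high(self):
        curve = km_curve([1, 2, 3, 4], [1, 0, 0, 0])
        assert median_survival(curve) is None


class TestCompareSurvival:
    def test_identical_groups_null(self):
        times = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        events = [1] * 10
        scores = _series([-1] * 5 + [1] * 5)
        comp = compare_survival(scores, make_survival(times, events, prefix="s"), cutoff=0.0)
        assert comp.logrank_p == pytest.approx(1.0)
        assert comp.hr_ci[0] < 1.0 < comp.hr_ci[1]

    def test_recovers_planted_hazard_ratio(self, rng):
        n = 300
        g = rng.integers(0, 2, n)
        lam = 0.05 * np.exp(np.log(3) * g)
        t = rng.exponential(1 / lam)
        c = rng.exponential(1 / 0.03, n)
        times, events = np.minimum(t, c), (t <= c).astype(int)
        scores = _series(g.astype(float) * 2 - 1)
        comp = compare_survival(scores, make_survival(times, events, prefix="s"), cutoff=0.0)
        assert 2.2 <= comp.hazard_ratio <= 4.1
        assert comp.logrank_p == pytest.approx(
            logrank_test(times, events, g)[1], rel=1e-12
        )

    def test_empty_group_errors(self):
        scores = _series([1, 2, 3])
        with pytest.raises(IrgpiError):
            compare_survival(scores, make_survival([1, 2, 3], [1, 1, 1], prefix="s"), cutoff=10.0)


class TestCoxBinaryBreslow:
    def test_matches_lifelines_breslow_free_fit(self, rng):
        # moderate effect, continuous times (no ties): Breslow == Efron
        n = 200
        g = rng.integers(0, 2, n)
        lam = 0.1 * np.exp(0.7 * g)
        t = rng.exponential(1 / lam)
        fit = cox_binary_breslow(t, np.ones(n, int), g)
        from lifelines import CoxPHFitter

        df = pd.DataFrame({"t": t, "e": 1, "g": g})
        cph = CoxPHFitter().fit(df, "t", "e")
        assert fit.log_hr == pytest.approx(float(cph.params_["g"]), abs=1e-6)
        assert fit.se == pytest.approx(float(cph.standard_errors_["g"]), abs=1e-6)

    def test_monotone_likelihood_capped_with_flag(self):
        t = np.r_[np.arange(1, 11), np.arange(20, 30)].astype(float)
        e = np.ones(20, int)
        g = np.r_[np.ones(10, int), np.zeros(10, int)]
        fit = cox_binary_breslow(t, e, g, cap=20.0)
        assert fit.capped and fit.log_hr == 20.0
        with pytest.raises(IrgpiError):
            cox_binary_breslow(t, e, g)


class TestOsDrivenCutpoint:
    def test_bimodal_scores_cut_between_modes(self, rng):
        n = 60
        scores = _series(np.r_[rng.normal(-3, 0.3, 30), rng.normal(3, 0.3, 30)])
        times = np.r_[rng.exponential(50, 30), rng.exponential(3, 30)]
        cut, p, scan = os_driven_cutpoint(scores, make_survival(times, np.ones(n, int), prefix="s"))
        low_mode_max = scores.iloc[:30].max()
        high_mode_min = scores.iloc[30:].min()
        assert low_mode_max <= cut < high_mode_min
        assert p < 1e-6

    def test_impossible_min_fraction_errors(self, rng):
        n = 21
        scores = _series(rng.normal(size=n))
        clinical = make_survival(rng.exponential(10, n), np.ones(n, int), prefix="s")
        with pytest.raises(IrgpiError):
            os_driven_cutpoint(scores, clinical, min_group_fraction=0.5)

    def test_scan_equals_brute_force(self, rng):
        n = 40
        scores = _series(rng.normal(size=n))
        times = rng.exponential(10, n)
        events = rng.integers(0, 2, n)
        events[:5] = 1
        clinical = make_survival(times, events, prefix="s")
        cut, p, scan = os_driven_cutpoint(scores, clinical, min_group_fraction=0.1)
        import math

        best_p, best_cut = 2.0, None
        vals = scores.to_numpy()
        for c in np.unique(vals)[:-1]:
            high = vals > c
            if high.sum() < math.ceil(0.1 * n) or (~high).sum() < math.ceil(0.1 * n):
                continue
            try:
                _, pv = logrank_test(times, events, high.astype(int))
            except Exception:
                pv = 1.0
            if pv < best_p:
                best_p, best_cut = pv, c
        assert cut == pytest.approx(float(best_cut))
        assert p == pytest.approx(best_p, rel=1e-12)


class TestMetaFixedEffect:
    def test_single_study_passthrough(self):
        m = meta_fixed_effect([(0.7, 0.2)])
        assert m.pooled_log_hr == pytest.approx(0.7)
        assert m.q_statistic == 0.0
        assert m.i_squared == 0.0

    def test_identical_studies_no_heterogeneity(self):
        m = meta_fixed_effect([(1.1, 0.3)] * 3)
        assert m.i_squared == 0.0
        assert m.pooled_log_hr == pytest.approx(1.1)

    def test_hand_inverse_variance_computation(self):
        x1, s1 = np.log(2), 0.2
        x2, s2 = np.log(4), 0.4
        m = meta_fixed_effect([(x1, s1), (x2, s2)])
        w1, w2 = 1 / s1**2, 1 / s2**2
        pooled = (w1 * x1 + w2 * x2) / (w1 + w2)
        q = w1 * (x1 - pooled) ** 2 + w2 * (x2 - pooled) ** 2
        assert m.pooled_log_hr == pytest.approx(pooled, rel=1e-12)
        assert m.q_statistic == pytest.approx(q, rel=1e-12)
        assert m.i_squared == pytest.approx(max(0, (q - 1) / q) * 100, rel=1e-9)

    def test_ci_shrinks_as_studies_accumulate(self):
        studies = [(0.5, 0.3), (0.6, 0.4), (0.4, 0.25), (0.55, 0.5)]
        widths = []
        for k in range(1, len(studies) + 1):
            m = meta_fixed_effect(studies[:k])
            lo, hi = m.pooled_hr_ci
            widths.append(np.log(hi) - np.log(lo))
        assert all(b < a for a, b in zip(widths, widths[1:]))

    def test_invalid_se(self):
        with pytest.raises(ValueError):
            meta_fixed_effect([(0.5, 0.0)])
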