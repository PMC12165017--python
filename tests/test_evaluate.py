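"""ROC/AUC, DeLong intervals, confusion metrics, decision curves and
operating-point matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from maldiag import evaluate as ev


class TestRocAuc:
    def test_perfect_ranking(self):
        assert ev.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_tied_is_half(self):
        assert ev.roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_pair_counting_example(self):
        # positives {0.9, 0.8}, negative {0.85} -> (1 + 0) / 2
        assert ev.roc_auc([0.9, 0.8, 0.85], [1, 1, 0]) == 0.5

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            ev.roc_auc([0.1, 0.9], [1, 1])

    @given(st.integers(0, 2**31 - 1))
    def test_equals_normalized_mannwhitney_u(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        scores = rng.normal(size=n)
        scores[rng.integers(0, n, 5)] = scores[0]  # inject ties
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        from scipy.stats import mannwhitneyu

        u = mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
        expected = u / ((y == 1).sum() * (y == 0).sum())
        assert ev.roc_auc(scores, y) == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn_oracle(self, rng):
        scores = rng.normal(size=200)
        y = rng.integers(0, 2, 200)
        from sklearn.metrics import roc_auc_score

        assert ev.roc_auc(scores, y) == pytest.approx(
            roc_auc_score(y, scores), abs=1e-12)


class TestAucCI:
    def test_perfect_separation_upper_bound_clipped(self):
        y = np.repeat([0, 1], 50)
        scores = y.astype(float)
        auc, lo, hi = ev.auc_ci(scores, y)
        assert auc == 1.0 and hi == 1.0 and lo <= 1.0

    def test_delong_variance_matches_placement_oracle(self, rng):
        scores = rng.normal(size=20)
        y = np.array([1] * 8 + [0] * 12)
        auc, var = ev._delong_variance(scores, y)
        pos, neg = scores[y == 1], scores[y == 0]
        # brute-force placement values
        v10 = np.array([np.mean((x > neg) + 0.5 * (x == neg)) for x in pos])
        v01 = np.array([np.mean((pos > x) + 0.5 * (pos == x)) for x in neg])
        var_oracle = np.var(v10, ddof=1) / 8 + np.var(v01, ddof=1) / 12
        assert auc == pytest.approx(v10.mean(), abs=1e-12)
        assert var == pytest.approx(var_oracle, abs=1e-12)

    def test_degenerate_scores_fall_back_to_bootstrap(self):
        y = np.repeat([0, 1], 20)
        scores = np.full(40, 0.5)
        with pytest.warns(UserWarning, match="degenerate"):
            auc, lo, hi = ev.auc_ci(scores, y)
        assert auc == 0.5

    def test_bootstrap_coverage_near_nominal(self):
        # true AUC for N(1,1) vs N(0,1) is Phi(1/sqrt(2)) ~ 0.7602
        from scipy.stats import norm

        true_auc = norm.cdf(1 / np.sqrt(2))
        covered = 0
        trials = 200
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            scores = np.concatenate([rng.normal(1, 1, 40), rng.normal(0, 1, 40)])
            y = np.repeat([1, 0], 40)
            _, lo, hi = ev.auc_ci(scores, y, method="bootstrap", n_boot=400,
                                  seed=seed)
            covered += lo <= true_auc <= hi
        assert 0.88 <= covered / trials <= 0.99


class TestConfusionMetrics:
    def test_validation_split_reconstruction(self):
        # 72 positives / 164 negatives with sens 83.33%, spec 74.39%
        m = ev.confusion_metrics(ev.ConfusionMatrix(tp=60, fp=42, fn=12, tn=122))
        assert ev.round_half_up(m["sensitivity"]) == 83.33
        assert ev.round_half_up(m["specificity"]) == 74.39
        assert ev.round_half_up(m["accuracy"]) == 77.12
        assert ev.round_half_up(m["ppv"]) == 58.82
        assert ev.round_half_up(m["npv"]) == 91.04

    def test_test_split_reconstruction(self):
        m = ev.confusion_metrics(ev.ConfusionMatrix(tp=58, fp=42, fn=13, tn=121))
        assert ev.round_half_up(m["ppv"]) == 58.00
        assert ev.round_half_up(m["npv"]) == 90.30
        assert ev.round_half_up(m["accuracy"]) == 76.50

    def test_symmetric_unit_matrix(self):
        m = ev.confusion_metrics(ev.ConfusionMatrix(tp=1, fp=1, fn=1, tn=1))
        for key in ("sensitivity", "specificity", "accuracy", "ppv", "npv", "f1"):
            assert m[key] == pytest.approx(50.0)

    def test_zero_denominator_flagged_nan(self):
        m = ev.confusion_metrics(ev.ConfusionMatrix(tp=0, fp=0, fn=0, tn=10))
        assert np.isnan(m["sensitivity"]) and np.isnan(m["ppv"])
        assert m["specificity"] == 100.0

    def test_round_trip_from_predictions(self, rng):
        scores = rng.uniform(0, 1, 200)
        y = rng.integers(0, 2, 200)
        report = ev.evaluate_predictions(scores, y, threshold=0.5)
        cm = report.cm
        again = ev.confusion_metrics(cm)
        for k, v in report.metrics.items():
            if not np.isnan(v):
                assert abs(v - again[k]) < 0.01

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ev.ConfusionMatrix(tp=-1, fp=0, fn=0, tn=0)


class TestRounding:
    def test_half_up_convention(self):
        assert ev.round_half_up(2.675, 2) == 2.68
        assert ev.round_half_up(83.335, 2) == 83.34
        assert ev.round_half_up(1.0, 2) == 1.0


class TestDecisionCurve:
    def test_treat_none_identically_zero(self, rng):
        curve = ev.decision_curve(rng.uniform(0, 1, 50),
                                  rng.integers(0, 2, 50))
        assert (curve["nb_none"] == 0).all()

    def test_treat_all_limit_is_prevalence(self):
        y = np.repeat([1, 0], [30, 70])
        curve = ev.decision_curve(np.linspace(0, 1, 100), y,
                                  thresholds=[0.001])
        prevalence = 0.3
        assert curve["nb_all"].iloc[0] == pytest.approx(prevalence, abs=0.001)

    def test_closed_form_spot_value(self):
        # TP=60, FP=42, n=236 at pt=0.2: NB = 60/236 - (42/236)(0.2/0.8)
        scores = np.concatenate([np.ones(60), np.ones(42),
                                 np.zeros(12), np.zeros(122)])
        y = np.concatenate([np.ones(60), np.zeros(42),
                            np.ones(12), np.zeros(122)])
        curve = ev.decision_curve(scores, y, thresholds=[0.2])
        assert curve["nb_model"].iloc[0] == pytest.approx(
            60 / 236 - (42 / 236) * 0.25, abs=1e-12)

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            ev.decision_curve([0.5], [1], thresholds=[1.0])

    def test_model_nb_bounded_by_prevalence(self, rng):
        scores = rng.uniform(0, 1, 100)
        y = rng.integers(0, 2, 100)
        curve = ev.decision_curve(scores, y)
        prevalence = y.mean()
        assert (curve["nb_model"] <= prevalence + 1e-12).all()


class TestSubgroupMetrics:
    def test_all_correct_gives_100(self):
        y = np.array([1, 1, 0, 0])
        meta = pd.DataFrame({"stage": ["IA", "IB", "NA", "NA"]})
        table = ev.subgroup_metrics(y, y, meta, by="stage")
        assert table.loc["IA", "sensitivity"] == 100.0
        assert table.loc["NA", "specificity"] == 100.0

    def test_small_level_counts_recorded(self):
        y = np.array([1, 1])
        pred = np.array([1, 0])
        meta = pd.DataFrame({"stage": ["II", "II"]})
        table = ev.subgroup_metrics(pred, y, meta, by="stage")
        assert table.loc["II", "n"] == 2
        assert table.loc["II", "sensitivity"] == 50.0

    def test_pooled_rate_is_count_weighted_mean(self, rng):
        n = 200
        y = np.ones(n, dtype=int)
        pred = rng.integers(0, 2, n)
        levels = rng.choice(["a", "b", "c"], n)
        meta = pd.DataFrame({"subtype": levels})
        table = ev.subgroup_metrics(pred, y, meta, by="subtype")
        pooled = 100.0 * pred.mean()
        weighted = (table["sensitivity"] * table["n_pos"]).sum() / n
        assert pooled == pytest.approx(weighted, abs=1e-9)

    def test_missing_column_error(self):
        with pytest.raises(ValueError):
            ev.subgroup_metrics([1], [1], pd.DataFrame({"x": [1]}), by="stage")


class TestMatchedOperatingPoint:
    def test_perfect_data_full_spec_keeps_full_sens(self):
        y = np.repeat([0, 1], 10)
        scores = y.astype(float)
        t, sens = ev.matched_operating_point(scores, y, target_specificity=1.0)
        assert sens == 1.0

    def test_zero_spec_target_all_positive(self):
        y = np.repeat([0, 1], 5)
        scores = np.linspace(0, 1, 10)
        t, sens = ev.matched_operating_point(scores, y, target_specificity=0.0)
        assert t < scores.min()
        assert sens == 1.0

    def test_matches_exhaustive_scan(self, rng):
        scores = np.array([0.1, 0.3, 0.35, 0.6, 0.8, 0.95])
        y = np.array([0, 0, 1, 0, 1, 1])
        for target in (0.3, 0.6, 0.9):
            t, sens = ev.matched_operating_point(scores, y,
                                                 target_specificity=target)
            # brute force over all cut positions
            best = None
            for cut in np.concatenate([[0.0], np.unique(scores), [1.01]]):
                spec = ((scores < cut) & (y == 0)).sum() / 3
                if spec >= target:
                    best = cut
                    break
            spec_at_t = ((scores < t) & (y == 0)).sum() / 3
            assert spec_at_t >= target
            assert t == pytest.approx(best, abs=0.2)

    def test_unachievable_target_errors_with_range(self):
        y = np.repeat([0, 1], 5)
        scores = np.zeros(10)
        with pytest.raises(ValueError, match="range"):
            ev.matched_operating_point(scores, y, target_sensitivity=1.5)
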