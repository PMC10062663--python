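"""Tests for classifiers, metrics, operating points and importance."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from ctptrunc.classifiers import (BASELINE_THETA_GRID, ClassifierSpec, baseline_predict,
                                  bootstrap_importance, error_by_osd_gap,
                                  evaluate_baseline_grid, fit_ml_model,
                                  grouped_cross_validate, roc_pr_curves,
                                  select_operating_point, single_feature_fit,
                                  _confusion)
from ctptrunc.features import FEATURE_NAMES
from ctptrunc.search import Dimension, bayes_search


def make_records(n_scans=10, n_per_scan=8, seed=0, separable=True,
                 noise=0.0) -> pd.DataFrame:
    """Truncation-record table whose label is driven by aif_coverage."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_scans):
        peak = rng.uniform(10, 20)
        osd = peak + 12.0
        full = rng.uniform(38, 55)
        for j in range(n_per_scan):
            dur = full - 3 * j
            cov = dur - peak + rng.normal(0, noise)
            label = "reliable" if dur >= osd else "unreliable"
            row = {"scan_id": f"s{i:02d}", "duration_s": dur, "osd_s": osd,
                   "label": label}
            for name in FEATURE_NAMES:
                row[name] = rng.normal(0, 1)
            row["scan_duration"] = dur
            row["argmax_aif"] = peak
            row["aif_coverage"] = cov if separable else rng.normal(0, 1)
            rows.append(row)
    return pd.DataFrame(rows)


class TestBaselinePredict:
    def test_long_scan_reliable(self):
        assert baseline_predict(65, 60) == "reliable"

    def test_short_scan_unreliable(self):
        assert baseline_predict(59, 60) == "unreliable"

    def test_boundary_equality_is_reliable(self):
        assert baseline_predict(60, 60) == "reliable"

    def test_invalid_theta(self):
        with pytest.raises(ValueError):
            baseline_predict(50, 0)


class TestRocPr:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 1.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        c = roc_pr_curves(scores, labels)
        assert c.roc_auc == 1.0 and c.pr_auc == 1.0

    def test_roc_auc_equals_rank_statistic(self):
        scores = np.array([3.0, 1.0, 2.0, 5.0, 4.0, 0.5])
        labels = np.array([1, 0, 0, 1, 1, 0])
        c = roc_pr_curves(scores, labels)
        u = mannwhitneyu(scores[labels == 1], scores[labels == 0],
                         alternative="two-sided").statistic
        assert c.roc_auc == pytest.approx(u / (3 * 3))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_pr_curves(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        assert abs(roc_pr_curves(scores, labels).roc_auc - 0.5) < 0.05


class TestOperatingPoint:
    def test_ideal_point_selected(self):
        thetas = np.array([0.2, 0.5, 0.8])
        assert select_operating_point([0.7, 1.0, 0.9], [0.9, 1.0, 0.5], thetas) == 0.5

    def test_tie_breaks_toward_higher_recall(self):
        thetas = np.array([0.3, 0.6])
        # (0.9, 0.8) and (0.8, 0.9) are equidistant from (1, 1)
        assert select_operating_point([0.9, 0.8], [0.8, 0.9], thetas) == 0.6

    def test_matches_exhaustive_argmin(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            p = rng.random(20)
            r = rng.random(20)
            th = np.sort(rng.random(20))
            got = select_operating_point(p, r, th)
            d2 = (p - 1) ** 2 + (r - 1) ** 2
            best = d2.min()
            cands = np.flatnonzero(d2 <= best + 1e-12)
            want = th[cands[np.argmax(r[cands])]]
            assert got == want

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_operating_point([], [], [])


class TestSingleFeature:
    def test_perfectly_separated_feature(self):
        df = make_records(n_scans=8, seed=1)
        clf = single_feature_fit(df, "aif_coverage")
        from sklearn.metrics import roc_auc_score
        y = (df["label"] == "unreliable").astype(int)
        assert roc_auc_score(y, clf.scores(df)) == 1.0
        assert np.array_equal(clf.predict(df), y.to_numpy())

    def test_anticorrelated_feature_flips_orientation(self):
        df = make_records(n_scans=8, seed=2)
        df["aif_coverage"] = -df["aif_coverage"]
        clf = single_feature_fit(df, "aif_coverage")
        assert clf.orientation == -1
        from sklearn.metrics import roc_auc_score
        y = (df["label"] == "unreliable").astype(int)
        assert roc_auc_score(y, clf.scores(df)) == 1.0

    def test_constant_feature_is_uninformative(self):
        df = make_records(n_scans=6, seed=3)
        df["vof_uci"] = 1.0
        clf = single_feature_fit(df, "vof_uci")
        c = roc_pr_curves(clf.scores(df),
                          (df["label"] == "unreliable").to_numpy(int))
        assert c.roc_auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        df = make_records(n_scans=4, seed=4)
        df["label"] = "reliable"
        with pytest.raises(ValueError):
            single_feature_fit(df, "aif_coverage")


class TestBayesSearch:
    def test_budget_one_returns_a_configuration(self):
        space = [Dimension("x", 0.0, 1.0)]
        best, val, hist = bayes_search(lambda p: -(p["x"] - 0.3) ** 2, space,
                                       n_calls=1, rng=np.random.default_rng(0))
        assert len(hist) == 1 and "x" in best

    def test_finds_good_region(self):
        space = [Dimension("x", 0.0, 1.0), Dimension("y", 0.0, 1.0)]
        best, val, _ = bayes_search(lambda p: -(p["x"] - 0.7) ** 2 - (p["y"] - 0.2) ** 2,
                                    space, n_calls=25, rng=np.random.default_rng(1))
        assert val > -0.02

    def test_deterministic(self):
        space = [Dimension("n", 10, 100, integer=True), Dimension("lr", 1e-3, 1, log=True)]
        f = lambda p: -abs(p["n"] - 40) / 100 - abs(np.log10(p["lr"]) + 1)
        a = bayes_search(f, space, n_calls=8, rng=np.random.default_rng(5))
        b = bayes_search(f, space, n_calls=8, rng=np.random.default_rng(5))
        assert a[0] == b[0] and a[1] == b[1]

    def test_zero_budget_rejected(self):
        with pytest.raises(ValueError):
            bayes_search(lambda p: 0.0, [Dimension("x", 0, 1)], n_calls=0,
                         rng=np.random.default_rng(0))


class TestFitMlModel:
    def test_budget_one_still_fits(self):
        df = make_records(n_scans=9, seed=5)
        spec = ClassifierSpec("logistic_regression")
        model = fit_ml_model(df, spec, seed=3, search_budget=1)
        assert model.params

    def test_separable_data_reaches_high_inner_prauc(self):
        df = make_records(n_scans=12, seed=6)
        spec = ClassifierSpec("gradient_boosting")
        model = fit_ml_model(df, spec, seed=3, search_budget=4)
        model.set_operating_point(df)
        m = _confusion((df["label"] == "unreliable").to_numpy(int), model.predict(df))
        assert m["f1"] >= 0.95

    def test_search_is_deterministic(self):
        df = make_records(n_scans=9, seed=7)
        spec = ClassifierSpec("logistic_regression")
        a = fit_ml_model(df, spec, seed=11, search_budget=5)
        b = fit_ml_model(df, spec, seed=11, search_budget=5)
        assert a.params == b.params

    def test_zero_budget_rejected(self):
        df = make_records(n_scans=6, seed=8)
        with pytest.raises(ValueError):
            fit_ml_model(df, ClassifierSpec("logistic_regression"), seed=0,
                         search_budget=0)


class TestGroupedCV:
    def test_folds_partition_scans(self):
        df = make_records(n_scans=10, seed=9)
        specs = [ClassifierSpec("baseline_duration")]
        res = grouped_cross_validate(df, specs, k=5)[specs[0].name]
        per_scan_folds = res.predictions.groupby("scan_id")["fold"].nunique()
        assert (per_scan_folds == 1).all()
        assert res.predictions["fold"].nunique() == 5
        # each fold holds exactly 2 of the 10 scans
        scans_per_fold = res.predictions.groupby("fold")["scan_id"].nunique()
        assert (scans_per_fold == 2).all()

    def test_specs_share_identical_splits(self):
        df = make_records(n_scans=10, seed=10)
        specs = [ClassifierSpec("baseline_duration"),
                 ClassifierSpec("single_feature", feature="aif_coverage")]
        res = grouped_cross_validate(df, specs, k=5, seed=1)
        a = res[specs[0].name].predictions.groupby("scan_id")["fold"].first()
        b = res[specs[1].name].predictions.groupby("scan_id")["fold"].first()
        assert a.equals(b)

    def test_too_many_folds_rejected(self):
        df = make_records(n_scans=3, seed=11)
        with pytest.raises(ValueError):
            grouped_cross_validate(df, [ClassifierSpec("baseline_duration")], k=5)

    def test_confusion_formula_identities(self):
        y_true = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 1, 0, 1, 0, 0, 0])
        m = _confusion(y_true, y_pred)
        assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (3, 1, 1, 3)
        assert m["precision"] == 0.75 and m["recall"] == 0.75 and m["f1"] == 0.75


class TestBaselineGrid:
    def test_grid_metrics_on_known_labels(self):
        df = pd.DataFrame({
            "duration_s": [25.0, 28.0, 35.0, 45.0, 65.0],
            "label": ["unreliable", "unreliable", "reliable", "reliable", "reliable"],
            "scan_id": list("abcde"),
        })
        out = evaluate_baseline_grid(df, thetas=(30.0,))
        m = out[30.0]
        # durations < 30 predicted unreliable: exactly the two true positives
        assert m["tp"] == 2 and m["fp"] == 0 and m["fn"] == 0
        assert set(out) == {30.0}
        assert BASELINE_THETA_GRID[0] == 27.0


class TestBootstrapImportance:
    def test_dominant_feature_identified(self):
        df = make_records(n_scans=10, seed=12)
        rep = bootstrap_importance(df, n_boot=5, seed=1,
                                   params={"n_estimators": 40, "max_depth": 2,
                                           "learning_rate": 0.2})
        assert rep.mean["aif_coverage"] > 0.5
        assert sum(rep.mean.values()) == pytest.approx(1.0, abs=0.02)

    def test_deterministic(self):
        df = make_records(n_scans=8, seed=13)
        kw = dict(n_boot=3, seed=9, params={"n_estimators": 20, "max_depth": 2,
                                            "learning_rate": 0.3})
        assert bootstrap_importance(df, **kw).mean == bootstrap_importance(df, **kw).mean

    def test_invalid_inputs(self):
        df = make_records(n_scans=4, seed=14)
        with pytest.raises(ValueError):
            bootstrap_importance(df, n_boot=1)
        with pytest.raises(ValueError):
            bootstrap_importance(df.iloc[:0], n_boot=5)


class TestErrorByOsdGap:
    def _preds(self, rows):
        return pd.DataFrame(rows, columns=["duration_s", "osd_s", "y_true", "y_pred"])

    def test_all_correct(self):
        p = self._preds([(30, 25, 1, 1), (40, 25, 0, 0)])
        out = error_by_osd_gap(p)
        assert sum(out["incorrect"]) == 0
        assert out["error_rate_outside_window_pct"] == 0.0

    def test_zero_gap_excluded_from_windowed_rate(self):
        p = self._preds([(25, 25, 1, 0)])  # wrong, but inside the +/- 2.3 s window
        out = error_by_osd_gap(p)
        assert out["n_outside_window"] == 0
        assert out["error_rate_outside_window_pct"] == 0.0

    def test_hand_built_rate(self):
        rows = [(30 + i, 20, 0, 0) for i in range(6)]        # 6 correct, outside
        rows += [(40, 20, 0, 1), (45, 20, 1, 0)]             # 2 errors, outside
        rows += [(21, 20, 1, 0), (22, 20, 0, 0)]             # inside the window
        out = error_by_osd_gap(self._preds(rows))
        assert out["n_outside_window"] == 8
        assert out["error_rate_outside_window_pct"] == pytest.approx(25.0)
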