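"""Truncation-detection classifiers and their evaluation.

Covers the scan-duration baseline rule g (reliable iff duration >= theta),
single-feature threshold classifiers g' built the same way from any of
the nine AIF/VOF features, and six ML families fitted with a sequential
model-based hyperparameter search (inner grouped 3-fold CV maximizing
PR-AUC).  Evaluation is a scan-grouped 5-fold cross-validation: all
truncated versions of a scan share a fold, training folds are augmented,
and the operating point is selected on training data only.  The positive
class throughout is *unreliable*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import (AdaBoostClassifier, GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (auc, average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)
from sklearn.model_selection import GroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_NAMES, AugmentationParams, FeatureVector, augment_features
from .search import Dimension, bayes_search

__all__ = [
    "ClassifierSpec", "ClassifierResult", "CurveSet", "ImportanceReport",
    "ML_FAMILIES", "baseline_predict", "ThresholdClassifier", "single_feature_fit",
    "fit_ml_model", "select_operating_point", "grouped_cross_validate",
    "roc_pr_curves", "bootstrap_importance", "error_by_osd_gap",
    "BASELINE_THETA_GRID",
]

POSITIVE_LABEL = "unreliable"
BASELINE_THETA_GRID = (27.0, 30.0, 40.0, 50.0, 60.0)

ML_FAMILIES = ("random_forest", "logistic_regression", "svm_linear",
               "svm_rbf", "adaboost", "gradient_boosting")

SEARCH_SPACES: dict[str, list[Dimension]] = {
    "random_forest": [
        Dimension("n_estimators", 50, 300, integer=True),
        Dimension("max_depth", 2, 8, integer=True),
        Dimension("min_samples_leaf", 1, 20, integer=True),
    ],
    "logistic_regression": [Dimension("C", 1e-2, 1e3, log=True)],
    "svm_linear": [Dimension("C", 1e-2, 1e3, log=True)],
    "svm_rbf": [
        Dimension("C", 1e-2, 1e3, log=True),
        Dimension("gamma", 1e-4, 1.0, log=True),
    ],
    "adaboost": [
        Dimension("n_estimators", 50, 300, integer=True),
        Dimension("learning_rate", 0.01, 1.0, log=True),
    ],
    "gradient_boosting": [
        Dimension("n_estimators", 50, 300, integer=True),
        Dimension("learning_rate", 0.01, 0.3, log=True),
        Dimension("max_depth", 2, 6, integer=True),
    ],
}


@dataclass
class ClassifierSpec:
    """What to fit: an ML family, the duration baseline, or one feature."""

    family: str  # ML family, "baseline_duration" or "single_feature"
    feature: Optional[str] = None  # required for single_feature
    name: Optional[str] = None
    search_budget: int = 16

    def __post_init__(self) -> None:
        if self.family == "single_feature":
            if self.feature not in FEATURE_NAMES:
                raise ValueError(f"unknown feature {self.feature!r}")
        elif self.family == "baseline_duration":
            self.feature = "scan_duration"
        elif self.family not in ML_FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")
        if self.name is None:
            self.name = self.family if self.feature is None else f"{self.family}:{self.feature}"


@dataclass
class CurveSet:
    fpr: np.ndarray
    tpr: np.ndarray
    roc_auc: float
    precisions: np.ndarray
    recalls: np.ndarray
    thresholds: np.ndarray
    pr_auc: float


@dataclass
class ClassifierResult:
    spec: ClassifierSpec
    fold_metrics: list[dict] = field(default_factory=list)
    pooled: dict = field(default_factory=dict)
    predictions: Optional[pd.DataFrame] = None
    fold_params: list[dict] = field(default_factory=list)


@dataclass
class ImportanceReport:
    mean: dict[str, float]
    sd: dict[str, float]
    n_boot: int


def baseline_predict(scan_duration: float, theta: float) -> str:
    """Duration rule g: reliable iff scan_duration >= theta."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    return "reliable" if scan_duration >= theta else POSITIVE_LABEL


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "precision": precision, "recall": recall, "f1": f1}


def roc_pr_curves(scores: np.ndarray, labels: np.ndarray) -> CurveSet:
    """ROC (trapezoid AUC) and PR (step-wise AUC) analysis.

    ``labels`` are 1 for unreliable; higher scores must indicate the
    positive class.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required for ROC/PR analysis")
    fpr, tpr, _ = roc_curve(labels, scores)
    prec, rec, thr = precision_recall_curve(labels, scores)
    return CurveSet(fpr=fpr, tpr=tpr, roc_auc=float(auc(fpr, tpr)),
                    precisions=prec, recalls=rec, thresholds=thr,
                    pr_auc=float(average_precision_score(labels, scores)))


def select_operating_point(precisions, recalls, thresholds) -> float:
    """Threshold closest to the ideal classifier (precision = recall = 1).

    Accepts the sklearn convention where the PR arrays carry one final
    sentinel point without a threshold.  Ties break toward higher recall.
    """
    precisions = np.asarray(precisions, dtype=float)
    recalls = np.asarray(recalls, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("empty threshold array")
    if precisions.size == thresholds.size + 1:
        precisions, recalls = precisions[:-1], recalls[:-1]
    if precisions.size != thresholds.size:
        raise ValueError("misaligned precision/recall/threshold arrays")
    d2 = (precisions - 1.0) ** 2 + (recalls - 1.0) ** 2
    best = np.min(d2)
    cand = np.flatnonzero(d2 <= best + 1e-12)
    winner = cand[np.argmax(recalls[cand])]
    return float(thresholds[winner])


class ThresholdClassifier:
    """One-feature rule of the baseline form: reliable iff oriented value >= theta.

    ``orientation`` +1 means higher feature values indicate reliability
    (as for durations and coverages); -1 flips the sign.  For the
    duration baseline the orientation is fixed; for g' classifiers it is
    chosen on training data by ROC-AUC.
    """

    def __init__(self, feature: str, orientation: Optional[int] = None):
        self.feature = feature
        self.orientation = orientation
        self.theta: Optional[float] = None

    def fit(self, df: pd.DataFrame) -> "ThresholdClassifier":
        y = label_array(df)
        if len(np.unique(y)) < 2:
            raise ValueError("both classes required to fit a threshold classifier")
        x = df[self.feature].to_numpy(dtype=float)
        if self.orientation is None:
            auc_pos_low = roc_auc_score(y, -x)  # low values => unreliable
            self.orientation = 1 if auc_pos_low >= 1.0 - auc_pos_low else -1
        v = self.orientation * x
        # candidate cutoffs: every observed value (Eq-1 semantics: v < theta => unreliable)
        cand = np.unique(v)
        cand = np.concatenate([cand, [cand[-1] + 1.0]])
        stats = [(_confusion(y, (v < th).astype(int)), th) for th in cand]
        d2 = [(m["precision"] - 1) ** 2 + (m["recall"] - 1) ** 2 for m, _ in stats]
        best = min(d2)
        ties = [i for i, val in enumerate(d2) if val <= best + 1e-12]
        winner = max(ties, key=lambda i: stats[i][0]["recall"])
        self.theta = float(stats[winner][1])
        return self

    def scores(self, df: pd.DataFrame) -> np.ndarray:
        # higher score => more likely unreliable (positive)
        return -self.orientation * df[self.feature].to_numpy(dtype=float)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        if self.theta is None:
            raise RuntimeError("classifier not fitted")
        v = self.orientation * df[self.feature].to_numpy(dtype=float)
        return (v < self.theta).astype(int)


def single_feature_fit(train: pd.DataFrame, feature: str) -> ThresholdClassifier:
    """Fit a g' classifier on one AIF/VOF feature (orientation + cutoff)."""
    return ThresholdClassifier(feature).fit(train)


def label_array(df: pd.DataFrame) -> np.ndarray:
    return (df["label"] == POSITIVE_LABEL).to_numpy(dtype=int)


def make_estimator(family: str, params: dict, seed: int):
    if family == "random_forest":
        clf = RandomForestClassifier(random_state=seed, **params)
    elif family == "logistic_regression":
        clf = Pipeline([("scale", StandardScaler()),
                        ("clf", LogisticRegression(max_iter=2000, random_state=seed, **params))])
    elif family == "svm_linear":
        clf = Pipeline([("scale", StandardScaler()),
                        ("clf", SVC(kernel="linear", random_state=seed, **params))])
    elif family == "svm_rbf":
        clf = Pipeline([("scale", StandardScaler()),
                        ("clf", SVC(kernel="rbf", random_state=seed, **params))])
    elif family == "adaboost":
        clf = AdaBoostClassifier(random_state=seed, **params)
    elif family == "gradient_boosting":
        clf = GradientBoostingClassifier(random_state=seed, **params)
    else:
        raise ValueError(f"unknown family {family!r}")
    return clf


def _estimator_scores(est, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(X), dtype=float)
    return np.asarray(est.predict_proba(X)[:, 1], dtype=float)


class MLClassifier:
    """A fitted sklearn estimator plus its selected operating point."""

    def __init__(self, estimator, params: dict):
        self.estimator = estimator
        self.params = params
        self.theta: Optional[float] = None

    def scores(self, df: pd.DataFrame) -> np.ndarray:
        return _estimator_scores(self.estimator, df[list(FEATURE_NAMES)].to_numpy(float))

    def set_operating_point(self, df: pd.DataFrame) -> None:
        y = label_array(df)
        s = self.scores(df)
        prec, rec, thr = precision_recall_curve(y, s)
        self.theta = select_operating_point(prec, rec, thr)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        if self.theta is None:
            raise RuntimeError("operating point not selected")
        return (self.scores(df) >= self.theta).astype(int)


def fit_ml_model(train: pd.DataFrame, spec: ClassifierSpec, seed: int,
                 inner_cv_folds: int = 3, search_budget: Optional[int] = None) -> MLClassifier:
    """Hyperparameter search (inner grouped CV, PR-AUC) then refit.

    ``train`` may already contain augmented rows; grouping by scan_id
    keeps a scan's originals and copies on the same side of every inner
    split.
    """
    budget = spec.search_budget if search_budget is None else search_budget
    if budget < 1:
        raise ValueError("search budget must be >= 1")
    space = SEARCH_SPACES[spec.family]
    X = train[list(FEATURE_NAMES)].to_numpy(float)
    y = label_array(train)
    groups = train["scan_id"].to_numpy()
    n_groups = len(np.unique(groups))
    folds = min(inner_cv_folds, n_groups)
    rng = np.random.default_rng(seed)

    def objective(params: dict) -> float:
        est_seed = seed
        aps = []
        for tr, va in GroupKFold(n_splits=folds).split(X, y, groups):
            if len(np.unique(y[tr])) < 2 or y[va].sum() == 0:
                continue
            est = make_estimator(spec.family, params, est_seed)
            est.fit(X[tr], y[tr])
            aps.append(average_precision_score(y[va], _estimator_scores(est, X[va])))
        return float(np.mean(aps)) if aps else 0.0

    best_params, _, _ = bayes_search(objective, space, n_calls=budget, rng=rng)
    est = make_estimator(spec.family, best_params, seed)
    est.fit(X, y)
    return MLClassifier(est, best_params)


def _augment_records(train: pd.DataFrame, params: AugmentationParams,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Append augmented copies of every training record (labels inherited)."""
    if params is None or params.n_augment_per_sample == 0:
        out = train.copy()
        out["is_augmented"] = False
        return out
    rows = []
    for _, row in train.iterrows():
        fv = FeatureVector(**{n: float(row[n]) for n in FEATURE_NAMES})
        for aug in augment_features(fv, params, rng):
            r = {n: getattr(aug, n) for n in FEATURE_NAMES}
            r.update({"scan_id": row["scan_id"], "label": row["label"],
                      "duration_s": row["duration_s"],
                      "osd_s": row.get("osd_s", np.nan), "is_augmented": True})
            rows.append(r)
    out = train.copy()
    out["is_augmented"] = False
    return pd.concat([out, pd.DataFrame(rows)], ignore_index=True)


def _fit_one(spec: ClassifierSpec, train_aug: pd.DataFrame, seed: int,
             search_budget: Optional[int]):
    if spec.family == "baseline_duration":
        model = ThresholdClassifier("scan_duration", orientation=1).fit(train_aug)
    elif spec.family == "single_feature":
        model = single_feature_fit(train_aug, spec.feature)
    else:
        model = fit_ml_model(train_aug, spec, seed=seed, search_budget=search_budget)
        model.set_operating_point(train_aug)
    return model


def grouped_cross_validate(dataset: pd.DataFrame, specs: list[ClassifierSpec],
                           k: int = 5, aug_params: Optional[AugmentationParams] = None,
                           seed: int = 0, search_budget: Optional[int] = None
                           ) -> dict[str, ClassifierResult]:
    """Scan-grouped k-fold cross-validation shared across all specs.

    Folds partition scan ids; training folds are augmented; operating
    points come from training data only; metrics are reported per fold
    and pooled over the concatenated test predictions.
    """
    groups = dataset["scan_id"].to_numpy()
    n_scans = len(np.unique(groups))
    if k > n_scans:
        raise ValueError(f"k={k} exceeds the number of scans ({n_scans})")
    gkf = GroupKFold(n_splits=k, shuffle=True, random_state=seed % (2 ** 31))
    splits = list(gkf.split(dataset, groups=groups))
    seeds = np.random.SeedSequence(seed).spawn(k)

    results = {spec.name: ClassifierResult(spec=spec) for spec in specs}
    pred_rows: dict[str, list[pd.DataFrame]] = {spec.name: [] for spec in specs}

    for fold_i, (tr, te) in enumerate(splits):
        train = dataset.iloc[tr].reset_index(drop=True)
        test = dataset.iloc[te].reset_index(drop=True)
        fold_seed = int(seeds[fold_i].generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
        rng = np.random.default_rng(seeds[fold_i])
        train_aug = _augment_records(train, aug_params, rng)
        y_test = label_array(test)
        for spec in specs:
            model = _fit_one(spec, train_aug, fold_seed, search_budget)
            s = model.scores(test)
            y_pred = model.predict(test)
            m = _confusion(y_test, y_pred)
            if len(np.unique(y_test)) == 2:
                m["roc_auc"] = float(roc_auc_score(y_test, s))
                m["pr_auc"] = float(average_precision_score(y_test, s))
            m["fold"] = fold_i
            m["theta"] = float(model.theta)
            results[spec.name].fold_metrics.append(m)
            if isinstance(model, MLClassifier):
                results[spec.name].fold_params.append(dict(model.params))
            pred_rows[spec.name].append(pd.DataFrame({
                "scan_id": test["scan_id"], "duration_s": test["duration_s"],
                "osd_s": test.get("osd_s", np.nan), "y_true": y_test,
                "y_pred": y_pred, "score": s, "fold": fold_i}))

    for spec in specs:
        res = results[spec.name]
        preds = pd.concat(pred_rows[spec.name], ignore_index=True)
        res.predictions = preds
        pooled = _confusion(preds["y_true"].to_numpy(), preds["y_pred"].to_numpy())
        curves = roc_pr_curves(preds["score"].to_numpy(), preds["y_true"].to_numpy())
        pooled["roc_auc"] = curves.roc_auc
        pooled["pr_auc"] = curves.pr_auc
        fold_df = pd.DataFrame(res.fold_metrics)
        for key in ("roc_auc", "pr_auc", "precision", "recall", "f1"):
            if key in fold_df:
                pooled[f"mean_fold_{key}"] = float(fold_df[key].mean())
        res.pooled = pooled
    return results


def evaluate_baseline_grid(predictions_source: pd.DataFrame,
                           thetas=BASELINE_THETA_GRID) -> dict[float, dict]:
    """Confusion metrics of the duration rule g at fixed cutoffs."""
    y = label_array(predictions_source) if "label" in predictions_source else \
        predictions_source["y_true"].to_numpy(int)
    d = predictions_source["duration_s"].to_numpy(float)
    out = {}
    for theta in thetas:
        y_pred = np.array([baseline_predict(x, theta) == POSITIVE_LABEL for x in d], dtype=int)
        out[float(theta)] = _confusion(y, y_pred)
    return out


def bootstrap_importance(dataset: pd.DataFrame, n_boot: int = 100, seed: int = 0,
                         params: Optional[dict] = None) -> ImportanceReport:
    """Impurity-based feature importance of gradient boosting over
    bootstrap resamples of the scans (drawn with replacement)."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    params = params or {"n_estimators": 150, "learning_rate": 0.1, "max_depth": 3}
    scan_ids = np.unique(dataset["scan_id"])
    rng = np.random.default_rng(seed)
    imps = []
    for b in range(n_boot):
        for _ in range(100):
            take = rng.choice(scan_ids, size=len(scan_ids), replace=True)
            rep = pd.concat([dataset[dataset["scan_id"] == sid] for sid in take],
                            ignore_index=True)
            y = label_array(rep)
            if len(np.unique(y)) == 2:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap replicate")
        est = GradientBoostingClassifier(random_state=int(rng.integers(2 ** 31)), **params)
        est.fit(rep[list(FEATURE_NAMES)].to_numpy(float), y)
        imps.append(est.feature_importances_)
    arr = np.vstack(imps)
    return ImportanceReport(
        mean={n: float(m) for n, m in zip(FEATURE_NAMES, arr.mean(axis=0))},
        sd={n: float(s) for n, s in zip(FEATURE_NAMES, arr.std(axis=0, ddof=1))},
        n_boot=n_boot)


def error_by_osd_gap(predictions: pd.DataFrame, window_s: float = 2.30,
                     bin_width_s: float = 1.0) -> dict:
    """Distribution of (scan duration - OSD) for correct vs incorrect
    predictions, and the error rate outside the +/- window."""
    gap = predictions["duration_s"].to_numpy(float) - predictions["osd_s"].to_numpy(float)
    correct = predictions["y_true"].to_numpy() == predictions["y_pred"].to_numpy()
    lo = np.floor(gap.min()) if len(gap) else 0.0
    hi = np.ceil(gap.max()) + bin_width_s if len(gap) else 1.0
    edges = np.arange(lo, hi + bin_width_s, bin_width_s)
    hist_correct, _ = np.histogram(gap[correct], bins=edges)
    hist_incorrect, _ = np.histogram(gap[~correct], bins=edges)
    outside = np.abs(gap) > window_s
    n_out = int(outside.sum())
    n_err_out = int((outside & ~correct).sum())
    rate = 100.0 * n_err_out / n_out if n_out else 0.0
    return {"bin_edges_s": edges.tolist(),
            "correct": hist_correct.tolist(),
            "incorrect": hist_incorrect.tolist(),
            "window_s": window_s,
            "n_outside_window": n_out,
            "n_errors_outside_window": n_err_out,
            "error_rate_outside_window_pct": rate}
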