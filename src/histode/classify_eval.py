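"""Stratified splitting, the eight benchmark classifiers, and the metric
report suite.

Classifier families and their default hyperparameters:

====================  =====================================================
medium_nn             MLP, hidden layers 64/32, ReLU, Adam lr=0.001,
                      batch 32, 10 epochs
wide_nn               MLP, hidden layers 256/128, same schedule
linear_svm            SVC linear kernel, C=1.0, gamma=scale, probability
quadratic_svm         SVC poly kernel degree 2, C=1.0, coef0=0, probability
cubic_svm             SVC poly kernel degree 3, C=1.0, coef0=0, probability
bagged_trees          50 bootstrap-aggregated decision trees
boosted_trees         gradient boosting, 100 learners, depth 3, lr 0.1
adaboost_trees        AdaBoost on stumps, 100 iterations, lr 0.5 (SAMME)
====================  =====================================================

Metrics are computed from the confusion matrix: accuracy, one-vs-rest
per-class precision/sensitivity/specificity/F1, macro aggregates, balanced
accuracy (macro sensitivity), Cohen's kappa, macro one-vs-rest AUC, a Wald
95% half-width on test accuracy, and wall-clock prediction time (recorded
for comparison tables but hardware-dependent).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
)
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import (
    InvalidConfigError,
    InvalidDatasetError,
    LabelSetError,
    PairingError,
)
from .io import FeatureMatrix

__all__ = [
    "SplitSpec",
    "ClassifierSpec",
    "EvaluationReport",
    "FAMILIES",
    "stratified_split",
    "build_classifier",
    "confusion_matrix",
    "f1_from_pr",
    "evaluate",
    "compare_reports",
    "report_table",
    "per_class_table",
]

FAMILIES = (
    "medium_nn",
    "wide_nn",
    "linear_svm",
    "quadratic_svm",
    "cubic_svm",
    "bagged_trees",
    "boosted_trees",
    "adaboost_trees",
)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    """Three-way stratified split proportions (default 65/15/20, seed 42)."""

    train_fraction: float = 0.65
    validation_fraction: float = 0.15
    test_fraction: float = 0.20
    seed: int = 42
    stratified: bool = True

    def validate(self) -> None:
        fracs = (self.train_fraction, self.validation_fraction, self.test_fraction)
        if any(not 0.0 < f < 1.0 for f in fracs):
            raise InvalidConfigError("all fractions must lie in (0, 1)")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise InvalidConfigError(f"fractions must sum to 1, got {sum(fracs)}")

    def to_dict(self) -> dict:
        return {
            "train_fraction": self.train_fraction,
            "validation_fraction": self.validation_fraction,
            "test_fraction": self.test_fraction,
            "seed": self.seed,
            "stratified": self.stratified,
        }


@dataclass
class Split:
    train: FeatureMatrix
    validation: FeatureMatrix
    test: FeatureMatrix
    train_idx: np.ndarray
    validation_idx: np.ndarray
    test_idx: np.ndarray


def _allocate(n: int, fractions: np.ndarray, deficit: np.ndarray) -> np.ndarray:
    """Split n into len(fractions) integer counts, each within 1 of its quota
    n·f.  Leftover units go to the parts with the largest fractional
    remainder plus accumulated global deficit, so per-part totals track the
    requested proportions across groups (controlled rounding)."""
    quota = n * fractions
    base = np.floor(quota).astype(int)
    leftover = n - base.sum()
    priority = (quota - base) + deficit
    order = np.argsort(-priority, kind="stable")
    counts = base.copy()
    counts[order[:leftover]] += 1
    return counts


def stratified_split(data: FeatureMatrix, spec: SplitSpec) -> Split:
    """Exact, disjoint, exhaustive three-way split; per-class proportions
    within ±1 sample of the requested fractions; deterministic per seed."""
    spec.validate()
    labels = data.labels.astype(str)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 3:
        raise InvalidDatasetError(
            "every class needs at least 3 samples for a three-way split"
        )
    rng = np.random.default_rng(spec.seed)
    fracs = np.array(
        [spec.train_fraction, spec.validation_fraction, spec.test_fraction]
    )
    groups: list[np.ndarray]
    if spec.stratified:
        groups = [
            np.flatnonzero(labels == cls) for cls in sorted(set(labels.tolist()))
        ]
    else:
        groups = [np.arange(data.n)]
    parts: list[list[np.ndarray]] = [[], [], []]
    deficit = np.zeros(3)
    for g in groups:
        g = rng.permutation(g)
        alloc = _allocate(len(g), fracs, deficit)
        deficit += len(g) * fracs - alloc
        bounds = np.cumsum(alloc)
        parts[0].append(g[: bounds[0]])
        parts[1].append(g[bounds[0] : bounds[1]])
        parts[2].append(g[bounds[1] :])
    train_idx, val_idx, test_idx = (
        np.sort(np.concatenate(p)) for p in parts
    )
    return Split(
        data.subset(train_idx),
        data.subset(val_idx),
        data.subset(test_idx),
        train_idx,
        val_idx,
        test_idx,
    )


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

@dataclass
class ClassifierSpec:
    """A classifier family plus any hyperparameter overrides (overrides are
    echoed into the evaluation report)."""

    family: str
    hyperparameters: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise InvalidConfigError(
                f"unknown classifier family {self.family!r}; choose from {FAMILIES}"
            )


def build_classifier(spec: ClassifierSpec):
    """Instantiate the family's default configuration, then apply overrides."""
    spec.validate()
    f = spec.family
    if f == "medium_nn":
        model = MLPClassifier(
            hidden_layer_sizes=(64, 32), activation="relu", solver="adam",
            learning_rate_init=0.001, batch_size=32, max_iter=10, random_state=42,
        )
    elif f == "wide_nn":
        model = MLPClassifier(
            hidden_layer_sizes=(256, 128), activation="relu", solver="adam",
            learning_rate_init=0.001, batch_size=32, max_iter=10, random_state=42,
        )
    elif f == "linear_svm":
        model = SVC(kernel="linear", C=1.0, gamma="scale", probability=True,
                    random_state=42)
    elif f == "quadratic_svm":
        model = SVC(kernel="poly", degree=2, C=1.0, gamma="scale", coef0=0.0,
                    probability=True, random_state=42)
    elif f == "cubic_svm":
        model = SVC(kernel="poly", degree=3, C=1.0, gamma="scale", coef0=0.0,
                    probability=True, random_state=42)
    elif f == "bagged_trees":
        model = BaggingClassifier(
            estimator=DecisionTreeClassifier(),
            n_estimators=50, bootstrap=True, random_state=42,
        )
    elif f == "boosted_trees":
        model = GradientBoostingClassifier(
            n_estimators=100, subsample=1.0, criterion="friedman_mse",
            max_depth=3, learning_rate=0.1, random_state=42,
        )
    else:  # adaboost_trees
        model = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1, criterion="gini"),
            n_estimators=100, learning_rate=0.5, random_state=42,
        )
    if spec.hyperparameters:
        model.set_params(**spec.hyperparameters)
    return model


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def confusion_matrix(
    truth, predicted, classes: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """K×K counts: entry (i, j) is the number of samples of true class i
    predicted as class j."""
    truth = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if truth.shape != predicted.shape:
        raise InvalidDatasetError("truth and predictions have different lengths")
    if classes is None:
        classes = sorted(set(truth.tolist()))
    index = {c: i for i, c in enumerate(classes)}
    K = len(classes)
    C = np.zeros((K, K), dtype=np.int64)
    for t, p in zip(truth, predicted):
        if t not in index or p not in index:
            raise LabelSetError(
                f"label outside the declared class set {classes}: {t!r}/{p!r}"
            )
        C[index[t], index[p]] += 1
    return C, list(classes)


def f1_from_pr(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity, at table precision
    (4 decimals).  Defined as 0 (with a warning) when both inputs are 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= sensitivity <= 1.0):
        raise InvalidConfigError("precision and sensitivity must be in [0, 1]")
    if precision == 0.0 and sensitivity == 0.0:
        warnings.warn("precision and sensitivity both 0; F1 defined as 0")
        return 0.0
    return round(2 * precision * sensitivity / (precision + sensitivity), 4)


@dataclass
class EvaluationReport:
    """Aggregate and per-class test metrics for one trained classifier."""

    model_name: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    misclassification_rate: float
    auc: float | None
    ci_halfwidth: float
    balanced_accuracy: float
    cohens_kappa: float
    per_class: dict[str, dict[str, float]]
    confusion: np.ndarray
    classes: list[str]
    prediction_time_s: float  # wall-clock; hardware-dependent, informational
    n_test: int
    config_echo: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "misclassification_rate": self.misclassification_rate,
            "auc": self.auc,
            "ci_halfwidth": self.ci_halfwidth,
            "balanced_accuracy": self.balanced_accuracy,
            "cohens_kappa": self.cohens_kappa,
            "per_class": self.per_class,
            "confusion": self.confusion.tolist(),
            "classes": self.classes,
            "prediction_time_s": self.prediction_time_s,
            "n_test": self.n_test,
            "config_echo": self.config_echo,
        }


def metrics_from_confusion(C: np.ndarray, classes: list[str]) -> dict:
    """All confusion-derived quantities (everything except AUC and timing)."""
    C = np.asarray(C, dtype=np.float64)
    n = C.sum()
    per_class: dict[str, dict[str, float]] = {}
    for i, cls in enumerate(classes):
        tp = C[i, i]
        fn = C[i, :].sum() - tp
        fp = C[:, i].sum() - tp
        tn = n - tp - fn - fp
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        sens = tp / (tp + fn) if tp + fn > 0 else 0.0
        spec = tn / (tn + fp) if tn + fp > 0 else 0.0
        f1 = 2 * prec * sens / (prec + sens) if prec + sens > 0 else 0.0
        per_class[cls] = {
            "precision": prec, "sensitivity": sens, "f1": f1, "specificity": spec,
        }
    acc = float(np.trace(C) / n)
    macro = lambda key: float(np.mean([v[key] for v in per_class.values()]))
    row = C.sum(axis=1)
    col = C.sum(axis=0)
    p_o = acc
    p_e = float((row * col).sum() / (n * n))
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1.0 else 1.0
    return {
        "accuracy": acc,
        "precision": macro("precision"),
        "recall": macro("sensitivity"),
        "f1": macro("f1"),
        "misclassification_rate": 1.0 - acc,
        "balanced_accuracy": macro("sensitivity"),
        "cohens_kappa": float(kappa),
        "per_class": per_class,
    }


def evaluate(
    model,
    test: FeatureMatrix,
    model_name: str = "",
    classes: list[str] | None = None,
    config_echo: dict | None = None,
) -> EvaluationReport:
    """Score a trained model on a held-out partition.

    Aggregate precision/recall/F1 are unweighted (macro) means of the
    one-vs-rest per-class values; AUC is macro one-vs-rest over class
    probabilities (or decision scores), reported absent when the model
    exposes neither; the CI half-width is the Wald 95% interval
    1.96·√(acc(1−acc)/n)."""
    if test.n == 0:
        raise InvalidDatasetError("test partition is empty")
    X, y = test.values, test.labels.astype(str)
    t0 = time.perf_counter()
    pred = model.predict(X)
    elapsed = time.perf_counter() - t0
    if classes is None:
        classes = sorted(set(y.tolist()) | set(np.asarray(pred, dtype=str).tolist()))
    C, classes = confusion_matrix(y, pred, classes)
    m = metrics_from_confusion(C, classes)

    auc: float | None = None
    scores = None
    if hasattr(model, "predict_proba"):
        scores = model.predict_proba(X)
    elif hasattr(model, "decision_function"):
        scores = model.decision_function(X)
    if scores is not None:
        try:
            if len(classes) == 2:
                s = scores[:, 1] if scores.ndim == 2 else scores
                auc = float(roc_auc_score((y == classes[1]).astype(int), s))
            else:
                auc = float(
                    roc_auc_score(y, scores, multi_class="ovr",
                                  average="macro", labels=classes)
                )
        except ValueError:
            auc = None

    n = test.n
    ci = 1.96 * np.sqrt(m["accuracy"] * (1 - m["accuracy"]) / n)
    return EvaluationReport(
        model_name=model_name or type(model).__name__,
        accuracy=m["accuracy"],
        precision=m["precision"],
        recall=m["recall"],
        f1=m["f1"],
        misclassification_rate=m["misclassification_rate"],
        auc=auc,
        ci_halfwidth=float(ci),
        balanced_accuracy=m["balanced_accuracy"],
        cohens_kappa=m["cohens_kappa"],
        per_class=m["per_class"],
        confusion=C,
        classes=classes,
        prediction_time_s=float(elapsed),
        n_test=int(n),
        config_echo=config_echo or {},
    )


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def report_table(reports: list[EvaluationReport]) -> pd.DataFrame:
    """One row per classifier: the aggregate-metric table layout."""
    rows = []
    for r in reports:
        rows.append(
            {
                "Model Name": r.model_name,
                "Accuracy": round(r.accuracy, 4),
                "Precision": round(r.precision, 4),
                "Recall": round(r.recall, 4),
                "F1-Score": round(r.f1, 4),
                "Misclassification Rate": round(r.misclassification_rate, 4),
                "AUC": round(r.auc, 4) if r.auc is not None else None,
                "CI": f"{round(r.accuracy, 4)} ± {round(r.ci_halfwidth, 4)}",
                "Balanced Accuracy": round(r.balanced_accuracy, 4),
                "Cohen's Kappa": round(r.cohens_kappa, 5),
            }
        )
    return pd.DataFrame(rows)


def per_class_table(report: EvaluationReport) -> pd.DataFrame:
    """Class-wise precision/sensitivity/F1/specificity table."""
    rows = []
    for cls in report.classes:
        v = report.per_class[cls]
        rows.append(
            {
                "Classes": cls,
                "Precision": round(v["precision"], 4),
                "Sensitivity": round(v["sensitivity"], 4),
                "F1-Score": round(v["f1"], 4),
                "Specificity": round(v["specificity"], 4),
            }
        )
    return pd.DataFrame(rows)


def compare_reports(
    before: dict[str, EvaluationReport], after: dict[str, EvaluationReport]
) -> pd.DataFrame:
    """Per-family accuracy difference (after − before) and prediction-time
    speed-up (before/after, rendered as "N.NN×")."""
    if set(before) != set(after):
        raise PairingError(
            f"classifier families differ: {sorted(before)} vs {sorted(after)}"
        )
    rows = []
    for family in before:
        b, a = before[family], after[family]
        speedup = (
            b.prediction_time_s / a.prediction_time_s
            if a.prediction_time_s > 0
            else float("inf")
        )
        rows.append(
            {
                "Classifiers": family,
                "Accuracy (before)": b.accuracy,
                "Accuracy (after)": a.accuracy,
                "Accuracy Difference": a.accuracy - b.accuracy,
                "Prediction Time (before, s)": b.prediction_time_s,
                "Prediction Time (after, s)": a.prediction_time_s,
                "Speed-Up": f"{speedup:.2f}×",
            }
        )
    return pd.DataFrame(rows)
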