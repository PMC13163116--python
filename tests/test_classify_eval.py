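"""Splitting, classifier configuration, and the metric suite."""

import numpy as np
import pytest

from histode import (
    ClassifierSpec,
    EvaluationReport,
    SplitSpec,
    SyntheticSpec,
    build_classifier,
    compare_reports,
    confusion_matrix,
    evaluate,
    f1_from_pr,
    generate_features,
    per_class_table,
    report_table,
    stratified_split,
)
from histode.classify_eval import FAMILIES, metrics_from_confusion
from histode.errors import (
    InvalidConfigError,
    InvalidDatasetError,
    LabelSetError,
    PairingError,
)


# ---------------------------------------------------------------------------
# stratified_split
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def balanced_data():
    spec = SyntheticSpec(d=6, n_per_class=50, n_classes=2, seed=0)
    data, _ = generate_features(spec)
    return data


def test_split_proportions_and_balance(balanced_data):
    split = stratified_split(balanced_data, SplitSpec())
    assert split.train.n == 65
    assert split.validation.n == 15
    assert split.test.n == 20
    for part in (split.train, split.validation, split.test):
        _, counts = np.unique(part.labels.astype(str), return_counts=True)
        assert abs(counts[0] - counts[1]) <= 1


def test_split_is_exact_partition_and_deterministic(balanced_data):
    s1 = stratified_split(balanced_data, SplitSpec(seed=42))
    s2 = stratified_split(balanced_data, SplitSpec(seed=42))
    np.testing.assert_array_equal(s1.train_idx, s2.train_idx)
    np.testing.assert_array_equal(s1.test_idx, s2.test_idx)
    all_idx = np.concatenate([s1.train_idx, s1.validation_idx, s1.test_idx])
    assert len(all_idx) == balanced_data.n
    assert len(np.unique(all_idx)) == balanced_data.n


def test_split_per_class_proportions_within_one_sample():
    spec = SyntheticSpec(d=4, n_per_class=97, n_classes=3, seed=1)
    data, _ = generate_features(spec)
    sp = SplitSpec()
    split = stratified_split(data, sp)
    for cls in data.classes:
        n_cls = int(np.sum(data.labels.astype(str) == cls))
        for part, frac in (
            (split.train, sp.train_fraction),
            (split.validation, sp.validation_fraction),
            (split.test, sp.test_fraction),
        ):
            got = int(np.sum(part.labels.astype(str) == cls))
            assert abs(got - frac * n_cls) <= 1


def test_split_rejects_tiny_classes_and_bad_fractions():
    spec = SyntheticSpec(d=3, n_per_class=2, n_classes=2, seed=0)
    data, _ = generate_features(spec)
    with pytest.raises(InvalidDatasetError):
        stratified_split(data, SplitSpec())
    with pytest.raises(InvalidConfigError):
        SplitSpec(0.5, 0.3, 0.3).validate()
    with pytest.raises(InvalidConfigError):
        SplitSpec(0.0, 0.5, 0.5).validate()


def test_alternative_80_10_10_protocol(balanced_data):
    split = stratified_split(balanced_data, SplitSpec(0.80, 0.10, 0.10))
    assert (split.train.n, split.validation.n, split.test.n) == (80, 10, 10)


# ---------------------------------------------------------------------------
# build_classifier
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "family, checks",
    [
        ("medium_nn", {"hidden_layer_sizes": (64, 32), "activation": "relu",
                       "solver": "adam", "learning_rate_init": 0.001,
                       "batch_size": 32, "max_iter": 10}),
        ("wide_nn", {"hidden_layer_sizes": (256, 128)}),
        ("linear_svm", {"kernel": "linear", "C": 1.0, "probability": True}),
        ("quadratic_svm", {"kernel": "poly", "degree": 2, "C": 1.0, "coef0": 0.0}),
        ("cubic_svm", {"kernel": "poly", "degree": 3, "C": 1.0}),
        ("bagged_trees", {"n_estimators": 50, "bootstrap": True}),
        ("boosted_trees", {"n_estimators": 100, "max_depth": 3,
                           "learning_rate": 0.1, "subsample": 1.0}),
        ("adaboost_trees", {"n_estimators": 100, "learning_rate": 0.5}),
    ],
)
def test_default_hyperparameters(family, checks):
    model = build_classifier(ClassifierSpec(family))
    params = model.get_params()
    for key, val in checks.items():
        assert params[key] == val, f"{family}.{key}"


def test_adaboost_uses_depth_one_stumps():
    model = build_classifier(ClassifierSpec("adaboost_trees"))
    assert model.get_params()["estimator"].max_depth == 1


def test_unknown_family_and_overrides():
    with pytest.raises(InvalidConfigError):
        build_classifier(ClassifierSpec("random_forest"))
    model = build_classifier(
        ClassifierSpec("bagged_trees", {"n_estimators": 7})
    )
    assert model.get_params()["n_estimators"] == 7


# ---------------------------------------------------------------------------
# confusion matrix
# ---------------------------------------------------------------------------

def test_confusion_perfect_predictions_are_diagonal():
    y = np.repeat(["a", "b", "c"], 4)
    C, classes = confusion_matrix(y, y)
    assert classes == ["a", "b", "c"]
    np.testing.assert_array_equal(C, np.diag([4, 4, 4]))


def test_confusion_conservation_and_swap_locality(rng):
    classes = ["a", "b", "c"]
    y = rng.choice(classes, 60)
    p = rng.choice(classes, 60)
    C, _ = confusion_matrix(y, p, classes)
    assert C.sum() == 60
    # swapping two prediction entries moves exactly 2 units of mass
    p2 = p.copy()
    i, j = 0, 1
    while p2[i] == p2[j]:
        j += 1
    p2[i], p2[j] = p2[j], p2[i]
    C2, _ = confusion_matrix(y, p2, classes)
    assert np.abs(C2 - C).sum() in (0, 2, 4)  # 0/4 possible if truths differ
    assert C2.sum() == 60


def test_confusion_rejects_unseen_label():
    with pytest.raises(LabelSetError):
        confusion_matrix(["a", "b"], ["a", "z"], classes=["a", "b"])


# ---------------------------------------------------------------------------
# F1 worked examples
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "precision, sensitivity, expected",
    [
        (0.9810, 0.9830, 0.9820),
        (1.0000, 1.0000, 1.0000),
        (0.9690, 0.9632, 0.9661),
    ],
)
def test_f1_harmonic_mean_examples(precision, sensitivity, expected):
    assert f1_from_pr(precision, sensitivity) == pytest.approx(expected, abs=5e-5)


def test_f1_both_zero_warns_and_returns_zero():
    with pytest.warns(UserWarning):
        assert f1_from_pr(0.0, 0.0) == 0.0


# ---------------------------------------------------------------------------
# evaluate
# ---------------------------------------------------------------------------

class _FixedPredictor:
    """Deterministic stand-in model returning canned predictions."""

    def __init__(self, predictions):
        self._p = np.asarray(predictions, dtype=object)

    def predict(self, X):
        return self._p


def _matrix(labels):
    labels = np.asarray(labels, dtype=object)
    values = np.zeros((len(labels), 2))
    from histode import FeatureMatrix

    return FeatureMatrix(values, labels)


def test_perfect_predictions_give_unit_metrics():
    y = np.repeat([f"c{k}" for k in range(5)], 10)
    report = evaluate(_FixedPredictor(y), _matrix(y), model_name="perfect")
    assert report.accuracy == 1.0
    assert report.cohens_kappa == 1.0
    assert report.auc is None  # no scores exposed, reported absent
    assert all(v["specificity"] == 1.0 for v in report.per_class.values())
    assert report.misclassification_rate == 0.0


def test_random_predictions_have_near_zero_kappa():
    rng = np.random.default_rng(0)
    classes = [f"c{k}" for k in range(4)]
    y = rng.choice(classes, 10_000)
    p = rng.choice(classes, 10_000)
    report = evaluate(_FixedPredictor(p), _matrix(y))
    assert abs(report.cohens_kappa) < 0.02


def test_metrics_match_brute_force_counting(rng):
    """Confusion-derived metrics equal direct counting over pairs."""
    classes = ["a", "b", "c", "d"]
    for _ in range(200):
        n = int(rng.integers(4, 40))
        y = rng.choice(classes, n)
        p = rng.choice(classes, n)
        C, _ = confusion_matrix(y, p, classes)
        m = metrics_from_confusion(C, classes)
        assert m["accuracy"] == pytest.approx(np.mean(y == p))
        for i, cls in enumerate(classes):
            tp = np.sum((y == cls) & (p == cls))
            fp = np.sum((y != cls) & (p == cls))
            fn = np.sum((y == cls) & (p != cls))
            prec = tp / (tp + fp) if tp + fp else 0.0
            sens = tp / (tp + fn) if tp + fn else 0.0
            assert m["per_class"][cls]["precision"] == pytest.approx(prec)
            assert m["per_class"][cls]["sensitivity"] == pytest.approx(sens)


def test_macro_metrics_invariant_under_relabeling(rng):
    classes = ["a", "b", "c"]
    y = rng.choice(classes, 300)
    p = rng.choice(classes, 300)
    C1, _ = confusion_matrix(y, p, classes)
    m1 = metrics_from_confusion(C1, classes)
    rename = {"a": "z", "b": "y", "c": "x"}
    y2 = np.array([rename[v] for v in y], dtype=object)
    p2 = np.array([rename[v] for v in p], dtype=object)
    C2, cl2 = confusion_matrix(y2, p2)
    m2 = metrics_from_confusion(C2, cl2)
    for key in ("precision", "recall", "f1", "balanced_accuracy", "cohens_kappa"):
        assert m1[key] == pytest.approx(m2[key])


def test_kappa_is_one_iff_confusion_diagonal(rng):
    diag = metrics_from_confusion(np.diag([5, 7, 3]), ["a", "b", "c"])
    assert diag["cohens_kappa"] == pytest.approx(1.0)
    off = metrics_from_confusion(np.array([[5, 1], [0, 6]]), ["a", "b"])
    assert off["cohens_kappa"] < 1.0


def test_misclassification_identity_and_ci(rng):
    y = rng.choice(["a", "b"], 200)
    p = rng.choice(["a", "b"], 200)
    r = evaluate(_FixedPredictor(p), _matrix(y))
    assert r.misclassification_rate == pytest.approx(1 - r.accuracy, abs=1e-12)
    assert r.ci_halfwidth == pytest.approx(
        1.96 * np.sqrt(r.accuracy * (1 - r.accuracy) / 200)
    )
    assert r.n_test == 200


def test_evaluate_rejects_empty_test():
    with pytest.raises(InvalidDatasetError):
        evaluate(_FixedPredictor([]), _matrix([]))


# ---------------------------------------------------------------------------
# comparison tables
# ---------------------------------------------------------------------------

def _report(name, acc, t):
    return EvaluationReport(
        model_name=name, accuracy=acc, precision=acc, recall=acc, f1=acc,
        misclassification_rate=1 - acc, auc=None, ci_halfwidth=0.0,
        balanced_accuracy=acc, cohens_kappa=acc, per_class={},
        confusion=np.zeros((2, 2), dtype=int), classes=["a", "b"],
        prediction_time_s=t, n_test=10,
    )


def test_comparison_reproduces_quadratic_svm_difference():
    before = {"quadratic_svm": _report("quadratic_svm", 0.9898104, 33.9344222)}
    after = {"quadratic_svm": _report("quadratic_svm", 0.9813742, 3.8435664)}
    table = compare_reports(before, after)
    assert table["Accuracy Difference"].iloc[0] == pytest.approx(-0.0084362)
    assert table["Speed-Up"].iloc[0] == "8.83×"


def test_comparison_identity_and_ratio():
    r = _report("linear_svm", 0.9, 20.0)
    table = compare_reports({"linear_svm": r}, {"linear_svm": r})
    assert table["Accuracy Difference"].iloc[0] == 0.0
    assert table["Speed-Up"].iloc[0] == "1.00×"
    fast = _report("linear_svm", 0.9, 2.0)
    table2 = compare_reports({"linear_svm": r}, {"linear_svm": fast})
    assert table2["Speed-Up"].iloc[0] == "10.00×"


def test_comparison_rejects_mismatched_families():
    with pytest.raises(PairingError):
        compare_reports(
            {"linear_svm": _report("linear_svm", 0.9, 1.0)},
            {"cubic_svm": _report("cubic_svm", 0.9, 1.0)},
        )


def test_report_tables_have_expected_columns(rng):
    y = rng.choice(["a", "b"], 50)
    r = evaluate(_FixedPredictor(y), _matrix(y), model_name="demo")
    agg = report_table([r])
    assert list(agg.columns) == [
        "Model Name", "Accuracy", "Precision", "Recall", "F1-Score",
        "Misclassification Rate", "AUC", "CI", "Balanced Accuracy",
        "Cohen's Kappa",
    ]
    pc = per_class_table(r)
    assert list(pc.columns) == [
        "Classes", "Precision", "Sensitivity", "F1-Score", "Specificity",
    ]
    assert len(pc) == len(r.classes)


def test_all_families_exceed_chance_on_planted_features(planted32):
    """Every classifier family, trained on the planted columns, clears
    chance + 0.2 on the held-out test partition."""
    data, truth = planted32
    reduced = data.select(truth.as_array())
    split = stratified_split(reduced, SplitSpec())
    chance = 1.0 / len(data.classes)
    import warnings

    for family in FAMILIES:
        model = build_classifier(ClassifierSpec(family))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(split.train.values, split.train.labels.astype(str))
        r = evaluate(model, split.test, model_name=family)
        assert r.accuracy > chance + 0.2, family
        assert r.auc is not None
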