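"""Pfirrmann grade prediction.

Grade 5 (collapsed disc) is decided by a hard rule: measured height
strictly below 3.0 mm.  Grades 1-4 come from a classifier trained on
self-similar color correlogram features of the disc nucleus.  Class
imbalance is countered by per-class training weights
``tw_c = median(f) / f_c`` (Eq-style median weighting), so the class of
median frequency carries weight 1.

Six classifier families are supported; the default is a Random Forest
ensemble of decision trees (15 learning cycles, minimum leaf size 1, at
most 114 splits per tree, 20 variables sampled per split) evaluated by
stratified 10-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TrainingError

#: discs measured strictly below this height (mm) are grade 5
DEFAULT_HEIGHT_THRESHOLD_MM = 3.0

GRADES = (1, 2, 3, 4, 5)

CLASSIFIER_FAMILIES = ("knn", "svm_ecoc", "discriminant", "neural_net", "tree", "ensemble")


@dataclass
class ClassWeights:
    frequencies: dict  # grade -> count
    weights: dict  # grade -> median(f)/f_c

    def sample_weights(self, grades) -> np.ndarray:
        return np.array([self.weights[int(g)] for g in grades])


def class_weights(frequencies) -> ClassWeights:
    """Median-over-frequency class weights.

    ``frequencies`` is either a mapping grade -> count or a sequence of
    counts (grades taken as 1..len).  Zero counts are rejected.
    """
    if isinstance(frequencies, dict):
        freq = {int(k): float(v) for k, v in frequencies.items()}
    else:
        freq = {i + 1: float(v) for i, v in enumerate(frequencies)}
    if any(v <= 0 for v in freq.values()):
        raise TrainingError("class weights undefined for zero-frequency classes")
    med = float(np.median(list(freq.values())))
    return ClassWeights(frequencies=freq, weights={g: med / f for g, f in freq.items()})


def apply_height_rule(height_mm: float, threshold_mm: float = DEFAULT_HEIGHT_THRESHOLD_MM):
    """Grade 5 iff the measured height is strictly below the threshold."""
    if height_mm < 0:
        raise ValueError("height must be nonnegative")
    return 5 if height_mm < threshold_mm else None


def _make_classifier(family: str, seed: int, criterion: str = "gini"):
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.multiclass import OutputCodeClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    if family == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if family == "svm_ecoc":
        return OutputCodeClassifier(SVC(kernel="rbf", random_state=seed), code_size=2, random_state=seed)
    if family == "discriminant":
        return LinearDiscriminantAnalysis()
    if family == "neural_net":
        return MLPClassifier(hidden_layer_sizes=(50,), max_iter=2000, random_state=seed)
    if family == "tree":
        return DecisionTreeClassifier(criterion=criterion, random_state=seed)
    if family == "ensemble":
        return RandomForestClassifier(
            n_estimators=15,
            min_samples_leaf=1,
            max_leaf_nodes=115,  # = 114 splits per tree
            max_features=20,
            criterion=criterion,
            random_state=seed,
        )
    raise ValueError(f"unknown classifier family {family!r}; choose from {CLASSIFIER_FAMILIES}")


def _supports_sample_weight(clf) -> bool:
    import inspect

    try:
        return "sample_weight" in inspect.signature(clf.fit).parameters
    except (TypeError, ValueError):
        return False


@dataclass
class GradingModel:
    family: str
    classifier: object
    weights: ClassWeights
    height_threshold_mm: float = DEFAULT_HEIGHT_THRESHOLD_MM
    cv_accuracy: float | None = None  # stratified k-fold mean accuracy, %
    cv_fold_accuracies: list = field(default_factory=list)
    feature_length: int | None = None
    fitted: bool = False


def train(features, grades, weights: ClassWeights | None = None, family: str = "ensemble",
          cv_folds: int = 10, seed: int = 0, criterion: str = "gini",
          height_threshold_mm: float = DEFAULT_HEIGHT_THRESHOLD_MM) -> GradingModel:
    """Fit a grade 1-4 classifier with class-weighted samples and k-fold CV.

    Grade-5 samples are excluded automatically (the height rule owns
    grade 5).  ``weights`` defaults to median-frequency weights of the
    retained grades.  The reported ``cv_accuracy`` is the mean
    stratified k-fold test accuracy (%); the returned model is then
    refitted on all retained samples.
    """
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray([np.asarray(f.values if hasattr(f, "values") else f, float) for f in features])
    y = np.asarray([int(g) for g in grades])
    keep = y != 5
    X, y = X[keep], y[keep]
    present = sorted(set(y.tolist()))
    if len(present) < 2:
        raise TrainingError(f"need at least two grade classes to train, found {present}")
    if weights is None:
        weights = class_weights({g: int((y == g).sum()) for g in present})
    sw = weights.sample_weights(y)

    n_features = X.shape[1]
    fold_accs = []
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        clf = _make_classifier(family, seed, criterion)
        _cap_max_features(clf, n_features)
        _fit(clf, X[tr], y[tr], sw[tr])
        fold_accs.append(100.0 * float((clf.predict(X[te]) == y[te]).mean()))

    final = _make_classifier(family, seed, criterion)
    _cap_max_features(final, n_features)
    _fit(final, X, y, sw)
    return GradingModel(
        family=family,
        classifier=final,
        weights=weights,
        height_threshold_mm=height_threshold_mm,
        cv_accuracy=float(np.mean(fold_accs)),
        cv_fold_accuracies=fold_accs,
        feature_length=n_features,
        fitted=True,
    )


def _cap_max_features(clf, n_features: int) -> None:
    if getattr(clf, "max_features", None) is not None and isinstance(clf.max_features, int):
        clf.max_features = min(clf.max_features, n_features)


def _fit(clf, X, y, sample_weight):
    if _supports_sample_weight(clf):
        clf.fit(X, y, sample_weight=sample_weight)
    else:
        clf.fit(X, y)


def predict(model: GradingModel, feature, height_mm: float) -> int:
    """Predict one disc's grade: height rule first, classifier otherwise."""
    if not model.fitted:
        raise TrainingError("model is not fitted")
    rule = apply_height_rule(height_mm, model.height_threshold_mm)
    if rule is not None:
        return rule
    x = np.asarray(feature.values if hasattr(feature, "values") else feature, float).reshape(1, -1)
    return int(model.classifier.predict(x)[0])


@dataclass
class EvalReport:
    confusion: np.ndarray  # 5x5, rows = true grade, cols = predicted
    class_accuracy: dict  # grade -> % (nan when the grade is absent)
    weighted_mean_accuracy_pct: float
    frequencies: dict

    def to_json(self):
        return {
            "confusion": self.confusion.tolist(),
            "class_accuracy": self.class_accuracy,
            "weighted_mean_accuracy_pct": self.weighted_mean_accuracy_pct,
            "frequencies": self.frequencies,
        }


def weighted_mean_accuracy(class_accuracies, frequencies) -> float:
    """Frequency-weighted mean of per-class accuracies (%)."""
    acc = np.asarray(list(class_accuracies), float)
    f = np.asarray(list(frequencies), float)
    if acc.shape != f.shape:
        raise ValueError("class accuracies and frequencies must align")
    ok = ~np.isnan(acc)
    return float((f[ok] * acc[ok]).sum() / f[ok].sum())


def evaluate(true_grades, predicted_grades, frequencies=None) -> EvalReport:
    """Confusion matrix, per-class accuracy, and weighted mean accuracy.

    ``frequencies`` defaults to the empirical class counts of
    ``true_grades``, in which case the weighted mean equals plain
    accuracy.
    """
    yt = np.asarray([int(g) for g in true_grades])
    yp = np.asarray([int(g) for g in predicted_grades])
    if yt.shape != yp.shape:
        raise ValueError("true and predicted grade vectors differ in length")
    conf = np.zeros((5, 5), dtype=int)
    for t, p in zip(yt, yp):
        conf[t - 1, p - 1] += 1
    acc = {}
    for g in GRADES:
        row = conf[g - 1]
        acc[g] = 100.0 * row[g - 1] / row.sum() if row.sum() else float("nan")
    if frequencies is None:
        freq = {g: int((yt == g).sum()) for g in GRADES}
    elif isinstance(frequencies, dict):
        freq = {int(k): float(v) for k, v in frequencies.items()}
    else:
        freq = {i + 1: float(v) for i, v in enumerate(frequencies)}
    wm = weighted_mean_accuracy(
        [acc[g] for g in GRADES if freq.get(g, 0) > 0],
        [freq[g] for g in GRADES if freq.get(g, 0) > 0],
    )
    return EvalReport(confusion=conf, class_accuracy=acc, weighted_mean_accuracy_pct=wm, frequencies=freq)
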