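"""Group classification from seed-map features with nested cross-validation.

Subjects are classified (patients vs controls) from their voxelwise seed
connectivity values.  The proportional threshold percentile doubles as a
feature-count hyperparameter: at percentile q, the top (100 - q)% of voxels
(ranked by the mean training-set map) are the feature set.  A nested
cross-validation separates hyperparameter selection from accuracy
estimation: inner folds pick the percentile with the best validation
accuracy, outer folds report unbiased accuracy at that choice.  Voxel
selection and feature standardisation are always fit on training subjects
only, so outer-fold test subjects never leak into any modelling choice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .seedmap import ConnectivityMap

__all__ = [
    "FeatureTable",
    "ClassificationReport",
    "build_features",
    "nested_cv",
    "roc_auc",
    "compare_measures",
]

DEFAULT_THRESHOLDS = (0.0, 10.0, 20.0, 25.0, 30.0, 35.0, 40.0, 50.0, 60.0)


@dataclass
class FeatureTable:
    """Subjects x voxels feature matrix at one threshold percentile."""

    matrix: NDArray[np.float64]
    labels: NDArray[np.int_]
    voxel_indices: NDArray[np.int_]
    threshold_percentile: float
    measure: str


@dataclass
class ClassificationReport:
    """Nested-CV outcome for one measure/classifier pair.

    ``accuracy`` is the mean outer-fold accuracy at the inner-selected
    threshold (the unbiased estimate); ``pooled_accuracy`` pools all outer
    predictions instead of averaging fold rates.  ``per_threshold_accuracy``
    is the descriptive accuracy-vs-threshold curve evaluated on the same
    outer folds.
    """

    classifier: str
    measure: str
    accuracy: float
    pooled_accuracy: float
    fold_accuracies: NDArray[np.float64]
    optimal_percentile: float
    per_threshold_accuracy: dict[float, float]
    roc_points: NDArray[np.float64]
    auc: float
    fold_seed: int | None = None
    selected_percentiles: list[float] = field(default_factory=list)


def _labels_from_maps(maps: list[ConnectivityMap]) -> NDArray[np.int_]:
    groups = [m.group for m in maps]
    if any(g is None for g in groups):
        raise ValueError("every map needs a group label")
    uniq = sorted(set(groups))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    # patients coded 1 when present, else lexicographic
    if "patient" in uniq:
        pos = "patient"
    else:
        pos = uniq[1]
    return np.array([1 if g == pos else 0 for g in groups])


def _stack_masked(maps: list[ConnectivityMap]) -> tuple[NDArray, NDArray]:
    mask = maps[0].mask
    for m in maps[1:]:
        if m.values.shape != maps[0].values.shape:
            raise ValueError("connectivity maps are on different grids")
        mask = mask & m.mask
    data = np.stack([m.values[mask] for m in maps])
    return data, mask


def _select_voxels(train_rows: NDArray, percentile: float) -> NDArray[np.int_]:
    """Top (100 - q)% voxels by training-mean association value."""
    mean_map = train_rows.mean(axis=0)
    if percentile <= 0:
        return np.arange(mean_map.size)
    cutoff = np.percentile(mean_map, percentile)
    idx = np.flatnonzero(mean_map >= cutoff)
    if idx.size == 0:  # all-equal degenerate map
        idx = np.arange(mean_map.size)
    return idx


def build_features(
    maps: list[ConnectivityMap],
    percentile: float,
    *,
    selector_rows: NDArray | None = None,
) -> FeatureTable:
    """Assemble a subjects x voxels matrix at one threshold percentile.

    Voxel selection ranks voxels by the mean map over ``selector_rows``
    (defaults to all subjects; pass training rows to avoid leakage in CV).
    """
    if not 0.0 <= percentile < 100.0:
        raise ValueError(f"percentile must lie in [0, 100), got {percentile}")
    data, _ = _stack_masked(maps)
    labels = _labels_from_maps(maps)
    sel = data if selector_rows is None else data[selector_rows]
    idx = _select_voxels(sel, percentile)
    return FeatureTable(
        matrix=data[:, idx],
        labels=labels,
        voxel_indices=idx,
        threshold_percentile=percentile,
        measure=maps[0].measure,
    )


def _make_classifier(name: str, *, C: float = 1.0, k: int = 5) -> Pipeline:
    if name == "svm":
        est = SVC(kernel="linear", C=C)
    elif name == "knn":
        est = KNeighborsClassifier(n_neighbors=k)
    else:
        raise ValueError(f"classifier must be 'svm' or 'knn', got {name!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", est)])


def _scores(model: Pipeline, X: NDArray) -> NDArray:
    clf = model.named_steps["clf"]
    if hasattr(clf, "decision_function"):
        return model.decision_function(X)
    return model.predict_proba(X)[:, 1]


def _stratified_folds(labels: NDArray, n_folds: int, rng: np.random.Generator) -> list[NDArray]:
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < n_folds:
            raise ValueError(
                f"class {cls} has {idx.size} subjects, fewer than {n_folds} folds"
            )
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % n_folds].append(j)
    return [np.sort(np.array(f)) for f in folds]


def nested_cv(
    maps: list[ConnectivityMap],
    *,
    classifier: str = "svm",
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    n_outer: int = 5,
    n_inner: int = 4,
    rng: np.random.Generator | int | None = None,
    labels: NDArray | None = None,
    svm_C: float = 1.0,
    knn_k: int = 5,
) -> ClassificationReport:
    """Nested cross-validation over the threshold-percentile hyperparameter.

    Outer folds are stratified; within each outer-training set, inner folds
    score every candidate percentile and the best (ties to the lowest
    percentile) is refit on the whole outer-training set and evaluated once
    on the held-out outer fold.  Deterministic given the RNG seed.
    """
    rng = np.random.default_rng(rng)
    data, _ = _stack_masked(maps)
    y = _labels_from_maps(maps) if labels is None else np.asarray(labels)
    if y.size != data.shape[0]:
        raise ValueError("label count does not match subject count")

    outer_folds = _stratified_folds(y, n_outer, rng)
    all_idx = np.arange(y.size)
    fold_accs: list[float] = []
    picked: list[float] = []
    pooled_true: list[int] = []
    pooled_pred: list[int] = []
    pooled_scores: list[float] = []
    curve_acc: dict[float, list[float]] = {q: [] for q in thresholds}

    for test_idx in outer_folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        y_tr = y[train_idx]
        inner_folds = _stratified_folds(y_tr, n_inner, rng)
        inner_scores = np.zeros(len(thresholds))
        for val_local in inner_folds:
            fit_local = np.setdiff1d(np.arange(train_idx.size), val_local)
            fit_idx, val_idx = train_idx[fit_local], train_idx[val_local]
            for qi, q in enumerate(thresholds):
                vox = _select_voxels(data[fit_idx], q)
                model = _make_classifier(classifier, C=svm_C, k=knn_k)
                model.fit(data[np.ix_(fit_idx, vox)], y[fit_idx])
                inner_scores[qi] += model.score(data[np.ix_(val_idx, vox)], y[val_idx])
        best_q = thresholds[int(np.argmax(inner_scores))]
        picked.append(best_q)

        vox = _select_voxels(data[train_idx], best_q)
        model = _make_classifier(classifier, C=svm_C, k=knn_k)
        model.fit(data[np.ix_(train_idx, vox)], y[train_idx])
        X_test = data[np.ix_(test_idx, vox)]
        pred = model.predict(X_test)
        fold_accs.append(float(np.mean(pred == y[test_idx])))
        pooled_true.extend(y[test_idx])
        pooled_pred.extend(pred)
        pooled_scores.extend(_scores(model, X_test))

        # descriptive accuracy-vs-threshold curve on the same outer split
        for q in thresholds:
            voxq = _select_voxels(data[train_idx], q)
            mq = _make_classifier(classifier, C=svm_C, k=knn_k)
            mq.fit(data[np.ix_(train_idx, voxq)], y[train_idx])
            curve_acc[q].append(float(mq.score(data[np.ix_(test_idx, voxq)], y[test_idx])))

    roc_points, auc_value = roc_auc(np.array(pooled_scores), np.array(pooled_true))
    return ClassificationReport(
        classifier=classifier,
        measure=maps[0].measure,
        accuracy=float(np.mean(fold_accs)),
        pooled_accuracy=float(np.mean(np.array(pooled_pred) == np.array(pooled_true))),
        fold_accuracies=np.array(fold_accs),
        optimal_percentile=float(max(set(picked), key=picked.count)),
        per_threshold_accuracy={q: float(np.mean(a)) for q, a in curve_acc.items()},
        roc_points=roc_points,
        auc=auc_value,
        selected_percentiles=picked,
    )


def roc_auc(scores: NDArray, labels: NDArray) -> tuple[NDArray, float]:
    """Empirical ROC points (FPR, TPR) and trapezoidal AUC."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr]), float(_sk_auc(fpr, tpr))


def compare_measures(
    report_a: ClassificationReport,
    report_b: ClassificationReport,
    *,
    n_permutations: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Paired sign-flip permutation test on per-fold accuracy differences.

    The statistic is the mean fold-wise accuracy difference (a - b); its
    null distribution flips the sign of each paired difference, enumerated
    exhaustively when there are at most 20 folds.  Returns (statistic,
    two-sided p).  Requires both reports to come from identical fold
    partitions (same count, same seed-driven splits).
    """
    da, db = report_a.fold_accuracies, report_b.fold_accuracies
    if da.size != db.size:
        raise ValueError("reports have different fold counts; refit with identical partitions")
    d = da - db
    observed = float(d.mean())
    k = d.size
    if k <= 20:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=k)))
        null = signs @ d / k
    else:
        gen = np.random.default_rng(rng)
        null = (gen.choice([-1.0, 1.0], size=(n_permutations, k)) * d).mean(axis=1)
    p = float(np.mean(np.abs(null) >= abs(observed) - 1e-12))
    return observed, p
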