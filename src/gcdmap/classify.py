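"""Substate classification from GCD maps.

Two procedures are implemented, mirroring the two stages of the analysis:

* a per-voxel linear SVM evaluated by leave-one-out cross-validation,
  thresholded (default 70% accuracy) and reported as contiguous clusters
  (default 6-connectivity, minimum extent 5 voxels); and
* a multi-metric combination classifier: feature tables concatenated across
  GCD metrics, SVM recursive feature elimination (linear SVM, C = 1) with
  the retained feature count chosen by an inner cross-validation, evaluated
  by stratified 5-fold outer cross-validation repeated 5 times, with ROC
  metrics from pooled decision values and a label-permutation test.

Standardisation, PCA, relief selection and RFE are always fitted on
training folds only; the permutation test reruns the whole nested procedure
per permuted labelling.

The hot path fits thousands of small SVMs, so the internal `_fit_svm_gram`
calls scikit-learn's low-level libsvm binding on a precomputed Gram matrix
(decision values are sign-flipped to match the public binary-SVC
convention, which a unit test asserts); the public `SVC` estimator is the
fallback if that binding is unavailable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger("gcdmap")

DEFAULT_C = 1.0
DEFAULT_THRESHOLD_PCT = 70.0
DEFAULT_MIN_EXTENT = 5
DEFAULT_RFE_STEP = 0.1
DEFAULT_INNER_FOLDS = 4
DEFAULT_OUTER_FOLDS = 5
DEFAULT_REPEATS = 5
DEFAULT_N_PERM = 100

RELIEF_SWEEP = (50, 250, 500, 750, 1000, 1500, 2000, 2500, 3000,
                3500, 4000, 4500, 4750, 5000)

try:  # low-level binding: ~25x faster than the public wrapper on tiny problems
    from sklearn.svm import _libsvm  # type: ignore[attr-defined]

    _HAVE_RAW_LIBSVM = True
    try:
        _libsvm.set_verbosity_wrap(0)
    except AttributeError:  # pragma: no cover
        pass
except ImportError:  # pragma: no cover - depends on sklearn internals
    _HAVE_RAW_LIBSVM = False


# ---------------------------------------------------------------------------
# internal linear-SVM plumbing
# ---------------------------------------------------------------------------


def _fit_svm_gram(K: np.ndarray, y01: np.ndarray, C: float = DEFAULT_C):
    """Fit a binary C-SVC on a precomputed Gram matrix.

    Returns (alpha_signed, intercept) with the convention that
    ``decision(x) = x @ (X_train.T @ alpha_signed) + intercept`` is positive
    for class 1 (labels must be 0/1 floats).
    """
    if _HAVE_RAW_LIBSVM:
        out = _libsvm.fit(np.ascontiguousarray(K), y01.astype(np.float64),
                          svm_type=0, kernel="precomputed", C=C)
        support, _, _, dual_coef, intercept = out[:5]
        alpha = np.zeros(len(y01))
        # binary libsvm decision values are negated relative to sklearn's
        # "positive = classes_[1]" convention
        alpha[support] = -dual_coef[0]
        return alpha, -float(intercept[0])
    model = SVC(kernel="precomputed", C=C).fit(K, y01)
    alpha = np.zeros(len(y01))
    alpha[model.support_] = model.dual_coef_[0]
    return alpha, float(model.intercept_[0])


class _Scaler:
    """Per-feature standardisation learned on training rows only."""

    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def _encode_labels(labels: np.ndarray, positive_label=None) -> tuple[np.ndarray, object, object]:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, found {list(classes)}")
    if positive_label is None:
        positive_label = classes[1]
    elif positive_label not in classes:
        raise ValueError(f"positive_label {positive_label!r} not among {list(classes)}")
    negative_label = classes[classes != positive_label][0]
    y01 = (labels == positive_label).astype(np.float64)
    return y01, positive_label, negative_label


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Subjects x features matrix with per-feature provenance."""

    matrix: np.ndarray
    feature_origin: list[tuple[str, int]]
    labels: np.ndarray
    scaling: object | None = None

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        self.labels = np.asarray(self.labels)
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature table must contain no missing values")
        if len(self.feature_origin) != self.matrix.shape[1]:
            raise ValueError("feature_origin length must equal feature count")
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("one label per subject required")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass
class AccuracyMap:
    """Per-voxel LOOCV accuracy (percent) with thresholded clusters."""

    accuracy_pct: np.ndarray
    voxel_index: np.ndarray
    threshold_pct: float
    min_extent: int
    clusters: list[dict] = field(default_factory=list)


@dataclass
class ClassifierReport:
    """Cross-validated performance of one metric combination."""

    auc: float
    accuracy_pct: float
    sensitivity_pct: float
    specificity_pct: float
    n_features_selected: int
    combination: tuple[str, ...]
    positive_label: object
    permutation_p: float | None = None
    fold_records: list[dict] = field(default_factory=list)
    pooled_decisions: np.ndarray | None = None
    pooled_truth: np.ndarray | None = None


def build_feature_table(metric_arrays: dict[str, np.ndarray], labels: np.ndarray,
                        combination: Sequence[str]) -> FeatureTable:
    """Concatenate per-metric subjects x voxels arrays feature-wise."""
    blocks, origin = [], []
    for metric in combination:
        arr = np.atleast_2d(np.asarray(metric_arrays[metric], dtype=np.float64))
        blocks.append(arr)
        origin.extend((metric, v) for v in range(arr.shape[1]))
    return FeatureTable(np.hstack(blocks), origin, labels)


# ---------------------------------------------------------------------------
# per-voxel stage
# ---------------------------------------------------------------------------


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def voxelwise_accuracy_map(
    metric_values: np.ndarray,
    labels: np.ndarray,
    voxel_index: np.ndarray,
    grid_shape: tuple[int, int, int],
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
    min_extent: int = DEFAULT_MIN_EXTENT,
    connectivity: int = 6,
    C: float = DEFAULT_C,
    positive_label=None,
) -> AccuracyMap:
    """Leave-one-out accuracy of a single-feature linear SVM at every voxel.

    ``metric_values`` is subjects x voxels for one GCD metric.  Clusters of
    supra-threshold voxels (strictly above ``threshold_pct``) are formed by
    face connectivity and reported when their extent reaches ``min_extent``.
    """
    X = np.atleast_2d(np.asarray(metric_values, dtype=np.float64))
    y01, pos, neg = _encode_labels(labels, positive_label)
    n, V = X.shape
    counts = np.bincount(y01.astype(int), minlength=2)
    if counts.min() < 4:
        raise ValueError("need at least 4 subjects per class")
    acc = np.zeros(V)
    idx_all = np.arange(n)
    for v in range(V):
        col = X[:, v]
        correct = 0
        for i in idx_all:
            tr = idx_all != i
            x_tr = col[tr]
            sd = x_tr.std()
            if sd == 0:
                # uninformative voxel in this fold: majority vote
                pred = 1.0 if y01[tr].mean() > 0.5 else 0.0
            else:
                z_tr = (x_tr - x_tr.mean()) / sd
                K = np.outer(z_tr, z_tr)
                alpha, b = _fit_svm_gram(K, y01[tr], C)
                z_te = (col[i] - x_tr.mean()) / sd
                pred = 1.0 if z_te * (z_tr @ alpha) + b > 0 else 0.0
            correct += pred == y01[i]
        acc[v] = 100.0 * correct / n
    clusters = _find_clusters(acc, voxel_index, grid_shape, threshold_pct,
                              min_extent, connectivity)
    return AccuracyMap(acc, np.asarray(voxel_index), threshold_pct, min_extent, clusters)


def _find_clusters(accuracy_pct, voxel_index, grid_shape, threshold_pct,
                   min_extent, connectivity) -> list[dict]:
    vol = np.zeros(grid_shape, dtype=bool)
    voxel_index = np.asarray(voxel_index)
    supra = accuracy_pct > threshold_pct
    vol[tuple(voxel_index[supra].T)] = True
    labeled, n_comp = ndimage.label(vol, structure=_connectivity_structure(connectivity))
    acc_vol = np.zeros(grid_shape)
    acc_vol[tuple(voxel_index.T)] = accuracy_pct
    clusters = []
    for comp in range(1, n_comp + 1):
        coords = np.argwhere(labeled == comp)
        if len(coords) < min_extent:
            continue
        accs = acc_vol[tuple(coords.T)]
        peak = int(np.argmax(accs))
        clusters.append({
            "voxels": coords,
            "size": int(len(coords)),
            "peak_accuracy_pct": float(accs[peak]),
            "peak_coordinate": tuple(int(c) for c in coords[peak]),
        })
    clusters.sort(key=lambda c: -c["peak_accuracy_pct"])
    return clusters


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------


def pca_reduce(features: FeatureTable, variance_kept: float = 0.95
               ) -> tuple[FeatureTable, Callable[[np.ndarray], np.ndarray]]:
    """Project onto the principal components reaching ``variance_kept``.

    Fitted on the rows it is given (training subjects); the returned
    callable applies the same centring/projection to held-out rows.
    """
    if not 0 < variance_kept <= 1:
        raise ValueError("variance_kept must be in (0, 1]")
    X = features.matrix
    if X.shape[1] == 1:
        return features, lambda Z: np.atleast_2d(np.asarray(Z, dtype=float))
    n_components = variance_kept if variance_kept < 1 else min(X.shape)
    pca = PCA(n_components=n_components, svd_solver="full").fit(X)
    reduced = pca.transform(X)
    origin = [("pc", i) for i in range(reduced.shape[1])]
    table = FeatureTable(reduced, origin, features.labels, scaling=pca)
    return table, pca.transform


def relief_weights(X: np.ndarray, y01: np.ndarray, n_neighbors: int = 5) -> np.ndarray:
    """ReliefF feature weights with k nearest hits/misses per sample.

    Features are standardised internally; weights reward features whose
    values separate each sample from its nearest misses more than from its
    nearest hits.  Fully deterministic (all samples used; ties broken by
    sample index).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y01 = np.asarray(y01)
    n, F = X.shape
    Z = _Scaler(X)(X)
    # pairwise L1 distances on standardised features
    dist = np.abs(Z[:, None, :] - Z[None, :, :]).sum(axis=2)
    np.fill_diagonal(dist, np.inf)
    priors = {c: float(np.mean(y01 == c)) for c in (0.0, 1.0)}
    w = np.zeros(F)
    for i in range(n):
        same = np.flatnonzero(y01 == y01[i])
        same = same[same != i]
        other = np.flatnonzero(y01 != y01[i])
        k_hit = min(n_neighbors, len(same))
        k_miss = min(n_neighbors, len(other))
        if k_hit == 0 or k_miss == 0:
            continue
        hits = same[np.argsort(dist[i, same], kind="stable")[:k_hit]]
        misses = other[np.argsort(dist[i, other], kind="stable")[:k_miss]]
        diff_hit = np.abs(Z[i] - Z[hits]).mean(axis=0)
        diff_miss = np.abs(Z[i] - Z[misses]).mean(axis=0)
        p_other = priors[1.0 - y01[i]] / (1.0 - priors[y01[i]])
        w += (p_other * diff_miss - diff_hit) / n
    return w


def relief_select(features: FeatureTable, k_keep: int,
                  n_neighbors: int = 5, positive_label=None) -> FeatureTable:
    """Keep the ``k_keep`` highest-weighted ReliefF features (ties by index)."""
    if k_keep > features.n_features:
        raise ValueError(f"k_keep={k_keep} exceeds {features.n_features} features")
    y01, _, _ = _encode_labels(features.labels, positive_label)
    w = relief_weights(features.matrix, y01, n_neighbors)
    # stable sort on -w keeps the lower feature index on ties
    keep = np.argsort(-w, kind="stable")[:k_keep]
    keep = np.sort(keep)
    return FeatureTable(features.matrix[:, keep],
                        [features.feature_origin[k] for k in keep],
                        features.labels)


def svm_rfe_rank(X: np.ndarray, y01: np.ndarray,
                 elimination_fraction: float = DEFAULT_RFE_STEP,
                 C: float = DEFAULT_C) -> np.ndarray:
    """SVM recursive feature elimination ranking (best feature first).

    A linear SVM is refit at each iteration and the ``elimination_fraction``
    of features with the smallest squared weight is removed (at least one)
    until one remains.  Ties are broken by feature index: the lower index
    survives longer.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    y01 = np.asarray(y01, dtype=np.float64)
    active = np.arange(X.shape[1])
    eliminated: list[int] = []
    K = X @ X.T
    while len(active) > 1:
        alpha, _ = _fit_svm_gram(K, y01, C)
        w = X[:, active].T @ alpha
        n_drop = max(1, int(elimination_fraction * len(active)))
        n_drop = min(n_drop, len(active) - 1)
        # stable sort on (w^2, index): among ties the higher index drops first
        order = np.lexsort((-active, w ** 2))
        drop_pos = order[:n_drop]
        drop = active[drop_pos]
        eliminated.extend(sorted(drop.tolist(), reverse=True))
        Xd = X[:, drop]
        K = K - Xd @ Xd.T
        active = np.delete(active, np.sort(drop_pos))
    ranking = np.concatenate([active, np.array(eliminated[::-1], dtype=int)])
    return ranking


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------


def _rfe_path_counts(n_features: int, step: float) -> list[int]:
    counts = [n_features]
    while counts[-1] > 1:
        drop = max(1, int(step * counts[-1]))
        counts.append(max(1, counts[-1] - drop))
    return counts


def _rfe_path_eval(X_tr, y_tr, X_te, y_te, step, C):
    """Run RFE on (X_tr, y_tr); accuracy on (X_te, y_te) at every count.

    Returns dict count -> held-out accuracy, reusing the SVM trained at each
    elimination step.
    """
    active = np.arange(X_tr.shape[1])
    K = X_tr @ X_tr.T
    accs: dict[int, float] = {}
    while True:
        alpha, b = _fit_svm_gram(K, y_tr, C)
        w = X_tr[:, active].T @ alpha
        dec = X_te[:, active] @ w + b
        accs[len(active)] = float(np.mean((dec > 0) == (y_te == 1.0)))
        if len(active) == 1:
            break
        n_drop = max(1, int(step * len(active)))
        n_drop = min(n_drop, len(active) - 1)
        order = np.lexsort((-active, w ** 2))
        drop_pos = order[:n_drop]
        drop = active[drop_pos]
        Xd = X_tr[:, drop]
        K = K - Xd @ Xd.T
        active = np.delete(active, np.sort(drop_pos))
    return accs


def _rfe_to_count(X_tr, y_tr, count, step, C):
    """RFE on (X_tr, y_tr) down to ``count`` features; fit final SVM."""
    active = np.arange(X_tr.shape[1])
    K = X_tr @ X_tr.T
    while len(active) > count:
        alpha, _ = _fit_svm_gram(K, y_tr, C)
        w = X_tr[:, active].T @ alpha
        n_drop = max(1, int(step * len(active)))
        n_drop = min(n_drop, len(active) - count)
        order = np.lexsort((-active, w ** 2))
        drop_pos = order[:n_drop]
        drop = active[drop_pos]
        Xd = X_tr[:, drop]
        K = K - Xd @ Xd.T
        active = np.delete(active, np.sort(drop_pos))
    alpha, b = _fit_svm_gram(K, y_tr, C)
    w = X_tr[:, active].T @ alpha
    return active, w, b


def fold_seeds(seed: int, n_repeats: int) -> list[int]:
    """Deterministic per-repeat fold seeds derived from the run seed."""
    rs = np.random.RandomState(seed % (2 ** 31))
    return [int(s) for s in rs.randint(0, 2 ** 31 - 1, size=n_repeats)]


def nested_cv_classify(
    features: FeatureTable,
    combination: Sequence[str] | None = None,
    n_outer: int = DEFAULT_OUTER_FOLDS,
    n_repeats: int = DEFAULT_REPEATS,
    inner_folds: int = DEFAULT_INNER_FOLDS,
    rfe_step: float = DEFAULT_RFE_STEP,
    C: float = DEFAULT_C,
    seed: int = 0,
    positive_label=None,
) -> ClassifierReport:
    """Nested stratified cross-validation of the combination classifier.

    The outer loop estimates performance; the inner loop (on each outer
    training set only) picks the SVM-RFE feature count with the highest mean
    inner accuracy (ties to the larger count).  Accuracy, sensitivity and
    specificity come from the pooled zero-threshold predictions across all
    repeats and folds; the ROC/AUC from the pooled decision values.
    """
    y01, pos, neg = _encode_labels(features.labels, positive_label)
    X = features.matrix
    n = len(y01)
    if min(np.bincount(y01.astype(int))) < n_outer:
        raise ValueError("stratification failure: a class has fewer members than folds")
    records: list[dict] = []
    pooled_dec = []
    pooled_truth = []
    counts_grid = _rfe_path_counts(X.shape[1], rfe_step)
    for repeat, fseed in enumerate(fold_seeds(seed, n_repeats)):
        outer = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=fseed)
        for fold, (tr, te) in enumerate(outer.split(X, y01)):
            scaler = _Scaler(X[tr])
            inner = StratifiedKFold(n_splits=inner_folds, shuffle=True,
                                    random_state=(fseed + fold) % (2 ** 31))
            acc_by_count = {c: [] for c in counts_grid}
            for itr, ite in inner.split(X[tr], y01[tr]):
                in_scaler = _Scaler(X[tr][itr])
                accs = _rfe_path_eval(in_scaler(X[tr][itr]), y01[tr][itr],
                                      in_scaler(X[tr][ite]), y01[tr][ite],
                                      rfe_step, C)
                for c, a in accs.items():
                    acc_by_count[c].append(a)
            mean_acc = {c: float(np.mean(a)) for c, a in acc_by_count.items() if a}
            best_count = max(mean_acc, key=lambda c: (mean_acc[c], c))
            active, w, b = _rfe_to_count(scaler(X[tr]), y01[tr], best_count, rfe_step, C)
            dec = scaler(X[te])[:, active] @ w + b
            pred = (dec > 0).astype(float)
            records.append({
                "repeat": repeat,
                "fold": fold,
                "test_idx": te,
                "decision_values": dec,
                "predicted": pred,
                "truth": y01[te],
                "n_features": int(best_count),
                "inner_best_accuracy": mean_acc[best_count],
                "selected_features": active,
            })
            pooled_dec.append(dec)
            pooled_truth.append(y01[te])
    dec_all = np.concatenate(pooled_dec)
    truth_all = np.concatenate(pooled_truth)
    pred_all = (dec_all > 0).astype(float)
    auc, acc, sens, spec = roc_metrics(dec_all, truth_all, positive_label=1.0)
    report = ClassifierReport(
        auc=auc,
        accuracy_pct=acc,
        sensitivity_pct=sens,
        specificity_pct=spec,
        n_features_selected=int(np.median([r["n_features"] for r in records])),
        combination=tuple(combination) if combination else tuple(
            sorted({m for m, _ in features.feature_origin})),
        positive_label=pos,
        fold_records=records,
        pooled_decisions=dec_all,
        pooled_truth=truth_all,
    )
    return report


def permutation_test(
    features: FeatureTable,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    observed: ClassifierReport | None = None,
    **cv_kwargs,
) -> tuple[float, np.ndarray]:
    """Label-permutation test of the nested-CV accuracy.

    The labels are randomly reassigned ``n_perm`` times and the full nested
    cross-validation is recomputed each time;
    p = (1 + #{perm accuracy >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if observed is None:
        observed = nested_cv_classify(features, seed=seed, **cv_kwargs)
    rng = np.random.default_rng(seed)
    perm_acc = np.empty(n_perm)
    for b in range(n_perm):
        perm_labels = rng.permutation(features.labels)
        perm_table = FeatureTable(features.matrix, features.feature_origin, perm_labels)
        rep = nested_cv_classify(perm_table, seed=seed, **cv_kwargs)
        perm_acc[b] = rep.accuracy_pct
    p = (1.0 + float(np.sum(perm_acc >= observed.accuracy_pct))) / (n_perm + 1.0)
    return p, perm_acc


def roc_metrics(decision_values: np.ndarray, labels: np.ndarray,
                positive_label=None) -> tuple[float, float, float, float]:
    """AUC plus accuracy/sensitivity/specificity at the zero threshold.

    AUC is the trapezoidal area under the ROC built from all decision-value
    thresholds; the three rates are percentages at decision = 0 with
    sensitivity attached to the positive class.
    """
    decision_values = np.asarray(decision_values, dtype=np.float64)
    y01, pos, neg = _encode_labels(labels, positive_label)
    if np.ptp(decision_values) == 0:
        warnings.warn("constant decision values: AUC undefined, reporting 0.5")
        auc = 0.5
    else:
        auc = float(roc_auc_score(y01, decision_values))
    pred = (decision_values > 0).astype(float)
    n_pos = float(np.sum(y01 == 1))
    n_neg = float(np.sum(y01 == 0))
    sens = 100.0 * float(np.sum((pred == 1) & (y01 == 1))) / n_pos
    spec = 100.0 * float(np.sum((pred == 0) & (y01 == 0))) / n_neg
    acc = 100.0 * float(np.mean(pred == y01))
    return auc, acc, sens, spec
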