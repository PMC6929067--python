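"""Training-set sampling, classifier training/evaluation and point prediction.

Five classifier configurations are compared: a 100-tree random forest, an
RBF-kernel SVM and k-nearest-neighbors with k in {2, 6, 8}. Model selection
uses mean accuracy over a 10-fold stratified cross-validation on a
class-balanced sample of ILM points, swept over the number of top-ranked
features. A trained model bundles everything prediction needs — the
selected feature indices, the training min-max scaling, the PCA window
basis and the fitted estimator — so prediction never refits anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .core import AnnotatedVolume, BScan, DataError, ILMContour
from .features import (
    PCABasis,
    REGISTRY,
    ScanFeatureExtractor,
    WindowGeometry,
    extract_window,
    fit_pca_basis,
)
from .selection import FeatureRanking, SampleSet, select_top

__all__ = [
    "CLASSIFIER_KINDS",
    "CVReport",
    "TrainedModel",
    "sample_training_set",
    "make_classifier",
    "cross_validate",
    "sweep_feature_counts",
    "refine_feature_count",
    "train_model",
    "predict_points",
    "save_model",
    "load_model",
]

CLASSIFIER_KINDS = ("RF", "SVM", "kNN-2", "kNN-6", "kNN-8")


def make_classifier(kind: str, seed: int = 0, hyper: dict | None = None):
    """Instantiate one of the five supported classifier configurations.

    kNN uses Euclidean distance with unweighted votes; a 2-NN vote tie is
    resolved toward class 0 (the conservative no-ERM call).
    """
    hyper = hyper or {}
    if kind == "RF":
        return RandomForestClassifier(
            n_estimators=hyper.get("n_estimators", 100), random_state=seed
        )
    if kind == "SVM":
        return SVC(
            kernel="rbf",
            C=hyper.get("C", 10.0),
            gamma=hyper.get("gamma", "scale"),
            random_state=seed,
        )
    if kind.startswith("kNN-"):
        return KNeighborsClassifier(n_neighbors=int(kind.split("-")[1]))
    raise DataError(f"unknown classifier kind {kind!r}; expected one of "
                    f"{CLASSIFIER_KINDS}")


@dataclass
class CVReport:
    """Per-fold and mean accuracies of one classifier/feature-count setting."""

    fold_accuracies: np.ndarray
    classifier_kind: str
    n_features: int
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


@dataclass
class TrainedModel:
    """A frozen, prediction-ready classifier bundle."""

    classifier_kind: str
    estimator: object
    selected_features: np.ndarray
    feat_min: np.ndarray
    feat_span: np.ndarray
    pca_basis: PCABasis
    geometry: WindowGeometry
    metadata: dict = field(default_factory=dict)

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (X[:, self.selected_features] - self.feat_min) / self.feat_span

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        """Predict from raw (unscaled, full-length) feature vectors."""
        if X.shape[1] != len(REGISTRY):
            raise DataError(
                f"feature matrix has {X.shape[1]} columns, expected "
                f"{len(REGISTRY)}"
            )
        return np.asarray(self.estimator.predict(self._scale(X)), dtype=np.uint8)


def _eligible_points(
    volumes: list[AnnotatedVolume], geom: WindowGeometry
) -> tuple[list[tuple[int, int, int]], np.ndarray]:
    """All (volume, slice, column) points with a full window, plus labels."""
    pts: list[tuple[int, int, int]] = []
    labels: list[int] = []
    for vi, av in enumerate(volumes):
        if av.truth is None:
            raise DataError("training volumes need ground-truth maps")
        shape = (av.volume.height, av.volume.width)
        for si, contour in enumerate(av.contours):
            for c in range(av.volume.width):
                if geom.fits(contour.rows[c], c, shape):
                    pts.append((vi, si, c))
                    labels.append(int(av.truth.grid[si, c]))
    return pts, np.asarray(labels)


def sample_training_set(
    volumes: list[AnnotatedVolume],
    n_samples: int,
    seed: int = 0,
    geom: WindowGeometry | None = None,
) -> tuple[SampleSet, PCABasis]:
    """Draw a class-balanced training sample of ILM points.

    Exactly ceil(n/2) ERM-positive and floor(n/2) negative points are drawn
    uniformly without replacement from all eligible (full-window) points of
    the annotated volumes. The PCA window basis is fitted on the sampled
    windows and returned alongside the feature matrix.
    """
    geom = geom or WindowGeometry()
    rng = np.random.default_rng(seed)
    pts, labels = _eligible_points(volumes, geom)
    pos_idx = np.nonzero(labels == 1)[0]
    neg_idx = np.nonzero(labels == 0)[0]
    n_pos = (n_samples + 1) // 2
    n_neg = n_samples // 2
    if len(pos_idx) < n_pos or len(neg_idx) < n_neg:
        raise DataError(
            f"class exhausted: requested {n_pos} positive / {n_neg} negative "
            f"points but only {len(pos_idx)} / {len(neg_idx)} available"
        )
    chosen = np.concatenate(
        [
            rng.choice(pos_idx, size=n_pos, replace=False),
            rng.choice(neg_idx, size=n_neg, replace=False),
        ]
    )
    chosen.sort()

    # cut the raw windows first so the PCA basis can be fitted before the
    # full feature pass
    windows = []
    for idx in chosen:
        vi, si, c = pts[idx]
        av = volumes[vi]
        win, _ = extract_window(av.volume.scan(si), av.contours[si], c, geom)
        windows.append(win)
    basis = fit_pca_basis(windows)

    X = np.empty((len(chosen), len(REGISTRY)))
    by_scan: dict[tuple[int, int], list[int]] = {}
    for row, idx in enumerate(chosen):
        vi, si, _ = pts[idx]
        by_scan.setdefault((vi, si), []).append(row)
    for (vi, si), rows_here in by_scan.items():
        av = volumes[vi]
        ext = ScanFeatureExtractor(av.volume.scan(si), geom, basis)
        for row in rows_here:
            _, _, c = pts[chosen[row]]
            X[row] = ext.features_at(av.contours[si], c)

    data = SampleSet(
        X=X,
        y=labels[chosen],
        feature_names=list(REGISTRY.names),
        point_ids=[pts[i] for i in chosen],
    )
    return data, basis


def cross_validate(
    data: SampleSet,
    classifier_kind: str,
    k_features: int,
    ranking: FeatureRanking,
    seed: int = 0,
    hyper: dict | None = None,
    n_folds: int = 10,
) -> CVReport:
    """Stratified k-fold cross-validation accuracy for one configuration.

    The feature subset is the fixed top-``k_features`` prefix of
    ``ranking``; min-max scaling is fitted on each training fold.
    """
    counts = np.bincount(data.y, minlength=2)
    if counts.min() < n_folds:
        raise DataError(
            f"need at least {n_folds} samples per class for {n_folds}-fold "
            f"stratified CV, got {counts.tolist()}"
        )
    sel = select_top(ranking, k_features)
    X, y = data.X[:, sel], data.y
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        lo = X[tr].min(axis=0)
        span = X[tr].max(axis=0) - lo
        span[span == 0] = 1.0
        clf = make_classifier(classifier_kind, seed=seed, hyper=hyper)
        clf.fit((X[tr] - lo) / span, y[tr])
        accs.append(float(np.mean(clf.predict((X[te] - lo) / span) == y[te])))
    return CVReport(
        fold_accuracies=np.asarray(accs),
        classifier_kind=classifier_kind,
        n_features=k_features,
        seed=seed,
    )


@dataclass
class SweepResult:
    """Mean CV accuracy per classifier (rows) and feature count (columns)."""

    table: pd.DataFrame
    best_k: dict[str, int]
    best_accuracy: dict[str, float]


def sweep_feature_counts(
    data: SampleSet,
    ranking: FeatureRanking,
    ks=None,
    kinds=CLASSIFIER_KINDS,
    seed: int = 0,
    hyper: dict | None = None,
) -> SweepResult:
    """Evaluate every classifier at every feature count of the grid.

    ``best_k`` holds each classifier's grid argmax (ties toward smaller k).
    """
    if ks is None:
        ks = [k for k in range(20, 201, 20) if k <= data.n_features]
    table = pd.DataFrame(index=list(kinds), columns=list(ks), dtype=float)
    for kind in kinds:
        for k in ks:
            table.loc[kind, k] = cross_validate(
                data, kind, k, ranking, seed=seed, hyper=hyper
            ).mean_accuracy
    best_k = {kind: int(table.loc[kind].idxmax()) for kind in kinds}
    best_acc = {kind: float(table.loc[kind].max()) for kind in kinds}
    return SweepResult(table=table, best_k=best_k, best_accuracy=best_acc)


def refine_feature_count(
    data: SampleSet,
    ranking: FeatureRanking,
    kind: str,
    coarse_k: int,
    radius: int = 10,
    seed: int = 0,
    hyper: dict | None = None,
) -> tuple[int, float]:
    """Unit-step search around a coarse optimum; returns (best_k, accuracy)."""
    lo = max(1, coarse_k - radius)
    hi = min(data.n_features, coarse_k + radius)
    best = (coarse_k, -1.0)
    for k in range(lo, hi + 1):
        acc = cross_validate(
            data, kind, k, ranking, seed=seed, hyper=hyper
        ).mean_accuracy
        if acc > best[1]:
            best = (k, acc)
    return best


def train_model(
    data: SampleSet,
    ranking: FeatureRanking,
    k_features: int,
    classifier_kind: str,
    pca_basis: PCABasis,
    geometry: WindowGeometry,
    seed: int = 0,
    hyper: dict | None = None,
    metadata: dict | None = None,
) -> TrainedModel:
    """Fit the final model on the full sample with the selected features."""
    sel = select_top(ranking, k_features)
    Xs = data.X[:, sel]
    lo = Xs.min(axis=0)
    span = Xs.max(axis=0) - lo
    span[span == 0] = 1.0
    clf = make_classifier(classifier_kind, seed=seed, hyper=hyper)
    clf.fit((Xs - lo) / span, data.y)
    meta = {"seed": seed, "k_features": int(k_features)}
    meta.update(metadata or {})
    return TrainedModel(
        classifier_kind=classifier_kind,
        estimator=clf,
        selected_features=sel,
        feat_min=lo,
        feat_span=span,
        pca_basis=pca_basis,
        geometry=geometry,
        metadata=meta,
    )


def predict_points(
    model: TrainedModel, scan: BScan, contour: ILMContour
) -> np.ndarray:
    """Per-column binary ERM labels for one B-scan.

    Columns whose window clips an image border are predicted 0
    (conservative background default).
    """
    ext = ScanFeatureExtractor(scan, model.geometry, model.pca_basis)
    elig = ext.eligible(contour)
    labels = np.zeros(contour.width, dtype=np.uint8)
    cols = np.nonzero(elig)[0]
    if cols.size:
        X = ext.feature_matrix(contour, cols)
        labels[cols] = model.predict_features(X)
    return labels


def save_model(model: TrainedModel, path) -> None:
    """Serialize a trained model as a single-file bundle."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "classifier_kind": model.classifier_kind,
        "estimator": model.estimator,
        "selected_features": model.selected_features,
        "feat_min": model.feat_min,
        "feat_span": model.feat_span,
        "pca_basis": model.pca_basis,
        "geometry": {"sub_side": model.geometry.sub_side},
        "metadata": model.metadata,
        "selected_feature_names": [
            REGISTRY.names[i] for i in model.selected_features
        ],
    }
    joblib.dump(payload, path)


def load_model(path) -> TrainedModel:
    payload = joblib.load(Path(path))
    return TrainedModel(
        classifier_kind=payload["classifier_kind"],
        estimator=payload["estimator"],
        selected_features=payload["selected_features"],
        feat_min=payload["feat_min"],
        feat_span=payload["feat_span"],
        pca_basis=payload["pca_basis"],
        geometry=WindowGeometry(sub_side=payload["geometry"]["sub_side"]),
        metadata=payload["metadata"],
    )
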