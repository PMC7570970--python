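"""Activity-grade classification with an RBF-SVM.

The five segment features (R, sigma, PAR, FF, v), min-max normalised,
feed a three-class support-vector machine with a Gaussian kernel
``kappa(x, x') = exp(-g ||x - x'||^2)`` where ``g = 1 / (2 sigma_k^2)``
and ``sigma_k`` is the kernel bandwidth.  Class imbalance is corrected
with SMOTE before an 8:2 stratified split; the penalty C and kernel
parameter g are chosen by grid search with stratified cross-validation,
ties broken toward the smallest C then the smallest g (the smoother
model).  Multiclass handling is one-vs-one, the classical SVM extension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

__all__ = ["LabelledDataset", "SvmModel", "DEFAULT_GRID", "smote_balance",
           "split_dataset", "train_classifier", "predict_grade",
           "save_model", "load_model"]

DEFAULT_GRID = 2.0 ** np.arange(-8, 9)  # powers of two, 2^-8 .. 2^8

_LABELS = (0, 1, 2)


@dataclass(frozen=True)
class LabelledDataset:
    """Feature rows (n x 5) with activity-grade labels in {0, 1, 2}."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        if x.ndim != 2 or x.shape[1] != 5:
            raise ValueError("X must be an (n, 5) feature matrix")
        if y.shape != (x.shape[0],):
            raise ValueError("y must have one label per row of X")
        if not np.isin(y, _LABELS).all():
            raise ValueError("labels must lie in {0, 1, 2}")
        object.__setattr__(self, "X", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def class_counts(self) -> dict[int, int]:
        return {int(c): int((self.y == c).sum()) for c in np.unique(self.y)}


@dataclass
class SvmModel:
    """A fitted RBF-SVM with its training metadata."""

    svc: SVC
    c: float
    g: float
    cv_score: float
    cv_folds: int
    seed: int
    c_grid: np.ndarray
    g_grid: np.ndarray
    norm_stats: object | None = None  # features.NormStats of the training split


def smote_balance(data: LabelledDataset, k_neighbors: int = 5,
                  seed: int = 0) -> LabelledDataset:
    """Upsample every minority class to the majority count with SMOTE.

    Each synthetic point is a convex combination of a minority sample and
    one of its k nearest same-class neighbours.  Original rows are
    preserved and come first in the returned dataset.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    counts = data.class_counts()
    majority = max(counts.values())
    rng = np.random.default_rng(seed)

    new_x, new_y = [data.X], [data.y]
    for cls in sorted(counts):
        deficit = majority - counts[cls]
        if deficit == 0:
            continue
        pts = data.X[data.y == cls]
        if pts.shape[0] < 2:
            raise ValueError(f"class {cls} has a single sample; "
                             "SMOTE neighbourhood undefined")
        k = min(k_neighbors, pts.shape[0] - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
        neigh = nn.kneighbors(pts, return_distance=False)[:, 1:]  # drop self
        base = rng.integers(pts.shape[0], size=deficit)
        pick = neigh[base, rng.integers(k, size=deficit)]
        lam = rng.uniform(size=(deficit, 1))
        synth = pts[base] + lam * (pts[pick] - pts[base])
        new_x.append(synth)
        new_y.append(np.full(deficit, cls, dtype=int))
    return LabelledDataset(np.vstack(new_x), np.concatenate(new_y))


def split_dataset(data: LabelledDataset, test_fraction: float = 0.2,
                  seed: int = 0) -> tuple[LabelledDataset, LabelledDataset]:
    """Stratified train/test split (default 8:2), reproducible under seed."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    try:
        x_tr, x_te, y_tr, y_te = train_test_split(
            data.X, data.y, test_size=test_fraction, stratify=data.y,
            random_state=seed)
    except ValueError:
        # a stratum is too small for the requested fractions
        warnings.warn("dataset too small to stratify; falling back to a "
                      "plain random split", stacklevel=2)
        x_tr, x_te, y_tr, y_te = train_test_split(
            data.X, data.y, test_size=test_fraction, random_state=seed)
    return LabelledDataset(x_tr, y_tr), LabelledDataset(x_te, y_te)


def train_classifier(train: LabelledDataset, c_grid=None, g_grid=None,
                     cv_folds: int = 5, seed: int = 0) -> SvmModel:
    """Grid-search C and g by stratified CV accuracy, refit on all data.

    The grid is scanned with C ascending (outer) and g ascending (inner);
    a strictly better mean CV accuracy is required to displace the
    incumbent, so ties resolve to the smallest C, then the smallest g.
    """
    c_grid = np.sort(np.asarray(DEFAULT_GRID if c_grid is None else c_grid, dtype=float))
    g_grid = np.sort(np.asarray(DEFAULT_GRID if g_grid is None else g_grid, dtype=float))
    if c_grid.size == 0 or g_grid.size == 0:
        raise ValueError("hyperparameter grids must be nonempty")
    if len(np.unique(train.y)) < 2:
        raise ValueError("training set must contain more than one class")

    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(train.X, train.y))
    best = (-np.inf, None, None)
    for c in c_grid:
        for g in g_grid:
            accs = []
            for tr_idx, va_idx in folds:
                svc = SVC(C=c, gamma=g, kernel="rbf")
                svc.fit(train.X[tr_idx], train.y[tr_idx])
                accs.append(np.mean(svc.predict(train.X[va_idx]) == train.y[va_idx]))
            score = float(np.mean(accs))
            if score > best[0]:
                best = (score, c, g)
    score, c, g = best
    svc = SVC(C=c, gamma=g, kernel="rbf")
    svc.fit(train.X, train.y)
    return SvmModel(svc=svc, c=float(c), g=float(g), cv_score=score,
                    cv_folds=cv_folds, seed=seed, c_grid=c_grid, g_grid=g_grid)


def predict_grade(model: SvmModel, x):
    """Predict the activity grade of one normalised 5-vector or a batch."""
    arr = np.asarray(x, dtype=float)
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != 5:
        raise ValueError("input must be a 5-vector or an (n, 5) matrix")
    if not np.isfinite(arr).all():
        raise ValueError("input contains non-finite values")
    pred = model.svc.predict(arr).astype(int)
    return int(pred[0]) if single else pred


def save_model(model: SvmModel, path) -> None:
    joblib.dump({"format": "walkweigh-svm", "version": 1, "model": model}, path)


def load_model(path) -> SvmModel:
    bundle = joblib.load(path)
    if not (isinstance(bundle, dict) and bundle.get("format") == "walkweigh-svm"):
        raise ValueError(f"{path} is not a walkweigh SVM bundle")
    return bundle["model"]
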