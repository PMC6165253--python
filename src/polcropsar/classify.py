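"""Supervised classification: complex-Wishart ML on C3, SVM-RBF on features.

The Wishart classifier assigns each multilook covariance pixel C to the
class m minimising d_m(C) = ln det(Sigma_m) + tr(Sigma_m^-1 C), the
maximum-likelihood rule under the complex Wishart distribution of multilook
PolSAR data.  The SVM route instead classifies stacked real-valued feature
vectors with an RBF kernel, hyperparameters chosen by cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC

from .integration import FeatureStack
from .polsar import C3Field

log = logging.getLogger(__name__)

__all__ = [
    "TrainingSet",
    "WishartModel",
    "ClassMap",
    "SVMModel",
    "NODATA",
    "wishart_train",
    "wishart_classify",
    "svm_train",
    "svm_predict",
]

NODATA = -1

DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (0.01, 0.1, 1.0, 10.0)


@dataclass
class TrainingSet:
    """Labeled pixel coordinates with a class legend.

    rows/cols are 0-based pixel indices; plot_ids (optional) tag which field
    polygon each pixel came from, for grouped splits.
    """

    rows: np.ndarray
    cols: np.ndarray
    labels: np.ndarray
    legend: dict[int, str]
    plot_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (self.rows.shape == self.cols.shape == self.labels.shape):
            raise ValueError("rows, cols and labels must have equal length")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels {sorted(missing)} absent from legend")
        if len(present) < 2:
            raise ValueError("training set needs at least 2 classes")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def class_ids(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass
class WishartModel:
    """Per-class mean covariance matrices for the Wishart ML rule."""

    class_ids: np.ndarray
    means: np.ndarray            # (K, 3, 3) Hermitian PSD
    counts: np.ndarray           # training pixels per class
    legend: dict[int, str]
    regularization: float = 0.0  # epsilon added to diagonals if singular


@dataclass
class ClassMap:
    """Integer label raster with legend and provenance."""

    labels: np.ndarray
    legend: dict[int, str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ok = np.isin(self.labels, np.array(list(self.legend) + [NODATA]))
        if not ok.all():
            bad = np.unique(self.labels[~ok])
            raise ValueError(f"labels {bad.tolist()} not in legend or nodata")

    @property
    def mask(self) -> np.ndarray:
        return self.labels != NODATA


@dataclass
class SVMModel:
    """Fitted SVM with the layer names it was trained on."""

    estimator: SVC
    layer_names: tuple[str, ...]
    legend: dict[int, str]
    cv_accuracy: float
    best_params: dict


def _training_pixels_valid(mask: np.ndarray, train: TrainingSet) -> None:
    if not mask[train.rows, train.cols].all():
        n = int((~mask[train.rows, train.cols]).sum())
        raise ValueError(f"{n} training pixels fall on invalid pixels")


def wishart_train(c3: C3Field, train: TrainingSet, min_pixels: int = 9) -> WishartModel:
    """Estimate per-class mean covariances Sigma_m from training pixels.

    Sigma_m is the arithmetic mean of the training C3 matrices of class m
    (the Wishart MLE).  If any mean is singular, eps = 1e-9 * mean(span) is
    added to all diagonals.
    """
    _training_pixels_valid(c3.mask, train)
    ids = train.class_ids
    means = np.empty((ids.size, 3, 3), dtype=complex)
    counts = np.empty(ids.size, dtype=int)
    for k, cid in enumerate(ids):
        sel = train.labels == cid
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"class {cid} ({train.legend.get(cid)}) has no training pixels")
        if n < min_pixels:
            raise ValueError(
                f"class {cid} ({train.legend.get(cid)}) has {n} < {min_pixels} training pixels"
            )
        mats = c3.data[train.rows[sel], train.cols[sel]]
        m = mats.mean(axis=0)
        means[k] = (m + m.conj().T) / 2.0  # enforce exact Hermitian symmetry
        counts[k] = n
    eps = 0.0
    det = np.abs(np.linalg.det(means))
    if (det < 1e-300).any():
        mean_span = float(np.einsum("kii->k", means).real.mean())
        eps = 1e-9 * max(mean_span, 1e-12)
        means += eps * np.eye(3)
        log.info("wishart_train: singular class mean, regularized with eps=%.3e", eps)
    return WishartModel(
        class_ids=ids, means=means, counts=counts,
        legend=dict(train.legend), regularization=eps,
    )


def wishart_classify(c3: C3Field, model: WishartModel) -> ClassMap:
    """Assign each pixel to argmin_m ln det(Sigma_m) + tr(Sigma_m^-1 C).

    Ties break to the lowest class id; pixels with a non-finite distance (or
    outside the mask) become nodata and are counted in provenance.
    """
    sign, logdet = np.linalg.slogdet(model.means)
    if not ((sign.real > 0) & np.isfinite(logdet)).all():
        raise ValueError("Wishart model has a non-positive-definite class mean")
    inv = np.linalg.inv(model.means)  # (K, 3, 3)
    # trace(inv_m C) per pixel and class
    tr = np.einsum("mij,rcji->rcm", inv, c3.data).real
    dist = logdet.real[None, None, :] + tr
    bad = ~np.isfinite(dist).all(axis=-1) | ~c3.mask
    # argmin takes the first (= lowest class id) on ties; class_ids sorted by np.unique
    idx = np.argmin(dist, axis=-1)
    labels = model.class_ids[idx]
    labels[bad] = NODATA
    n_bad = int(bad.sum() - (~c3.mask).sum())
    return ClassMap(
        labels=labels,
        legend=dict(model.legend),
        provenance={"model": "wishart", "n_nonfinite": n_bad},
    )


def svm_train(
    stack: FeatureStack,
    train: TrainingSet,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    cv_folds: int = 5,
    seed: int = 0,
    max_train_per_class: int | None = None,
) -> SVMModel:
    """Fit an RBF-kernel SVM on training pixels of a normalized stack.

    C and the kernel width gamma are selected by ``cv_folds``-fold
    cross-validated accuracy over the log grids; the chosen values and CV
    accuracy are logged and stored on the model.  ``max_train_per_class``
    optionally subsamples large training sets (seeded) to bound fit cost.
    """
    _training_pixels_valid(stack.mask, train)
    arr = stack.as_array()
    x = arr[train.rows, train.cols]
    y = train.labels.copy()
    if max_train_per_class is not None:
        rng = np.random.default_rng(seed)
        keep = []
        for cid in train.class_ids:
            idx = np.flatnonzero(y == cid)
            if idx.size > max_train_per_class:
                idx = rng.choice(idx, size=max_train_per_class, replace=False)
            keep.append(idx)
        keep = np.sort(np.concatenate(keep))
        x, y = x[keep], y[keep]
    grid = {"C": list(c_grid), "gamma": list(gamma_grid)}
    search = GridSearchCV(
        SVC(kernel="rbf", random_state=seed),
        grid,
        cv=cv_folds,
        scoring="accuracy",
        n_jobs=1,
    )
    search.fit(x, y)
    log.info(
        "svm_train: best params %s, CV accuracy %.4f",
        search.best_params_, search.best_score_,
    )
    return SVMModel(
        estimator=search.best_estimator_,
        layer_names=stack.names,
        legend=dict(train.legend),
        cv_accuracy=float(search.best_score_),
        best_params=dict(search.best_params_),
    )


def svm_predict(stack: FeatureStack, model: SVMModel) -> ClassMap:
    """Predict a label raster; invalid pixels become nodata.

    Layers are aligned to the training layers by name, so a permuted stack
    with the same names yields identical output; a genuine mismatch raises
    with the differing names listed.
    """
    missing = set(model.layer_names) - set(stack.names)
    extra = set(stack.names) - set(model.layer_names)
    if missing or extra:
        raise ValueError(
            f"stack layers do not match training layers: missing {sorted(missing)}, "
            f"unexpected {sorted(extra)}"
        )
    arr = np.stack([stack.layers[n] for n in model.layer_names], axis=-1)
    labels = np.full(stack.shape, NODATA, dtype=int)
    x = arr[stack.mask]
    if x.shape[0]:
        labels[stack.mask] = model.estimator.predict(x)
    return ClassMap(
        labels=labels,
        legend=dict(model.legend),
        provenance={"model": "svm-rbf", **model.best_params},
    )
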