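"""Soft-margin RBF support-vector classification of sparse component scores.

The classifier mirrors the configuration that works well for spectra with
few labeled samples: box constraint C = 1, Gaussian (RBF) kernel with an
"auto" kernel scale, and predictor standardization.  The "auto" scale is
resolved deterministically as the median pairwise Euclidean distance among
the standardized training points; the RBF then uses
``K(a, b) = exp(-||a - b||^2 / (2 sigma^2))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.svm import SVC

from .calibration import ReferencePair, calibrate
from .cube_io import CLEAN, CONTAMINATED, HSCube, LabelMask
from .preprocess import SpectrumMatrix, preprocess_pipeline
from .sparse_pca import ScoreMatrix, SparsePCAModel, transform

__all__ = ["ClassifierModel", "train_svm", "predict", "crossval", "classify_cube"]


@dataclass
class ClassifierModel:
    """Trained soft-margin RBF machine plus its feature standardization."""

    svc: SVC
    C: float
    kernel_scale: float
    kernel_scale_policy: str
    feature_means: np.ndarray
    feature_sds: np.ndarray
    n_per_class: dict
    seed: int | None = None


def _score_values(scores) -> np.ndarray:
    v = scores.values if isinstance(scores, ScoreMatrix) else np.asarray(scores, float)
    return np.atleast_2d(v)


def train_svm(
    scores,
    labels,
    C: float = 1.0,
    kernel_scale: float | str = "auto",
    seed: int | None = None,
) -> ClassifierModel:
    """Fit the soft-margin RBF SVM on component scores.

    Features are standardized to zero mean / unit variance; when
    ``kernel_scale`` is ``"auto"`` the RBF width sigma is the median pairwise
    distance of the standardized training points (computed on the full
    training set, so the resolution is deterministic).
    """
    X = _score_values(scores)
    y = np.asarray(labels)
    if not np.isfinite(X).all():
        raise ValueError("non-finite score values")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    if C <= 0:
        raise ValueError("box constraint C must be positive")

    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    Z = (X - means) / sds

    if kernel_scale == "auto":
        sigma = float(np.median(pdist(Z)))
        policy = "auto"
        if sigma <= 0:
            raise ValueError("degenerate features: median pairwise distance is zero")
    else:
        sigma = float(kernel_scale)
        policy = "numeric"
        if sigma <= 0:
            raise ValueError("kernel scale must be positive")

    svc = SVC(C=C, kernel="rbf", gamma=1.0 / (2.0 * sigma**2), random_state=seed)
    svc.fit(Z, y)
    return ClassifierModel(
        svc=svc,
        C=C,
        kernel_scale=sigma,
        kernel_scale_policy=policy,
        feature_means=means,
        feature_sds=sds,
        n_per_class={int(c): int(n) for c, n in zip(classes, counts)},
        seed=seed,
    )


def predict(model: ClassifierModel, scores) -> np.ndarray:
    """Hard class codes {0 clean, 1 contaminated}, one per score row."""
    X = _score_values(scores)
    if X.shape[1] != model.feature_means.size:
        raise ValueError(
            f"scores have {X.shape[1]} features, model expects "
            f"{model.feature_means.size}"
        )
    Z = (X - model.feature_means) / model.feature_sds
    return model.svc.predict(Z).astype(int)


def crossval(
    spectra,
    labels,
    folds: int = 10,
    stratified: bool = True,
    seed: int | None = 0,
    k: int = 4,
    lam: float = 0.5,
    C: float = 1.0,
):
    """Stratified k-fold cross-validation of the full feature+classifier stack.

    Sparse PCA and the SVM are refit inside every training fold — the
    held-out spectra never influence the loadings, standardization or the
    kernel scale.  Returns ``(per_fold, summary)`` where ``per_fold`` is a
    list of per-fold metric dicts and ``summary`` maps each metric to its
    mean and standard deviation across folds.
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    from .evaluate import ConfusionCounts, metrics
    from .sparse_pca import fit_sparse_pca

    values = spectra.values if isinstance(spectra, SpectrumMatrix) else np.asarray(
        spectra, dtype=float
    )
    y = np.asarray(labels)
    if folds < 2:
        raise ValueError("cross-validation needs at least 2 folds")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need both classes")
    if counts.min() < folds:
        raise ValueError(f"each class needs >= {folds} samples for {folds} folds")

    splitter = (
        StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        if stratified
        else KFold(n_splits=folds, shuffle=True, random_state=seed)
    )
    per_fold = []
    for train_idx, test_idx in splitter.split(values, y):
        spca = fit_sparse_pca(values[train_idx], k=k, lam=lam)
        clf = train_svm(
            transform(spca, values[train_idx]), y[train_idx], C=C, seed=seed
        )
        pred = predict(clf, transform(spca, values[test_idx]))
        truth = y[test_idx]
        counts_ = ConfusionCounts(
            tp=int(np.sum((pred == 1) & (truth == 1))),
            tn=int(np.sum((pred == 0) & (truth == 0))),
            fp=int(np.sum((pred == 1) & (truth == 0))),
            fn=int(np.sum((pred == 0) & (truth == 1))),
        )
        report = metrics(counts_)
        per_fold.append(
            {
                "n_test": int(test_idx.size),
                "accuracy": report.accuracy,
                "precision": report.precision,
                "recall": report.recall,
                "f1": report.f1,
            }
        )

    summary = {}
    for key in ("accuracy", "precision", "recall", "f1"):
        vals = np.array(
            [f[key] for f in per_fold if f[key] is not None], dtype=float
        )
        summary[key] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        }
    return per_fold, summary


def classify_cube(
    cube: HSCube,
    refs: ReferencePair,
    spca: SparsePCAModel,
    svm: ClassifierModel,
    preprocess_kwargs: dict | None = None,
) -> LabelMask:
    """Pixel-wise contamination map for a whole raw cube.

    Every pixel spectrum is calibrated, run through the preprocessing
    pipeline, projected onto the sparse components and classified.  Pixels
    whose preprocessed spectrum carries no signal at all (zero integral after
    background removal — e.g. a dead pixel) cannot be area-normalized and
    are mapped to the clean class.
    """
    from .preprocess import (
        clip_negatives,
        remove_laser_bands,
        savgol_smooth,
        subtract_baseline,
    )

    kwargs = dict(
        cutoff_nm=480.0, baseline_percentile=10.0, savgol_order=3, savgol_window=11
    )
    kwargs.update(preprocess_kwargs or {})

    calibrated = calibrate(cube, refs)
    m = SpectrumMatrix(calibrated.flatten_spectra(), calibrated.grid)
    m = remove_laser_bands(m, kwargs["cutoff_nm"])
    m = subtract_baseline(m, kwargs["baseline_percentile"])
    m = clip_negatives(m)

    areas = np.trapezoid(m.values, m.grid.centers, axis=1)
    ok = areas > 0
    out = np.full(m.n, CLEAN, dtype=np.uint8)
    if ok.any():
        good = SpectrumMatrix(m.values[ok] / areas[ok, None], m.grid)
        good = savgol_smooth(good, kwargs["savgol_order"], kwargs["savgol_window"])
        scores = transform(spca, good)
        out[ok] = predict(svm, scores).astype(np.uint8)
    out[out == 1] = CONTAMINATED

    return LabelMask(out.reshape(cube.rows, cube.cols))
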