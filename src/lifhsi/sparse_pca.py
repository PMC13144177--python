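"""Sparse principal component analysis with an adaptive relative threshold.

Standard PCA loadings on fluorescence spectra are dense: every band, signal
or noise, receives a non-zero weight.  The variant implemented here drives
most loading coefficients to exactly zero so that each component names the
wavelength region it responds to.

Each component is found by a power-iteration scheme on the standardized data
matrix X (n pixels x p bands).  One update is

    z     = X^T (X v_old)                     (power step)
    tau   = lambda * max|z|                   (adaptive relative threshold)
    v_new = S(z, tau) / ||S(z, tau)||_2       (shrink + renormalize)

where S is the element-wise soft-threshold operator
``sign(z) * max(|z| - tau, 0)``.  Because tau rescales with the current
proxy vector z, the same ``lambda`` produces comparable sparsity across
components of very different variance — a static tau would annihilate the
weak secondary-emission components outright.  After convergence the matrix
is deflated by Hotelling's rule ``X <- X - (X v) v^T`` and the next
component extracted.

``lambda = 0`` reduces exactly to power iteration, i.e. ordinary PCA; this
identity is used as the test oracle against eigendecomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import SpectrumMatrix

__all__ = [
    "SparsePCAModel",
    "ScoreMatrix",
    "soft_threshold",
    "fit_sparse_pca",
    "fit_standard_pca",
    "transform",
    "sparsity_stats",
    "select_k",
    "scan_lambda",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID = (0.001, 0.005, 0.010, 0.050, 0.100, 0.500, 1.000, 2.000)


def soft_threshold(z: np.ndarray, tau: float) -> np.ndarray:
    """Element-wise shrinkage sign(z) * max(|z| - tau, 0)."""
    if tau < 0:
        raise ValueError("threshold tau must be non-negative")
    z = np.asarray(z, dtype=float)
    return np.sign(z) * np.maximum(np.abs(z) - tau, 0.0)


@dataclass
class SparsePCAModel:
    """Fitted sparse loadings plus the standardization used to obtain them.

    ``loadings`` is p x k with unit-norm columns; ``column_means`` and
    ``column_scales`` reproduce the internal standardization so new spectra
    can be projected consistently.  ``explained_variance`` is the variance of
    each score column of the *training* data; sparse components are not
    orthogonal, so these do not partition the total variance.
    """

    loadings: np.ndarray
    column_means: np.ndarray
    column_scales: np.ndarray
    sparsity_lambda: float
    n_components: int
    iterations: np.ndarray
    converged: np.ndarray
    explained_variance: np.ndarray
    nonzero_counts: np.ndarray
    total_variance: float

    @property
    def p(self) -> int:
        return self.loadings.shape[0]

    def to_dict(self) -> dict:
        return {
            "loadings": self.loadings.tolist(),
            "column_means": self.column_means.tolist(),
            "column_scales": self.column_scales.tolist(),
            "sparsity_lambda": self.sparsity_lambda,
            "n_components": self.n_components,
            "iterations": self.iterations.tolist(),
            "converged": self.converged.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "nonzero_counts": self.nonzero_counts.tolist(),
            "total_variance": self.total_variance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SparsePCAModel":
        return cls(
            loadings=np.asarray(d["loadings"], dtype=float),
            column_means=np.asarray(d["column_means"], dtype=float),
            column_scales=np.asarray(d["column_scales"], dtype=float),
            sparsity_lambda=float(d["sparsity_lambda"]),
            n_components=int(d["n_components"]),
            iterations=np.asarray(d["iterations"], dtype=int),
            converged=np.asarray(d["converged"], dtype=bool),
            explained_variance=np.asarray(d["explained_variance"], dtype=float),
            nonzero_counts=np.asarray(d["nonzero_counts"], dtype=int),
            total_variance=float(d["total_variance"]),
        )


@dataclass
class ScoreMatrix:
    """n x k component scores together with the model that produced them."""

    values: np.ndarray
    model: SparsePCAModel

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.model.n_components:
            raise ValueError("score width must equal model.n_components")


def _values(X) -> np.ndarray:
    v = X.values if isinstance(X, SpectrumMatrix) else np.asarray(X, dtype=float)
    return np.atleast_2d(v)


def _standardize(values: np.ndarray, scale: bool = True):
    means = values.mean(axis=0)
    if scale:
        scales = values.std(axis=0)
        scales = np.where(scales > 0, scales, 1.0)  # zero-variance columns stay 0
    else:
        scales = np.ones(values.shape[1])
    return (values - means) / scales, means, scales


def _leading_singular_vector(M: np.ndarray) -> np.ndarray:
    # deterministic initialization: removes the RNG sensitivity a random
    # start would introduce into the fixed-point iteration
    _, _, vt = np.linalg.svd(M, full_matrices=False)
    v = vt[0]
    return _sign_fix(v)


def _sign_fix(v: np.ndarray) -> np.ndarray:
    j = int(np.argmax(np.abs(v)))
    return -v if v[j] < 0 else v


def fit_sparse_pca(
    X,
    k: int = 4,
    lam: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 500,
    scale: bool = True,
) -> SparsePCAModel:
    """Extract ``k`` sparse components from spectra ``X`` at sparsity ``lam``.

    ``X`` may be a :class:`~lifhsi.preprocess.SpectrumMatrix` or a plain
    n x p array.  Columns are centered and (by default) scaled to unit
    variance before fitting; the standardization is stored on the model.
    ``scale=False`` gives center-only fitting for data already on a common
    scale.  ``lam`` is the relative threshold fraction; values >= 1 force
    full shrinkage every update and trigger the single-coefficient fallback
    (kept, with a warning, so that parameter scans over wide grids stay
    total).
    """
    values = _values(X)
    n, p = values.shape
    if n < 2:
        raise ValueError("need at least 2 spectra")
    if not np.isfinite(values).all():
        raise ValueError("non-finite values in input spectra")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if not 1 <= k <= p:
        raise ValueError(f"k must lie in [1, {p}]")

    Z, means, scales = _standardize(values, scale)
    total_variance = float(Z.var(axis=0, ddof=1).sum())
    work = Z.copy()

    loadings = np.zeros((p, k))
    iterations = np.zeros(k, dtype=int)
    converged = np.zeros(k, dtype=bool)

    for j in range(k):
        v = _leading_singular_vector(work)
        it = 0
        for it in range(1, max_iter + 1):
            z = work.T @ (work @ v)
            zmax = float(np.max(np.abs(z)))
            if zmax == 0.0:  # deflated matrix is exactly zero
                break
            s = soft_threshold(z, lam * zmax)
            if not np.any(s):
                # lam >= 1 regime: the threshold swallows every coefficient;
                # keep the single strongest band instead of aborting
                warnings.warn(
                    f"component {j + 1}: threshold removed every coefficient "
                    f"(lambda={lam}); keeping the single largest one",
                    RuntimeWarning,
                    stacklevel=2,
                )
                s = np.zeros_like(z)
                jmax = int(np.argmax(np.abs(z)))
                s[jmax] = z[jmax]
            v_new = s / np.linalg.norm(s)
            delta = min(
                np.linalg.norm(v_new - v), np.linalg.norm(v_new + v)
            )
            v = v_new
            if delta < tol:
                converged[j] = True
                break
        loadings[:, j] = _sign_fix(v)
        iterations[j] = it
        work = work - np.outer(work @ v, v)  # Hotelling deflation

    scores = Z @ loadings
    return SparsePCAModel(
        loadings=loadings,
        column_means=means,
        column_scales=scales,
        sparsity_lambda=float(lam),
        n_components=k,
        iterations=iterations,
        converged=converged,
        explained_variance=scores.var(axis=0, ddof=1),
        nonzero_counts=(loadings != 0).sum(axis=0),
        total_variance=total_variance,
    )


def fit_standard_pca(X, k: int = 4) -> SparsePCAModel:
    """Dense PCA baseline by exact eigendecomposition (recorded as lambda=0)."""
    values = _values(X)
    n, p = values.shape
    if n < 2:
        raise ValueError("need at least 2 spectra")
    if not np.isfinite(values).all():
        raise ValueError("non-finite values in input spectra")
    if not 1 <= k <= p:
        raise ValueError(f"k must lie in [1, {p}]")

    Z, means, scales = _standardize(values)
    cov = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1][:k]
    loadings = np.column_stack([_sign_fix(eigvec[:, i]) for i in order])
    scores = Z @ loadings
    return SparsePCAModel(
        loadings=loadings,
        column_means=means,
        column_scales=scales,
        sparsity_lambda=0.0,
        n_components=k,
        iterations=np.zeros(k, dtype=int),
        converged=np.ones(k, dtype=bool),
        explained_variance=scores.var(axis=0, ddof=1),
        nonzero_counts=(loadings != 0).sum(axis=0),
        total_variance=float(Z.var(axis=0, ddof=1).sum()),
    )


def transform(model: SparsePCAModel, X) -> ScoreMatrix:
    """Project spectra onto the sparse components using the stored scaling."""
    values = _values(X)
    if values.shape[1] != model.p:
        raise ValueError(
            f"spectra have {values.shape[1]} bands, model expects {model.p}"
        )
    Z = (values - model.column_means) / model.column_scales
    return ScoreMatrix(Z @ model.loadings, model)


def sparsity_stats(model: SparsePCAModel) -> dict:
    """Per-component and overall sparsity bookkeeping.

    Sparsity is the fraction of *exactly* zero loadings, reported as a
    percentage rounded to one decimal.
    """
    p, k = model.loadings.shape
    nnz = model.nonzero_counts.astype(int)
    per = (p - nnz) / p * 100.0
    overall = (k * p - int(nnz.sum())) / (k * p) * 100.0
    return {
        "p": p,
        "k": k,
        "nonzero_counts": nnz.tolist(),
        "per_component_sparsity_pct": [round(float(s), 1) for s in per],
        "total_nonzero": int(nnz.sum()),
        "total_coefficients": k * p,
        "overall_sparsity_pct": round(float(overall), 1),
    }


# --------------------------------------------------------------------------
# Hyperparameter scans
# --------------------------------------------------------------------------

def _cv_accuracy(values, labels, k, lam, folds, seed, C=1.0):
    """Stratified CV accuracy with sparse PCA + SVM refit inside each fold."""
    from sklearn.model_selection import StratifiedKFold

    from .classify import predict, train_svm

    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for train_idx, test_idx in skf.split(values, labels):
            model = fit_sparse_pca(values[train_idx], k=k, lam=lam)
            clf = train_svm(
                transform(model, values[train_idx]), labels[train_idx], C=C, seed=seed
            )
            pred = predict(clf, transform(model, values[test_idx]))
            accs.append(float(np.mean(pred == labels[test_idx])))
    return np.asarray(accs)


def _check_cv_inputs(labels, folds):
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need both classes for a supervised scan")
    if counts.min() < folds:
        raise ValueError(
            f"each class needs at least {folds} samples for {folds}-fold CV"
        )
    return labels


def select_k(
    X,
    labels,
    k_range=range(1, 13),
    folds: int = 5,
    seed: int | None = 0,
    lam: float = 0.5,
    C: float = 1.0,
):
    """Choose the number of components by a cross-validated plateau rule.

    For every candidate ``k`` the full feature pipeline (sparse PCA at
    ``lam`` + RBF SVM) is refit inside each of ``folds`` stratified folds.
    The selected ``k`` is the smallest whose mean accuracy is within one
    standard error of the best mean (the usual operationalization of an
    accuracy plateau).  Returns ``(k, table)`` where ``table`` also carries
    the dense-PCA scree values and cumulative explained variance.
    """
    values = _values(X)
    labels = _check_cv_inputs(labels, folds)
    k_range = sorted(set(int(k) for k in k_range))
    kmax = max(k_range)

    dense = fit_standard_pca(values, k=min(kmax, values.shape[1]))
    eig = dense.explained_variance
    cumvar = np.cumsum(eig) / dense.total_variance * 100.0

    rows = []
    for k in k_range:
        accs = _cv_accuracy(values, labels, k, lam, folds, seed, C)
        rows.append(
            {
                "k": k,
                "eigenvalue": float(eig[k - 1]) if k - 1 < eig.size else np.nan,
                "cumulative_variance_pct": float(cumvar[k - 1])
                if k - 1 < cumvar.size
                else np.nan,
                "cv_accuracy_mean": float(accs.mean()),
                "cv_accuracy_sd": float(accs.std(ddof=1)) if folds > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows)

    best = table["cv_accuracy_mean"].idxmax()
    threshold = table.loc[best, "cv_accuracy_mean"] - table.loc[
        best, "cv_accuracy_sd"
    ] / np.sqrt(folds)
    ok = table[table["cv_accuracy_mean"] >= threshold]
    return int(ok["k"].min()), table


def scan_lambda(
    X,
    labels,
    grid=DEFAULT_LAMBDA_GRID,
    folds: int = 5,
    seed: int | None = 0,
    k: int = 4,
    C: float = 1.0,
):
    """Grid-search the sparsity parameter for maximal sparsity at no accuracy cost.

    Returns ``(lam, table)``; the selected value is the *largest* lambda whose
    cross-validated accuracy stays within one standard error of the best —
    i.e. the sparsest model that classifies as well as the densest.  Values
    ``lam >= 1`` are evaluated but flagged: there the relative threshold
    equals or exceeds max|z| and the single-coefficient fallback engages.
    """
    values = _values(X)
    labels = _check_cv_inputs(labels, folds)

    rows = []
    for lam in grid:
        accs = _cv_accuracy(values, labels, k, lam, folds, seed, C)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            stats = sparsity_stats(fit_sparse_pca(values, k=k, lam=lam))
        rows.append(
            {
                "lambda": float(lam),
                "overall_sparsity_pct": stats["overall_sparsity_pct"],
                "mean_nonzero_per_component": stats["total_nonzero"] / k,
                "cv_accuracy_mean": float(accs.mean()),
                "cv_accuracy_sd": float(accs.std(ddof=1)) if folds > 1 else 0.0,
                "fallback_regime": bool(lam >= 1.0),
            }
        )
    table = pd.DataFrame(rows)

    best = table["cv_accuracy_mean"].idxmax()
    threshold = table.loc[best, "cv_accuracy_mean"] - table.loc[
        best, "cv_accuracy_sd"
    ] / np.sqrt(folds)
    ok = table[table["cv_accuracy_mean"] >= threshold]
    return float(ok["lambda"].max()), table
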