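"""End-to-end orchestration: scene -> calibrate -> preprocess -> features -> map.

A run is described by a single :class:`RunConfig` (JSON-serializable).  The
scene either comes from the phantom generator (``phantom`` settings) or from
files on disk (ENVI cube + white/dark references + PNG ground truth).  The
canonical training design mirrors the instrument study: 900 clean + 900
contaminated labeled spectra, sparse PCA with k=4 components at lambda=0.5,
and an RBF SVM at C=1; the trained stack is then applied to every pixel and
scored against the eroded ground truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from . import calibration, classify, cube_io, evaluate, phantom, preprocess, sparse_pca
from .cube_io import CLEAN, CONTAMINATED, HSCube, LabelMask

__all__ = ["RunConfig", "run_pipeline", "compare_baselines", "CLASS_MAP_PALETTE"]

log = logging.getLogger("lifhsi")

#: Class-map export palette: green = clean salt, blue = contaminated.
CLASS_MAP_PALETTE = {CLEAN: (0, 255, 0), CONTAMINATED: (0, 0, 255)}


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    # scene source: phantom settings, or paths to cube/white/dark/truth
    phantom: dict | None = None
    cube_path: str | None = None
    white_path: str | None = None
    dark_path: str | None = None
    truth_path: str | None = None
    output_dir: str | None = None

    # preprocessing
    cutoff_nm: float = 480.0
    baseline_percentile: float = 10.0
    savgol_order: int = 3
    savgol_window: int = 11

    # feature extraction / classification
    k: int = 4
    sparsity_lambda: float = 0.5
    svm_C: float = 1.0
    folds: int = 10
    n_train_per_class: int = 900
    erosion_radius: int = 1
    run_crossval: bool = False

    # optional second scene classified with the trained stack (e.g. an
    # independently rendered all-clean phantom, mirroring an independent
    # control sample)
    independent_phantom: dict | None = None

    seed: int = 0
    origin_is_xy: bool = True

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def validate_paths(self) -> None:
        """Fail fast on missing inputs before any computation starts."""
        if self.phantom is not None:
            return
        for name in ("cube_path", "white_path", "dark_path"):
            value = getattr(self, name)
            if value is None or not os.path.exists(value):
                raise FileNotFoundError(f"{name} = {value!r} does not exist")
        if self.truth_path is not None and not os.path.exists(self.truth_path):
            raise FileNotFoundError(f"truth_path = {self.truth_path!r} does not exist")


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(arr).tobytes()).hexdigest()[:12]


def _load_scene(config: RunConfig):
    """Returns (cube, refs, truth-or-None)."""
    if config.phantom is not None:
        pconf = dict(config.phantom)
        pconf.setdefault("seed", config.seed)
        if "grid" in pconf and not isinstance(pconf["grid"], cube_io.WavelengthGrid):
            pconf["grid"] = cube_io.WavelengthGrid(np.asarray(pconf["grid"]))
        scene = phantom.render_scene(phantom.PhantomConfig(**pconf))
        log.info(
            "stage=simulate seed=%s cube=%s truth=%s",
            scene.config.seed,
            _digest(scene.cube.data),
            _digest(scene.truth.labels),
        )
        return scene.cube, scene.refs, scene.truth

    config.validate_paths()
    cube = cube_io.read_envi_cube(config.cube_path)
    white = cube_io.read_envi_cube(config.white_path).data
    dark = cube_io.read_envi_cube(config.dark_path).data
    truth = (
        cube_io.read_mask(config.truth_path) if config.truth_path is not None else None
    )
    log.info("stage=load cube=%s", _digest(cube.data))
    return cube, calibration.ReferencePair(white, dark), truth


def _training_spectra(calibrated: HSCube, truth: LabelMask, config: RunConfig):
    """Balanced labeled spectra drawn from the eroded ground truth."""
    eroded = evaluate.erode_mask(truth, config.erosion_radius)
    sample = evaluate.balanced_sample(
        eroded, config.n_train_per_class, seed=config.seed
    )
    rows = np.array([s[0] for s in sample])
    cols = np.array([s[1] for s in sample])
    labels = np.array([s[2] for s in sample])
    values = calibrated.data[rows, cols, :]
    return preprocess.SpectrumMatrix(values, calibrated.grid, labels), eroded


def _preprocess(m, config: RunConfig):
    return preprocess.preprocess_pipeline(
        m,
        cutoff_nm=config.cutoff_nm,
        baseline_percentile=config.baseline_percentile,
        savgol_order=config.savgol_order,
        savgol_window=config.savgol_window,
    )


def save_class_map_png(mask: LabelMask, path: str) -> str:
    rgb = np.zeros(mask.shape + (3,), dtype=np.uint8)
    for code, color in CLASS_MAP_PALETTE.items():
        rgb[mask.labels == code] = color
    Image.fromarray(rgb).save(path, format="PNG")
    return path


def run_pipeline(config: RunConfig, feature_extractor: str = "sparse") -> dict:
    """Execute the full pipeline and return the run report.

    ``feature_extractor`` is ``"sparse"`` (adaptive soft-threshold sparse
    PCA) or ``"dense"`` (ordinary PCA baseline at the same k).  When
    ``config.output_dir`` is set, the metrics JSON, the fitted feature model,
    the class map and (given truth) the error map are written there.
    """
    if feature_extractor not in ("sparse", "dense"):
        raise ValueError("feature_extractor must be 'sparse' or 'dense'")

    cube, refs, truth = _load_scene(config)
    calibrated = calibration.calibrate(cube, refs)
    log.info("stage=calibrate invalid=%s", calibrated.meta.get("n_invalid"))

    if truth is None:
        raise ValueError("a ground-truth mask is required to train the classifier")

    train_raw, eroded = _training_spectra(calibrated, truth, config)
    train = _preprocess(train_raw, config)
    log.info(
        "stage=preprocess n=%d p=%d steps=%s",
        train.n,
        train.p,
        ",".join(train.meta.get("steps", ())),
    )

    if feature_extractor == "sparse":
        spca = sparse_pca.fit_sparse_pca(
            train, k=config.k, lam=config.sparsity_lambda
        )
    else:
        spca = sparse_pca.fit_standard_pca(train, k=config.k)
    stats = sparse_pca.sparsity_stats(spca)
    log.info(
        "stage=fit extractor=%s k=%d lambda=%.3f sparsity=%.1f%%",
        feature_extractor,
        config.k,
        spca.sparsity_lambda,
        stats["overall_sparsity_pct"],
    )

    svm = classify.train_svm(
        sparse_pca.transform(spca, train),
        train.labels,
        C=config.svm_C,
        seed=config.seed,
    )
    log.info("stage=train sigma=%.4f C=%.2f", svm.kernel_scale, svm.C)

    class_map = classify.classify_cube(
        cube,
        refs,
        spca,
        svm,
        preprocess_kwargs={
            "cutoff_nm": config.cutoff_nm,
            "baseline_percentile": config.baseline_percentile,
            "savgol_order": config.savgol_order,
            "savgol_window": config.savgol_window,
        },
    )
    fractions = evaluate.class_fraction(class_map)
    log.info("stage=classify contaminated=%.1f%%", fractions["contaminated"] * 100)

    counts = evaluate.confusion(class_map, eroded)
    report_metrics = evaluate.metrics(counts)
    emap = evaluate.error_map(class_map, eroded)

    report: dict = {
        "feature_extractor": feature_extractor,
        "seed": config.seed,
        "k": config.k,
        "sparsity_lambda": spca.sparsity_lambda,
        "svm_C": config.svm_C,
        "kernel_scale": svm.kernel_scale,
        "n_train_per_class": config.n_train_per_class,
        "sparsity": stats,
        "class_fractions": {k_: v for k_, v in fractions.items()},
        "confusion": {
            "TP": counts.tp,
            "TN": counts.tn,
            "FP": counts.fp,
            "FN": counts.fn,
        },
        "metrics": report_metrics.as_percent(),
    }

    if config.independent_phantom is not None:
        pconf = dict(config.independent_phantom)
        if "grid" in pconf and not isinstance(pconf["grid"], cube_io.WavelengthGrid):
            pconf["grid"] = cube_io.WavelengthGrid(np.asarray(pconf["grid"]))
        indep = phantom.render_scene(phantom.PhantomConfig(**pconf))
        indep_map = classify.classify_cube(indep.cube, indep.refs, spca, svm)
        indep_fraction = evaluate.class_fraction(indep_map)
        report["independent"] = {
            "class_fractions": indep_fraction,
            "n_contaminated_pixels": int(
                np.sum(indep_map.labels == CONTAMINATED)
            ),
        }
        log.info(
            "stage=independent contaminated=%.1f%%",
            indep_fraction["contaminated"] * 100,
        )

    if config.run_crossval:
        _, cv_summary = classify.crossval(
            train,
            train.labels,
            folds=config.folds,
            seed=config.seed,
            k=config.k,
            lam=config.sparsity_lambda,
            C=config.svm_C,
        )
        report["crossval"] = cv_summary
        log.info("stage=crossval accuracy=%.4f", cv_summary["accuracy"]["mean"])

    if config.output_dir:
        os.makedirs(config.output_dir, exist_ok=True)
        out = config.output_dir
        with open(os.path.join(out, f"metrics_{feature_extractor}.json"), "w") as fh:
            json.dump(report, fh, indent=2)
        with open(os.path.join(out, f"model_{feature_extractor}.json"), "w") as fh:
            json.dump(spca.to_dict(), fh)
        save_class_map_png(
            class_map, os.path.join(out, f"class_map_{feature_extractor}.png")
        )
        Image.fromarray(emap).save(
            os.path.join(out, f"error_map_{feature_extractor}.png"), format="PNG"
        )
        report["artifacts"] = sorted(os.listdir(out))

    return report


def compare_baselines(config: RunConfig) -> dict:
    """Paired sparse-vs-dense feature comparison under the same SVM protocol.

    Both runs share the scene, the training sample, the preprocessing and the
    classifier settings; only the feature extractor differs.  The report
    carries both full run reports, both sparsity tables, and the pairwise
    metric deltas (sparse minus dense).
    """
    sparse_report = run_pipeline(config, feature_extractor="sparse")
    dense_report = run_pipeline(config, feature_extractor="dense")

    delta = {}
    for key in ("accuracy_pct", "precision", "recall", "f1"):
        a = sparse_report["metrics"][key]
        b = dense_report["metrics"][key]
        delta[key] = None if a is None or b is None else round(a - b, 4)

    return {
        "sparse": sparse_report,
        "dense": dense_report,
        "delta_sparse_minus_dense": delta,
        "sparsity_tables": {
            "sparse": sparse_report["sparsity"],
            "dense": dense_report["sparsity"],
        },
    }
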