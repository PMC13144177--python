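"""Synthetic laser-induced-fluorescence scenes for pipeline testing.

No public hyperspectral acquisitions of contaminated salt exist, so every
downstream stage is exercised on phantoms that emulate the instrument data:

* clean-salt pixels: a flat background drawn uniformly from ~200-400 counts
  plus a narrow reflection of the 450 nm excitation line;
* contaminated pixels: the same background plus Gaussian emission peaks — a
  dominant band peaking inside 480-520 nm (~4100 counts at unit
  concentration), and weaker secondary bands near 575, 750 and 990 nm;
* spatially clustered contamination from a thresholded smoothed Gaussian
  random field;
* additive Gaussian sensor noise, a dark-current offset, and a white
  reference frame with a small smooth spatial nonuniformity.

Peak amplitudes scale linearly with ``concentration_scale`` and carry
per-pixel, per-peak multiplicative jitter emulating heterogeneous residue
concentration and photochemical aging; that jitter is what gives each
emission band an independent variance factor, as in real residue scenes.
All randomness flows from a single seed through split substreams, so scenes
are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .calibration import ReferencePair
from .cube_io import (
    CLEAN,
    CONTAMINATED,
    HSCube,
    LabelMask,
    WavelengthGrid,
    make_wavelength_grid,
)

__all__ = [
    "Peak",
    "PhantomConfig",
    "PhantomScene",
    "clean_salt_spectrum",
    "sunscreen_spectrum",
    "contamination_field",
    "render_scene",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Peak:
    """Gaussian emission band parameterized by center, FWHM and amplitude."""

    center_nm: float
    fwhm_nm: float
    amplitude: float

    def profile(self, centers: np.ndarray) -> np.ndarray:
        sigma = self.fwhm_nm * _FWHM_TO_SIGMA
        return np.exp(-0.5 * ((centers - self.center_nm) / sigma) ** 2)


def _default_grid() -> WavelengthGrid:
    return make_wavelength_grid(400.0, 1000.0, 128)


@dataclass
class PhantomConfig:
    """Study conditions of a synthetic scene (defaults emulate the instrument)."""

    rows: int = 200
    cols: int = 200
    grid: WavelengthGrid = field(default_factory=_default_grid)
    clean_baseline_range: tuple[float, float] = (200.0, 400.0)
    laser_center_nm: float = 450.0
    laser_fwhm_nm: float = 12.0
    laser_amplitude: float = 1500.0
    main_peak: Peak = field(default_factory=lambda: Peak(500.0, 40.0, 4100.0))
    secondary_peaks: tuple[Peak, ...] = field(
        default_factory=lambda: (
            Peak(575.0, 50.0, 350.0),
            Peak(750.0, 60.0, 300.0),
            Peak(990.0, 20.0, 250.0),
        )
    )
    concentration_scale: float = 1.0
    amplitude_jitter: float = 0.25
    contamination_fraction: float = 0.578
    correlation_length_px: float = 10.0
    noise_sd: float = 20.0
    dark_level: float = 50.0
    white_level: float = 10000.0
    white_nonuniformity: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.main_peak.amplitude < 0 or any(
            p.amplitude < 0 for p in self.secondary_peaks
        ):
            raise ValueError("peak amplitudes must be non-negative")
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise ValueError("contamination_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def peaks(self) -> tuple[Peak, ...]:
        return (self.main_peak, *self.secondary_peaks)

    def emission_band_set(self, threshold_fwhm: float = 1.0) -> np.ndarray:
        """Boolean mask of grid bands inside center +- threshold_fwhm * FWHM
        of any emission peak (the planted support used by recovery checks)."""
        centers = self.grid.centers
        mask = np.zeros(centers.size, dtype=bool)
        for pk in self.peaks:
            mask |= np.abs(centers - pk.center_nm) <= threshold_fwhm * pk.fwhm_nm
        return mask

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = self.grid.centers.tolist()
        return d


@dataclass
class PhantomScene:
    """A rendered phantom: raw cube, references, ground truth, and its config."""

    cube: HSCube
    white: np.ndarray
    dark: np.ndarray
    truth: LabelMask
    config: PhantomConfig

    @property
    def refs(self) -> ReferencePair:
        return ReferencePair(self.white, self.dark)


def _batch_spectra(
    grid: WavelengthGrid,
    config: PhantomConfig,
    scales: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized generator core shared by the per-pixel ops and the renderer.

    Draw order is fixed (baseline, noise, peak jitter) so that a
    zero-concentration spectrum is bit-identical to a clean one under the
    same stream.
    """
    centers = grid.centers
    n = scales.size
    lo, hi = config.clean_baseline_range
    baseline = rng.uniform(lo, hi, size=(n, 1))
    noise = (
        rng.normal(0.0, config.noise_sd, size=(n, centers.size))
        if config.noise_sd > 0
        else 0.0
    )
    laser = config.laser_amplitude * Peak(
        config.laser_center_nm, config.laser_fwhm_nm, 1.0
    ).profile(centers)

    peaks = config.peaks
    jitter = np.maximum(
        0.0,
        1.0 + config.amplitude_jitter * rng.standard_normal(size=(n, len(peaks))),
    )
    emission = np.zeros((n, centers.size))
    for i, pk in enumerate(peaks):
        emission += (
            pk.amplitude * jitter[:, i : i + 1] * pk.profile(centers)[None, :]
        )
    return baseline + laser[None, :] + scales[:, None] * emission + noise


def clean_salt_spectrum(
    grid: WavelengthGrid,
    rng: np.random.Generator,
    config: PhantomConfig | None = None,
) -> np.ndarray:
    """One clean-salt spectrum: flat background plus the 450 nm laser line."""
    config = config or PhantomConfig(grid=grid)
    return _batch_spectra(grid, config, np.zeros(1), rng)[0]


def sunscreen_spectrum(
    grid: WavelengthGrid,
    concentration_scale: float,
    rng: np.random.Generator,
    config: PhantomConfig | None = None,
) -> np.ndarray:
    """One contaminated spectrum at the given concentration scale.

    At unit scale (and noise off) the emission maximum above the laser cut
    lies inside 480-520 nm with height ~4100 counts over the background.
    """
    if concentration_scale < 0:
        raise ValueError("concentration_scale must be non-negative")
    config = config or PhantomConfig(grid=grid)
    return _batch_spectra(grid, config, np.full(1, float(concentration_scale)), rng)[0]


def contamination_field(
    rows: int,
    cols: int,
    target_fraction: float,
    correlation_length_px: float,
    rng: np.random.Generator,
) -> LabelMask:
    """Spatially clustered contamination mask from a thresholded random field.

    White noise is smoothed with a Gaussian kernel of width
    ``correlation_length_px`` and thresholded at the empirical quantile that
    realizes ``target_fraction``; contiguous clusters emerge at correlation
    lengths of a few pixels and above.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in [0, 1]")
    if target_fraction == 0.0:
        return LabelMask(np.full((rows, cols), CLEAN, dtype=np.uint8))
    if target_fraction == 1.0:
        return LabelMask(np.full((rows, cols), CONTAMINATED, dtype=np.uint8))
    fld = gaussian_filter(
        rng.standard_normal((rows, cols)), sigma=correlation_length_px
    )
    threshold = np.quantile(fld, 1.0 - target_fraction)
    labels = np.where(fld > threshold, CONTAMINATED, CLEAN).astype(np.uint8)
    return LabelMask(labels)


def render_scene(config: PhantomConfig) -> PhantomScene:
    """Render a full scene: raw cube, white/dark references, and ground truth.

    The raw cube is per-pixel generated spectra plus the dark-current offset;
    the white frame is a spectrally flat high-count frame with a smooth
    spatial nonuniformity of at most ``white_nonuniformity``; the dark frame
    is the dark level plus sensor noise.  Negative draws are clamped at 0.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_field, rng_pixels, rng_white, rng_dark = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    truth = contamination_field(
        config.rows,
        config.cols,
        config.contamination_fraction,
        config.correlation_length_px,
        rng_field,
    )

    scales = np.where(
        truth.labels.reshape(-1) == CONTAMINATED, config.concentration_scale, 0.0
    )
    spectra = _batch_spectra(config.grid, config, scales, rng_pixels)
    raw = np.maximum(spectra + config.dark_level, 0.0).reshape(
        config.rows, config.cols, config.grid.count
    )

    eta = gaussian_filter(
        rng_white.standard_normal((config.rows, config.cols)),
        sigma=max(config.rows, config.cols) / 8.0,
    )
    peak = float(np.max(np.abs(eta)))
    if peak > 0:
        eta = eta / peak * config.white_nonuniformity
    white = config.white_level * (1.0 + eta)[:, :, None] * np.ones(
        (1, 1, config.grid.count)
    )

    dark = np.maximum(
        config.dark_level
        + (
            rng_dark.normal(
                0.0, config.noise_sd, size=(config.rows, config.cols, config.grid.count)
            )
            if config.noise_sd > 0
            else 0.0
        ),
        0.0,
    )

    cube = HSCube(raw, config.grid, {"phantom_seed": config.seed})
    return PhantomScene(cube=cube, white=white, dark=dark, truth=truth, config=config)
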