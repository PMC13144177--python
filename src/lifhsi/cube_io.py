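"""Hyperspectral cube, wavelength-grid and label-mask containers with file I/O.

The on-disk cube format is the de-facto ENVI convention: a plain-text header
(``.hdr``) describing dimensions, data type, interleave and band-center
wavelengths, next to a raw binary raster.  Only the subset needed for
little-endian float32/uint16 cubes in BSQ/BIL/BIP interleave is supported;
writing always emits BSQ.  Label masks are 8-bit grayscale PNGs restricted to
the codes 0 (clean), 1 (contaminated) and 255 (unlabeled).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

__all__ = [
    "CLEAN",
    "CONTAMINATED",
    "UNLABELED",
    "WavelengthGrid",
    "HSCube",
    "LabelMask",
    "FormatError",
    "make_wavelength_grid",
    "read_envi_cube",
    "write_envi_cube",
    "read_mask",
    "write_mask",
    "spectra_to_csv",
]

#: Label codes used throughout the package.
CLEAN = 0
CONTAMINATED = 1
UNLABELED = 255

_VALID_CODES = frozenset({CLEAN, CONTAMINATED, UNLABELED})


class FormatError(ValueError):
    """Raised when an on-disk raster violates the supported format subset."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing band-center wavelengths in nanometres."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        if centers.ndim != 1 or centers.size < 1:
            raise ValueError("wavelength grid needs at least one band center")
        if centers.size > 1 and not np.all(np.diff(centers) > 0):
            raise ValueError("band centers must be strictly increasing")
        object.__setattr__(self, "centers", centers)

    @property
    def count(self) -> int:
        return int(self.centers.size)

    def __len__(self) -> int:
        return self.count

    def __eq__(self, other) -> bool:
        return isinstance(other, WavelengthGrid) and np.array_equal(
            self.centers, other.centers
        )


def make_wavelength_grid(start_nm: float, stop_nm: float, n: int) -> WavelengthGrid:
    """Uniform, endpoint-inclusive grid of ``n`` band centers.

    The instrument convention adopted here is a uniform 400–1000 nm grid of
    128 bands (spacing 600/127 ≈ 4.7244 nm); the nominal "5.1 nm" resolution
    quoted for such cameras is not consistent with that span and is ignored.
    """
    if n < 2:
        raise ValueError(f"grid needs n >= 2 bands, got {n}")
    if not stop_nm > start_nm:
        raise ValueError("stop_nm must exceed start_nm")
    return WavelengthGrid(np.linspace(start_nm, stop_nm, n))


@dataclass
class HSCube:
    """rows x cols x bands intensity raster bound to a wavelength grid."""

    data: np.ndarray
    grid: WavelengthGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        if self.data.shape[2] != self.grid.count:
            raise ValueError(
                f"cube has {self.data.shape[2]} bands but grid has {self.grid.count}"
            )

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]

    @property
    def n_pixels(self) -> int:
        return self.rows * self.cols

    def flatten_spectra(self) -> np.ndarray:
        """(rows*cols) x bands view in row-major pixel order."""
        return self.data.reshape(self.n_pixels, self.bands)


@dataclass
class LabelMask:
    """rows x cols integer raster over the codes {0 clean, 1 contaminated, 255 unlabeled}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("mask must be 2-D")
        bad = set(np.unique(labels).tolist()) - _VALID_CODES
        if bad:
            raise FormatError(f"mask contains invalid codes {sorted(bad)}")
        self.labels = labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def labeled(self) -> np.ndarray:
        """Boolean raster marking pixels carrying a class label."""
        return self.labels != UNLABELED


# --------------------------------------------------------------------------
# ENVI header + raw raster
# --------------------------------------------------------------------------

# ENVI data-type codes supported (little-endian only).
_DTYPES = {4: np.dtype("<f4"), 12: np.dtype("<u2")}
_DTYPE_CODES = {v: k for k, v in _DTYPES.items()}


def _parse_envi_header(text: str) -> dict:
    """Parse the ``key = value`` / ``key = { ... }`` ENVI header dialect."""
    body = text
    if body.lstrip().lower().startswith("envi"):
        body = body.lstrip()[4:]
    fields: dict[str, str] = {}
    i = 0
    lines = body.splitlines()
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{"):
            while "}" not in value and i < len(lines):
                value += " " + lines[i].strip()
                i += 1
            value = value.strip("{}").strip()
        fields[key] = value
    return fields


def read_envi_cube(header_path: str | os.PathLike) -> HSCube:
    """Read an ENVI header + companion binary raster into an :class:`HSCube`."""
    header_path = os.fspath(header_path)
    with open(header_path) as fh:
        fields = _parse_envi_header(fh.read())

    try:
        samples = int(fields["samples"])
        lines_ = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise FormatError(f"header missing required field {exc}") from exc

    if dtype_code not in _DTYPES:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    if int(fields.get("byte order", "0")) != 0:
        raise FormatError("only little-endian (byte order = 0) is supported")
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"unknown interleave {interleave!r}")

    if "wavelength" not in fields:
        raise FormatError("header lacks a wavelength list")
    centers = np.array(
        [float(v) for v in fields["wavelength"].split(",") if v.strip()]
    )
    if centers.size != bands:
        raise FormatError(
            f"header declares {bands} bands but {centers.size} wavelengths"
        )

    raw_path = fields.get("_raw_path") or _companion_raw(header_path)
    if not os.path.exists(raw_path):
        raise FormatError(f"companion raster {raw_path!r} not found")

    dtype = _DTYPES[dtype_code]
    flat = np.fromfile(raw_path, dtype=dtype)
    expected = samples * lines_ * bands
    if flat.size != expected:
        raise FormatError(
            f"raster holds {flat.size} values, header declares {expected}"
        )

    if interleave == "bsq":  # band-sequential: (bands, rows, cols)
        data = flat.reshape(bands, lines_, samples).transpose(1, 2, 0)
    elif interleave == "bil":  # band-interleaved-by-line: (rows, bands, cols)
        data = flat.reshape(lines_, bands, samples).transpose(0, 2, 1)
    else:  # bip: (rows, cols, bands)
        data = flat.reshape(lines_, samples, bands)

    meta = {
        k: v
        for k, v in fields.items()
        if k.startswith("meta ")
    }
    meta = {k[5:]: v for k, v in meta.items()}
    return HSCube(np.ascontiguousarray(data), WavelengthGrid(centers), meta)


def _companion_raw(header_path: str) -> str:
    stem, ext = os.path.splitext(header_path)
    return stem + ".raw" if ext.lower() == ".hdr" else header_path + ".raw"


def write_envi_cube(cube: HSCube, header_path: str | os.PathLike) -> str:
    """Write ``cube`` as an ENVI header + BSQ raster; returns the header path.

    float inputs are stored as float32 (ENVI type 4), unsigned 16-bit ints as
    type 12.  ``cube.meta`` string values are preserved as ``meta <key>``
    header lines.
    """
    header_path = os.fspath(header_path)
    data = cube.data
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype("<u2")
        code = 12
    else:
        data = data.astype("<f4")
        code = 4

    raw_path = _companion_raw(header_path)
    # BSQ layout: band-major
    data.transpose(2, 0, 1).tofile(raw_path)

    wl = ", ".join(f"{w:.6f}" for w in cube.grid.centers)
    lines = [
        "ENVI",
        f"samples = {cube.cols}",
        f"lines = {cube.rows}",
        f"bands = {cube.bands}",
        f"data type = {code}",
        "interleave = bsq",
        "byte order = 0",
        f"wavelength = {{ {wl} }}",
    ]
    for key, value in cube.meta.items():
        lines.append(f"meta {key} = {value}")
    with open(header_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return header_path


# --------------------------------------------------------------------------
# Mask PNG I/O
# --------------------------------------------------------------------------

def read_mask(path: str | os.PathLike) -> LabelMask:
    """Read an 8-bit grayscale PNG mask; any code outside {0,1,255} is rejected."""
    img = Image.open(path)
    if img.mode != "L":
        raise FormatError(f"mask must be 8-bit single channel, got mode {img.mode!r}")
    return LabelMask(np.asarray(img))


def write_mask(mask: LabelMask, path: str | os.PathLike) -> str:
    """Write a :class:`LabelMask` as an 8-bit grayscale PNG."""
    Image.fromarray(mask.labels, mode="L").save(os.fspath(path), format="PNG")
    return os.fspath(path)


def spectra_to_csv(cube: HSCube, path: str | os.PathLike) -> str:
    """Export per-pixel spectra: one row per pixel, columns = band centers."""
    import pandas as pd

    frame = pd.DataFrame(
        cube.flatten_spectra(), columns=[f"{w:.4f}" for w in cube.grid.centers]
    )
    frame.to_csv(os.fspath(path), index=False)
    return os.fspath(path)
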