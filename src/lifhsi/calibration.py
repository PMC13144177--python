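"""Two-point radiometric correction of raw hyperspectral cubes.

A raw acquisition R_o is converted to reflectance-like units with a white
(bright) reference R_B and a dark reference R_D:

    R_f = (R_o - R_D) / (R_B - R_D)

The white frame is acquired from a diffuse reflectance standard under the
measurement illumination; the dark frame with the lens capped.  The result is
0 where the sample matches the dark level and 1 where it matches the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cube_io import HSCube

__all__ = ["ReferencePair", "calibrate"]

#: Relative threshold below which the (white - dark) denominator is treated
#: as a dead band: the output is forced to 0 and the location recorded.
DENOM_GUARD_REL = 1e-6


@dataclass
class ReferencePair:
    """White (R_B) and dark (R_D) reference rasters.

    Each reference may be a full rows x cols x bands frame, a single spectrum
    of length ``bands`` (broadcast over space), or a scalar.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)

    def broadcast_to(self, shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
        try:
            return (
                np.broadcast_to(self.white, shape),
                np.broadcast_to(self.dark, shape),
            )
        except ValueError as exc:
            raise ValueError(
                f"reference shapes {self.white.shape}/{self.dark.shape} are "
                f"incompatible with cube shape {shape}"
            ) from exc


def calibrate(raw: HSCube, refs: ReferencePair) -> HSCube:
    """Apply the two-point correction (R_o - R_D) / (R_B - R_D) element-wise.

    Locations where |R_B - R_D| falls below ``DENOM_GUARD_REL * max(R_B)``
    carry no radiometric information (dead band / dead pixel); they are set
    to 0 and their count recorded under ``meta["n_invalid"]``.
    """
    white, dark = refs.broadcast_to(raw.data.shape)
    num = raw.data.astype(float) - dark
    den = white - dark

    guard = DENOM_GUARD_REL * float(np.max(white)) if white.size else 0.0
    invalid = np.abs(den) < guard
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=~invalid)
    out[invalid] = 0.0

    meta = dict(raw.meta)
    meta["calibrated"] = True
    meta["n_invalid"] = int(invalid.sum())
    return HSCube(out, raw.grid, meta)
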