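"""Detector geometry and momentum-transfer conversions.

A small-angle fiber-diffraction frame is indexed by pixel radius ``r`` from
the beam center; the scattering vector magnitude follows from the flat
detector geometry as

    q = (4*pi/lambda) * sin(theta),   2*theta = atan(r * pixel_size / distance)

with ``q`` in inverse Angstrom when the wavelength is given in Angstrom.
Real-space repeats are recovered as ``d = 2*pi/q``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "DetectorGeometry",
    "q_of_radius",
    "radius_of_q",
    "q_of_d",
    "d_of_q",
    "pixel_grids",
]


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat-detector geometry sidecar.

    Parameters
    ----------
    wavelength : float
        X-ray wavelength in Angstrom.
    distance : float
        Sample-detector distance in mm.
    pixel_size : float
        Square pixel edge in mm.
    beam_center : tuple of float
        Direct-beam position ``(col, row)`` in 0-based pixels.
    image_shape : tuple of int
        Detector shape ``(rows, cols)``.
    """

    wavelength: float = 1.033
    distance: float = 2500.0
    pixel_size: float = 0.172
    beam_center: tuple[float, float] = (255.5, 255.5)
    image_shape: tuple[int, int] = (512, 512)

    def __post_init__(self) -> None:
        if self.wavelength <= 0 or self.distance <= 0 or self.pixel_size <= 0:
            raise ValueError("wavelength, distance and pixel_size must be positive")
        col, row = self.beam_center
        rows, cols = self.image_shape
        if not (0 <= col < cols and 0 <= row < rows):
            raise ValueError(f"beam center {self.beam_center} outside image {self.image_shape}")

    def to_dict(self) -> dict:
        return {
            "wavelength_A": self.wavelength,
            "distance_mm": self.distance,
            "pixel_size_mm": self.pixel_size,
            "beam_center_colrow": list(self.beam_center),
            "image_shape_rowscols": list(self.image_shape),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorGeometry":
        return cls(
            wavelength=d["wavelength_A"],
            distance=d["distance_mm"],
            pixel_size=d["pixel_size_mm"],
            beam_center=tuple(d["beam_center_colrow"]),
            image_shape=tuple(d["image_shape_rowscols"]),
        )


def q_of_radius(geometry: DetectorGeometry, r):
    """Map pixel radius to q (1/A). Vectorized; ``r`` may be array-like."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("pixel radius must be non-negative")
    two_theta = np.arctan(r * geometry.pixel_size / geometry.distance)
    q = (4.0 * math.pi / geometry.wavelength) * np.sin(two_theta / 2.0)
    return q if q.ndim else float(q)

def radius_of_q(geometry: DetectorGeometry, q):
    """Inverse of :func:`q_of_radius` (pixel radius of a given q)."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    s = q * geometry.wavelength / (4.0 * math.pi)
    if np.any(s >= 1.0):
        raise ValueError("q beyond the diffraction limit for this wavelength")
    r = geometry.distance * np.tan(2.0 * np.arcsin(s)) / geometry.pixel_size
    return r if r.ndim else float(r)


def q_of_d(d: float) -> float:
    """q (1/A) of a real-space repeat d (A)."""
    if d <= 0:
        raise ValueError("d-spacing must be positive")
    return 2.0 * math.pi / d


def d_of_q(q: float) -> float:
    """Real-space repeat d (A) of a scattering vector q (1/A)."""
    if q <= 0:
        raise ValueError("q must be positive")
    return 2.0 * math.pi / q


@lru_cache(maxsize=8)
def pixel_grids(geometry: DetectorGeometry, beam_center: tuple[float, float] | None = None):
    """Per-pixel radius (px) and azimuth (deg, [0, 360)) grids.

    Azimuth is measured counterclockwise from the detector +x (column) axis
    with the row axis pointing up, i.e. chi = 90 deg is the top of the image
    (the meridian for a vertical fiber axis). Cached per geometry.
    """
    cx, cy = beam_center if beam_center is not None else geometry.beam_center
    rows, cols = geometry.image_shape
    y = np.arange(rows, dtype=float)[:, None] - cy
    x = np.arange(cols, dtype=float)[None, :] - cx
    r = np.hypot(x, y)
    chi = np.degrees(np.arctan2(-y, x)) % 360.0
    return r, chi
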