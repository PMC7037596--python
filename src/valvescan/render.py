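"""Phenomenological rendering of the phantom's raw data products.

Diffraction frames are built from Gaussian arcs: collagen meridional orders
n = 1..9 of the local D-period, muscle (1,0)/(1,1) equatorial reflections
with amplitude proportional to the local muscle fraction, and a smooth
power-law background.  Arc positions follow the exact flat-detector
geometry; no structure factors or wide-angle corrections are modelled.

Video frames are light fields with dark Gaussian fiducial blobs advected by
the per-region strain ground truth of a simulated pull.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import DetectorGeometry, pixel_grids, q_of_d, radius_of_q
from .phantom import LoadTrace, PhantomError, TissuePhantom

logger = logging.getLogger(__name__)

__all__ = [
    "DiffractionFrame",
    "VideoStack",
    "render_diffraction",
    "render_video_frames",
    "COLLAGEN_ORDER_WEIGHTS",
]

#: relative integrated intensity of collagen meridional orders 1..9
#: (order 5 carries unit weight; odd orders strong, as for the D-period
#: intensity distribution of fibrillar collagen)
COLLAGEN_ORDER_WEIGHTS = {1: 0.9, 2: 0.35, 3: 0.7, 4: 0.25, 5: 1.0,
                          6: 0.3, 7: 0.45, 8: 0.2, 9: 0.5}
#: muscle (1,0) integrated intensity relative to (1,1)
MUSCLE_10_WEIGHT = 1.3


@dataclass
class DiffractionFrame:
    """One detector image with its geometry and scan metadata."""

    image: np.ndarray
    geometry: DetectorGeometry
    position_mm: float = 0.0
    eng_strain: float = 0.0            # overall engineering strain, fraction
    load_g: float | None = None
    scan_index: int | None = None


@dataclass
class VideoStack:
    """Image sequence of a pull plus generator truth for testing."""

    frames: np.ndarray                 # (n_frames, rows, cols) float32
    times: np.ndarray                  # s
    frame_rate: float                  # Hz
    scale_px_per_mm: float
    true_positions: np.ndarray         # (n_frames, n_markers, 2) as (col, row)
    marker_pairs: dict[str, tuple[int, int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# diffraction
# ---------------------------------------------------------------------------

def _azimuthal_density(chi: np.ndarray, center: float, sigma: float | None) -> np.ndarray:
    """Two-lobed (180-deg periodic) azimuthal density, normalized over 360 deg.

    ``sigma=None`` renders an isotropic ring (uniform density).
    """
    if sigma is None or not np.isfinite(sigma):
        return np.full(chi.shape, 1.0 / 360.0)
    dens = np.zeros_like(chi)
    norm = 0.5 / (math.sqrt(2.0 * math.pi) * sigma)  # half weight per lobe
    for lobe in (center, center + 180.0):
        d = (chi - lobe + 180.0) % 360.0 - 180.0
        dens += norm * np.exp(-0.5 * (d / sigma) ** 2)
    return dens


def _add_arc(image, r, chi, d_angstrom, counts, sigma_chi, axis_deg,
             sigma_r, geometry, label):
    """Accumulate one Gaussian arc; returns False if it falls off-detector."""
    try:
        r0 = radius_of_q(geometry, q_of_d(d_angstrom))
    except ValueError:
        return False
    rows, cols = geometry.image_shape
    cx, cy = geometry.beam_center
    r_edge = min(cx, cols - 1 - cx, cy, rows - 1 - cy)
    if r0 + 3.0 * sigma_r > r_edge:
        logger.info("arc %s at r=%.1f px falls off-detector; omitted", label, r0)
        return False
    sel = np.abs(r - r0) < 6.0 * sigma_r
    rs, chis = r[sel], chi[sel]
    radial = np.exp(-0.5 * ((rs - r0) / sigma_r) ** 2) / (math.sqrt(2 * math.pi) * sigma_r)
    azim = _azimuthal_density(chis, axis_deg, sigma_chi)
    # pixel at radius rs spans (180/pi)/rs degrees of azimuth and 1 px radially
    image[sel] += counts * radial * azim * (180.0 / math.pi) / np.maximum(rs, 0.5)
    return True


def render_diffraction(
    phantom: TissuePhantom,
    x: float,
    eng_strain: float,
    geometry: DetectorGeometry | None = None,
    noise_seed: int | None = None,
    counts_scale: float = 2.0e5,
    sigma_r: float = 1.5,
    fiber_axis_deg: float = 90.0,
    background: tuple[float, float, float] = (30.0, 40.0, 1.8),
    peak_snr: float | None = None,
    scan_index: int | None = None,
    load_g: float | None = None,
    isotropic: bool = False,
) -> DiffractionFrame:
    """Render the detector frame for a probe position and strain level.

    Parameters
    ----------
    x : float
        Material position along the strip, mm from the PM end.
    eng_strain : float
        Overall engineering strain (fraction) of the scan series.
    counts_scale : float
        Total photons shared by the composition-defining reflections: the
        collagen 5th order receives ``counts_scale * (1 - f_m)`` and the
        muscle (1,1) ``counts_scale * f_m``, so the relative composition is
        encoded in integrated arc intensities on a common scale.
    background : tuple
        ``(amplitude, r_scale_px, exponent)`` of the smooth power-law
        background ``amp * (1 + r/r_scale)**-exponent``.
    peak_snr : float, optional
        If given, rescale all arc intensities so the brightest pixel of the
        5th-order collagen arc has Poisson SNR ``s/sqrt(s+b) = peak_snr``.
    noise_seed : int, optional
        Apply Poisson noise with this seed; rendering is noise-free without
        it (the seed is mandatory for any stochastic render).
    """
    geometry = geometry or DetectorGeometry()
    if not 0.0 <= x <= phantom.total_length:
        raise PhantomError(f"position {x} mm outside sample [0, {phantom.total_length}]")
    if eng_strain < 0:
        raise PhantomError("engineering strain must be non-negative")

    r, chi = pixel_grids(geometry)
    fm = float(phantom.muscle_fraction(x))
    sigma_chi = None if isotropic else float(phantom.orientation_spread(x, eng_strain))
    rot_frac = float(phantom.rotated_fraction(x))
    d_period_a = phantom.d_period(x, eng_strain) * 10.0   # nm -> A
    d11_a = phantom.d11(x, eng_strain) * 10.0
    d10_a = d11_a * math.sqrt(3.0)                        # hexagonal lattice

    image = np.zeros(geometry.image_shape, dtype=float)
    scale = counts_scale
    if peak_snr is not None:
        scale *= _snr_scale(geometry, d_period_a / 5.0, counts_scale * (1 - fm),
                            sigma_chi, fiber_axis_deg, sigma_r, background, peak_snr)

    coll_total = scale * (1.0 - fm)
    for n, w in COLLAGEN_ORDER_WEIGHTS.items():
        counts = coll_total * w
        d_n = d_period_a / n
        for frac, axis in ((1.0 - rot_frac, fiber_axis_deg),
                           (rot_frac, fiber_axis_deg + 90.0)):
            if frac <= 0:
                continue
            # the rotated (90-deg) collagen population shares the equator with
            # the muscle reflections; orders radially colliding with them are
            # omitted to keep reflections separated (no deconvolution in scope)
            if axis != fiber_axis_deg and (
                    abs(d_n - d11_a) < 0.08 * d11_a or abs(d_n - d10_a) < 0.08 * d10_a):
                logger.info("rotated collagen order %d overlaps a muscle "
                            "reflection radially; omitted", n)
                continue
            _add_arc(image, r, chi, d_n, counts * frac, sigma_chi,
                     axis, sigma_r, geometry, f"collagen n={n}")
    if fm > 0:
        equator = fiber_axis_deg + 90.0
        _add_arc(image, r, chi, d11_a, scale * fm, sigma_chi, equator,
                 sigma_r, geometry, "muscle (1,1)")
        _add_arc(image, r, chi, d10_a, scale * fm * MUSCLE_10_WEIGHT, sigma_chi,
                 equator, sigma_r, geometry, "muscle (1,0)")

    amp, r_scale, expo = background
    image += amp * (1.0 + r / r_scale) ** (-expo)

    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        image = rng.poisson(image).astype(float)

    return DiffractionFrame(image=image, geometry=geometry, position_mm=float(x),
                            eng_strain=float(eng_strain), scan_index=scan_index,
                            load_g=load_g)


def _snr_scale(geometry, d5_a, counts5, sigma_chi, axis_deg, sigma_r,
               background, target_snr) -> float:
    """Scale factor on arc counts giving the 5th-order peak pixel the target SNR."""
    r5 = radius_of_q(geometry, q_of_d(d5_a))
    az_peak = _azimuthal_density(np.array([axis_deg]), axis_deg, sigma_chi)[0]
    s1 = counts5 * az_peak * (180.0 / math.pi) / r5 / (math.sqrt(2 * math.pi) * sigma_r)
    if s1 <= 0:
        raise PhantomError("cannot set SNR: 5th-order arc has no intensity")
    amp, r_scale, expo = background
    b = amp * (1.0 + r5 / r_scale) ** (-expo)
    # solve k*s1 / sqrt(k*s1 + b) = target
    t2 = target_snr ** 2
    s_needed = 0.5 * t2 * (1.0 + math.sqrt(1.0 + 4.0 * b / t2))
    return s_needed / s1


# ---------------------------------------------------------------------------
# video
# ---------------------------------------------------------------------------

def render_video_frames(
    phantom: TissuePhantom,
    trace: LoadTrace,
    fps: float = 5.0,
    blob_sigma: float = 2.0,
    scale_px_per_mm: float = 12.0,
    frame_shape: tuple[int, int] | None = None,
    lateral_offset_px: float = 0.0,
    background_level: float = 230.0,
    blob_depth: float = 170.0,
    noise_sigma: float = 0.0,
    noise_seed: int | None = None,
) -> VideoStack:
    """Render the marker video of a pull at ``fps`` frames per second.

    The strip hangs vertically with the LL-end grip fixed at the bottom of
    the field of view; markers are dark Gaussian blobs advected by the
    per-region strain ground truth of ``trace``.  Markers sit on the strip
    midline by default (``lateral_offset_px`` alternates them sideways for
    clutter experiments, at the cost of a cosine error in pair distances).
    Returns the frames along with the true marker trajectories (testing
    oracle).
    """
    if fps <= 0:
        raise PhantomError("fps must be positive")
    if noise_sigma > 0 and noise_seed is None:
        raise PhantomError("noisy renders require a seed")
    times = np.arange(0.0, trace.time[-1] + 0.5 / fps, 1.0 / fps)
    times = times[times <= trace.time[-1]]

    markers = phantom.marker_positions()
    names = [r.name for r in phantom.regions]
    # absolute stretch per region at frame times (truth is frame0-referenced,
    # which only rescales lengths by a common per-region constant)
    strains_t = {n: np.interp(times, trace.time, trace.per_region_strain_truth[n])
                 for n in names}

    max_len = phantom.total_length + float(trace.displacement[-1]) + 1.0
    margin = 24
    if frame_shape is None:
        rows = int(math.ceil(max_len * scale_px_per_mm)) + 2 * margin
        frame_shape = (rows, 128)
    rows, cols = frame_shape
    col_center = cols / 2.0

    n_f, n_m = len(times), len(markers)
    true_pos = np.empty((n_f, n_m, 2))
    lateral = col_center + lateral_offset_px * np.where(np.arange(n_m) % 2 == 0, -1.0, 1.0)
    for i in range(n_f):
        strains = {n: float(strains_t[n][i]) for n in names}
        lab = np.atleast_1d(phantom.material_to_lab(markers, strains))
        row = rows - margin - lab * scale_px_per_mm
        true_pos[i, :, 0] = lateral
        true_pos[i, :, 1] = row
        if np.any(row < 2 * blob_sigma) or np.any(row > rows - 2 * blob_sigma):
            raise PhantomError(f"marker leaves the field of view at frame {i}")

    rng = np.random.default_rng(noise_seed) if noise_seed is not None else None
    frames = np.empty((n_f, rows, cols), dtype=np.float32)
    yy = np.arange(rows, dtype=float)
    xx = np.arange(cols, dtype=float)
    half = int(math.ceil(4 * blob_sigma))
    for i in range(n_f):
        img = np.full((rows, cols), background_level, dtype=float)
        for m in range(n_m):
            cx, cy = true_pos[i, m]
            r0, r1 = max(0, int(cy) - half), min(rows, int(cy) + half + 1)
            c0, c1 = max(0, int(cx) - half), min(cols, int(cx) + half + 1)
            gy = np.exp(-0.5 * ((yy[r0:r1] - cy) / blob_sigma) ** 2)
            gx = np.exp(-0.5 * ((xx[c0:c1] - cx) / blob_sigma) ** 2)
            img[r0:r1, c0:c1] -= blob_depth * gy[:, None] * gx[None, :]
        if rng is not None and noise_sigma > 0:
            img += rng.normal(0.0, noise_sigma, img.shape)
        frames[i] = np.clip(img, 0.0, 255.0)

    return VideoStack(frames=frames, times=times, frame_rate=fps,
                      scale_px_per_mm=scale_px_per_mm, true_positions=true_pos,
                      marker_pairs=phantom.marker_pairs())
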