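"""Video-extensometry mechanics: marker tracking, regional stress-strain and
failure features.

Fiducial markers (dark blobs) are detected per frame by a single-scale
Laplacian-of-Gaussian filter with intensity-centroid refinement, linked
frame-to-frame by gated nearest-neighbour assignment, and converted to
regional engineering strain with the first frame as the resting reference.
Stress is the shared load divided by the regional cross-sectional area.

Failure detection: because the chain shares one load cell, every regional
stress trace drops proportionally when the sample tears.  A region is
therefore flagged as *failed* only when its stress falls at least
``drop_frac`` below its running maximum for ``m`` consecutive samples while
its strain exceeds the strain at that maximum — material softening at
increasing strain.  Intact regions recoil elastically (strain decreasing)
and keep ``failure_detected = False`` with the observed maximum as their
ultimate stress.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_laplace
from skimage.feature import peak_local_max

from .phantom import G0, LoadTrace

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerTrack",
    "StressStrainCurve",
    "MechanicalFeatures",
    "MechanicsError",
    "NoFailureError",
    "detect_markers",
    "track_markers",
    "regional_strain",
    "stress_series",
    "extract_features",
    "failure_locus",
]


class MechanicsError(ValueError):
    pass


class NoFailureError(MechanicsError):
    """No region shows a failure event."""


@dataclass
class MarkerTrack:
    positions: np.ndarray          # (n_frames, n_markers, 2) as (col, row); NaN = lost
    frame_rate: float
    lost: dict[int, int] = field(default_factory=dict)   # marker -> first lost frame

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]


@dataclass
class StressStrainCurve:
    region: str
    strain: np.ndarray             # %, starts at 0 (frame 0 reference)
    stress: np.ndarray             # MPa
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.strain) != len(self.stress):
            raise MechanicsError("strain and stress lengths differ")
        first = self.strain[np.isfinite(self.strain)]
        if len(first) and abs(first[0]) > 1e-9:
            raise MechanicsError("strain must start at 0 (first frame is the reference)")


@dataclass
class MechanicalFeatures:
    region: str
    toe_modulus: float             # MPa (per unit strain fraction)
    linear_modulus: float          # MPa
    ultimate_stress: float         # MPa
    strain_at_ultimate: float      # %
    failure_detected: bool
    failure_index: int | None = None
    toe_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.toe_modulus < -1e-9 or self.linear_modulus < -1e-9:
            raise MechanicsError("moduli must be non-negative")


# ---------------------------------------------------------------------------
# detection and tracking
# ---------------------------------------------------------------------------

def detect_markers(
    image: np.ndarray,
    blob_sigma: float = 2.0,
    threshold_rel: float = 0.3,
    merge_warn_factor: float = 1.15,
) -> np.ndarray:
    """Sub-pixel centers of dark blobs, as an (n, 2) array of (col, row).

    Detection inverts the image, applies a Laplacian-of-Gaussian at the blob
    scale and takes local maxima; centers are refined by intensity centroid
    over a window after local background removal.  A detection whose second
    moment is much larger than ``blob_sigma`` triggers a merged-detection
    warning (two blobs closer than ~2 sigma are not resolvable).
    """
    img = np.asarray(image, dtype=float)
    if float(np.ptp(img)) <= 1e-12:
        return np.empty((0, 2))
    inv = img.max() - img
    resp = -gaussian_laplace(inv, sigma=blob_sigma)
    peaks = peak_local_max(resp, min_distance=max(1, int(round(2 * blob_sigma))),
                           threshold_abs=threshold_rel * float(resp.max()))
    half = int(np.ceil(2.5 * blob_sigma))
    out = []
    rows, cols = img.shape
    for pr, pc in peaks:
        r0, r1 = max(0, pr - half), min(rows, pr + half + 1)
        c0, c1 = max(0, pc - half), min(cols, pc + half + 1)
        patch = inv[r0:r1, c0:c1].copy()
        border = np.concatenate([patch[0], patch[-1], patch[:, 0], patch[:, -1]])
        patch = np.clip(patch - np.median(border), 0.0, None)
        total = patch.sum()
        if total <= 0:
            continue
        ys = np.arange(r0, r1, dtype=float)
        xs = np.arange(c0, c1, dtype=float)
        cy = float((patch.sum(axis=1) * ys).sum() / total)
        cx = float((patch.sum(axis=0) * xs).sum() / total)
        # second-moment ellipticity check for merged blobs
        dy, dx = ys - cy, xs - cx
        vyy = float((patch * dy[:, None] ** 2).sum() / total)
        vxx = float((patch * dx[None, :] ** 2).sum() / total)
        vxy = float((patch * dy[:, None] * dx[None, :]).sum() / total)
        major = np.sqrt(max(np.linalg.eigvalsh([[vyy, vxy], [vxy, vxx]])[-1], 0.0))
        if major > merge_warn_factor * blob_sigma:
            warnings.warn(f"possible merged detection near (col={cx:.1f}, row={cy:.1f}): "
                          f"major-axis width {major:.2f} px vs blob sigma {blob_sigma}",
                          stacklevel=2)
        out.append((cx, cy))
    return np.asarray(out) if out else np.empty((0, 2))


def track_markers(
    frames: np.ndarray,
    blob_sigma: float = 2.0,
    max_displacement: float = 10.0,
    frame_rate: float = 5.0,
    expected_count: int | None = None,
    threshold_rel: float = 0.3,
) -> MarkerTrack:
    """Link per-frame detections into identity-stable trajectories.

    Frame-0 detections define the marker identities (sorted by row then
    column).  Each subsequent frame assigns every live track its nearest
    detection within ``max_displacement`` px; contested detections go to the
    closer track (ties logged), and a track with no candidate is terminated
    and flagged, never silently interpolated.
    """
    det0 = detect_markers(frames[0], blob_sigma, threshold_rel=threshold_rel)
    if expected_count is not None and len(det0) < expected_count:
        warnings.warn(f"expected {expected_count} markers, found {len(det0)} "
                      "in the first frame", stacklevel=2)
    order = np.lexsort((det0[:, 0], det0[:, 1])) if len(det0) else []
    det0 = det0[order]
    n_m = len(det0)
    n_f = len(frames)
    pos = np.full((n_f, n_m, 2), np.nan)
    if n_m:
        pos[0] = det0
    lost: dict[int, int] = {}

    for f in range(1, n_f):
        dets = detect_markers(frames[f], blob_sigma, threshold_rel=threshold_rel)
        assigned: dict[int, tuple[int, float]] = {}   # detection -> (track, dist)
        for t in range(n_m):
            if t in lost:
                continue
            last = pos[f - 1, t]
            if not np.all(np.isfinite(last)):
                lost.setdefault(t, f)
                continue
            if len(dets) == 0:
                lost.setdefault(t, f)
                continue
            d = np.hypot(dets[:, 0] - last[0], dets[:, 1] - last[1])
            inside = np.nonzero(d <= max_displacement)[0]
            if len(inside) == 0:
                lost.setdefault(t, f)
                logger.info("track %d terminated at frame %d (no candidate in gate)", t, f)
                continue
            if len(inside) > 1:
                logger.info("ambiguous link for track %d at frame %d: %d candidates; "
                            "taking the smaller displacement", t, f, len(inside))
            j = int(inside[np.argmin(d[inside])])
            if j in assigned and assigned[j][1] <= d[j]:
                lost.setdefault(t, f)
                continue
            if j in assigned:
                lost.setdefault(assigned[j][0], f)
                pos[f, assigned[j][0]] = np.nan
            assigned[j] = (t, float(d[j]))
            pos[f, t] = dets[j]
    return MarkerTrack(positions=pos, frame_rate=frame_rate, lost=lost)


# ---------------------------------------------------------------------------
# strain, stress, features
# ---------------------------------------------------------------------------

def regional_strain(
    track: MarkerTrack,
    pairs: dict[str, tuple[int, int]],
) -> dict[str, np.ndarray]:
    """Engineering strain (%) per region from flanking marker pairs.

    ``eps(t) = 100 * (|p_a - p_b| - L0) / L0`` with L0 from frame 0; frames
    where either marker is missing yield NaN for that region.
    """
    out = {}
    for region, (ia, ib) in pairs.items():
        if max(ia, ib) >= track.n_markers:
            raise MechanicsError(f"pair {ia, ib} outside the {track.n_markers}-marker track")
        pa, pb = track.positions[:, ia], track.positions[:, ib]
        dist = np.hypot(pa[:, 0] - pb[:, 0], pa[:, 1] - pb[:, 1])
        l0 = dist[0]
        if not np.isfinite(l0) or l0 <= 0:
            raise MechanicsError(f"region {region}: invalid reference length")
        out[region] = 100.0 * (dist - l0) / l0
    return out


def stress_series(
    trace: LoadTrace,
    area: float,
    times: np.ndarray | None = None,
) -> np.ndarray:
    """Stress (MPa) from the load trace: ``sigma = load_g * g0 * 1e-3 / area``.

    With ``times`` given, the load is linearly resampled at those instants
    (video frame times).
    """
    if area <= 0:
        raise MechanicsError("cross-sectional area must be positive")
    load = trace.load_g if times is None else np.interp(times, trace.time, trace.load_g)
    return load * G0 * 1e-3 / area


def extract_features(
    curve: StressStrainCurve,
    drop_frac: float = 0.10,
    m: int = 3,
    toe_window_frac: float = 0.10,
    linear_window_frac: float = 0.15,
    low_slope_frac: float = 0.3,
) -> MechanicalFeatures:
    """Toe/linear moduli, ultimate stress and failure state of one curve.

    The failure frame is the first index where the stress stays below
    ``(1 - drop_frac)`` of its running maximum for ``m`` consecutive samples
    *at strains beyond the strain of that maximum* (see module docstring);
    the ultimate stress is the running maximum there.  Without such an event
    the ultimate stress is the global maximum and ``failure_detected`` is
    False.  Moduli are least-squares slopes (MPa per unit strain): the toe
    modulus over the initial window, the linear modulus over the steepest
    sustained window before failure.  Multiple toe intervals (low-slope
    plateaus before the linear region) are reported when present.
    """
    ok = np.isfinite(curve.strain) & np.isfinite(curve.stress)
    strain = curve.strain[ok] / 100.0      # fraction
    stress = curve.stress[ok]
    n = len(stress)
    if n < 10:
        raise MechanicsError(f"curve has {n} valid samples; need >= 10")

    runmax = np.maximum.accumulate(stress)
    argmax = np.zeros(n, dtype=int)
    best = 0
    for i in range(n):
        if stress[i] >= stress[best]:
            best = i
        argmax[i] = best

    failure_index = None
    below = (stress < (1.0 - drop_frac) * runmax) & (strain > strain[argmax])
    run = 0
    for i in range(n):
        run = run + 1 if below[i] else 0
        if run >= m:
            failure_index = i - m + 1
            break
    failure_detected = failure_index is not None

    if failure_detected:
        ult_idx = argmax[failure_index]
    else:
        ult_idx = int(np.argmax(stress))
    ultimate = float(stress[ult_idx])
    strain_at_ult = float(strain[ult_idx] * 100.0)

    pre_end = failure_index if failure_detected else n
    pre_s, pre_sig = strain[:pre_end], stress[:pre_end]

    def window_slope(a, b):
        if b - a < 2 or np.ptp(pre_s[a:b]) <= 0:
            return 0.0
        return float(np.polyfit(pre_s[a:b], pre_sig[a:b], 1)[0])

    toe_n = max(5, int(round(toe_window_frac * len(pre_s))))
    toe_modulus = max(window_slope(0, min(toe_n, len(pre_s))), 0.0)

    win = max(5, int(round(linear_window_frac * len(pre_s))))
    slopes = [window_slope(a, a + win) for a in range(0, max(1, len(pre_s) - win + 1))]
    lin_at = int(np.argmax(slopes)) if slopes else 0
    linear_modulus = max(slopes[lin_at] if slopes else 0.0, 0.0)

    # low-slope plateaus before the steepest window ("multiple toe regions")
    toe_intervals: list[tuple[int, int]] = []
    if len(pre_s) > 2 * win and linear_modulus > 0:
        ds = np.gradient(pre_s)
        dsig = np.gradient(pre_sig)
        with np.errstate(divide="ignore", invalid="ignore"):
            local = np.where(np.abs(ds) > 1e-12, dsig / ds, np.inf)
        low = local[:lin_at] < low_slope_frac * linear_modulus
        start = None
        for i, flag in enumerate(low):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                if i - start >= max(3, win // 3):
                    toe_intervals.append((start, i))
                start = None
        if start is not None and len(low) - start >= max(3, win // 3):
            toe_intervals.append((start, len(low)))

    return MechanicalFeatures(
        region=curve.region, toe_modulus=toe_modulus, linear_modulus=linear_modulus,
        ultimate_stress=ultimate, strain_at_ultimate=strain_at_ult,
        failure_detected=failure_detected, failure_index=failure_index,
        toe_intervals=toe_intervals,
    )


def failure_locus(features: dict[str, MechanicalFeatures]) -> str:
    """Region where failure localized: earliest failure frame, ties broken
    by the lower ultimate stress."""
    failed = {k: f for k, f in features.items() if f.failure_detected}
    if not failed:
        raise NoFailureError("no region failed during the pull")
    return min(failed, key=lambda k: (failed[k].failure_index, failed[k].ultimate_stress))
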