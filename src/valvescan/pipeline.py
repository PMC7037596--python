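"""End-to-end drivers tying the stages together.

These functions operate only on the observable data products (detector
frames, load traces, video frames, per-region areas); generator ground
truth is never consulted, so the same drivers run on rendered phantoms and
on real scans.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from . import maps as maps_mod
from .geometry import DetectorGeometry
from .mechanics import (
    MechanicalFeatures,
    StressStrainCurve,
    extract_features,
    failure_locus,
    regional_strain,
    stress_series,
    track_markers,
)
from .peaks import ReflectionAbsent, arc_counts, collagen_d_period, muscle_d11, orientation
from .phantom import LoadTrace, TissuePhantom, simulate_pull
from .reduction import azimuthal_profile, sector_profile, subtract_background
from .render import DiffractionFrame, render_diffraction, render_video_frames

logger = logging.getLogger(__name__)

__all__ = [
    "reduce_and_fit",
    "scan_phantom",
    "analyze_scan",
    "run_mechanics",
]

FIT_TABLE_COLUMNS = ["scan_index", "position_mm", "eng_strain", "D_nm", "d11_nm",
                     "I5_area", "I11_area", "angle_deg", "spread_deg", "isotropic"]


def reduce_and_fit(
    frame: DiffractionFrame,
    d0_guess_nm: float = 67.0,
    d11_guess_nm: float = 21.5,
    half_angle: float = 15.0,
    beamstop_radius: float = 6.0,
    background_window: int = 31,
    with_orientation: bool = True,
    fit_muscle: bool = True,
) -> dict:
    """Reduce one frame and fit the named reflections; returns a fit-table row.

    The collagen 5th order is fitted on the meridional sector, the muscle
    (1,1) on the equatorial sector; integrated arc intensities are corrected
    for the wedge's azimuthal capture using the fitted angular spread, so
    ``I5_area`` and ``I11_area`` are comparable photon counts.  An absent
    muscle reflection (pure chordae) enters as ``d11_nm = NaN, I11_area = 0``.
    """
    mer = subtract_background(
        sector_profile(frame, "meridional", half_angle, beamstop_radius=beamstop_radius),
        window=background_window)

    row = {"scan_index": frame.scan_index, "position_mm": frame.position_mm,
           "eng_strain": 100.0 * frame.eng_strain,
           "D_nm": np.nan, "d11_nm": np.nan, "I5_area": 0.0, "I11_area": 0.0,
           "angle_deg": np.nan, "spread_deg": np.nan, "isotropic": True}

    spread5 = spread11 = None
    ori = None
    d_nm = None
    try:
        d_nm, fit5 = collagen_d_period(mer, d0_guess_nm)
    except ReflectionAbsent:
        fit5 = None
        logger.info("no collagen 5th order at x=%.2f mm", frame.position_mm)

    if with_orientation and fit5 is not None:
        band = (fit5.center_q - 4 * fit5.sigma_q, fit5.center_q + 4 * fit5.sigma_q)
        ori = orientation(azimuthal_profile(frame, band))
        row["angle_deg"] = ori.angle
        row["spread_deg"] = ori.spread
        row["isotropic"] = bool(ori.isotropic)
        if not ori.isotropic:
            spread5 = ori.spread

    if fit5 is not None:
        row["D_nm"] = d_nm
        row["I5_area"] = arc_counts(fit5, mer, spread_deg=spread5)

    if fit_muscle:
        eq = subtract_background(
            sector_profile(frame, "equatorial", half_angle, beamstop_radius=beamstop_radius),
            window=background_window)
        try:
            d11, fit11 = muscle_d11(eq, d11_guess_nm)
            if with_orientation:
                band = (fit11.center_q - 4 * fit11.sigma_q,
                        fit11.center_q + 4 * fit11.sigma_q)
                ori11 = orientation(azimuthal_profile(frame, band))
                if not ori11.isotropic:
                    spread11 = ori11.spread
            row["d11_nm"] = d11
            row["I11_area"] = arc_counts(fit11, eq, spread_deg=spread11)
        except ReflectionAbsent:
            logger.info("no muscle (1,1) at x=%.2f mm (pure collagen)", frame.position_mm)
    return row


def scan_phantom(
    phantom: TissuePhantom,
    geometry: DetectorGeometry | None = None,
    levels_pct: tuple[float, ...] = (0, 2, 4, 6, 8, 10),
    n_points: int = 10,
    noise_seed: int | None = None,
    peak_snr: float | None = None,
    with_orientation: bool = True,
    fit_muscle: bool = True,
    **render_kw,
) -> pd.DataFrame:
    """Render and analyse a full scan: ``n_points`` positions x strain levels.

    Returns the per-frame fit table (see ``FIT_TABLE_COLUMNS``).  With a
    ``noise_seed``, every frame gets an independent Poisson draw derived
    from it.
    """
    geometry = geometry or DetectorGeometry()
    positions = phantom.scan_positions(n_points)
    rows = []
    for j, level in enumerate(levels_pct):
        for i, x in enumerate(positions):
            seed = None if noise_seed is None else int(noise_seed + 1009 * j + i) % (2**31)
            frame = render_diffraction(phantom, x, level / 100.0, geometry,
                                       noise_seed=seed, peak_snr=peak_snr,
                                       scan_index=i, **render_kw)
            rows.append(reduce_and_fit(frame, d0_guess_nm=phantom.d_period_nm,
                                       d11_guess_nm=phantom.d11_nm,
                                       with_orientation=with_orientation,
                                       fit_muscle=fit_muscle))
    return pd.DataFrame(rows, columns=FIT_TABLE_COLUMNS)


def analyze_scan(
    fit_table: pd.DataFrame,
    thickness: tuple[np.ndarray, np.ndarray],
    w: float = 1.0,
    spt_level: float = 10.0,
) -> dict:
    """Composition profile, molecular-strain map, strain-per-thickness and
    transition calls from a fit table."""
    rest = fit_table["eng_strain"].min()
    comp = maps_mod.composition_profile(fit_table[fit_table["eng_strain"] == rest], w=w)
    smap = maps_mod.molecular_strain_map(fit_table)
    pos, spt, failure_pos = maps_mod.strain_per_thickness(smap, thickness, level=spt_level)
    ori_tab = fit_table[fit_table["eng_strain"] == rest]
    calls = maps_mod.call_transitions(comp, orientation_table=ori_tab)
    return {"composition": comp, "strain_map": smap,
            "strain_per_thickness": (pos, spt), "predicted_failure_mm": failure_pos,
            "transitions": calls}


def run_mechanics(
    phantom: TissuePhantom,
    rate: float = 0.04,
    fps: float = 5.0,
    seed: int | None = None,
    noise_sigma: float = 0.0,
    blob_sigma: float = 2.0,
    trace: LoadTrace | None = None,
) -> dict:
    """Simulate a pull and run the full video-extensometry analysis.

    Renders the marker video from the load trace, tracks the markers,
    derives regional stress-strain curves (regional areas taken from the
    phantom, standing in for the measured cross sections) and extracts the
    mechanical features and the failure locus.
    """
    if trace is None:
        trace = simulate_pull(phantom, rate=rate)
    video = render_video_frames(phantom, trace, fps=fps, blob_sigma=blob_sigma,
                                noise_sigma=noise_sigma, noise_seed=seed)
    gate = _tracking_gate(phantom, trace, video)
    track = track_markers(video.frames, blob_sigma=blob_sigma, frame_rate=fps,
                          max_displacement=gate,
                          expected_count=2 * len(phantom.regions))
    strains = regional_strain(track, video.marker_pairs)
    curves, features = {}, {}
    for r in phantom.regions:
        sigma = stress_series(trace, r.area, times=video.times)
        curve = StressStrainCurve(region=r.name, strain=strains[r.name], stress=sigma,
                                  provenance={"area_mm2": r.area})
        curves[r.name] = curve
        features[r.name] = extract_features(curve)
    try:
        locus = failure_locus(features)
    except Exception:
        locus = None
    return {"trace": trace, "video": video, "track": track, "curves": curves,
            "features": features, "failure_locus": locus}


def _tracking_gate(phantom, trace, video) -> float:
    """Per-frame displacement gate covering the fastest expected marker motion."""
    # worst case: full elastic recovery redistributed over the tear time
    recovery_mm = float(trace.displacement[-1])
    tear_frames = max(1.0, 2.0 * video.frame_rate)
    per_frame = recovery_mm * video.scale_px_per_mm / tear_frames
    return float(max(10.0, math.ceil(1.8 * per_frame)))
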