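"""Assemble per-frame fit results into composition, strain-map and
transition products.

The relative composition at each scan position is
``pct_muscle = 100 * I11 / (I11 + w * I5)`` from the integrated muscle (1,1)
and collagen 5th-order arc intensities, with a configurable calibration
weight ``w`` (default 1).  Molecular strain is the percent change of the
collagen D-period relative to the resting (minimum-load) level, tracked per
scan point across engineering-strain levels; dividing the 10%-level values
by the local thickness gives the strain-per-unit-thickness profile whose
argmax is the predicted failure locus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CompositionProfile",
    "MolecularStrainMap",
    "TransitionCall",
    "MapError",
    "composition_profile",
    "molecular_strain_map",
    "strain_per_thickness",
    "call_transitions",
]


class MapError(ValueError):
    pass


@dataclass
class CompositionProfile:
    position: np.ndarray            # mm (resting-state coordinates)
    pct_muscle: np.ndarray          # % (NaN where undefined)
    pct_collagen: np.ndarray
    calibration_weight: float = 1.0
    masked: np.ndarray = None       # True where both intensities were zero

    def __post_init__(self) -> None:
        ok = np.isfinite(self.pct_muscle)
        if np.any(np.abs(self.pct_muscle[ok] + self.pct_collagen[ok] - 100.0) > 1e-9):
            raise MapError("composition does not close to 100%")


@dataclass
class MolecularStrainMap:
    positions: np.ndarray           # mm, resting position of each tracked point
    eng_strain_levels: np.ndarray   # %
    strain: np.ndarray              # % matrix (n_positions, n_levels)

    def __post_init__(self) -> None:
        i0 = int(np.argmin(self.eng_strain_levels))
        col0 = self.strain[:, i0]
        if np.any(np.abs(col0[np.isfinite(col0)]) > 1e-9):
            raise MapError("strain at the resting level must be zero by definition")


@dataclass
class TransitionCall:
    interval: tuple[float, float]   # mm
    kind: str                       # "PM-CT" or "CT-LL"

    def __post_init__(self) -> None:
        if self.interval[0] >= self.interval[1]:
            raise MapError("transition interval must have start < end")


def composition_profile(fit_table: pd.DataFrame, w: float = 1.0) -> CompositionProfile:
    """Relative %muscle / %collagen along the scan from a per-frame fit table.

    Expects columns ``position_mm``, ``I5_area``, ``I11_area`` (one row per
    position at the composition level, conventionally the resting scan).  An
    absent reflection enters as zero intensity; a position where both are
    zero is undefined and masked.
    """
    if w <= 0:
        raise MapError("calibration weight must be positive")
    tab = fit_table.sort_values("position_mm")
    pos = tab["position_mm"].to_numpy(dtype=float)
    i5 = np.nan_to_num(tab["I5_area"].to_numpy(dtype=float), nan=0.0)
    i11 = np.nan_to_num(tab["I11_area"].to_numpy(dtype=float), nan=0.0)
    total = i11 + w * i5
    masked = total <= 0
    pct_m = np.full(len(pos), np.nan)
    pct_m[~masked] = 100.0 * i11[~masked] / total[~masked]
    return CompositionProfile(position=pos, pct_muscle=pct_m,
                              pct_collagen=100.0 - pct_m,
                              calibration_weight=w, masked=masked)


def molecular_strain_map(fit_table: pd.DataFrame) -> MolecularStrainMap:
    """Molecular strain (%) per tracked point and engineering-strain level.

    Expects columns ``scan_index`` (tracked-point identity), ``position_mm``
    (resting position), ``eng_strain`` (%, level) and ``D_nm``; the level
    with the smallest strain is the resting reference, which must carry a
    valid D for every tracked point.
    """
    levels = np.sort(fit_table["eng_strain"].unique())
    pivot = fit_table.pivot_table(index="scan_index", columns="eng_strain",
                                  values="D_nm", aggfunc="first")
    pivot = pivot.reindex(columns=levels)
    rest = levels[0]
    d0 = pivot[rest]
    if d0.isna().any():
        bad = pivot.index[d0.isna()].tolist()
        raise MapError(f"missing resting-level D-period for tracked points {bad}")
    strain = 100.0 * (pivot.to_numpy() - d0.to_numpy()[:, None]) / d0.to_numpy()[:, None]
    pos = (fit_table[fit_table["eng_strain"] == rest]
           .set_index("scan_index")["position_mm"]
           .reindex(pivot.index).to_numpy(dtype=float))
    return MolecularStrainMap(positions=pos, eng_strain_levels=np.asarray(levels, float),
                              strain=strain)


def strain_per_thickness(
    strain_map: MolecularStrainMap,
    thickness: tuple[np.ndarray, np.ndarray],
    level: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Molecular strain per unit thickness, %/mm, at one strain level.

    ``thickness`` is ``(positions_mm, thickness_mm)``; values at tracked
    positions are interpolated linearly.  Returns ``(positions, s, argmax
    position)``; the argmax is the predicted failure locus.
    """
    levels = strain_map.eng_strain_levels
    try:
        j = int(np.nonzero(np.isclose(levels, level))[0][0])
    except IndexError:
        raise MapError(f"strain level {level}% not in map (levels: {levels})") from None
    tx, tv = np.asarray(thickness[0], float), np.asarray(thickness[1], float)
    if np.any(tv <= 0):
        raise MapError("thickness must be positive")
    t_at = np.interp(strain_map.positions, tx, tv)
    s = strain_map.strain[:, j] / t_at
    ok = np.isfinite(s)
    if not ok.any():
        raise MapError("no valid strain values at the requested level")
    argmax_pos = float(strain_map.positions[ok][np.argmax(s[ok])])
    return strain_map.positions, s, argmax_pos


def call_transitions(
    profile: CompositionProfile,
    lo: float = 5.0,
    hi: float = 80.0,
    orientation_table: pd.DataFrame | None = None,
    fiber_axis_deg: float = 90.0,
    rotation_threshold_deg: float = 45.0,
) -> list[TransitionCall]:
    """Locate the diffuse transitions along the strip.

    PM-CT is the maximal interval over which the muscle percentage crosses
    from >= ``hi`` down to <= ``lo`` scanning from the PM end; crossing
    positions are interpolated linearly.  A CT-LL call additionally requires
    the orientation signature (a collagen population rotated ~90 deg off the
    strip axis near the junction) and is only attempted when orientation
    data are provided.
    """
    calls: list[TransitionCall] = []
    ok = np.isfinite(profile.pct_muscle)
    pos, pct = profile.position[ok], profile.pct_muscle[ok]
    order = np.argsort(pos)
    pos, pct = pos[order], pct[order]

    above = np.nonzero(pct >= hi)[0]
    if len(above) == 0:
        warnings.warn("no position reaches the high composition threshold; "
                      "PM-CT transition not called", stacklevel=2)
    else:
        i_hi = above[-1]
        below = np.nonzero((np.arange(len(pct)) > i_hi) & (pct <= lo))[0]
        if len(below) == 0:
            warnings.warn("composition never falls below the low threshold; "
                          "PM-CT transition not called", stacklevel=2)
        else:
            i_lo = below[0]
            start = _crossing(pos, pct, i_hi, hi)
            end = _crossing(pos, pct, i_lo - 1, lo)
            if end <= start:   # step profile: degenerate interval at the step
                eps = 1e-9
                start, end = start - eps, start + eps
            calls.append(TransitionCall(interval=(start, end), kind="PM-CT"))

    if orientation_table is not None and len(orientation_table):
        tab = orientation_table.sort_values("position_mm")
        ang = tab["angle_deg"].to_numpy(dtype=float)
        p = tab["position_mm"].to_numpy(dtype=float)
        iso = tab["isotropic"].to_numpy(dtype=bool) if "isotropic" in tab else \
            np.zeros(len(p), bool)
        dev = np.abs((ang - fiber_axis_deg + 90.0) % 180.0 - 90.0)
        rotated = (dev > rotation_threshold_deg) & ~iso & np.isfinite(ang)
        if rotated.any():
            lo_p, hi_p = float(p[rotated].min()), float(p[rotated].max())
            if hi_p <= lo_p:
                lo_p, hi_p = lo_p - 1e-9, lo_p + 1e-9
            calls.append(TransitionCall(interval=(lo_p, hi_p), kind="CT-LL"))
    return calls


def _crossing(pos, pct, i, level) -> float:
    """Linear interpolation of the position where pct crosses ``level``
    between samples i and i+1 (descending profile)."""
    if i + 1 >= len(pos) or pct[i] == pct[i + 1]:
        return float(pos[i])
    frac = (pct[i] - level) / (pct[i] - pct[i + 1])
    frac = min(max(frac, 0.0), 1.0)
    return float(pos[i] + frac * (pos[i + 1] - pos[i]))
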