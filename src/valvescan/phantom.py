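"""Synthetic valve-strip phantom: ground truth and forward mechanical model.

A phantom describes a papillary-muscle (PM) -> chordae-tendinae (CT) ->
leaflet (LL) strip as an ordered chain of regions, including the two diffuse
transition regions (PM-CT, CT-LL).  Each region carries a cross-sectional
area, a thickness, a relative muscle fraction, a fiber-orientation spread and
a nonlinear constitutive law.  The phantom also defines the molecular-scale
ground truth: a resting collagen D-period, a resting muscle (1,1) d-spacing
and a strain-coupling profile ``c(x)`` so that the local collagen molecular
strain under an overall engineering strain ``eps`` is ``c(x) * eps``, with
``c(x)`` peaking over the PM-CT transition.

The constitutive law per region is a toe-then-linear-then-failure curve,

    sigma(eps) = (E_t/k) * (exp(k*eps) - 1)          for eps < eps_toe
    sigma(eps) = sigma_toe + E * (eps - eps_toe)     up to sigma_ult

with ``eps_toe = ln(E/E_t)/k`` so the tangent modulus is continuous.  Past
the ultimate stress the region tears: the force relaxes to a residual
fraction of the peak over a short tear-propagation time.

Regions act mechanically in series: a single tensile force F satisfies
``sigma_i(eps_i) * A_i = F`` in every region while the regional elongations
sum to the imposed grip displacement.  Because the force is shared, the
per-region ultimate stresses measured from a single pull obey
``sigma_ult_i = F_tear / A_i``; preset areas are chosen strength-consistent
(``A_i = F0 / sigma_ult_i``) with a small cross-section deficit at the
designated weak region (default PM-CT) so that failure initiates there, as
observed for real valve strips.
"""

from __future__ import annotations

import copy
import importlib.resources
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

#: standard gravity used to convert grams-force to newtons
G0 = 9.80665
#: load-cell capacity in grams
SENSOR_MAX_G = 455.0
#: approximate pre-tension of the resting state, grams
RESTING_LOAD_G = 0.1

__all__ = [
    "Constitutive",
    "Region",
    "TissuePhantom",
    "LoadTrace",
    "SeriesState",
    "make_phantom",
    "available_presets",
    "solve_series_pull",
    "simulate_pull",
    "G0",
    "SENSOR_MAX_G",
    "RESTING_LOAD_G",
]


class PhantomError(ValueError):
    """Invalid phantom specification or request."""


# ---------------------------------------------------------------------------
# constitutive law
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Constitutive:
    """Toe/linear/failure constitutive law for one region.

    Parameters are the toe stiffness ``E_t`` (MPa), toe exponent ``k``
    (dimensionless), linear modulus ``E`` (MPa), ultimate stress (MPa) and
    the residual stress fraction retained after tearing.
    """

    toe_stiffness: float
    toe_exponent: float
    linear_modulus: float
    ultimate_stress: float
    residual_fraction: float = 0.05

    def __post_init__(self) -> None:
        if min(self.toe_stiffness, self.toe_exponent, self.linear_modulus,
               self.ultimate_stress) <= 0:
            raise PhantomError("constitutive parameters must be positive")
        if self.linear_modulus <= self.toe_stiffness:
            raise PhantomError("linear modulus must exceed toe stiffness")
        if not 0.0 <= self.residual_fraction < 1.0:
            raise PhantomError("residual fraction must be in [0, 1)")
        if self.stress_toe >= self.ultimate_stress:
            raise PhantomError("toe region must end below the ultimate stress")

    @property
    def strain_toe(self) -> float:
        """Toe/linear transition strain (tangent-modulus continuity)."""
        return math.log(self.linear_modulus / self.toe_stiffness) / self.toe_exponent

    @property
    def stress_toe(self) -> float:
        return (self.linear_modulus - self.toe_stiffness) / self.toe_exponent

    @property
    def strain_ultimate(self) -> float:
        return self.strain_toe + (self.ultimate_stress - self.stress_toe) / self.linear_modulus

    def stress(self, eps):
        """Loading-branch stress (MPa) at engineering strain ``eps`` (fraction)."""
        eps = np.asarray(eps, dtype=float)
        et, k, e = self.toe_stiffness, self.toe_exponent, self.linear_modulus
        toe = (et / k) * (np.exp(k * np.minimum(eps, self.strain_toe)) - 1.0)
        lin = self.stress_toe + e * (eps - self.strain_toe)
        out = np.where(eps < self.strain_toe, toe, lin)
        return out if out.ndim else float(out)

    def strain_of_stress(self, sigma):
        """Inverse of :meth:`stress` on the loading branch (sigma <= sigma_ult)."""
        sigma = np.asarray(sigma, dtype=float)
        if np.any(sigma < 0) or np.any(sigma > self.ultimate_stress * (1 + 1e-12)):
            raise PhantomError("stress outside the loading branch")
        et, k, e = self.toe_stiffness, self.toe_exponent, self.linear_modulus
        toe = np.log1p(k * sigma / et) / k
        lin = self.strain_toe + (sigma - self.stress_toe) / e
        out = np.where(sigma < self.stress_toe, toe, lin)
        return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# regions and the phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    name: str
    length: float                     # mm
    area: float                       # mm^2
    thickness: float                  # mm
    constitutive: Constitutive
    muscle_fraction: float | None     # plateau value; None for transitions (ramp)
    sigma_chi0: float                 # resting azimuthal spread, deg
    transition: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0 or self.area <= 0 or self.thickness <= 0:
            raise PhantomError(f"region {self.name}: length, area, thickness must be positive")
        if self.muscle_fraction is not None and not 0.0 <= self.muscle_fraction <= 1.0:
            raise PhantomError(f"region {self.name}: muscle fraction outside [0, 1]")
        if self.sigma_chi0 <= 0:
            raise PhantomError(f"region {self.name}: azimuthal spread must be positive")


@dataclass(frozen=True)
class TissuePhantom:
    """Ground-truth description of a valve strip (see module docstring)."""

    regions: tuple[Region, ...]
    preset: str = "custom"
    d_period_nm: float = 67.0           # resting collagen D-period
    d11_nm: float = 21.5                # resting muscle (1,1) d-spacing
    d11_strain_gain: float = 0.3        # relative (1,1) shrink per unit eng. strain
    coupling_baseline: float = 0.10     # c(x) away from transitions
    coupling_bumps: tuple[tuple[float, float, float], ...] = ()  # (center, amp, sigma) mm
    alignment_rate: float = 1.5         # fractional spread reduction per unit strain
    rotated_bump: tuple[float, float, float] | None = None       # (center, amp, sigma)
    marker_inset: float = 0.5           # mm from each region boundary

    def __post_init__(self) -> None:
        if len(self.regions) < 1:
            raise PhantomError("phantom needs at least one region")
        if self.d_period_nm <= 0 or self.d11_nm <= 0:
            raise PhantomError("resting d-spacings must be positive")
        for c, a, s in self.coupling_bumps:
            if s <= 0 or a < 0:
                raise PhantomError("coupling bumps need non-negative amplitude, positive width")

    # -- geometry ----------------------------------------------------------
    @property
    def region_bounds(self) -> np.ndarray:
        """Cumulative boundary positions, mm, from the PM end (len = n+1)."""
        return np.concatenate([[0.0], np.cumsum([r.length for r in self.regions])])

    @property
    def total_length(self) -> float:
        return float(self.region_bounds[-1])

    def region_named(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise PhantomError(f"no region named {name!r}")

    def region_interval(self, name: str) -> tuple[float, float]:
        b = self.region_bounds
        for i, r in enumerate(self.regions):
            if r.name == name:
                return float(b[i]), float(b[i + 1])
        raise PhantomError(f"no region named {name!r}")

    def region_at(self, x: float) -> Region:
        if not 0.0 <= x <= self.total_length:
            raise PhantomError(f"position {x} mm outside sample [0, {self.total_length}]")
        idx = int(np.searchsorted(self.region_bounds[1:-1], x, side="right"))
        return self.regions[idx]

    # -- scalar profiles ---------------------------------------------------
    def _plateau_nodes(self, values: list[float]) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-linear nodes: plateaus on pure regions, ramps across transitions."""
        b = self.region_bounds
        xs, ys = [], []
        for i, r in enumerate(self.regions):
            if not r.transition:
                xs += [b[i], b[i + 1]]
                ys += [values[i], values[i]]
        if not xs:  # all transitions: fall back to midpoints
            mids = 0.5 * (b[:-1] + b[1:])
            xs, ys = list(mids), list(values)
        return np.asarray(xs), np.asarray(ys)

    def muscle_fraction(self, x) -> np.ndarray | float:
        """Relative muscle fraction f_m(x) in [0, 1]; linear ramps across transitions."""
        vals = []
        for i, r in enumerate(self.regions):
            if r.muscle_fraction is not None:
                vals.append(r.muscle_fraction)
            else:  # transition: ramp endpoints come from the neighbours
                left = self.regions[i - 1].muscle_fraction if i > 0 else 0.0
                right = self.regions[i + 1].muscle_fraction if i + 1 < len(self.regions) else 0.0
                vals.append(0.5 * (left + right))
        xs, ys = self._plateau_nodes(vals)
        out = np.interp(np.asarray(x, dtype=float), xs, ys)
        return out if out.ndim else float(out)

    def thickness(self, x) -> np.ndarray | float:
        """Piecewise-linear thickness t(x), mm (> 0)."""
        b = self.region_bounds
        mids = 0.5 * (b[:-1] + b[1:])
        vals = [r.thickness for r in self.regions]
        out = np.interp(np.asarray(x, dtype=float), mids, vals)
        return out if out.ndim else float(out)

    def area(self, x) -> float:
        """Cross-sectional area at position x (per-region constant), mm^2."""
        return self.region_at(float(x)).area

    def strain_coupling(self, x) -> np.ndarray | float:
        """Molecular-strain gain c(x) >= 0 (baseline plus Gaussian bumps)."""
        x = np.asarray(x, dtype=float)
        c = np.full(x.shape, self.coupling_baseline)
        for center, amp, sig in self.coupling_bumps:
            c = c + amp * np.exp(-0.5 * ((x - center) / sig) ** 2)
        return c if c.ndim else float(c)

    def molecular_strain(self, x, eng_strain: float):
        """Local collagen molecular strain (fraction): c(x) * eng_strain."""
        return self.strain_coupling(x) * eng_strain

    def d_period(self, x, eng_strain: float):
        """Collagen D-period (nm) at position x and overall strain level."""
        return self.d_period_nm * (1.0 + self.molecular_strain(x, eng_strain))

    def d11(self, x, eng_strain: float):
        """Muscle (1,1) d-spacing (nm); shrinks linearly with strain (relative measure)."""
        return self.d11_nm * (1.0 - self.d11_strain_gain * eng_strain)

    def orientation_spread(self, x, eng_strain: float):
        """Azimuthal spread sigma_chi (deg); non-increasing in engineering strain."""
        mids = 0.5 * (self.region_bounds[:-1] + self.region_bounds[1:])
        vals = [r.sigma_chi0 for r in self.regions]
        base = np.interp(np.asarray(x, dtype=float), mids, vals)
        factor = max(0.2, 1.0 - self.alignment_rate * eng_strain)
        out = base * factor
        return out if out.ndim else float(out)

    def rotated_fraction(self, x) -> np.ndarray | float:
        """Fraction of collagen aligned 90 deg off-axis (CT-LL junction signature)."""
        x = np.asarray(x, dtype=float)
        out = np.zeros(x.shape)
        if self.rotated_bump is not None:
            center, amp, sig = self.rotated_bump
            out = amp * np.exp(-0.5 * ((x - center) / sig) ** 2)
        return out if out.ndim else float(out)

    # -- markers and scan points -------------------------------------------
    def marker_positions(self) -> np.ndarray:
        """Material marker coordinates, mm: one just inside each region end.

        Guarantees at least one marker per region and one marker on each side
        of every transition.
        """
        b = self.region_bounds
        pos = []
        for i in range(len(self.regions)):
            pos += [b[i] + self.marker_inset, b[i + 1] - self.marker_inset]
        return np.asarray(pos)

    def marker_pairs(self) -> dict[str, tuple[int, int]]:
        """Marker-index pair flanking each region (for regional strain)."""
        return {r.name: (2 * i, 2 * i + 1) for i, r in enumerate(self.regions)}

    def scan_positions(self, n: int = 10, inset: float = 0.5) -> np.ndarray:
        """n probe positions along the strip (material coords, mm)."""
        return np.linspace(inset, self.total_length - inset, n)

    def material_to_lab(self, x, regional_strains: dict[str, float]):
        """Distance (mm) of material point x from the fixed LL-end grip.

        ``regional_strains`` are engineering strains (fractions) per region.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        b = self.region_bounds
        out = np.zeros_like(x)
        for j, xm in enumerate(x):
            d = 0.0
            for i, r in enumerate(self.regions):
                lam = 1.0 + regional_strains.get(r.name, 0.0)
                lo, hi = b[i], b[i + 1]
                below = max(0.0, hi - max(xm, lo))  # length of region below x
                d += below * lam
            out[j] = d
        return out if out.shape != (1,) else float(out[0])

    # -- convenience --------------------------------------------------------
    @property
    def weak_region(self) -> str:
        """Region with the smallest tear force sigma_ult * A."""
        forces = [r.constitutive.ultimate_stress * r.area for r in self.regions]
        return self.regions[int(np.argmin(forces))].name

    def with_overrides(self, **kw) -> "TissuePhantom":
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        d.update(kw)
        return TissuePhantom(**d)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _load_preset_config(name: str) -> dict:
    ref = importlib.resources.files("valvescan") / "presets" / f"{name.lower()}.yaml"
    if not ref.is_file():
        raise PhantomError(f"unknown preset {name!r}; available: {available_presets()}")
    return yaml.safe_load(ref.read_text())


def available_presets() -> list[str]:
    root = importlib.resources.files("valvescan") / "presets"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def make_phantom(preset: str = "mv", overrides: dict | None = None) -> TissuePhantom:
    """Build a phantom from a named preset (``mv``, ``tv`` or ``av``).

    ``overrides`` is a nested mapping merged over the preset configuration,
    e.g. ``{"regions": {"CT": {"ultimate_stress_mpa": 2.0}},
    "coupling": {"baseline": 0.2}}``.  Per-region cross-sectional areas are
    strength-consistent: ``A_i = F0 / sigma_ult_i`` with the tear force
    ``F0`` set by the reference region's area, and the designated weak
    region's area reduced by ``weak_area_deficit`` so failure initiates
    there.
    """
    cfg = _load_preset_config(preset)
    if overrides:
        cfg = _merge(cfg, overrides)

    region_cfgs = cfg["regions"]
    ref_name = cfg.get("reference_region", region_cfgs[0]["name"])
    ref_cfg = next(r for r in region_cfgs if r["name"] == ref_name)
    f0 = cfg["reference_area_mm2"] * ref_cfg["ultimate_stress_mpa"]  # newtons
    weak = cfg.get("weak_region")
    deficit = cfg.get("weak_area_deficit", 0.0)

    regions = []
    for rc in region_cfgs:
        law = Constitutive(
            toe_stiffness=rc["toe_stiffness_mpa"],
            toe_exponent=rc["toe_exponent"],
            linear_modulus=rc["linear_modulus_mpa"],
            ultimate_stress=rc["ultimate_stress_mpa"],
            residual_fraction=rc.get("residual_fraction", 0.05),
        )
        area = rc.get("area_mm2", f0 / law.ultimate_stress)
        if rc["name"] == weak:
            area *= 1.0 - deficit
        regions.append(Region(
            name=rc["name"], length=rc["length_mm"], area=area,
            thickness=rc["thickness_mm"], constitutive=law,
            muscle_fraction=rc.get("muscle_fraction"),
            sigma_chi0=rc["sigma_chi_deg"],
            transition=bool(rc.get("transition", False)),
        ))

    bounds = np.concatenate([[0.0], np.cumsum([r.length for r in regions])])
    mid = {r.name: 0.5 * (bounds[i] + bounds[i + 1]) for i, r in enumerate(regions)}
    bumps = []
    for bump in cfg.get("coupling", {}).get("bumps", []):
        center = bump.get("center_mm", mid.get(bump.get("region", ""), None))
        if center is None:
            raise PhantomError("coupling bump needs center_mm or a valid region name")
        bumps.append((float(center), float(bump["amplitude"]), float(bump["sigma_mm"])))

    rotated = None
    rp = cfg.get("rotated_population")
    if rp:
        center = rp.get("center_mm", mid.get(rp.get("region", ""), None))
        if center is None:
            raise PhantomError("rotated population needs center_mm or a valid region name")
        rotated = (float(center), float(rp["amplitude"]), float(rp["sigma_mm"]))

    return TissuePhantom(
        regions=tuple(regions),
        preset=cfg.get("name", preset).upper(),
        d_period_nm=cfg.get("d_period_nm", 67.0),
        d11_nm=cfg.get("d11_nm", 21.5),
        d11_strain_gain=cfg.get("d11_strain_gain", 0.3),
        coupling_baseline=cfg.get("coupling", {}).get("baseline", 0.10),
        coupling_bumps=tuple(bumps),
        alignment_rate=cfg.get("alignment_rate", 1.5),
        rotated_bump=rotated,
        marker_inset=cfg.get("marker_inset_mm", 0.5),
    )


def _merge(base: dict, over: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in over.items():
        if k == "regions" and isinstance(v, dict):
            for rc in out["regions"]:
                if rc["name"] in v:
                    rc.update(v[rc["name"]])
        elif isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


# ---------------------------------------------------------------------------
# series mechanics
# ---------------------------------------------------------------------------

@dataclass
class SeriesState:
    """Equilibrium of the series chain at one grip displacement."""

    force: float                       # N
    strains: dict[str, float]          # engineering strain (fraction) per region
    displacement: float                # mm
    post_failure: bool = False
    torn_region: str | None = None


@dataclass
class LoadTrace:
    """Load-displacement record of a pull, plus hidden generator truth.

    ``per_region_strain_truth`` holds the true engineering strain of each
    region relative to the first sample (the resting reference) and exists
    for testing only; analysis code must not read it.
    """

    time: np.ndarray                   # s
    displacement: np.ndarray           # mm, grip displacement beyond resting
    load_g: np.ndarray                 # grams-force
    per_region_strain_truth: dict[str, np.ndarray] = field(default_factory=dict)
    tear_region: str | None = None
    tear_time: float | None = None
    tear_force_n: float | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.displacement) < -1e-12):
            raise PhantomError("displacement must be non-decreasing during a pull")
        if np.any(self.load_g < -1e-9) or np.any(self.load_g > SENSOR_MAX_G):
            raise PhantomError(f"load outside the sensor range [0, {SENSOR_MAX_G}] g")


def _chain_displacement(phantom: TissuePhantom, force: float) -> float:
    """Total elongation (mm) of the chain on the loading branch at force F (N)."""
    d = 0.0
    for r in phantom.regions:
        d += r.constitutive.strain_of_stress(force / r.area) * r.length
    return d


def _tear_force(phantom: TissuePhantom) -> tuple[float, str]:
    forces = {r.name: r.constitutive.ultimate_stress * r.area for r in phantom.regions}
    weak = min(forces, key=forces.get)
    return forces[weak], weak


def solve_series_pull(phantom: TissuePhantom, total_displacement: float) -> SeriesState:
    """Equilibrium force and regional strains at a grip displacement (mm).

    Solves ``sigma_i(eps_i) * A_i = F`` for all regions with
    ``sum_i eps_i * L0_i = total_displacement`` by bracketed root finding on
    the force.  Valid on the loading branch; a displacement beyond the tear
    point returns the at-tear state flagged ``post_failure`` (the tear
    trajectory itself is produced by :func:`simulate_pull`).
    """
    if total_displacement < 0:
        raise PhantomError("displacement must be non-negative")
    f_tear, weak = _tear_force(phantom)
    if total_displacement == 0.0:
        return SeriesState(0.0, {r.name: 0.0 for r in phantom.regions}, 0.0)
    d_tear = _chain_displacement(phantom, f_tear)
    if total_displacement > d_tear * (1 + 1e-12):
        strains = {r.name: r.constitutive.strain_of_stress(f_tear / r.area)
                   for r in phantom.regions}
        return SeriesState(f_tear, strains, d_tear, post_failure=True, torn_region=weak)
    force = brentq(lambda f: _chain_displacement(phantom, f) - total_displacement,
                   0.0, f_tear, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    strains = {r.name: r.constitutive.strain_of_stress(force / r.area)
               for r in phantom.regions}
    return SeriesState(float(force), strains, total_displacement)


def simulate_pull(
    phantom: TissuePhantom,
    rate: float = 0.04,
    sample_hz: float = 25.0,
    tear_tau: float = 2.0,
    post_tear_time: float = 3.0,
    resting_load_g: float = RESTING_LOAD_G,
) -> LoadTrace:
    """Simulate a constant-rate pull to failure and a short post-tear tail.

    The ramp starts from the resting state (a ~0.1 g pre-tension).  Once the
    grip displacement passes the tear point of the weakest region
    (``argmin sigma_ult * A``), the force relaxes linearly in time from the
    peak to the residual fraction over ``tear_tau`` seconds (tear
    propagation); intact regions unload elastically along their own curves
    while the torn region absorbs the freed displacement.

    Returns a :class:`LoadTrace` sampled at ``sample_hz``; strains in
    ``per_region_strain_truth`` are referenced to the first sample.
    """
    if rate <= 0:
        raise PhantomError("pull rate must be positive")
    f_tear, weak = _tear_force(phantom)
    if f_tear / (G0 * 1e-3) > SENSOR_MAX_G:
        raise PhantomError("tear force exceeds the load-cell capacity")
    f_rest = resting_load_g * G0 * 1e-3
    d_rest = _chain_displacement(phantom, f_rest)
    d_tear = _chain_displacement(phantom, f_tear)
    t_tear = (d_tear - d_rest) / rate
    t_end = t_tear + tear_tau + post_tear_time
    time = np.arange(0.0, t_end + 0.5 / sample_hz, 1.0 / sample_hz)
    disp = d_rest + rate * time

    weak_reg = phantom.region_named(weak)
    f_res = weak_reg.constitutive.residual_fraction * f_tear
    names = [r.name for r in phantom.regions]
    strains = {n: np.zeros_like(time) for n in names}
    load = np.zeros_like(time)

    for i, t in enumerate(time):
        if t <= t_tear:
            st = solve_series_pull(phantom, disp[i])
            load[i] = st.force
            for n in names:
                strains[n][i] = st.strains[n]
        else:
            frac = min(1.0, (t - t_tear) / tear_tau)
            force = f_tear - (f_tear - f_res) * frac
            intact_elong = 0.0
            for r in phantom.regions:
                if r.name == weak:
                    continue
                strains[r.name][i] = r.constitutive.strain_of_stress(force / r.area)
                intact_elong += strains[r.name][i] * r.length
            strains[weak][i] = (disp[i] - intact_elong) / weak_reg.length
            load[i] = force

    # reference strains to the resting (first-sample) state
    truth = {}
    for n in names:
        lam0 = 1.0 + strains[n][0]
        truth[n] = (1.0 + strains[n]) / lam0 - 1.0

    return LoadTrace(
        time=time,
        displacement=disp - disp[0],
        load_g=load / (G0 * 1e-3),
        per_region_strain_truth=truth,
        tear_region=weak,
        tear_time=float(t_tear),
        tear_force_n=float(f_tear),
    )
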