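"""Shared fixtures: phantoms, geometries and precomputed pipeline products.

Everything is generated programmatically at test time; expensive products
(the noise-free MV scan fit table, the full-quality MV mechanics run) are
session-scoped so several test modules can share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from valvescan.geometry import DetectorGeometry
from valvescan.phantom import Constitutive, Region, TissuePhantom, make_phantom
from valvescan.pipeline import run_mechanics, scan_phantom


@pytest.fixture(scope="session")
def geometry():
    return DetectorGeometry()


@pytest.fixture(scope="session")
def mv_phantom():
    return make_phantom("mv")


@pytest.fixture(scope="session")
def tv_phantom():
    return make_phantom("tv")


def linear_law(modulus: float, ultimate: float, residual: float = 0.05) -> Constitutive:
    """An effectively linear constitutive law (vanishing toe region)."""
    return Constitutive(toe_stiffness=modulus * (1 - 1e-9), toe_exponent=1.0,
                        linear_modulus=modulus, ultimate_stress=ultimate,
                        residual_fraction=residual)


def single_region_phantom(sigma_chi: float = 10.0, muscle_fraction: float = 0.0,
                          d_period_nm: float = 67.0, length: float = 10.0,
                          coupling: float = 0.2, **kw) -> TissuePhantom:
    """Minimal one-region phantom for controlled rendering tests."""
    region = Region(name="R", length=length, area=1.0, thickness=1.0,
                    constitutive=linear_law(1.0, 0.5),
                    muscle_fraction=muscle_fraction, sigma_chi0=sigma_chi)
    return TissuePhantom(regions=(region,), d_period_nm=d_period_nm,
                         coupling_baseline=coupling, alignment_rate=0.0, **kw)


@pytest.fixture(scope="session")
def mv_fit_table(mv_phantom, geometry):
    """Noise-free MV scan: 10 positions x 6 strain levels, full fitting."""
    return scan_phantom(mv_phantom, geometry)


@pytest.fixture(scope="session")
def mv_mech(mv_phantom):
    """Full-quality noise-free MV mechanics run (slow ramp, 5 fps video)."""
    return run_mechanics(mv_phantom)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
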