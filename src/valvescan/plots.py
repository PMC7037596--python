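"""Figures mirroring the standard presentation of scan results: composition
profile, molecular-strain heatmap, strain-per-thickness profile with
failure locus, orientation ellipse map and regional stress-strain curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from matplotlib.patches import Ellipse  # noqa: E402

__all__ = ["plot_composition", "plot_strain_heatmap", "plot_strain_per_thickness",
           "plot_stress_strain", "plot_orientation_map"]


def _save(fig, path):
    if path is not None:
        fig.savefig(Path(path), dpi=130, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_composition(profile, transitions=(), path=None):
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(profile.position, profile.pct_muscle, "o-", label="% muscle")
    ax.plot(profile.position, profile.pct_collagen, "s-", label="% collagen")
    for call in transitions:
        for xb in call.interval:
            ax.axvline(xb, color="purple", ls=":", lw=1)
    ax.set_xlabel("position along strip (mm, PM end at 0)")
    ax.set_ylabel("relative composition (%)")
    ax.set_ylim(-3, 103)
    ax.legend(frameon=False)
    return _save(fig, path)


def plot_strain_heatmap(strain_map, path=None):
    fig, ax = plt.subplots(figsize=(6, 3))
    mesh = ax.pcolormesh(strain_map.positions, strain_map.eng_strain_levels,
                         strain_map.strain.T, shading="nearest", cmap="inferno")
    fig.colorbar(mesh, ax=ax, label="molecular strain (%)")
    ax.set_xlabel("resting position (mm)")
    ax.set_ylabel("engineering strain (%)")
    return _save(fig, path)


def plot_strain_per_thickness(positions, spt, failure_pos=None, path=None):
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(positions, spt, "o-")
    if failure_pos is not None:
        ax.axvline(failure_pos, color="red", ls="--", lw=1,
                   label=f"predicted failure {failure_pos:.1f} mm")
        ax.legend(frameon=False)
    ax.set_xlabel("resting position (mm)")
    ax.set_ylabel("molecular strain / thickness (%/mm)")
    return _save(fig, path)


def plot_stress_strain(curves, features=None, path=None):
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, curve in curves.items():
        ax.plot(curve.strain, curve.stress, label=name, lw=1.2)
        if features and features[name].failure_detected:
            f = features[name]
            ax.plot(f.strain_at_ultimate, f.ultimate_stress, "kx", ms=6)
    ax.set_xlabel("engineering strain (%)")
    ax.set_ylabel("stress (MPa)")
    ax.legend(frameon=False, fontsize=8)
    return _save(fig, path)


def plot_orientation_map(positions, results, path=None, spacing=1.0):
    """Ellipse per scan position: major axis along the fiber direction,
    minor axis inversely proportional to the angular spread; dots mark
    isotropic positions."""
    fig, ax = plt.subplots(figsize=(7, 2.2))
    for x, res in zip(positions, results):
        if res.isotropic:
            ax.plot(x, 0.0, "ko", ms=3)
            continue
        a, b, ang = res.ellipse
        ax.add_patch(Ellipse((x, 0.0), width=spacing * a, height=spacing * b,
                             angle=ang, fill=False, color="tab:blue"))
    ax.set_xlim(float(np.min(positions)) - 1, float(np.max(positions)) + 1)
    ax.set_ylim(-1, 1)
    ax.set_xlabel("position (mm)")
    ax.set_yticks([])
    return _save(fig, path)
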