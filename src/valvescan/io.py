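"""Readers and writers for the on-disk data products.

Diffraction frames are 32-bit TIFF with a JSON geometry sidecar; load
traces are CSV with the header ``time_s,displacement_mm,load_g`` (the
format logged by the strain rig); profiles are CSV with a JSON provenance
file; fit tables are TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import DetectorGeometry
from .phantom import LoadTrace
from .reduction import RadialProfile
from .render import DiffractionFrame

__all__ = [
    "write_frame", "read_frame",
    "write_load_trace", "read_load_trace",
    "write_profile", "read_profile",
    "write_fit_table", "read_fit_table",
    "write_video_frames",
    "read_thickness_csv", "write_thickness_csv",
    "frame_filename",
]


def frame_filename(scan_index: int, eng_strain: float) -> str:
    """Canonical frame name encoding scan index and strain percent."""
    return f"scan{scan_index:03d}_strain{100 * eng_strain:05.1f}pct.tif"


def write_frame(frame: DiffractionFrame, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = frame_filename(frame.scan_index or 0, frame.eng_strain)
    path = directory / name
    tifffile.imwrite(path, frame.image.astype(np.float32))
    sidecar = frame.geometry.to_dict()
    sidecar.update({"position_mm": frame.position_mm,
                    "eng_strain": frame.eng_strain,
                    "scan_index": frame.scan_index,
                    "load_g": frame.load_g})
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_frame(path: str | Path) -> DiffractionFrame:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    geometry = DetectorGeometry.from_dict(meta)
    return DiffractionFrame(image=tifffile.imread(path).astype(float),
                            geometry=geometry,
                            position_mm=meta.get("position_mm", 0.0),
                            eng_strain=meta.get("eng_strain", 0.0),
                            scan_index=meta.get("scan_index"),
                            load_g=meta.get("load_g"))


def write_load_trace(trace: LoadTrace, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.time, "displacement_mm": trace.displacement,
                       "load_g": trace.load_g})
    df.to_csv(path, index=False)
    return path


def read_load_trace(path: str | Path) -> LoadTrace:
    df = pd.read_csv(path)
    return LoadTrace(time=df["time_s"].to_numpy(float),
                     displacement=df["displacement_mm"].to_numpy(float),
                     load_g=df["load_g"].to_numpy(float))


def write_profile(profile: RadialProfile, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"q_invA": profile.q, "intensity": profile.intensity}).to_csv(
        path, index=False)
    prov = dict(profile.provenance)
    prov.update({"sector": profile.sector, "half_angle_deg": profile.half_angle})
    path.with_suffix(".json").write_text(json.dumps(prov, indent=1))
    return path


def read_profile(path: str | Path) -> RadialProfile:
    path = Path(path)
    df = pd.read_csv(path)
    prov = json.loads(path.with_suffix(".json").read_text()) \
        if path.with_suffix(".json").exists() else {}
    return RadialProfile(q=df["q_invA"].to_numpy(float),
                         intensity=df["intensity"].to_numpy(float),
                         sector=prov.get("sector", "full"),
                         half_angle=prov.get("half_angle_deg", 15.0),
                         provenance=prov)


def write_fit_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_fit_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_video_frames(frames: np.ndarray, directory: str | Path,
                       prefix: str = "frame") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = directory / f"{prefix}{i:05d}.tif"
        tifffile.imwrite(p, np.asarray(frame, dtype=np.float32))
        paths.append(p)
    return paths


def write_thickness_csv(positions_mm: np.ndarray, thickness_mm: np.ndarray,
                        path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"position_mm": positions_mm,
                  "thickness_mm": thickness_mm}).to_csv(path, index=False)
    return path


def read_thickness_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["position_mm"].to_numpy(float), df["thickness_mm"].to_numpy(float)
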