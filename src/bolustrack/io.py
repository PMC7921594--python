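"""File formats and run configuration.

NIfTI (via nibabel) carries the 4D dynamic series, masks and arrival maps;
CSV carries signal-time curves (columns ``time_ms``, ``value``); JSON
carries cine contours, configuration and the analysis report.  Times are
milliseconds throughout, volumes microliters, coordinates 0-based with x
varying fastest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .arrival import ArrivalMap
from .timecurve import SampledCurve

__all__ = [
    "AnalysisConfig",
    "read_dynamic_series",
    "write_dynamic_series",
    "read_mask",
    "write_mask",
    "write_arrival_map",
    "read_curve_csv",
    "write_curve_csv",
    "read_contours",
    "write_contours",
]

_TIME_UNIT_TO_MS = {"sec": 1000.0, "msec": 1.0, "usec": 0.001, "unknown": 1.0}


def read_dynamic_series(path: str | Path) -> tuple[np.ndarray, float, tuple[float, ...]]:
    """Load a 4D dynamic series from NIfTI.

    Returns ``(array, frame_interval_ms, voxel_size_mm)``.  The frame
    interval is taken from the header time step (pixdim over the 4th
    dimension) converted to ms according to the declared time unit; a
    header without time units is taken to be in ms already.

    Raises
    ------
    ValueError
        If the image is not 4D or the header declares no positive time step.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        msg = f"{path}: expected a 4D series (X, Y, Z, T), got {data.ndim} dimensions"
        if data.ndim == 3:
            msg += " — the time dimension is missing"
        raise ValueError(msg)
    zooms = img.header.get_zooms()
    _, t_unit = img.header.get_xyzt_units()
    step = float(zooms[3]) if len(zooms) > 3 else 0.0
    if step <= 0:
        raise ValueError(f"{path}: header declares no positive time step")
    frame_interval = step * _TIME_UNIT_TO_MS.get(t_unit, 1.0)
    voxel_size = tuple(float(z) for z in zooms[:3])
    return data.astype(float), frame_interval, voxel_size


def write_dynamic_series(
    path: str | Path,
    series: np.ndarray,
    frame_interval: float,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> None:
    """Write a 4D series as NIfTI with the frame interval in ms in the header."""
    if series.ndim != 4:
        raise ValueError("series must be 4D (X, Y, Z, T)")
    affine = np.diag([*voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(series, dtype=np.float64), affine)
    img.header.set_zooms((*voxel_size, frame_interval))
    img.header.set_xyzt_units("mm", "msec")
    nib.save(img, str(path))


def read_mask(path: str | Path) -> np.ndarray:
    """Load a 3D label/mask volume as boolean (nonzero = inside)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got {data.ndim} dimensions")
    return data != 0


def write_mask(
    path: str | Path, mask: np.ndarray, voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> None:
    affine = np.diag([*voxel_size, 1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def write_arrival_map(
    out_dir: str | Path,
    amap: ArrivalMap,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    prefix: str = "arrival",
) -> dict[str, Path]:
    """Write an arrival map as three NIfTI volumes: t0 (ms), sd (ms), quality.

    Returns the mapping of component name to file path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*voxel_size, 1.0])
    paths = {}
    for name, vol, dtype in (
        ("t0", amap.t0, np.float64),
        ("sd", amap.sd, np.float64),
        ("quality", amap.quality, np.uint8),
    ):
        p = out_dir / f"{prefix}_{name}.nii"
        nib.save(nib.Nifti1Image(vol.astype(dtype), affine), str(p))
        paths[name] = p
    return paths


def write_curve_csv(path: str | Path, curve: SampledCurve) -> None:
    pd.DataFrame({"time_ms": curve.t, "value": curve.y}).to_csv(path, index=False)


def read_curve_csv(path: str | Path) -> SampledCurve:
    df = pd.read_csv(path)
    if not {"time_ms", "value"} <= set(df.columns):
        raise ValueError(f"{path}: curve CSV needs columns time_ms, value")
    return SampledCurve(df["time_ms"].to_numpy(float), df["value"].to_numpy(float))


def write_contours(
    path: str | Path,
    contours: dict[tuple[int, int], np.ndarray],
    pixel_spacing: float = 1.0,
) -> None:
    """Write cine contours as JSON: per (slice, phase) an ordered vertex list."""
    entries = [
        {
            "slice": int(sl),
            "phase": int(ph),
            "vertices": np.asarray(v, dtype=float).tolist(),
        }
        for (sl, ph), v in sorted(contours.items())
    ]
    payload = {"pixel_spacing_mm": pixel_spacing, "contours": entries}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_contours(path: str | Path) -> tuple[dict[tuple[int, int], np.ndarray], float]:
    """Read cine contours from JSON (or CSV) into a (slice, phase) mapping.

    JSON layout: ``{"pixel_spacing_mm": s, "contours": [{"slice": i,
    "phase": p, "vertices": [[x, y], ...]}, ...]}``.  CSV layout: columns
    ``slice, phase, x, y`` with vertices in file order (a
    ``pixel_spacing_mm`` column, constant, is optional).  Vertex
    coordinates are multiplied by the pixel spacing downstream, not here.

    Raises
    ------
    ValueError
        On contours with fewer than 3 vertices or duplicate (slice, phase)
        entries.
    """
    path = Path(path)
    contours: dict[tuple[int, int], np.ndarray] = {}
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if not {"slice", "phase", "x", "y"} <= set(df.columns):
            raise ValueError(f"{path}: contour CSV needs columns slice, phase, x, y")
        spacing = float(df["pixel_spacing_mm"].iloc[0]) if "pixel_spacing_mm" in df else 1.0
        for (sl, ph), grp in df.groupby(["slice", "phase"], sort=True):
            contours[(int(sl), int(ph))] = grp[["x", "y"]].to_numpy(float)
    else:
        payload = json.loads(path.read_text())
        spacing = float(payload.get("pixel_spacing_mm", 1.0))
        for entry in payload["contours"]:
            key = (int(entry["slice"]), int(entry["phase"]))
            if key in contours:
                raise ValueError(f"{path}: duplicate contour for (slice, phase) = {key}")
            contours[key] = np.asarray(entry["vertices"], dtype=float)
    for key, v in contours.items():
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError(
                f"{path}: contour {key} needs an ordered (n >= 3, 2) vertex list"
            )
    return contours, spacing


@dataclass
class AnalysisConfig:
    """Configuration of a full pulmonary-blood-volume analysis run.

    Paths reference the dynamic series, the RV/LV search-region masks and
    the cine contour file; the remaining fields are the tunable analysis
    parameters with their standard defaults.
    """

    series_path: str = ""
    rv_mask_path: str = ""
    lv_mask_path: str = ""
    contours_path: str = ""
    slice_thickness_mm: float = 1.0
    diastole_phase: int = 0
    systole_phase: int = 0
    cine_phase_interval_ms: float = 5.0
    cine_phase_count_between_contractions: int | None = None
    sg_window_ms: float = 150.0
    sg_order: int = 2
    band_hz: tuple[float, float] = (4.0, 15.0)
    b_max: float = 100.0
    roi_extent_mm2: float = 1.0
    pre_window_ms: float = 400.0
    d_vol_rel: float = 0.05
    d_rr_rel: float = 0.03
    frame_interval_override_ms: float | None = None
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "band_hz" in raw and raw["band_hz"] is not None:
            raw["band_hz"] = tuple(raw["band_hz"])
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("series_path", "rv_mask_path", "lv_mask_path", "contours_path"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
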