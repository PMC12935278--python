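"""File I/O: TIFF volumes with JSON sidecars, PLY meshes with vertex
scalars, snapshot series, transforms and CSV reports.

Volumes are stored as multi-page TIFF with pages along depth (file axis
order z, y, x) and a ``<stem>.json`` sidecar holding spacing, origin,
units, frame and axis order; complex velocity fields go to a companion
``<stem>.velocity.tif`` with real/imaginary channels.  All grid metadata
round-trips losslessly and arrays are written at full precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh

from .containers import ComplexVelocityField, VolumeGrid
from .geometry import RigidTransform
from .reconstruction import AcquisitionSchedule, SnapshotSeries

AXIS_ORDER = "xyz"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(path: str | Path, volume: VolumeGrid) -> None:
    path = Path(path)
    tifffile.imwrite(path, volume.data.transpose(2, 1, 0),
                     photometric="minisblack")
    meta = {
        "spacing_mm": volume.spacing.tolist(),
        "origin_mm": volume.origin.tolist(),
        "units": volume.units,
        "frame": volume.frame,
        "axis_order": AXIS_ORDER,
        "file_axis_order": "zyx",
        "has_velocity": volume.velocity is not None,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    if volume.velocity is not None:
        v = volume.velocity.transpose(2, 1, 0)
        tifffile.imwrite(
            path.with_suffix(".velocity.tif"),
            np.stack([v.real, v.imag]),
            photometric="minisblack",
        )


def read_volume(path: str | Path) -> VolumeGrid:
    path = Path(path)
    try:
        meta = json.loads(_sidecar(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed volume sidecar {_sidecar(path)}: {e}") from e
    data = tifffile.imread(path).transpose(2, 1, 0)
    velocity = None
    if meta.get("has_velocity"):
        ri = tifffile.imread(path.with_suffix(".velocity.tif"))
        velocity = (ri[0] + 1j * ri[1]).transpose(2, 1, 0)
    return VolumeGrid(
        data,
        spacing=meta["spacing_mm"],
        origin=meta["origin_mm"],
        units=meta["units"],
        frame=meta["frame"],
        velocity=velocity,
    )


def write_field(path: str | Path, field: ComplexVelocityField) -> None:
    path = Path(path)
    v = field.values
    tifffile.imwrite(path, np.stack([v.real, v.imag]),
                     photometric="minisblack")
    _sidecar(path).write_text(json.dumps({"shape": list(v.shape)}))


def read_field(path: str | Path) -> ComplexVelocityField:
    ri = tifffile.imread(Path(path))
    return ComplexVelocityField(ri[0] + 1j * ri[1])


def write_snapshot_series(path: str | Path, series: SnapshotSeries) -> None:
    path = Path(path)
    tifffile.imwrite(path, series.values, photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps({"schedule": series.schedule.to_dict(),
                    "saturated": series.saturated})
    )


def read_snapshot_series(path: str | Path) -> SnapshotSeries:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    return SnapshotSeries(
        tifffile.imread(path),
        schedule=AcquisitionSchedule.from_dict(meta["schedule"]),
        saturated=meta.get("saturated", False),
    )


def write_transform(path: str | Path, T: RigidTransform) -> None:
    Path(path).write_text(T.to_json())


def read_transform(path: str | Path) -> RigidTransform:
    return RigidTransform.from_json(Path(path).read_text())


def write_mesh(
    path: str | Path, mesh: trimesh.Trimesh,
    vertex_scalars: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a PLY mesh; per-vertex scalars become float32 vertex
    properties (amplitude mm/s, phase rad, ...)."""
    out = mesh.copy()
    for name, arr in (vertex_scalars or {}).items():
        out.vertex_attributes[name] = np.asarray(arr, dtype=np.float32)
    out.export(Path(path), encoding="ascii")


def read_mesh(path: str | Path) -> tuple[trimesh.Trimesh, dict[str, np.ndarray]]:
    """Read a PLY mesh and recover any non-coordinate vertex properties."""
    mesh = trimesh.load(Path(path), process=False)
    scalars: dict[str, np.ndarray] = {}
    raw = mesh.metadata.get("_ply_raw", {}).get("vertex", {}).get("data", {})
    if hasattr(raw, "dtype") and raw.dtype.names:
        raw = {n: raw[n] for n in raw.dtype.names}
    for name, arr in raw.items():
        if name in ("x", "y", "z", "nx", "ny", "nz", "red", "green", "blue",
                    "alpha"):
            continue
        scalars[name] = np.asarray(arr).reshape(-1)
    return mesh, scalars


def write_report(path: str | Path, df: pd.DataFrame) -> None:
    """CSV report with fixed column order and repr-precision floats, so
    identical inputs yield byte-identical files."""
    df.to_csv(Path(path), index=False, lineterminator="\n")


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
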