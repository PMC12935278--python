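"""In-memory containers shared by the reconstruction, registration and
decomposition stages.

Conventions (fixed package-wide): right-handed coordinates, physical units
of millimetres, voxel-centre positions, 0-based indices.  Volume arrays are
axis-ordered ``(x, y, z)`` where ``x`` is the lateral (fast) scan axis,
``y`` the slice axis and ``z`` the depth along the optical axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from dataclasses import field as dc_field
from typing import Any

import numpy as np


@dataclass
class VolumeGrid:
    """A regular 3D reflectivity grid with physical anchoring.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Reflectivity in dB (``units == "dB"``).
    spacing : (3,) array
        Voxel pitch along (x, y, z) in mm.
    origin : (3,) array
        Physical position of voxel (0, 0, 0) in mm, in ``frame``.
    frame : str
        Label of the anchoring coordinate frame ("WCS", "OCS:<name>", ...).
    velocity : complex ndarray or None
        Optional co-registered per-voxel complex velocity field (mm/s),
        same shape as ``data``.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None  # type: ignore[assignment]
    units: str = "dB"
    frame: str = "WCS"
    velocity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D (x, y, z)")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.velocity is not None:
            self.velocity = np.asarray(self.velocity, dtype=complex)
            if self.velocity.shape != self.data.shape:
                raise ValueError("velocity field shape must match data")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Physical coordinates (mm) of voxel indices, shape (..., 3)."""
        idx = np.asarray(indices, dtype=float)
        return self.origin + idx * self.spacing

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates of (masked) voxel centres, shape (N, 3)."""
        if mask is None:
            mask = np.ones(self.shape, dtype=bool)
        idx = np.argwhere(mask)
        return self.index_to_world(idx)

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    @property
    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        lo = self.origin.copy()
        hi = self.origin + (np.array(self.shape) - 1) * self.spacing
        return lo, hi


@dataclass
class ComplexVelocityField:
    """Per-pixel complex velocity ``v`` (mm/s): ``|v|`` is the vibration
    amplitude and ``angle(v)`` the vibration phase at the stimulus
    frequency."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if not np.all(np.isfinite(self.values[~np.isnan(self.values)])):
            raise ValueError("velocity field contains non-finite values")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    @property
    def shape(self):
        return self.values.shape


@dataclass
class DirectionMeasurement:
    """One optical-axis acquisition: C-scan volume, assembled velocity
    field, estimated unit optical axis and noise level.

    ``truth`` optionally carries simulator ground truth (rigid transform,
    true axis, motion spec, analytic surface) for validation studies.
    """

    name: str
    volume: VolumeGrid
    field: ComplexVelocityField | None = None
    axis: np.ndarray | None = None
    sigma_n: float | None = None
    series: Any = None
    truth: dict[str, Any] = dc_field(default_factory=dict)
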