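"""Pipeline configuration: pydantic-validated schema and packaged
direction-measurement tables."""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .phantom import MotionSpec, PhantomSpec
from .reconstruction import AcquisitionSchedule
from .registration import RegistrationParams


def load_dm_table() -> dict[str, tuple[float, float]]:
    """Packaged phantom-study orientations: name -> (theta_deg, phi_deg)."""
    text = resources.files("octvib.data").joinpath("table_dms.json").read_text()
    d = json.loads(text)
    return {e["name"]: (e["theta_deg"], e["phi_deg"]) for e in d["dms"]}


def phantom_decompositions() -> list[str]:
    """The 13 phantom orthogonal decompositions: Z as reference combined
    with every azimuth-separated pair of A-F."""
    table = load_dm_table()
    names = ["A", "B", "C", "D", "E", "F"]
    excluded = {"ZCD", "ZEF"}  # equal azimuths: singular direction matrix
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            label = f"Z{a}{b}"
            if label not in excluded:
                out.append(label)
    assert len(out) == 13
    return out


class ScheduleConfig(BaseModel):
    n_snapshots: int = 60
    phase_step: float = 2 * np.pi / 15
    pair_dt: float = 9e-6
    wavelength: float = 1310e-9
    stim_freq: float = 1000.0
    n_lateral: int = 512
    slice_step: float = 0.1

    def build(self) -> AcquisitionSchedule:
        return AcquisitionSchedule(**self.model_dump())


class PhantomConfig(BaseModel):
    step_widths: list[float] = [0.9, 0.7, 1.1, 0.5]
    step_heights: list[float] = [0.2, 0.45, 0.8, 0.6]
    cross_widths: list[float] = [1.4, 1.0, 0.8]
    cross_heights: list[float] = [0.0, 0.3, 0.15]
    base_depth: float = 1.6
    base_thickness: float = 0.4
    spacing: float = 0.025
    surface_db: float = 80.0
    decay_db_per_mm: float = 40.0
    background_db: float = 20.0

    def build(self) -> PhantomSpec:
        d = self.model_dump()
        d["step_widths"] = tuple(d["step_widths"])
        d["step_heights"] = tuple(d["step_heights"])
        return PhantomSpec(**d)


class MotionConfig(BaseModel):
    mode: str = "uniform"
    velocity_real: list[float] = [0.1, 0.15, 0.45]
    velocity_imag: list[float] = [0.0, 0.0, 0.0]
    hinge_point: list[float] = [0.0, 0.0, 0.0]
    hinge_axis: list[float] = [1.0, 0.0, 0.0]
    omega: float = 1.0
    phase0: float = 0.0
    frequency: float = 1000.0

    def build(self) -> MotionSpec:
        v = tuple(
            complex(r, i)
            for r, i in zip(self.velocity_real, self.velocity_imag)
        )
        return MotionSpec(
            mode=self.mode, velocity=v,
            hinge_point=tuple(self.hinge_point),
            hinge_axis=tuple(self.hinge_axis),
            omega=self.omega, phase0=self.phase0, frequency=self.frequency,
        )


class DMConfig(BaseModel):
    name: str
    theta_deg: float = Field(ge=0.0, le=180.0)
    phi_deg: float = Field(gt=-180.0, le=180.0)


class RegistrationConfig(BaseModel):
    voxel_size: float = 0.08
    ransac_iterations: int = 8000
    min_fitness: float = 0.3
    jitter_mm: float = 0.0  # optional point jitter added to extracted clouds

    def build(self) -> RegistrationParams:
        return RegistrationParams(
            voxel_size=self.voxel_size,
            ransac_iterations=self.ransac_iterations,
            min_fitness=self.min_fitness,
        )


class PipelineConfig(BaseModel):
    """Full pipeline configuration (simulate -> reconstruct -> register ->
    decompose -> report -> map-to-mesh).  The first DM is the reference."""

    schedule: ScheduleConfig = ScheduleConfig()
    phantom: PhantomConfig = PhantomConfig()
    motion: MotionConfig = MotionConfig()
    dms: list[DMConfig] = Field(min_length=3)
    sigma_n: float = Field(default=1e-4, ge=0.0)
    threshold_db: float = 50.0
    registration: RegistrationConfig = RegistrationConfig()
    seed: int = 0
    mesh_path: str | None = None
    output_dir: str = "results"

    @field_validator("mesh_path")
    @classmethod
    def _mesh_exists(cls, v):
        if v is not None and not Path(v).exists():
            raise ValueError(f"mesh_path does not exist: {v}")
        return v


def default_config(output_dir: str = "results", seed: int = 0) -> PipelineConfig:
    """Three-DM synthetic fixture: reference Z plus orientations A and B."""
    table = load_dm_table()
    dms = [
        DMConfig(name=n, theta_deg=table[n][0], phi_deg=table[n][1])
        for n in ("Z", "A", "B")
    ]
    return PipelineConfig(dms=dms, output_dir=output_dir, seed=seed)


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.model_validate_json(Path(path).read_text())
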