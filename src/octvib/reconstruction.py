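"""Stimulus-synchronous tone reconstruction from OCT phase data.

An acquisition interleaves the beam scan with the acoustic stimulus: at
every lateral position a pair of A-scans separated by ``pair_dt`` yields
one wrapped phase difference, i.e. one instantaneous axial velocity.  The
trigger phase is advanced by ``phase_step`` between snapshots so that the
``n_snapshots`` snapshots sample the stimulus uniformly over an integer
number of cycles (60 snapshots x 2*pi/15 = 4 cycles by default).  A
correlation filter at the stimulus frequency then recovers the complex
tone (amplitude + phase) per pixel.

The pair estimator attenuates a tone at frequency ``f`` by
``sinc(f * pair_dt)`` = ``sin(pi f dt)/(pi f dt)``; at 1 kHz with
dt = 9 us this factor exceeds 0.9998, so samples are treated as
instantaneous velocities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .containers import ComplexVelocityField, VolumeGrid
from .errors import SaturationWarning, UnitError

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Stimulus-synchronous snapshot schedule.

    Attributes
    ----------
    n_snapshots : int
        Snapshots per lateral position (default 60).
    phase_step : float
        Trigger-phase advance between snapshots, rad (default 2*pi/15).
    pair_dt : float
        Time between the two A-scans of a phase-difference pair, s.
    wavelength : float
        Centre wavelength of the source, m.
    stim_freq : float
        Stimulus frequency, Hz.
    n_lateral : int
        Lateral A-scan positions per snapshot.
    slice_step : float
        Slice separation (delta-y) between successive cross-sections, mm.
    """

    n_snapshots: int = 60
    phase_step: float = TWO_PI / 15.0
    pair_dt: float = 9e-6
    wavelength: float = 1310e-9
    stim_freq: float = 1000.0
    n_lateral: int = 512
    slice_step: float = 0.1

    def __post_init__(self) -> None:
        if self.n_snapshots <= 0 or self.pair_dt <= 0 or self.wavelength <= 0:
            raise ValueError("schedule parameters must be positive")
        cycles = self.n_snapshots * self.phase_step / TWO_PI
        if abs(cycles - round(cycles)) > 1e-9 or round(cycles) < 1:
            raise ValueError(
                "n_snapshots * phase_step must span an integer number of "
                f"stimulus cycles (got {cycles:.6g})"
            )

    @property
    def step_cycles(self) -> Fraction:
        """Phase step as an exact fraction of a stimulus cycle."""
        return Fraction(self.phase_step / TWO_PI).limit_denominator(10**6)

    def cumulative_phases(self) -> np.ndarray:
        """phi_c[N] = (N - 1) * phase_step for N = 1..n_snapshots (rad)."""
        return np.arange(self.n_snapshots) * self.phase_step

    def to_dict(self) -> dict:
        return {
            "n_snapshots": self.n_snapshots,
            "phase_step": self.phase_step,
            "pair_dt": self.pair_dt,
            "wavelength": self.wavelength,
            "stim_freq": self.stim_freq,
            "n_lateral": self.n_lateral,
            "slice_step": self.slice_step,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionSchedule":
        return cls(**d)


def phase_to_displacement(dphi: np.ndarray, wavelength: float) -> np.ndarray:
    """Axial displacement (m) from an OCT phase difference (rad):
    ``dz = wavelength * dphi / (4 pi)``."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return np.asarray(dphi) * wavelength / (4.0 * np.pi)


def phase_to_velocity(
    dphi: np.ndarray, schedule: AcquisitionSchedule
) -> np.ndarray:
    """Instantaneous axial velocity (mm/s) from a phase difference:
    ``v = wavelength * dphi / (4 pi pair_dt)``."""
    return (
        phase_to_displacement(dphi, schedule.wavelength) / schedule.pair_dt
    ) * 1e3


def trigger_phase_schedule(
    schedule: AcquisitionSchedule,
) -> tuple[np.ndarray, np.ndarray]:
    """Trigger phases phi_t (wrapped to [0, 2 pi)) and cumulative phases
    phi_c for snapshots N = 1..n_snapshots.

    The wrap is computed in exact rational cycle arithmetic so that
    snapshots completing a whole number of cycles (e.g. N = 16 with the
    default 2*pi/15 step) yield a trigger phase of exactly zero.
    """
    phi_c = schedule.cumulative_phases()
    step = schedule.step_cycles
    frac = [(n * step) % 1 for n in range(schedule.n_snapshots)]
    phi_t = np.array([TWO_PI * float(f) for f in frac])
    return phi_t, phi_c


@dataclass
class SnapshotSeries:
    """Per-pixel instantaneous axial velocities over the snapshot schedule.

    ``values`` has shape ``(n_snapshots, ...)`` in mm/s.  Use
    :meth:`from_phase_differences` when starting from wrapped phase
    differences; amplitudes pushing |dphi| beyond pi are outside the linear
    regime and flagged via ``saturated``.
    """

    values: np.ndarray
    schedule: AcquisitionSchedule = field(default_factory=AcquisitionSchedule)
    saturated: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.schedule.n_snapshots:
            raise ValueError(
                f"series has {self.values.shape[0]} snapshots, schedule "
                f"expects {self.schedule.n_snapshots}"
            )

    @classmethod
    def from_phase_differences(
        cls,
        dphi: np.ndarray,
        schedule: AcquisitionSchedule,
        check_saturation: bool = True,
    ) -> "SnapshotSeries":
        dphi = np.asarray(dphi, dtype=float)
        saturated = bool(np.any(np.abs(dphi) > np.pi))
        if saturated and check_saturation:
            warnings.warn(
                "phase differences exceed (-pi, pi]; vibration amplitude "
                "outside the linear regime",
                SaturationWarning,
            )
        return cls(
            values=phase_to_velocity(dphi, schedule),
            schedule=schedule,
            saturated=saturated,
        )


def reconstruct_tone(
    series: SnapshotSeries | np.ndarray,
    schedule: AcquisitionSchedule | None = None,
) -> ComplexVelocityField:
    """Reconstruct the complex tone response at the stimulus frequency.

    Applies the correlation filter ``v = (2/N) sum_k v_k exp(-i phi_c[k])``
    per pixel.  On the uniform multi-cycle phase grid this recovers a
    noiseless tone ``v_k = A cos(phi_c[k] + phi0)`` exactly as
    ``A exp(i phi0)`` (peak-amplitude convention) and rejects DC and the
    second harmonic exactly.
    """
    if isinstance(series, SnapshotSeries):
        values, schedule = series.values, series.schedule
    else:
        if schedule is None:
            raise ValueError("schedule required for a bare array")
        values = np.asarray(series, dtype=float)
    n = schedule.n_snapshots
    if values.shape[0] < n:
        raise ValueError(
            f"series has {values.shape[0]} snapshots, schedule needs {n}"
        )
    phases = schedule.cumulative_phases()
    kernel = np.exp(-1j * phases) * (2.0 / n)
    v = np.tensordot(kernel, values[:n], axes=(0, 0))
    return ComplexVelocityField(np.asarray(v, dtype=complex))


def background_subtract(
    volume: VolumeGrid, threshold_db: float = 50.0
) -> np.ndarray:
    """Boolean retention mask: reflectivity >= ``threshold_db``.

    The boundary is inclusive so masks are deterministic.  Raises
    :class:`UnitError` unless the volume is flagged as dB.
    """
    if volume.units != "dB":
        raise UnitError(f"expected a dB volume, got units={volume.units!r}")
    return volume.data >= threshold_db


def apply_mask(values: np.ndarray, mask: np.ndarray, fill=np.nan) -> np.ndarray:
    """Invalidate (default: NaN) entries excluded by ``mask``."""
    out = np.array(values, copy=True)
    out[~mask] = fill
    return out
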