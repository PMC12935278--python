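"""Coordinate frames, optical axes, direction matrices and rigid transforms.

The world coordinate system (WCS) is the optical coordinate system (OCS) of
the reference direction measurement, so the reference optical axis is
``z_w = [0, 0, 1]``.  Non-reference optical axes are described either as
unit 3-vectors or in spherical coordinates: polar angle ``theta`` from the
reference optical axis and azimuth ``phi`` from the reference x-axis toward
y (right-handed about z).  All public angles are degrees; radians are used
internally.

A *direction matrix* ``O`` stacks three unit optical axes as rows
(reference first).  Solving ``v = O^-1 m`` recovers the Cartesian complex
velocity vector from three axial projections (the orthogonal
decomposition); the Euclidean norms of the first two rows of ``O^-1`` are
the noise amplification factors (NAF) for the decomposed x and y
components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, SingularDirectionsError

#: |det(O)| at or below this value raises :class:`SingularDirectionsError`.
DET_TOL = 1e-6

Z_AXIS = np.array([0.0, 0.0, 1.0])


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize ``v`` to unit Euclidean length."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0 or not np.isfinite(n):
        raise DegenerateGeometryError("cannot normalize zero/non-finite vector")
    return v / n


def check_unit(v: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Validate that ``v`` is a finite unit 3-vector and return it."""
    v = np.asarray(v, dtype=float).reshape(3)
    if not np.all(np.isfinite(v)):
        raise ValueError("axis has non-finite entries")
    if abs(np.linalg.norm(v) - 1.0) > tol:
        raise ValueError(f"axis is not unit length: |v| = {np.linalg.norm(v)!r}")
    return v


def spherical_to_axis(theta_deg: float, phi_deg: float) -> np.ndarray:
    """Unit optical axis from spherical direction in the WCS.

    Parameters
    ----------
    theta_deg : float
        Polar angle from the reference optical axis, in [0, 180] degrees.
    phi_deg : float
        Azimuth from the reference x-axis toward y, in (-180, 180] degrees.

    Returns
    -------
    ndarray, shape (3,)
        ``[sin(theta) cos(phi), sin(theta) sin(phi), cos(theta)]``.
    """
    if not 0.0 <= theta_deg <= 180.0:
        raise ValueError("theta must lie in [0, 180] degrees")
    if not -180.0 < phi_deg <= 180.0:
        raise ValueError("phi must lie in (-180, 180] degrees")
    th, ph = np.deg2rad(theta_deg), np.deg2rad(phi_deg)
    return np.array(
        [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
    )


def axis_to_spherical(d: np.ndarray) -> tuple[float, float]:
    """Inverse of :func:`spherical_to_axis`; returns (theta_deg, phi_deg)."""
    d = check_unit(d)
    theta = np.rad2deg(np.arccos(np.clip(d[2], -1.0, 1.0)))
    phi = np.rad2deg(np.arctan2(d[1], d[0]))
    if phi <= -180.0:
        phi += 360.0
    return float(theta), float(phi)


def closed_form_determinant(
    theta1_deg: float, phi1_deg: float, theta2_deg: float, phi2_deg: float
) -> float:
    """det(O) of the direction matrix built from two spherical directions.

    For ``O = [z_w, d(theta1, phi1), d(theta2, phi2)]`` the determinant has
    the closed form ``sin(theta1) sin(theta2) sin(phi2 - phi1)``, which
    exposes the singular configurations: either non-reference axis
    approaching the reference axis (theta -> 0), or both non-reference axes
    at the same azimuth (phi2 - phi1 -> 0).
    """
    th1, ph1 = np.deg2rad(theta1_deg), np.deg2rad(phi1_deg)
    th2, ph2 = np.deg2rad(theta2_deg), np.deg2rad(phi2_deg)
    return float(np.sin(th1) * np.sin(th2) * np.sin(ph2 - ph1))


@dataclass(frozen=True)
class DirectionMatrix:
    """Row-stacked unit optical axes (reference first) with inversion
    diagnostics.

    Attributes
    ----------
    matrix : ndarray (3, 3)
        Rows are the unit axes; row 0 is the reference axis.
    inverse : ndarray (3, 3)
        ``matrix^-1``; its first two row norms are the NAFs.
    determinant : float
    naf_x, naf_y : float
        Noise amplification factors of the decomposed x and y components.
    """

    matrix: np.ndarray
    inverse: np.ndarray
    determinant: float
    naf_x: float
    naf_y: float

    @property
    def rows(self) -> np.ndarray:
        return self.matrix

    @property
    def naf_max(self) -> float:
        return max(self.naf_x, self.naf_y)


def build_direction_matrix(
    d2: np.ndarray,
    d3: np.ndarray,
    reference: np.ndarray = Z_AXIS,
    det_tol: float = DET_TOL,
) -> DirectionMatrix:
    """Build the direction matrix ``O = [reference; d2; d3]``.

    Raises
    ------
    SingularDirectionsError
        If ``|det(O)| <= det_tol`` (linearly dependent axes); such
        configurations are treated as ill-conditioned rather than returning
        enormous noise amplification factors.
    """
    rows = np.vstack([check_unit(reference), check_unit(d2), check_unit(d3)])
    det = float(np.linalg.det(rows))
    if abs(det) <= det_tol:
        raise SingularDirectionsError(
            f"optical axes are linearly dependent (|det| = {abs(det):.3g})"
        )
    inv = np.linalg.inv(rows)
    return DirectionMatrix(
        matrix=rows,
        inverse=inv,
        determinant=det,
        naf_x=float(np.linalg.norm(inv[0])),
        naf_y=float(np.linalg.norm(inv[1])),
    )


def direction_matrix_from_angles(
    theta1_deg: float, phi1_deg: float, theta2_deg: float, phi2_deg: float,
    det_tol: float = DET_TOL,
) -> DirectionMatrix:
    """Direction matrix with reference ``z_w`` and two spherical axes."""
    return build_direction_matrix(
        spherical_to_axis(theta1_deg, phi1_deg),
        spherical_to_axis(theta2_deg, phi2_deg),
        det_tol=det_tol,
    )


@dataclass(frozen=True)
class RigidTransform:
    """4x4 homogeneous rotation + translation (translation in mm) mapping
    moving-frame points into the reference frame."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float).reshape(4, 4)
        object.__setattr__(self, "matrix", m)
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-12):
            raise ValueError("last row of a rigid transform must be [0,0,0,1]")
        R = m[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation block must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation(
        cls, R: np.ndarray, t: np.ndarray | None = None
    ) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(R, dtype=float)
        if t is not None:
            m[:3, 3] = np.asarray(t, dtype=float).reshape(3)
        return cls(m)

    @classmethod
    def from_axis_angle(
        cls, axis: np.ndarray, angle_deg: float, t: np.ndarray | None = None
    ) -> "RigidTransform":
        R = Rotation.from_rotvec(unit(axis) * np.deg2rad(angle_deg)).as_matrix()
        return cls.from_rotation(R, t)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points (..., 3) from the moving into the reference frame."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def apply_vector(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate free vectors (no translation)."""
        return np.asarray(vectors) @ self.rotation.T

    def inverse(self) -> "RigidTransform":
        R = self.rotation.T
        return RigidTransform.from_rotation(R, -R @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first."""
        return RigidTransform(self.matrix @ other.matrix)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    # --- serialization (4x4 row-major JSON) -------------------------------
    def to_json(self) -> str:
        return json.dumps(self.matrix.tolist())

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        return cls(np.asarray(json.loads(text), dtype=float))


def axis_from_transform(T: RigidTransform) -> np.ndarray:
    """Estimated optical axis of a registered measurement: the rotated
    reference axis, i.e. the first three rows of the third column of the
    4x4 transform."""
    return T.matrix[:3, 2].copy()


def dm_rotation(theta_deg: float, phi_deg: float) -> np.ndarray:
    """Rotation taking the reference OCS into a measurement OCS whose
    optical axis points along ``spherical_to_axis(theta, phi)``:
    ``Rz(phi) @ Ry(theta)``."""
    return (
        Rotation.from_euler("z", phi_deg, degrees=True).as_matrix()
        @ Rotation.from_euler("y", theta_deg, degrees=True).as_matrix()
    )


def change_basis(v: np.ndarray, T: "RigidTransform | np.ndarray") -> np.ndarray:
    """Rotate a (complex) velocity vector into another frame.

    Only the rotation block acts: velocities are free vectors.  For a
    unitary rotation the Euclidean norm of component amplitudes is
    preserved.
    """
    R = T.rotation if isinstance(T, RigidTransform) else np.asarray(T, dtype=float)
    v = np.asarray(v)
    return v @ R.T


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (for tests and phantom studies)."""
    return Rotation.random(random_state=rng).as_matrix()


@dataclass(frozen=True)
class CoordinateFrame:
    """Right-handed orthonormal frame: rows of ``basis`` are the X, Y, Z
    unit axes expressed in the parent frame; ``origin`` in mm."""

    label: str
    basis: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.basis, dtype=float).reshape(3, 3)
        object.__setattr__(self, "basis", b)
        object.__setattr__(
            self, "origin", np.asarray(self.origin, dtype=float).reshape(3)
        )
        if not np.allclose(b @ b.T, np.eye(3), atol=1e-9):
            raise ValueError("frame basis is not orthonormal")
        if np.linalg.det(b) < 0:
            raise ValueError("frame must be right-handed")


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through points: returns (centroid, unit normal).

    The normal is the singular vector of the smallest singular value of the
    centred point matrix; its sign is arbitrary.
    """
    p = np.asarray(points, dtype=float)
    if p.shape[0] < 3:
        raise DegenerateGeometryError("plane fit needs >= 3 points")
    c = p.mean(axis=0)
    q = p - c
    _, s, vt = np.linalg.svd(q, full_matrices=False)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise DegenerateGeometryError("points are (near-)collinear")
    return c, vt[2]


def construct_acs(
    footplate_points: np.ndarray,
    posterior_process: np.ndarray,
    umbo: np.ndarray,
    medial_hint: np.ndarray,
    superior_hint: np.ndarray | None = None,
    tol: float = 1e-9,
) -> CoordinateFrame:
    """Anatomical coordinate system from middle-ear landmarks.

    Z is the stapes-footplate plane normal oriented along ``medial_hint``
    (pointing medially); Y is the component of the posterior-process ->
    umbo landmark line orthogonal to Z (pointing superiorly, disambiguated
    by ``superior_hint`` if given); X = Y x Z (pointing posteriorly).  Sign
    conventions are anatomical, so the caller supplies hint vectors.
    """
    centroid, n = fit_plane(footplate_points)
    medial_hint = np.asarray(medial_hint, dtype=float)
    if np.dot(n, medial_hint) < 0:
        n = -n
    z = unit(n)
    w = np.asarray(posterior_process, dtype=float) - np.asarray(umbo, dtype=float)
    wn = np.linalg.norm(w)
    if wn == 0:
        raise DegenerateGeometryError("posterior process and umbo coincide")
    y = w - np.dot(w, z) * z
    if np.linalg.norm(y) <= tol * wn:
        raise DegenerateGeometryError(
            "landmark line is parallel to the footplate normal"
        )
    y = unit(y)
    if superior_hint is not None and np.dot(y, np.asarray(superior_hint)) < 0:
        y = -y
    x = np.cross(y, z)
    return CoordinateFrame(label="ACS", basis=np.vstack([x, y, z]), origin=centroid)
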