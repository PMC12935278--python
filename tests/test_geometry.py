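"""Direction matrices, spherical axes, rigid transforms and the
anatomical frame."""

import numpy as np
import pytest

from octvib.errors import DegenerateGeometryError, SingularDirectionsError
from octvib.geometry import (
    CoordinateFrame,
    RigidTransform,
    axis_from_transform,
    axis_to_spherical,
    build_direction_matrix,
    change_basis,
    closed_form_determinant,
    construct_acs,
    direction_matrix_from_angles,
    dm_rotation,
    random_rotation,
    spherical_to_axis,
)


@pytest.mark.parametrize(
    "theta, phi, expected",
    [
        (0.0, 0.0, [0.0, 0.0, 1.0]),
        (90.0, 90.0, [0.0, 1.0, 0.0]),
        (90.0, 0.0, [1.0, 0.0, 0.0]),
        (40.0, 60.0, [0.3214, 0.5567, 0.7660]),
    ],
)
def test_spherical_to_axis(theta, phi, expected):
    d = spherical_to_axis(theta, phi)
    assert np.allclose(d, expected, atol=1e-4)
    assert abs(np.linalg.norm(d) - 1.0) < 1e-12


def test_spherical_to_axis_rejects_out_of_range():
    with pytest.raises(ValueError):
        spherical_to_axis(-1.0, 0.0)
    with pytest.raises(ValueError):
        spherical_to_axis(45.0, 181.0)


def test_axis_to_spherical_round_trip(rng):
    for _ in range(50):
        theta = rng.uniform(1.0, 179.0)
        phi = rng.uniform(-179.0, 180.0)
        t2, p2 = axis_to_spherical(spherical_to_axis(theta, phi))
        assert abs(t2 - theta) < 1e-9
        assert abs(p2 - phi) < 1e-9


def test_orthonormal_direction_matrix_is_permutation_with_unit_nafs():
    O = build_direction_matrix([1, 0, 0], [0, 1, 0])
    assert abs(abs(O.determinant) - 1.0) < 1e-12
    assert abs(O.naf_x - 1.0) < 1e-12
    assert abs(O.naf_y - 1.0) < 1e-12
    assert np.allclose(O.inverse @ O.matrix, np.eye(3), atol=1e-12)


def test_dependent_axes_raise_singular():
    with pytest.raises(SingularDirectionsError):
        build_direction_matrix([0, 0, 1], [0, 0, 1])


def test_phantom_pair_determinant_matches_closed_form():
    # orientations (40, 0) and (30, 30): |det| = sin40 sin30 sin30
    O = direction_matrix_from_angles(40, 0, 30, 30)
    expected = np.sin(np.deg2rad(40)) * 0.5 * 0.5
    assert abs(abs(O.determinant) - expected) < 1e-12
    assert abs(closed_form_determinant(40, 0, 30, 30) - O.determinant) < 1e-12


def test_closed_form_determinant_printed_angles():
    # the ex-vivo measurement geometry: d2(20, -143), d3(45, -177)
    assert abs(closed_form_determinant(20, -143, 45, -177) - (-0.1352)) < 1e-4


def test_closed_form_matches_numeric_over_random_angles(rng):
    for _ in range(1000):
        t1, t2 = rng.uniform(0, 180, 2)
        p1, p2 = rng.uniform(-179.999, 180, 2)
        rows = np.vstack(
            [[0, 0, 1], spherical_to_axis(t1, p1), spherical_to_axis(t2, p2)]
        )
        assert abs(
            closed_form_determinant(t1, p1, t2, p2) - np.linalg.det(rows)
        ) < 1e-12


def test_reference_axis_singularity():
    assert closed_form_determinant(0.0, 0.0, 45.0, 90.0) == 0.0
    with pytest.raises(SingularDirectionsError):
        direction_matrix_from_angles(0.0, 0.0, 45.0, 90.0)


def test_inverse_third_row_is_reference_selector(rng):
    """With reference row [0,0,1] the decomposed z-component is the
    reference measurement itself: row 3 of the inverse is [1,0,0]."""
    n = 0
    while n < 100:
        t1, t2 = rng.uniform(5, 175, 2)
        p1, p2 = rng.uniform(-179, 180, 2)
        if abs(closed_form_determinant(t1, p1, t2, p2)) < 1e-3:
            continue
        O = direction_matrix_from_angles(t1, p1, t2, p2)
        assert np.allclose(O.inverse[2], [1.0, 0.0, 0.0], atol=1e-12)
        assert O.naf_x > 0 and O.naf_y > 0
        n += 1


def test_axis_from_transform_examples(rng):
    assert np.allclose(axis_from_transform(RigidTransform.identity()), [0, 0, 1])
    T = RigidTransform.from_axis_angle([1, 0, 0], 90.0)
    assert np.allclose(axis_from_transform(T), [0, -1, 0], atol=1e-12)
    for _ in range(100):
        R = random_rotation(rng)
        T = RigidTransform.from_rotation(R, rng.normal(size=3))
        assert np.allclose(axis_from_transform(T), R @ [0, 0, 1], atol=1e-12)


def test_dm_rotation_takes_z_to_spherical_axis(rng):
    for _ in range(50):
        th = rng.uniform(0, 180)
        ph = rng.uniform(-179, 180)
        assert np.allclose(
            dm_rotation(th, ph) @ [0, 0, 1], spherical_to_axis(th, ph), atol=1e-12
        )


def test_change_basis(rng):
    v = np.array([1 + 2j, -0.5j, 0.25])
    assert np.allclose(change_basis(v, RigidTransform.identity()), v)
    Tz = RigidTransform.from_axis_angle([0, 0, 1], 90.0)
    assert np.allclose(change_basis([1, 0, 0], Tz), [0, 1, 0], atol=1e-12)
    for _ in range(20):
        R = random_rotation(rng)
        vv = rng.normal(size=3) + 1j * rng.normal(size=3)
        out = change_basis(vv, RigidTransform.from_rotation(R))
        assert np.allclose(out, R @ vv, atol=1e-12)
        assert abs(
            np.linalg.norm(np.abs(out)) - np.linalg.norm(np.abs(vv))
        ) < 1e-10


def test_rigid_transform_validation():
    bad = np.eye(4)
    bad[3, 0] = 1.0
    with pytest.raises(ValueError):
        RigidTransform(bad)
    shear = np.eye(4)
    shear[0, 1] = 0.5
    with pytest.raises(ValueError):
        RigidTransform(shear)


def test_rigid_transform_inverse_compose_round_trip(rng):
    T = RigidTransform.from_axis_angle(rng.normal(size=3), 33.0, rng.normal(size=3))
    assert np.allclose((T @ T.inverse()).matrix, np.eye(4), atol=1e-12)
    p = rng.normal(size=(10, 3))
    assert np.allclose(T.inverse().apply(T.apply(p)), p, atol=1e-12)
    T2 = RigidTransform.from_json(T.to_json())
    assert np.allclose(T2.matrix, T.matrix)


def test_construct_acs_canonical():
    rng = np.random.default_rng(0)
    pts = np.column_stack(
        [rng.uniform(-1, 1, 30), rng.uniform(-1, 1, 30), np.zeros(30)]
    )
    frame = construct_acs(pts, posterior_process=[0, 2, 0], umbo=[0, 0, 0],
                          medial_hint=[0, 0, 1])
    assert np.allclose(frame.basis, np.eye(3), atol=1e-9)


def test_construct_acs_projects_tilted_landmark_line():
    rng = np.random.default_rng(1)
    pts = np.column_stack(
        [rng.uniform(-1, 1, 30), rng.uniform(-1, 1, 30), np.zeros(30)]
    )
    frame = construct_acs(pts, posterior_process=[0, 1, 1], umbo=[0, 0, 0],
                          medial_hint=[0, 0, 1])
    assert abs(np.dot(frame.basis[1], frame.basis[2])) < 1e-12
    assert np.allclose(frame.basis[1], [0, 1, 0], atol=1e-9)


def test_construct_acs_random_orthonormal_right_handed(rng):
    for _ in range(25):
        R = random_rotation(rng)
        pts = (np.column_stack(
            [rng.uniform(-1, 1, 40), rng.uniform(-1, 1, 40), np.zeros(40)]
        ) @ R.T) + rng.normal(size=3)
        pp, um = rng.normal(size=3), rng.normal(size=3)
        if np.linalg.norm(np.cross(pp - um, R @ [0, 0, 1])) < 1e-2:
            continue
        frame = construct_acs(pts, pp, um, medial_hint=R @ [0, 0, 1])
        b = frame.basis
        assert np.allclose(b @ b.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(b) > 0
        # Gram-Schmidt oracle for the Y axis
        z = b[2]
        w = pp - um
        y = w - np.dot(w, z) * z
        y = y / np.linalg.norm(y)
        assert min(np.linalg.norm(b[1] - y), np.linalg.norm(b[1] + y)) < 1e-9


def test_construct_acs_degenerate_landmarks():
    pts = np.column_stack(
        [np.linspace(-1, 1, 20), np.linspace(-1, 1, 20) ** 2, np.zeros(20)]
    )
    with pytest.raises(DegenerateGeometryError):
        construct_acs(pts, posterior_process=[0, 0, 2], umbo=[0, 0, 0],
                      medial_hint=[0, 0, 1])
    with pytest.raises(DegenerateGeometryError):
        construct_acs(pts, posterior_process=[1, 1, 0], umbo=[1, 1, 0],
                      medial_hint=[0, 0, 1])


def test_coordinate_frame_rejects_left_handed():
    with pytest.raises(ValueError):
        CoordinateFrame("OCS", np.diag([1.0, 1.0, -1.0]), np.zeros(3))
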