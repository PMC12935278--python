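"""Surface extraction, rigid registration, cross-section assembly,
multi-measurement fusion and mesh mapping."""

import numpy as np
import pytest
import trimesh

from octvib.containers import VolumeGrid
from octvib.errors import (
    DegenerateGeometryError,
    EmptyCloudError,
    RegistrationWarning,
)
from octvib.geometry import RigidTransform
from octvib.phantom import MotionSpec, make_phantom, simulate_dm
from octvib.registration import (
    SurfaceCloud,
    align_mb_to_c,
    assemble_mc,
    extract_surface,
    fuse_dms,
    map_to_mesh,
    register_clouds,
    registration_error_planes,
)


@pytest.fixture(scope="module")
def stair_cloud(request):
    """Surface cloud of the coarse phantom, subsampled for speed."""
    from octvib.phantom import PhantomSpec

    vol, _ = make_phantom(PhantomSpec(spacing=0.05))
    cloud = extract_surface(vol, 50.0)
    return SurfaceCloud(cloud.points[::6], cloud.spacing)


def test_extract_surface_flat_slab():
    data = np.full((6, 5, 10), 20.0)
    data[:, :, 4:] = 60.0  # slab starting at depth index 4
    vol = VolumeGrid(data, spacing=[0.1, 0.1, 0.05], origin=[0, 0, 1.0])
    cloud = extract_surface(vol, 50.0)
    assert len(cloud.points) == 30
    assert np.allclose(cloud.points[:, 2], 1.0 + 4 * 0.05)


def test_extract_surface_matches_analytic_stair(coarse_spec):
    vol, surface = make_phantom(coarse_spec)
    cloud = extract_surface(vol, 50.0)
    s = surface(cloud.points[:, 0], cloud.points[:, 1])
    ok = np.isfinite(s)
    # first-crossing depth equals the analytic surface within one voxel
    assert np.all(np.abs(cloud.points[ok, 2] - s[ok]) <= coarse_spec.spacing + 1e-12)
    # the designed step heights appear as distinct surface levels
    levels = np.unique(np.round(s[ok], 6))
    assert len(levels) >= len(coarse_spec.step_heights)


def test_extract_surface_empty():
    vol = VolumeGrid(np.full((4, 4, 4), 10.0), spacing=[0.1] * 3)
    with pytest.raises(EmptyCloudError):
        extract_surface(vol, 50.0)


def test_register_identical_clouds_is_identity(stair_cloud):
    fixed = SurfaceCloud(stair_cloud.points.copy(), stair_cloud.spacing)
    reg = register_clouds(stair_cloud, fixed, seed=0)
    assert np.abs(reg.transform.matrix - np.eye(4)).max() < 1e-6
    assert reg.inlier_fraction > 0.99


def test_register_known_rotation_with_jitter(stair_cloud, rng):
    """A 10 degree rotation with 10 um point jitter is recovered with
    axis-direction error at the sub-half-degree level."""
    T = RigidTransform.from_axis_angle(rng.normal(size=3), 10.0, [0.2, -0.1, 0.05])
    moving = SurfaceCloud(
        T.inverse().apply(stair_cloud.points)
        + rng.normal(0, 0.010, stair_cloud.points.shape),
        stair_cloud.spacing,
    )
    reg = register_clouds(moving, stair_cloud, seed=1)
    true_axis = T.inverse().rotation.T @ [0, 0, 1]
    err = np.rad2deg(np.arccos(np.clip(abs(reg.axis @ true_axis), 0, 1)))
    assert err <= 0.4


def test_register_exact_for_noiseless_rotations(stair_cloud, rng):
    """Noiseless transformed copies are recovered to machine precision
    for rotations up to 45 degrees."""
    for trial in range(20):
        axis = rng.normal(size=3)
        angle = rng.uniform(5.0, 45.0)
        T = RigidTransform.from_axis_angle(axis, angle, rng.uniform(-0.5, 0.5, 3))
        moving = SurfaceCloud(
            T.inverse().apply(stair_cloud.points), stair_cloud.spacing
        )
        reg = register_clouds(moving, stair_cloud, seed=trial)
        assert np.abs(reg.transform.matrix - T.inverse().inverse().matrix).max() < 1e-6


def test_register_single_plane_warns(rng):
    pts = np.column_stack(
        [rng.uniform(0, 2, 400), rng.uniform(0, 2, 400), np.zeros(400)]
    )
    with pytest.warns(RegistrationWarning):
        register_clouds(
            SurfaceCloud(pts, 0.05), SurfaceCloud(pts.copy(), 0.05), seed=0
        )


def test_register_rejects_tiny_clouds():
    pts = np.random.default_rng(0).normal(size=(10, 3))
    with pytest.raises(DegenerateGeometryError):
        register_clouds(SurfaceCloud(pts, 0.1), SurfaceCloud(pts, 0.1))


def test_plane_angle_metric(rng):
    pts = np.column_stack(
        [rng.uniform(0, 1, 500), rng.uniform(0, 1, 500), np.zeros(500)]
    )
    assert registration_error_planes(pts, pts.copy()) < 1e-9
    # normals constructed 1 degree apart
    tilt = RigidTransform.from_axis_angle([0, 1, 0], 1.0)
    assert abs(registration_error_planes(pts, tilt.apply(pts)) - 1.0) < 1e-6
    # invariant to in-plane rotation of the point sets
    spin = RigidTransform.from_axis_angle([0, 0, 1], 37.0)
    assert registration_error_planes(pts, spin.apply(pts)) < 1e-9
    with pytest.raises(DegenerateGeometryError):
        registration_error_planes(pts[:2], pts[:2])


@pytest.fixture(scope="module")
def coarse_volume():
    from octvib.phantom import PhantomSpec

    vol, _ = make_phantom(PhantomSpec(spacing=0.05))
    return vol


def test_align_mb_zero_shift(coarse_volume):
    j = coarse_volume.shape[1] // 2
    mb = coarse_volume.data[:, j, :]
    prealign = coarse_volume.origin + [0.0, j * coarse_volume.spacing[1], 0.0]
    shift = align_mb_to_c(mb, coarse_volume, prealign)
    assert np.allclose(shift, prealign, atol=1e-9)


def test_align_mb_recovers_integer_offset():
    # a smooth random volume: every slice is unique, so all three shift
    # components are observable
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(7)
    data = gaussian_filter(rng.normal(size=(24, 16, 20)), 2.0) * 100 + 50
    vol = VolumeGrid(data, spacing=[0.05, 0.05, 0.05])
    j = 8
    mb = vol.data[:, j, :]
    sp = vol.spacing
    true_pos = vol.origin + [0.0, j * sp[1], 0.0]
    # pretend the calibration pre-alignment is off by (2, -1, 1) voxels
    prealign = true_pos + np.array([2, -1, 1]) * sp
    shift = align_mb_to_c(mb, vol, prealign)
    assert np.allclose(shift, true_pos, atol=1e-9)


def test_align_mb_noise_slice_warns(coarse_volume, rng):
    mb = rng.normal(size=(coarse_volume.shape[0], coarse_volume.shape[2]))
    prealign = coarse_volume.origin.copy()
    with pytest.warns(RegistrationWarning):
        align_mb_to_c(mb, coarse_volume, prealign)


def _small_volume():
    data = np.full((6, 4, 5), 60.0)
    return VolumeGrid(data, spacing=[0.1, 0.1, 0.1])


def test_assemble_mc_copies_verbatim():
    vol = _small_volume()
    vals = (np.arange(30).reshape(6, 5) + 1.0) * (1 + 1j)
    mask2d = np.ones((6, 5), dtype=bool)
    mask3d = np.zeros(vol.shape, dtype=bool)
    mask3d[:, 1, :] = True
    out = assemble_mc(
        [(vals, mask2d, vol.origin + [0, 0.1, 0])], vol, mask3d
    )
    assert np.allclose(out.velocity[:, 1, :], vals)
    assert np.isnan(out.velocity[:, 0, :].real).all()


def test_assemble_mc_matches_nearest_neighbor_oracle(rng):
    vol = _small_volume()
    slices = []
    pts, vals = [], []
    for j, y in ((0, 0.05), (2, 0.25)):
        v = rng.normal(size=(6, 5)) + 1j * rng.normal(size=(6, 5))
        m = rng.random((6, 5)) > 0.3
        shift = vol.origin + [0.0, y, 0.0]
        slices.append((v, m, shift))
        ix, iz = np.nonzero(m)
        for a, b in zip(ix, iz):
            pts.append([a * 0.1, y, b * 0.1])
            vals.append(v[a, b])
    mask3d = np.ones(vol.shape, dtype=bool)
    out = assemble_mc(slices, vol, mask3d, radius=0.15)
    pts = np.array(pts)
    vals = np.array(vals)
    filled = ~np.isnan(out.velocity.real)
    # oracle: brute-force nearest neighbour, smallest index on ties,
    # no extrapolation
    centers = vol.voxel_centers()
    d = np.linalg.norm(centers[:, None, :] - pts[None, :, :], axis=2)
    dmin = d.min(axis=1)
    nn = np.array(
        [np.nonzero(np.abs(row - m) < 1e-12)[0].min() for row, m in zip(d, dmin)]
    )
    expect_filled = dmin <= 0.15
    assert filled.sum() == expect_filled.sum()
    got = out.velocity.reshape(-1)[expect_filled]
    assert np.allclose(got, vals[nn[expect_filled]])
    # resampling never invents values
    assert set(np.round(got, 12)) <= set(np.round(vals, 12))


def test_assemble_mc_empty_stack():
    vol = _small_volume()
    with pytest.raises(ValueError):
        assemble_mc([], vol, np.ones(vol.shape, dtype=bool))


@pytest.fixture(scope="module")
def fused_noiseless():
    from octvib.phantom import PhantomSpec
    from octvib.reconstruction import AcquisitionSchedule

    spec = PhantomSpec(spacing=0.05)
    sched = AcquisitionSchedule()
    v_true = (0.3 + 0.1j, 0.2 - 0.05j, 0.4 + 0.2j)
    motion = MotionSpec(velocity=v_true)
    ref = simulate_dm(spec, motion, sched, 0.0, seed=0, name="Z")
    dms = [
        simulate_dm(spec, motion, sched, 0.0, seed=i + 1,
                    theta_deg=th, phi_deg=ph, name=n)
        for i, (n, th, ph) in enumerate([("A", 40, 0), ("B", 30, 30)])
    ]
    return spec, v_true, ref, dms


def test_fuse_dms_recovers_uniform_motion(fused_noiseless):
    _, v_true, ref, dms = fused_noiseless
    fused = fuse_dms(
        ref, [(d, d.truth["transform"], d.truth["axis"]) for d in dms]
    )
    pts, vals = fused.points_and_values()
    assert len(vals) > 1000
    assert np.abs(vals - np.array(v_true)).max() < 1e-6
    assert fused.n_singular == 0


def test_fuse_dms_requires_three_contributions(fused_noiseless):
    _, _, ref, dms = fused_noiseless
    fused = fuse_dms(ref, [(dms[0], dms[0].truth["transform"],
                            dms[0].truth["axis"])])
    assert fused.decomposed_mask.sum() == 0
    assert fused.counts.max() <= 2


def test_fuse_dms_skips_singular_axes(fused_noiseless):
    _, _, ref, dms = fused_noiseless
    # both non-reference axes along the reference axis: locally singular
    bad_axis = np.array([0.0, 0.0, 1.0])
    fused = fuse_dms(
        ref,
        [(dms[0], dms[0].truth["transform"], bad_axis),
         (dms[1], dms[1].truth["transform"], bad_axis)],
    )
    assert fused.decomposed_mask.sum() == 0
    assert fused.n_singular > 0


def _grid_mesh(n=20, pitch=0.05):
    x, y = np.meshgrid(np.arange(n) * pitch, np.arange(n) * pitch)
    verts = np.column_stack([x.ravel(), y.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def test_map_to_mesh_assignment_and_floor_filter():
    mesh = _grid_mesh()
    pts = np.array([[0.5, 0.5, 0.05], [0.7, 0.7, 0.05]])
    vals = np.array([[1.0 + 0j, 0, 0], [0.001 + 0j, 0, 0]])  # 2nd below floor
    out = map_to_mesh(pts, vals, mesh, a_min_decomposed=0.01, max_dist=0.1)
    assert out["assigned"].any()
    vi = np.linalg.norm(mesh.vertices - [0.5, 0.5, 0.0], axis=1).argmin()
    assert abs(out["amplitude"][vi, 0] - 1.0) < 1e-12
    # the sub-floor datapoint must not appear anywhere
    finite = np.isfinite(out["amplitude"][:, 0])
    assert not np.any(np.isclose(out["amplitude"][finite, 0], 0.001))
    # boundary extrapolation fills the remaining vertices along the mesh
    assert out["filled"].all()
    assert np.allclose(out["amplitude"][finite, 0], 1.0)


def test_map_to_mesh_all_far_warns():
    mesh = _grid_mesh()
    pts = np.array([[5.0, 5.0, 5.0]])
    vals = np.array([[1.0 + 0j, 0, 0]])
    with pytest.warns(RegistrationWarning):
        out = map_to_mesh(pts, vals, mesh, a_min_decomposed=0.01, max_dist=0.1)
    assert not out["assigned"].any()
    assert not out["filled"].any()
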