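"""Optical-axis estimation and multi-direction assembly by surface
point-cloud registration.

Surfaces are extracted from C-scans as the first above-threshold voxel
along the depth axis of each transverse column.  The surface cloud of a
non-reference measurement is aligned to the reference cloud in two
stages: a coarse alignment that pools hypotheses from RANSAC over
descriptor-matched salient points and from a heightfield rotation scan
(both exploit that beam-scanned surfaces are oriented toward the
source), then refinement with point-to-plane ICP augmented by
edge-point constraints and a final point-to-point polish.  The
estimated optical axis of the measurement is the rotated depth axis of
the recovered 4x4 transform.  Registration quality is quantified by the plane-angle
registration error: the acute angle between least-squares planes fitted
to the designated upper horizontal surface of the fixed and the
transformed moving cloud.

Velocity data from aligned cross-sections (or whole measurements) are
assembled by scattered nearest-neighbour interpolation with no
extrapolation: a grid voxel is filled only if a data point lies within
the support radius (default 1.5 x the maximum voxel pitch), and filled
values are always original measured values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .containers import DirectionMeasurement, VolumeGrid
from .decomposition import decompose
from .errors import (
    DegenerateGeometryError,
    EmptyCloudError,
    RegistrationWarning,
    SingularDirectionsError,
)
from .geometry import (
    RigidTransform,
    axis_from_transform,
    build_direction_matrix,
    fit_plane,
)
from .reconstruction import background_subtract


@dataclass
class SurfaceCloud:
    """Extracted surface points (N, 3) in mm, plus the source grid pitch."""

    points: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("surface cloud contains non-finite coordinates")


def extract_surface(volume: VolumeGrid, threshold_db: float = 50.0) -> SurfaceCloud:
    """First-crossing surface extraction.

    For every transverse (x, y) column the first voxel along the optical
    axis with reflectivity >= threshold becomes a surface point in
    physical mm.  Raises :class:`EmptyCloudError` when nothing passes.
    """
    mask = background_subtract(volume, threshold_db)
    hit = mask.any(axis=2)
    if not hit.any():
        raise EmptyCloudError("no voxel above the reflectivity threshold")
    k = np.argmax(mask, axis=2)
    ix, iy = np.nonzero(hit)
    idx = np.column_stack([ix, iy, k[ix, iy]])
    return SurfaceCloud(volume.index_to_world(idx), float(volume.spacing.max()))


@dataclass
class RegistrationParams:
    """Tunables of the RANSAC + ICP registration."""

    voxel_size: float = 0.08  # mm, downsampling pitch for matching
    ransac_iterations: int = 8000
    descriptor_neighbors: int = 16
    candidate_matches: int = 6
    inlier_threshold: float | None = None  # default 1.5 * voxel_size
    min_triangle_edge: float | None = None  # default 5 * voxel_size
    icp_max_iterations: int = 200
    icp_tolerance: float = 1e-8
    icp_max_correspondence: float | None = None  # default 3 * voxel_size
    icp_normal_threshold_deg: float = 45.0  # reject incompatible normals
    edge_normal_spread: float = 0.97  # |n.n_nb| mean below this marks edges
    n_hypotheses: int = 5
    max_icp_points: int = 2500
    score_points: int = 400
    min_points: int = 100
    min_fitness: float = 0.3

    @property
    def thr(self) -> float:
        return self.inlier_threshold or 1.5 * self.voxel_size


@dataclass
class RegistrationResult:
    """Outcome of one cloud-to-cloud rigid registration."""

    transform: RigidTransform
    inlier_fraction: float
    rms: float
    converged: bool

    @property
    def axis(self) -> np.ndarray:
        return axis_from_transform(self.transform)


def _voxel_downsample(points: np.ndarray, size: float) -> np.ndarray:
    """Deterministic voxel-grid downsampling: the lowest-index point of
    each occupied cell is kept (smallest index wins)."""
    keys = np.floor((points - points.min(axis=0)) / size).astype(np.int64)
    _, first = np.unique(keys, axis=0, return_index=True)
    return points[np.sort(first)]


def _normals(points: np.ndarray, k: int = 12) -> np.ndarray:
    """Local PCA normals, oriented to face the beam (n_z <= 0 in the
    cloud's own frame; first-crossing surfaces always face the source)."""
    tree = cKDTree(points)
    _, idx = tree.query(points, k=min(k, len(points)))
    nb = points[idx]
    nb = nb - nb.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", nb, nb)
    _, vecs = np.linalg.eigh(cov)
    n = vecs[:, :, 0]
    # deterministic orientation: prefer -z, tie-break on -x then -y
    sign = np.where(
        np.abs(n[:, 2]) > 1e-6, -np.sign(n[:, 2]),
        np.where(np.abs(n[:, 0]) > 1e-6, -np.sign(n[:, 0]),
                 -np.sign(n[:, 1] + 1e-300)),
    )
    return n * sign[:, None]


def _descriptors(points: np.ndarray, normals: np.ndarray, k: int) -> np.ndarray:
    """Rotation-invariant local-shape descriptor: normalized covariance
    eigenvalue features plus normal-agreement statistics."""
    tree = cKDTree(points)
    _, idx = tree.query(points, k=min(k, len(points)))
    nb = points[idx] - points[idx].mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", nb, nb)
    vals = np.linalg.eigvalsh(cov)[:, ::-1]  # descending
    vals = vals / np.maximum(vals[:, :1], 1e-300)
    dots = np.abs(np.einsum("ni,nki->nk", normals, normals[idx]))
    return np.column_stack(
        [
            (vals[:, 0] - vals[:, 1]),  # linearity
            (vals[:, 1] - vals[:, 2]),  # planarity
            vals[:, 2],                 # scatter
            dots.mean(axis=1),
            dots.std(axis=1),
        ]
    )


def _kabsch(a: np.ndarray, b: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping points ``a`` onto ``b``."""
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    H = (a - ca).T @ (b - cb)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform.from_rotation(R, cb - R @ ca)


def _rotation_angle_deg(Ra: np.ndarray, Rb: np.ndarray) -> float:
    c = (np.trace(Ra @ Rb.T) - 1.0) / 2.0
    return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


def _ransac_coarse(
    moving: np.ndarray,
    fixed: np.ndarray,
    params: RegistrationParams,
    rng: np.random.Generator,
) -> list[RigidTransform]:
    """Descriptor-correspondence RANSAC; returns up to ``n_hypotheses``
    rotation-diverse candidate transforms ranked by inlier fraction."""
    nm = _normals(moving)
    nf = _normals(fixed)
    dm = _descriptors(moving, nm, params.descriptor_neighbors)
    df = _descriptors(fixed, nf, params.descriptor_neighbors)
    # sample and match only salient (edge/corner) points: descriptors of
    # planar patches do not localize, so flat-region correspondences are
    # uninformative
    def salient(desc):
        score = 1.0 - desc[:, 3] + desc[:, 2]  # normal spread + scatter
        n_keep = max(50, len(desc) // 4)
        return np.argsort(score)[::-1][: min(n_keep, len(desc))]

    sal_m = salient(dm)
    sal_f = salient(df)
    mu, sd = df[sal_f].mean(axis=0), df[sal_f].std(axis=0) + 1e-12
    tree = cKDTree((df[sal_f] - mu) / sd)
    kc = min(params.candidate_matches, len(sal_f))
    _, cand_s = tree.query((dm[sal_m] - mu) / sd, k=kc)
    cand_s = np.atleast_2d(cand_s.reshape(len(sal_m), -1))

    score_idx = np.linspace(
        0, len(moving) - 1, min(params.score_points, len(moving))
    ).astype(int)
    score_pts = moving[score_idx]
    score_nm = nm[score_idx]
    ftree = cKDTree(fixed)
    min_edge = params.min_triangle_edge or 5 * params.voxel_size
    edge_tol = 2.0 * params.voxel_size
    hyps: list[tuple[tuple, RigidTransform]] = []
    ns = len(sal_m)
    for _ in range(params.ransac_iterations):
        s3 = rng.choice(ns, 3, replace=False)
        i3 = sal_m[s3]
        j3 = sal_f[cand_s[s3, rng.integers(0, kc, 3)]]
        if len(set(j3.tolist())) < 3:
            continue
        a, b = moving[i3], fixed[j3]
        ok = True
        for p, q in ((0, 1), (0, 2), (1, 2)):
            da = np.linalg.norm(a[p] - a[q])
            if da < min_edge or abs(da - np.linalg.norm(b[p] - b[q])) > edge_tol:
                ok = False
                break
        if not ok:
            continue
        T = _kabsch(a, b)
        # normal consistency of the sample itself (cheap flip rejection)
        if np.any(np.einsum("ni,ni->n", nm[i3] @ T.rotation.T, nf[j3]) < 0.0):
            continue
        d, jn = ftree.query(T.apply(score_pts))
        # inliers must agree in position and oriented normal (rejects
        # flipped plane-on-plane alignments)
        agree = np.einsum("ni,ni->n", score_nm @ T.rotation.T, nf[jn]) > 0.5
        inl = (d < params.thr) & agree
        frac = inl.mean()
        key = (frac, -(d[inl].mean() if inl.any() else np.inf))
        # keep the best few rotation-diverse hypotheses
        merged = False
        for k, (key0, T0) in enumerate(hyps):
            if _rotation_angle_deg(T.rotation, T0.rotation) < 3.0:
                if key > key0:
                    hyps[k] = (key, T)
                merged = True
                break
        if not merged:
            hyps.append((key, T))
        hyps.sort(key=lambda h: h[0], reverse=True)
        del hyps[params.n_hypotheses:]
    return [T for _, T in hyps]


def _dominant_normal(normals: np.ndarray) -> np.ndarray:
    """Mode of the oriented normal distribution (mean-shift refinement of
    the mean; the dominant flat surface wins)."""
    m = normals.mean(axis=0)
    m = m / np.linalg.norm(m)
    for _ in range(4):
        sel = normals @ m > np.cos(np.deg2rad(25.0))
        if sel.sum() < 3:
            break
        m = normals[sel].mean(axis=0)
        m = m / np.linalg.norm(m)
    return m


def _minimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smallest rotation taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(np.dot(a, b))
    if s < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3) + 2 * np.outer(a, a)
    return _small_rotation(v / s * np.arctan2(s, c))


def _height_image(points: np.ndarray, origin: np.ndarray, pix: float,
                  shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    ij = np.floor((points[:, :2] - origin) / pix).astype(int)
    ok = (ij[:, 0] >= 0) & (ij[:, 0] < shape[0]) & (ij[:, 1] >= 0) & (
        ij[:, 1] < shape[1]
    )
    ij = ij[ok]
    z = points[ok, 2]
    H = np.full(shape, np.inf)
    # top surface = smallest depth per pixel
    np.minimum.at(H, (ij[:, 0], ij[:, 1]), z)
    M = np.isfinite(H)
    H[~M] = 0.0
    return H, M.astype(float)


def _plane_scan_hypotheses(
    moving: np.ndarray,
    m_normals: np.ndarray,
    fixed: np.ndarray,
    f_normals: np.ndarray,
    params: RegistrationParams,
    n_psi: int = 48,
    pix: float = 0.1,
) -> list[RigidTransform]:
    """Heightfield hypothesis generator for beam-scanned surfaces.

    The dominant oriented surface normals of the two clouds are aligned
    (2 rotational DOF); the remaining rotation about that normal is
    scanned on a regular grid, and for each candidate angle the in-plane
    translation is recovered by masked correlation of the rasterized
    top-surface height images (the out-of-plane shift from the mean
    height difference of the overlap).  Complements correspondence
    RANSAC, whose local descriptors do not discriminate on piecewise-flat
    geometry."""
    from scipy.signal import fftconvolve

    nf0 = _dominant_normal(f_normals)
    nm0 = _dominant_normal(m_normals)
    R1 = _minimal_rotation(nm0, nf0)
    lo_f = fixed[:, :2].min(axis=0)
    hi_f = fixed[:, :2].max(axis=0)
    out = []
    Hf = Mf = None
    for psi in np.linspace(0.0, 2 * np.pi, n_psi, endpoint=False):
        R = _small_rotation(nf0 * psi) @ R1
        pm = moving @ R.T
        lo = np.minimum(lo_f, pm[:, :2].min(axis=0)) - pix
        hi = np.maximum(hi_f, pm[:, :2].max(axis=0)) + pix
        shape = (int((hi[0] - lo[0]) / pix) + 2, int((hi[1] - lo[1]) / pix) + 2)
        Hm, Mm = _height_image(pm, lo, pix, shape)
        Hf, Mf = _height_image(fixed, lo, pix, shape)
        # per-shift mean-offset-corrected SSD via correlations
        k = Mm[::-1, ::-1]
        kh = (Hm * Mm)[::-1, ::-1]
        kh2 = (Hm**2 * Mm)[::-1, ::-1]
        n_ov = fftconvolve(Mf, k, mode="full")
        s_f = fftconvolve(Hf * Mf, k, mode="full")
        s_f2 = fftconvolve(Hf**2 * Mf, k, mode="full")
        s_m = fftconvolve(Mf, kh, mode="full")
        s_m2 = fftconvolve(Mf, kh2, mode="full")
        s_fm = fftconvolve(Hf * Mf, kh, mode="full")
        with np.errstate(divide="ignore", invalid="ignore"):
            ssd = s_f2 + s_m2 - 2 * s_fm - (s_f - s_m) ** 2 / n_ov
            score = ssd / n_ov
        score[~np.isfinite(score)] = np.inf
        score[n_ov < 0.3 * Mm.sum()] = np.inf
        if not np.isfinite(score).any():
            continue
        ci, cj = np.unravel_index(np.argmin(score), score.shape)
        # full correlation: zero shift sits at index (kernel size - 1)
        c0 = np.array(Hm.shape) - 1
        dx = (ci - c0[0]) * pix
        dy = (cj - c0[1]) * pix
        dz = float((s_f[ci, cj] - s_m[ci, cj]) / n_ov[ci, cj])
        out.append(
            RigidTransform.from_rotation(R, np.array([dx, dy, dz]))
        )
    return out


def _edge_mask(
    points: np.ndarray, normals: np.ndarray, spread: float, k: int = 12
) -> np.ndarray:
    """Points whose neighbourhood normals disagree: surface creases/edges."""
    tree = cKDTree(points)
    _, idx = tree.query(points, k=min(k, len(points)))
    dots = np.abs(np.einsum("ni,nki->nk", normals, normals[idx]))
    return dots.mean(axis=1) < spread


def _icp_point_to_plane(
    moving: np.ndarray,
    moving_normals: np.ndarray,
    fixed: np.ndarray,
    fixed_normals: np.ndarray,
    T0: RigidTransform,
    params: RegistrationParams,
    max_iterations: int | None = None,
) -> tuple[RigidTransform, float]:
    """Hybrid ICP refinement.

    Smooth-surface pairs contribute point-to-plane residuals with two
    outlier guards: a distance gate that shrinks toward the residual
    level, and rejection of pairs with incompatible surface normals
    (patches visible from only one view, e.g. stair risers seen
    obliquely, otherwise bias the rotation).  Because near-planar scenes
    leave in-plane motion unconstrained by point-to-plane residuals,
    crease/edge points (detected by neighbourhood normal spread in both
    clouds) additionally contribute point-to-point residuals, locking
    translation and rotation about the surface normal."""
    tree = cKDTree(fixed)
    max_d0 = params.icp_max_correspondence or 3 * params.voxel_size
    cos_thr = np.cos(np.deg2rad(params.icp_normal_threshold_deg))
    m_edge = _edge_mask(moving, moving_normals, params.edge_normal_spread)
    f_edge = np.nonzero(
        _edge_mask(fixed, fixed_normals, params.edge_normal_spread)
    )[0]
    etree = cKDTree(fixed[f_edge]) if len(f_edge) >= 3 else None
    T = T0
    max_d = max_d0
    prev_rms = np.inf
    n_iter = max_iterations or params.icp_max_iterations

    def correspondences(T, max_d):
        p = T.apply(moving)
        d, j = tree.query(p)
        nm = moving_normals @ T.rotation.T
        compat = np.einsum("ni,ni->n", nm, fixed_normals[j]) > cos_thr
        keep = (d < max_d) & compat
        return p, d, j, keep

    eye = np.eye(3)
    for _ in range(n_iter):
        p, d, j, keep = correspondences(T, max_d)
        if keep.sum() < 6:
            break
        ps, qs, ns = p[keep], fixed[j[keep]], fixed_normals[j[keep]]
        b = np.einsum("ni,ni->n", qs - ps, ns)
        A = np.hstack([np.cross(ps, ns), ns])
        rows_A, rows_b = [A], [b]
        if etree is not None and m_edge.any():
            pe = p[m_edge]
            de, je = etree.query(pe)
            ke = de < max_d
            if ke.sum() >= 3:
                pse = pe[ke]
                qse = fixed[f_edge[je[ke]]]
                r = (qse - pse).ravel()
                # d(p) = dtheta x p + dt  ->  rows [-[p]x | I] per component
                n_e = len(pse)
                Ae = np.zeros((3 * n_e, 6))
                px = np.zeros((n_e, 3, 3))  # -[p]x
                px[:, 0, 1], px[:, 0, 2] = pse[:, 2], -pse[:, 1]
                px[:, 1, 0], px[:, 1, 2] = -pse[:, 2], pse[:, 0]
                px[:, 2, 0], px[:, 2, 1] = pse[:, 1], -pse[:, 0]
                Ae[:, :3] = px.reshape(-1, 3)
                Ae[:, 3:] = np.tile(eye, (n_e, 1))
                rows_A.append(Ae)
                rows_b.append(r)
        x, *_ = np.linalg.lstsq(
            np.vstack(rows_A), np.concatenate(rows_b), rcond=None
        )
        T = RigidTransform.from_rotation(_small_rotation(x[:3]), x[3:]) @ T
        rms = float(np.sqrt(np.mean(b**2)))
        # shrink the gate toward the residual level (never below it)
        max_d = max(3.0 * rms, 0.5 * params.voxel_size)
        if abs(prev_rms - rms) < params.icp_tolerance * max(prev_rms, 1e-30):
            prev_rms = rms
            break
        prev_rms = rms
    # point-to-point polish on tight compatible correspondences; accepted
    # only when it clearly reduces the residual (exact for identical
    # point sets, where it converges to machine precision)
    p, d, j, keep = correspondences(T, max_d)
    if keep.sum() >= 3:
        T2 = _kabsch(moving[keep], fixed[j[keep]])
        d2, _ = tree.query(T2.apply(moving))
        if np.sqrt(np.mean(d2[keep] ** 2)) < 0.5 * np.sqrt(np.mean(d[keep] ** 2)):
            T = T2
            d = d2
    fin = d[d < max_d0]
    rms = float(np.sqrt(np.mean(fin**2))) if fin.size else np.inf
    return T, rms


def _small_rotation(w: np.ndarray) -> np.ndarray:
    """Proper rotation from a small rotation vector (exact exponential)."""
    theta = np.linalg.norm(w)
    if theta < 1e-300:
        return np.eye(3)
    k = w / theta
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def register_clouds(
    moving: SurfaceCloud,
    fixed: SurfaceCloud,
    params: RegistrationParams | None = None,
    seed: int = 0,
) -> RegistrationResult:
    """Rigidly register ``moving`` into the frame of ``fixed``.

    Coarse RANSAC over descriptor correspondences is followed by
    point-to-plane ICP; the refinement is also started from the identity
    and the better of the two (lower residual RMS) is kept.  The result
    carries the estimated optical axis (rotated depth axis), the inlier
    fraction and the inlier RMS residual.  A warning is emitted for
    degenerate (single-plane) clouds -- in-plane translation is then
    unobservable -- and when the final fitness is below
    ``params.min_fitness``.
    """
    params = params or RegistrationParams()
    mp, fp = moving.points, fixed.points
    if len(mp) < params.min_points or len(fp) < params.min_points:
        raise DegenerateGeometryError(
            f"clouds need >= {params.min_points} points for registration"
        )
    for label, pts in (("moving", mp), ("fixed", fp)):
        c = pts - pts.mean(axis=0)
        ev = np.linalg.eigvalsh(c.T @ c / len(pts))
        if ev[0] < (0.05 * params.voxel_size) ** 2:
            warnings.warn(
                f"{label} cloud is (near-)planar; registration is "
                "degenerate for in-plane translation",
                RegistrationWarning,
            )
    rng = np.random.default_rng(seed)
    m_ds = _voxel_downsample(mp, params.voxel_size)
    f_ds = _voxel_downsample(fp, params.voxel_size)
    coarse = _ransac_coarse(m_ds, f_ds, params, rng)

    icp_src = mp[
        np.linspace(0, len(mp) - 1, min(params.max_icp_points, len(mp))).astype(int)
    ]
    icp_dst = fp[
        np.linspace(0, len(fp) - 1, min(4 * params.max_icp_points, len(fp))).astype(int)
    ]
    src_normals = _normals(icp_src)
    dst_normals = _normals(icp_dst)

    f_tree = cKDTree(f_ds)
    n_m_ds = _normals(m_ds)
    n_f_ds = _normals(f_ds)
    plane_scan = _plane_scan_hypotheses(m_ds, n_m_ds, f_ds, n_f_ds, params)
    candidates = coarse + plane_scan + [RigidTransform.identity()]

    def coverage(T: RigidTransform) -> float:
        """Symmetric inlier fraction with oriented-normal agreement:
        penalizes alignments that leave part of either cloud uncovered or
        that flip the surface (wrong-basin detector)."""
        moved = T.apply(m_ds)
        d1, j1 = f_tree.query(moved)
        agree = np.einsum("ni,ni->n", n_m_ds @ T.rotation.T, n_f_ds[j1]) > 0.5
        d2, _ = cKDTree(moved).query(f_ds)
        return 0.5 * float(
            ((d1 < params.thr) & agree).mean() + (d2 < params.thr).mean()
        )

    # rank all hypotheses by coverage, shortly refine the most promising,
    # keep the best basin, then refine fully
    candidates.sort(key=coverage, reverse=True)
    best_T0, best_cov = None, -1.0
    for T0 in candidates[: params.n_hypotheses + 1]:
        T, _ = _icp_point_to_plane(
            icp_src, src_normals, icp_dst, dst_normals, T0, params,
            max_iterations=20,
        )
        cov = coverage(T)
        if cov > best_cov:
            best_T0, best_cov = T, cov
    assert best_T0 is not None
    best_T, best_rms = _icp_point_to_plane(
        icp_src, src_normals, icp_dst, dst_normals, best_T0, params
    )
    if coverage(best_T) < best_cov - 0.05:  # full refinement left the basin
        best_T = best_T0
        d0, _ = cKDTree(fp).query(best_T.apply(icp_src))
        keep0 = d0 < (params.icp_max_correspondence or 3 * params.voxel_size)
        best_rms = float(np.sqrt(np.mean(d0[keep0] ** 2))) if keep0.any() else np.inf
    d, _ = cKDTree(fp).query(best_T.apply(m_ds))
    frac = float((d < params.thr).mean())
    converged = frac >= params.min_fitness
    if not converged:
        warnings.warn(
            f"registration fitness {frac:.2f} below threshold "
            f"{params.min_fitness}", RegistrationWarning,
        )
    return RegistrationResult(
        transform=best_T, inlier_fraction=frac, rms=best_rms, converged=converged
    )


def select_box(points: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Points inside an axis-aligned bounding box (inclusive)."""
    p = np.asarray(points)
    keep = np.all((p >= np.asarray(lo)) & (p <= np.asarray(hi)), axis=1)
    return p[keep]


def registration_error_planes(
    fixed_points: np.ndarray,
    transformed_points: np.ndarray,
    plane_box: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Plane-angle registration error in degrees.

    A least-squares plane is fitted to the designated upper horizontal
    surface (points inside ``plane_box``, an axis-aligned box in the
    reference frame) of the fixed cloud and of the transformed moving
    cloud; the acute angle between the two plane normals is returned.
    The metric depends only on the normals, so it is invariant to
    in-plane rotations of the point sets.
    """
    a, b = np.asarray(fixed_points), np.asarray(transformed_points)
    if plane_box is not None:
        a = select_box(a, *plane_box)
        b = select_box(b, *plane_box)
    if len(a) < 3 or len(b) < 3:
        raise DegenerateGeometryError("plane regions need >= 3 points each")
    _, n1 = fit_plane(a)
    _, n2 = fit_plane(b)
    return float(np.rad2deg(np.arccos(np.clip(abs(np.dot(n1, n2)), 0.0, 1.0))))


# --------------------------------------------------------------------------
# Cross-section alignment and volume assembly
# --------------------------------------------------------------------------


def _gradient_magnitude(img: np.ndarray) -> np.ndarray:
    g = np.gradient(np.asarray(img, dtype=float))
    return np.sqrt(sum(gi**2 for gi in g))


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _parabolic(fm: float, f0: float, fp: float) -> float:
    denom = fm - 2 * f0 + fp
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))


def align_mb_to_c(
    mb_slice: np.ndarray,
    c_volume: VolumeGrid,
    prealign: np.ndarray,
    search_voxels: int = 3,
    min_score: float = 0.2,
) -> np.ndarray:
    """Refine the placement of a cross-sectional magnitude image inside a
    C-scan by gradient correlation.

    The slice (axes x, z; same pixel pitch as the volume) is pre-placed at
    ``prealign`` (mm offset of its (0, 0) pixel from the volume origin,
    from the scanner's internal calibration).  Normalized
    cross-correlation of gradient-magnitude images is maximized over
    integer-voxel 3D translations within ``+-search_voxels``, then refined
    to sub-voxel precision by parabolic interpolation per axis.  Returns
    the refined shift in mm; warns when the best correlation stays below
    ``min_score``.
    """
    mb_g = _gradient_magnitude(mb_slice)
    # in-plane (x, z) gradients per candidate slice, to match the 2D
    # gradient content of the cross-section
    slice_g = {}

    def vol_slice_g(j: int) -> np.ndarray:
        if j not in slice_g:
            slice_g[j] = _gradient_magnitude(c_volume.data[:, j, :])
        return slice_g[j]

    base = np.round(
        (np.asarray(prealign, dtype=float) - c_volume.origin) / c_volume.spacing
    ).astype(int)
    s = search_voxels
    nx, nz = mb_g.shape
    NX, NY, NZ = c_volume.shape
    scores = np.full((2 * s + 1,) * 3, -np.inf)
    for a, dx in enumerate(range(-s, s + 1)):
        for b, dy in enumerate(range(-s, s + 1)):
            j = base[1] + dy
            if not 0 <= j < NY:
                continue
            plane = vol_slice_g(j)
            for c, dz in enumerate(range(-s, s + 1)):
                x0, z0 = base[0] + dx, base[2] + dz
                xs0, zs0 = max(0, -x0), max(0, -z0)
                xe = min(nx, NX - x0)
                ze = min(nz, NZ - z0)
                if xe - xs0 < 4 or ze - zs0 < 4:
                    continue
                sub_m = mb_g[xs0:xe, zs0:ze]
                sub_v = plane[x0 + xs0 : x0 + xe, z0 + zs0 : z0 + ze]
                scores[a, b, c] = _ncc(sub_m, sub_v)
    # prefer the shift closest to the pre-alignment among (near-)ties --
    # featureless directions otherwise resolve arbitrarily
    offs = np.abs(np.arange(-s, s + 1, dtype=float))
    penalty = 1e-9 * (
        offs[:, None, None] + offs[None, :, None] + offs[None, None, :]
    )
    best = np.unravel_index(np.argmax(scores - penalty), scores.shape)
    if not np.isfinite(scores[best]) or scores[best] < min_score:
        warnings.warn(
            f"gradient correlation peak {scores[best]:.2f} below "
            f"{min_score}; alignment unreliable", RegistrationWarning,
        )
    off = np.array(best, dtype=float) - s
    if scores[best] > 0.999:
        # (near-)perfect correlation: the integer peak is exact and the
        # parabolic vertex would only be biased by neighbour asymmetry
        return np.asarray(prealign, dtype=float) + off * c_volume.spacing
    for ax in range(3):
        i = best[ax]
        if 0 < i < 2 * s:
            lo = list(best)
            hi = list(best)
            lo[ax] -= 1
            hi[ax] += 1
            fm, f0, fp = scores[tuple(lo)], scores[best], scores[tuple(hi)]
            if np.isfinite(fm) and np.isfinite(fp):
                off[ax] += _parabolic(fm, f0, fp)
    return np.asarray(prealign, dtype=float) + off * c_volume.spacing


def _query_nearest_smallest_index(
    tree: cKDTree, pts: np.ndarray, k: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbour query with a deterministic tie-break: among
    equidistant data points the smallest index wins."""
    k = min(k, tree.n)
    d, j = tree.query(pts, k=k)
    if k == 1:
        return d, j
    tie = np.abs(d - d[:, :1]) < 1e-12
    jj = np.where(tie, j, tree.n + 1).min(axis=1)
    return d[:, 0], jj


def assemble_mc(
    mb_stack: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    c_volume: VolumeGrid,
    mask: np.ndarray,
    radius: float | None = None,
) -> VolumeGrid:
    """Assemble a volumetric velocity field from aligned cross-sections.

    ``mb_stack`` holds ``(values2d, mask2d, shift_mm)`` per cross-section:
    complex velocities on the (x, z) pixel grid, the background-subtracted
    retention mask, and the world position of pixel (0, 0).  Masked pixels
    become scattered data points; every C-scan mask voxel within
    ``radius`` (default 1.5 x max pitch) of a data point receives its
    nearest neighbour's value -- never an invented one -- and voxels
    beyond the support radius stay empty (no extrapolation).
    """
    if not mb_stack:
        raise ValueError("empty cross-section stack")
    radius = radius or 1.5 * float(c_volume.spacing.max())
    pts, vals = [], []
    for values2d, mask2d, shift in mb_stack:
        values2d = np.asarray(values2d)
        mask2d = np.asarray(mask2d, dtype=bool)
        ix, iz = np.nonzero(mask2d)
        shift = np.asarray(shift, dtype=float)
        p = np.column_stack(
            [
                shift[0] + ix * c_volume.spacing[0],
                np.full(ix.shape, shift[1]),
                shift[2] + iz * c_volume.spacing[2],
            ]
        )
        pts.append(p)
        vals.append(values2d[ix, iz])
    pts = np.vstack(pts)
    vals = np.concatenate(vals)
    if len(pts) == 0:
        raise EmptyCloudError("no cross-section pixel survived masking")
    tree = cKDTree(pts)
    centers = c_volume.voxel_centers(mask)
    d, j = _query_nearest_smallest_index(tree, centers)
    keep = d <= radius
    field = np.full(c_volume.shape, np.nan + 0j, dtype=complex)
    idx = np.argwhere(mask)[keep]
    field[idx[:, 0], idx[:, 1], idx[:, 2]] = vals[j[keep]]
    return VolumeGrid(
        c_volume.data,
        spacing=c_volume.spacing,
        origin=c_volume.origin,
        units=c_volume.units,
        frame=c_volume.frame,
        velocity=field,
    )


# --------------------------------------------------------------------------
# Fusion of direction measurements and mesh mapping
# --------------------------------------------------------------------------


@dataclass
class FusedVoxelField:
    """Per-voxel fusion of >= 3 direction measurements on the reference
    grid: the decomposed Cartesian complex velocity where at least three
    axis/velocity pairs exist, NaN elsewhere."""

    grid: VolumeGrid
    decomposed: np.ndarray  # (nx, ny, nz, 3) complex, NaN where undecomposed
    counts: np.ndarray
    n_singular: int

    @property
    def decomposed_mask(self) -> np.ndarray:
        return ~np.isnan(self.decomposed[..., 0])

    def points_and_values(self) -> tuple[np.ndarray, np.ndarray]:
        mask = self.decomposed_mask
        return self.grid.voxel_centers(mask), self.decomposed[mask]


def fuse_dms(
    reference: DirectionMeasurement,
    others: list[tuple[DirectionMeasurement, RigidTransform, np.ndarray]],
    threshold_db: float = 50.0,
    radius: float | None = None,
) -> FusedVoxelField:
    """Fuse direction measurements into a decomposed Cartesian field.

    Each non-reference measurement comes with the rigid transform mapping
    its frame into the reference frame and its estimated optical axis (in
    the reference frame).  Reference voxel centres are inverse-transformed
    into each moving grid and assigned the nearest masked moving voxel's
    complex value within ``radius`` (nearest neighbour, no extrapolation,
    values never altered).  Voxels holding the reference value plus at
    least two others are decomposed with the direction matrix of the
    reference axis ``[0, 0, 1]`` and the first two contributing axes (in
    list order); voxels with fewer than three contributions stay
    undecomposed, and voxels whose local axes are singular are skipped and
    counted.
    """
    ref_vol = reference.volume
    if ref_vol.velocity is None:
        raise ValueError("reference measurement has no velocity field")
    radius = radius or 1.5 * float(ref_vol.spacing.max())
    ref_mask = background_subtract(ref_vol, threshold_db) & ~np.isnan(
        ref_vol.velocity.real
    )
    centers = ref_vol.voxel_centers(ref_mask)
    n_pts = len(centers)
    contrib_vals = np.full((len(others), n_pts), np.nan + 0j, dtype=complex)
    axes = []
    for i, (dm, T, axis) in enumerate(others):
        mv = dm.volume
        if mv.velocity is None:
            raise ValueError(f"measurement {dm.name!r} has no velocity field")
        m_mask = background_subtract(mv, threshold_db) & ~np.isnan(mv.velocity.real)
        m_centers = mv.voxel_centers(m_mask)
        if len(m_centers) == 0:
            axes.append(np.asarray(axis, dtype=float))
            continue
        m_vals = mv.velocity[m_mask]
        back = T.inverse().apply(centers)
        d, j = cKDTree(m_centers).query(back)
        keep = d <= radius
        contrib_vals[i, keep] = m_vals[j[keep]]
        axes.append(np.asarray(axis, dtype=float))

    have = ~np.isnan(contrib_vals.real)
    counts_pts = 1 + have.sum(axis=0)
    ref_vals = ref_vol.velocity[ref_mask]

    dec_pts = np.full((n_pts, 3), np.nan + 0j, dtype=complex)
    n_singular = 0
    enough = counts_pts >= 3
    # group voxels by the (ordered) pair of contributing measurements
    pair_ids = {}
    for p in np.nonzero(enough)[0]:
        ids = tuple(np.nonzero(have[:, p])[0][:2])
        pair_ids.setdefault(ids, []).append(p)
    for (i1, i2), plist in pair_ids.items():
        try:
            O = build_direction_matrix(axes[i1], axes[i2])
        except SingularDirectionsError:
            n_singular += len(plist)
            continue
        plist = np.asarray(plist)
        m = np.column_stack(
            [ref_vals[plist], contrib_vals[i1, plist], contrib_vals[i2, plist]]
        )
        dec_pts[plist] = decompose(m, O)

    shape = ref_vol.shape
    decomposed = np.full((*shape, 3), np.nan + 0j, dtype=complex)
    counts = np.zeros(shape, dtype=int)
    idx = np.argwhere(ref_mask)
    counts[idx[:, 0], idx[:, 1], idx[:, 2]] = counts_pts
    decomposed[idx[:, 0], idx[:, 1], idx[:, 2]] = dec_pts
    return FusedVoxelField(
        grid=ref_vol, decomposed=decomposed, counts=counts, n_singular=n_singular
    )


def map_to_mesh(
    points: np.ndarray,
    values: np.ndarray,
    mesh,
    a_min_decomposed: float,
    max_dist: float = 0.1,
    mesh_radius: float | None = None,
) -> dict[str, np.ndarray]:
    """Map decomposed voxel data onto a surface mesh (trimesh.Trimesh).

    Data voxels outside the mesh neighbourhood (farther than
    ``mesh_radius``, default ``max_dist``, from every vertex) and voxels
    whose overall amplitude ``sqrt(sum_i |v_i|^2)`` is at or below the
    amplified noise floor are dropped.  Vertices within ``max_dist`` of a
    surviving data point take its value (nearest neighbour); remaining
    vertices inherit the value of the nearest assigned vertex along the
    mesh edge graph (boundary extrapolation).  Returns per-vertex
    ``amplitude`` and ``phase`` arrays (n_vertices, n_components) plus the
    ``assigned`` and ``filled`` masks.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    values = np.asarray(values, dtype=complex)
    if values.ndim == 1:
        values = values[:, None]
    verts = np.asarray(mesh.vertices, dtype=float)
    nv = len(verts)
    ncomp = values.shape[1]
    amp_out = np.full((nv, ncomp), np.nan)
    ph_out = np.full((nv, ncomp), np.nan)
    assigned = np.zeros(nv, dtype=bool)

    overall = np.sqrt((np.abs(values) ** 2).sum(axis=1))
    keep = overall > a_min_decomposed
    if keep.any():
        vtree = cKDTree(verts)
        d_to_mesh, _ = vtree.query(points[keep])
        keep_idx = np.nonzero(keep)[0][d_to_mesh <= (mesh_radius or max_dist)]
    else:
        keep_idx = np.array([], dtype=int)
    if len(keep_idx) == 0:
        warnings.warn(
            "no data voxel survived noise-floor and mesh-distance "
            "filtering; nothing mapped", RegistrationWarning,
        )
        return {
            "amplitude": amp_out, "phase": ph_out,
            "assigned": assigned, "filled": assigned.copy(),
        }
    dtree = cKDTree(points[keep_idx])
    d, j = dtree.query(verts)
    assigned = d < max_dist
    vv = values[keep_idx[j[assigned]]]
    amp_out[assigned] = np.abs(vv)
    ph_out[assigned] = np.angle(vv)

    filled = assigned.copy()
    if assigned.any() and not assigned.all():
        e = np.asarray(mesh.edges_unique)
        w = np.linalg.norm(verts[e[:, 0]] - verts[e[:, 1]], axis=1)
        g = csr_matrix(
            (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(nv, nv),
        )
        sources = np.nonzero(assigned)[0]
        dist, _, src = dijkstra(
            g, indices=sources, min_only=True, return_predecessors=True
        )
        reach = np.isfinite(dist) & ~assigned
        amp_out[reach] = amp_out[src[reach]]
        ph_out[reach] = ph_out[src[reach]]
        filled |= reach
    return {
        "amplitude": amp_out, "phase": ph_out,
        "assigned": assigned, "filled": filled,
    }
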