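"""Orthogonal decomposition, noise amplification, noise floors, Rician
bias and axis-misalignment error propagation."""

import numpy as np
import pytest
from scipy import stats

from octvib.config import load_dm_table, phantom_decompositions
from octvib.decomposition import (
    amplified_noise_floor,
    cone_uncertainty,
    decompose,
    decomposition_error,
    naf,
    noise_floor,
    phase_error_summary,
    phase_std,
    project,
    propagate_noise,
    rician_check,
    wrap_phase,
)
from octvib.errors import LowSNRWarning
from octvib.geometry import (
    build_direction_matrix,
    direction_matrix_from_angles,
    spherical_to_axis,
)


def _table_matrix(name_pair: str):
    """Direction matrix ZXY -> reference Z plus the two named axes."""
    table = load_dm_table()
    a, b = name_pair[1], name_pair[2]
    return direction_matrix_from_angles(*table[a], *table[b])


def test_project_examples(rng):
    assert project([0, 0, 1], [0, 0, 1]) == 1.0
    assert project([1 + 1j, 0, 0], [1, 0, 0]) == 1 + 1j
    for _ in range(20):
        v = rng.normal(size=3) + 1j * rng.normal(size=3)
        d = rng.normal(size=3)
        d = d / np.linalg.norm(d)
        assert abs(project(v, d) - (v * d).sum()) < 1e-12


def test_decompose_project_identity(rng):
    """decompose(project(v)) == v on C^3 for random well-separated axes."""
    for _ in range(1000):
        t1, t2 = rng.uniform(10, 170, 2)
        p1 = rng.uniform(-179, 180)
        p2 = p1 + rng.uniform(20, 160)
        if p2 > 180:
            p2 -= 360
        O = direction_matrix_from_angles(t1, p1, t2, p2)
        v = rng.normal(size=3) + 1j * rng.normal(size=3)
        m = O.matrix @ v
        rec = decompose(m, O)
        assert np.max(np.abs(rec - v)) < 1e-9 * max(1.0, np.abs(v).max())


def test_decompose_permutation_and_reference_passthrough():
    O = build_direction_matrix([1, 0, 0], [0, 1, 0])
    m = np.array([1 + 2j, 3.0, 4j])
    v = decompose(m, O)
    assert np.allclose(v, [3.0, 4j, 1 + 2j])
    assert v[2] == m[0]  # z equals the reference measurement exactly


def test_decompose_against_linear_solver_oracle():
    # uncertainty-study geometry: d2(25, 30), d3(20, 40), m = (1, 1, 1)
    O = direction_matrix_from_angles(25, 30, 20, 40)
    m = np.ones(3, dtype=complex)
    assert np.allclose(decompose(m, O), np.linalg.solve(O.matrix, m), atol=1e-12)


def test_naf_against_independent_inversion():
    O = _table_matrix("ZAB")
    inv = np.linalg.inv(O.matrix)
    nx, ny = naf(O)
    assert abs(nx - np.linalg.norm(inv[0])) < 1e-12
    assert abs(ny - np.linalg.norm(inv[1])) < 1e-12


def test_naf_blows_up_near_singular():
    O = direction_matrix_from_angles(40, 0, 40, 1.0)  # 1 degree azimuth gap
    assert max(O.naf_x, O.naf_y) > 50
    # error growth consistent with 1/|det| scaling
    O2 = direction_matrix_from_angles(40, 0, 40, 2.0)
    ratio = max(O.naf_x, O.naf_y) / max(O2.naf_x, O2.naf_y)
    assert abs(ratio - abs(O2.determinant) / abs(O.determinant)) < 0.1 * ratio


def test_propagate_noise_monte_carlo_all_decompositions(rng):
    """Empirical decomposed-noise stds match NAF*sigma_n within 2% at 1e5
    draws for all 13 phantom decompositions."""
    n_draws = 100_000
    sigma = 1.0
    noise = sigma * (
        rng.standard_normal((n_draws, 3)) + 1j * rng.standard_normal((n_draws, 3))
    )
    for name in phantom_decompositions():
        O = _table_matrix(name)
        model = propagate_noise(sigma, O)
        dec = decompose(noise, O)
        for comp, pred in ((0, model.sigma_nx), (1, model.sigma_ny),
                           (2, model.sigma_nz)):
            emp = np.sqrt(
                0.5 * (dec[:, comp].real.var() + dec[:, comp].imag.var())
            )
            assert abs(emp / pred - 1.0) < 0.02, (name, comp)


def test_propagate_noise_trivial_cases():
    O = build_direction_matrix([1, 0, 0], [0, 1, 0])
    m = propagate_noise(0.0, O)
    assert m.sigma_nx == m.sigma_ny == m.sigma_nz == 0.0
    m1 = propagate_noise(1.0, O)
    assert np.allclose([m1.sigma_nx, m1.sigma_ny, m1.sigma_nz], 1.0, atol=1e-12)


def test_noise_floor_values():
    assert noise_floor(0.0) == 0.0
    assert noise_floor(1.0) == 3.0
    # smoothed phantom noise level: sigma_n = 0.33e-4 m/s = 0.033 mm/s
    assert abs(noise_floor(0.033) - 0.099) < 1e-12


def test_amplified_noise_floor():
    O = build_direction_matrix([1, 0, 0], [0, 1, 0])
    assert amplified_noise_floor(1.0, O=O) == noise_floor(1.0)
    assert abs(amplified_noise_floor(0.033, naf_max=3.87) - 3 * 3.87 * 0.033) < 1e-12
    assert amplified_noise_floor(2.0, naf_max=2.0) == 2 * amplified_noise_floor(
        1.0, naf_max=2.0
    )
    with pytest.raises(ValueError):
        amplified_noise_floor(1.0)


def test_phase_std_closed_form_and_monte_carlo(rng):
    with pytest.warns(LowSNRWarning):
        assert abs(phase_std(1.0, 3.0) - 1.0 / 3.0) < 1e-12
    assert phase_std(0.0, 1.0) == 0.0
    with pytest.raises(ValueError):
        phase_std(1.0, 0.0)
    # SNR 10: empirical phase std within 5% of 0.1 rad
    n = 100_000
    v = 10.0 + rng.standard_normal(n) + 1j * rng.standard_normal(n)
    assert abs(np.angle(v).std() / 0.1 - 1.0) < 0.05
    s = phase_error_summary(1.0, 3.0)
    assert abs(s["std"] - 1 / 3) < 1e-12
    assert abs(s["mean_abs_error"] - np.sqrt(2 / np.pi) / 3) < 1e-12


def test_rician_bias_and_threshold(rng):
    ok, bias = rician_check(0.0, 1.0)
    assert not ok
    assert abs(bias - np.sqrt(np.pi / 2)) < 1e-9  # Rayleigh mean
    ok10, bias10 = rician_check(10.0, 1.0)
    assert ok10 and bias10 / 10.0 < 0.01
    ok3, _ = rician_check(3.0, 1.0)
    assert not ok3  # boundary: SNR must exceed 3
    # bias direction below threshold, negligible above SNR 5
    for snr in (0.5, 1.0, 2.0, 2.9):
        assert rician_check(snr, 1.0)[1] > 0.0
    for snr in (5.5, 8.0, 12.0):
        assert rician_check(snr, 1.0)[1] / snr < 0.02


def test_noise_only_amplitude_is_rayleigh(rng):
    n = 10_000
    v = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    p = stats.kstest(np.abs(v), "rayleigh", args=(0, 1.0)).pvalue
    assert p > 0.01


def test_cone_uncertainty_zero_angle_gives_zero_errors():
    d2 = spherical_to_axis(25, 30)
    d3 = spherical_to_axis(20, 40)
    res = cone_uncertainty(d2, d3, 0.0, np.ones(3), n_samples=50, seed=0)
    assert np.allclose(res.eps_dx, 0.0, atol=1e-12)
    assert np.allclose(res.eps_dy, 0.0, atol=1e-12)
    assert res.n_skipped == 0


def test_cone_uncertainty_linearity_in_amplitude():
    d2 = spherical_to_axis(25, 30)
    d3 = spherical_to_axis(20, 40)
    m = np.array([1 + 0.5j, 0.8, 1.2 - 0.1j])
    r1 = cone_uncertainty(d2, d3, 0.4, m, n_samples=200, seed=3)
    r2 = cone_uncertainty(d2, d3, 0.4, 2 * m, n_samples=200, seed=3)
    assert np.allclose(r2.eps_dx, 2 * r1.eps_dx, rtol=1e-12)
    assert np.allclose(r2.eps_dy, 2 * r1.eps_dy, rtol=1e-12)


def test_cone_uncertainty_grid_matches_brute_force():
    from octvib.decomposition import cone_axes

    d2 = spherical_to_axis(25, 30)
    d3 = spherical_to_axis(20, 40)
    m = np.ones(3, dtype=complex)
    n = 12
    res = cone_uncertainty(d2, d3, 0.4, m, n_samples=n, seed=None, method="grid")
    O_true = build_direction_matrix(d2, d3)
    v_true = np.linalg.solve(O_true.matrix, m)
    grid = np.linspace(0, 2 * np.pi, n, endpoint=False)
    brute = []
    for a in grid:
        e2 = cone_axes(d2, 0.4, np.array([a]))[0]
        for b in grid:
            e3 = cone_axes(d3, 0.4, np.array([b]))[0]
            rows = np.vstack([[0, 0, 1], e2, e3])
            brute.append((v_true - np.linalg.solve(rows, m))[0])
    brute = np.asarray(brute)
    assert np.allclose(res.eps_dx, brute, atol=1e-10)
    assert abs(res.eps_dx.real.max() - brute.real.max()) < 1e-10
    assert abs(res.eps_dx.real.min() - brute.real.min()) < 1e-10


def test_decomposition_error_zero_and_linearity():
    O = direction_matrix_from_angles(25, 30, 20, 40)
    v = np.array([0.2 + 0.1j, 0.15, 0.4 - 0.2j])
    zero = decomposition_error(v, O, O)
    assert abs(zero.eps_dx) < 1e-12 and abs(zero.eps_dy) < 1e-12
    O_err = direction_matrix_from_angles(25.4, 30, 20.4, 40)
    e1 = decomposition_error(v, O, O_err)
    e2 = decomposition_error(2 * v, O, O_err)
    # doubling the stimulus amplitude doubles the error: +6.02 dB
    db = 20 * np.log10(abs(e2.eps_dx) / abs(e1.eps_dx))
    assert abs(db - 20 * np.log10(2)) < 1e-9


def test_decomposition_error_grows_with_misalignment():
    O = direction_matrix_from_angles(25, 30, 20, 40)
    v = np.array([0.2 + 0.1j, 0.15, 0.4 - 0.2j])
    errs = [
        abs(decomposition_error(
            v, O, direction_matrix_from_angles(25 + e, 30, 20 + e, 40)
        ).eps_dx)
        for e in (0.1, 0.2, 0.4, 0.8)
    ]
    assert all(a < b for a, b in zip(errs, errs[1:]))


def test_wrap_phase_range():
    x = np.array([0.0, np.pi, -np.pi, 3.5, -3.5, 7.0])
    w = wrap_phase(x)
    assert np.all((w > -np.pi - 1e-12) & (w <= np.pi + 1e-12))
    assert abs(w[1] - np.pi) < 1e-12  # pi maps to pi, not -pi
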