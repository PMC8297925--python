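"""Two-current reference algorithm: weights, GCV solve, log-η integration."""

import numpy as np
import pytest

from dtmreit.grid import TensorField, VectorField, VoxelGrid
from dtmreit.projected import boundary_ring
from dtmreit.two_current import (GradientSolveConfig,
                                 assemble_gradient_system, gcv_function,
                                 integrate_log_eta, magnitude_weights,
                                 minimize_gcv, reconstruct_two_current,
                                 solve_gradient_slice, solve_window_gcv)


# --- magnitude weights ---------------------------------------------------

def test_weights_uniform_for_h_zero_or_flat_rho():
    rho = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    w = magnitude_weights(rho, h=0.0)
    assert np.allclose(w, 0.2)
    w2 = magnitude_weights(np.full(9, 3.3), h=7.5)
    assert np.allclose(w2, 1 / 9)
    assert np.isclose(w.sum(), 1.0)


def test_weights_concentrate_for_large_h():
    rho = np.array([0.5, 1.0, 1.001, 5.0, 1.0])  # centre index 2
    w = magnitude_weights(rho, h=1e4)
    assert w[2] > 0.99
    assert w[3] < 1e-6


# --- GCV -----------------------------------------------------------------

def test_gcv_zero_rhs_gives_zero_solution():
    A = np.array([[1.0, 0.0], [0.0, 0.5], [0.3, 0.3], [0.1, -0.2]])
    e, zeta = solve_window_gcv(A, np.zeros(4))
    assert np.allclose(e, 0.0)


def test_gcv_well_conditioned_matches_pseudo_inverse():
    """Noise-free consistent system: ζ* ≈ 0 and e ≈ lstsq solution."""
    rng = np.random.default_rng(1)
    A = rng.normal(size=(18, 2))
    e_true = np.array([0.3, -0.7])
    b = A @ e_true
    e, zeta = solve_window_gcv(A, b)
    assert np.linalg.norm(e - e_true) < 1e-3 * np.linalg.norm(e_true)


def test_gcv_minimizer_matches_dense_grid_scan():
    """Optimiser vs brute-force ζ grid on random (b̂, s) draws."""
    rng = np.random.default_rng(7)
    cfg = GradientSolveConfig()
    for _ in range(100):
        s = np.sort(rng.uniform(0.1, 3.0, size=2))[::-1]
        b_hat = rng.normal(size=2)
        zeta = float(minimize_gcv(b_hat, s, cfg))
        grid = np.logspace(np.log10(cfg.zeta_bracket[0] * s[0] ** 2),
                           np.log10(cfg.zeta_bracket[1] * s[0] ** 2), 4000)
        vals = gcv_function(b_hat, s, grid)
        best = grid[np.argmin(vals)]
        # agreement within grid spacing (log-scale neighbours)
        assert gcv_function(b_hat, s, zeta) <= vals.min() * (1 + 1e-6) \
            or abs(np.log(zeta) - np.log(best)) < np.log(grid[1] / grid[0]) * 2


def test_collinear_window_flagged():
    F = np.tile(np.array([1.0, 2.0]), (9, 1))
    curl = np.zeros(9)
    w = np.full(9, 1 / 9)
    with pytest.raises(ValueError, match="collinear"):
        assemble_gradient_system(F, F, curl, curl, w)


# --- manufactured gradient recovery --------------------------------------

def _exp_eta_fields(a=0.05, nx=24, ny=20):
    """F-fields satisfying the curl identity for η = exp(a·x) exactly:
    F = η·c with constant unit vectors c — curl F = a·η c_y matches
    (∇ln η × F)_z."""
    grid = VoxelGrid((nx, ny, 1), (1.0, 1.0, 1.0))
    x, y, _ = grid.coordinates()
    eta = np.exp(a * x)
    F1 = np.zeros((nx, ny, 2))
    F2 = np.zeros((nx, ny, 2))
    F1[..., 0] = eta[:, :, 0]
    F2[..., 1] = eta[:, :, 0]
    return grid, eta, F1, F2


def test_gradient_solve_recovers_exponential_eta_gradient():
    grid, eta, F1, F2 = _exp_eta_fields(a=0.05)
    m2 = grid.slice_mask(0)
    e, defined = solve_gradient_slice([F1, F2], np.ones(m2.shape), m2,
                                      (1.0, 1.0))
    got = e[defined]
    assert np.abs(got[:, 0] - 0.05).max() < 1e-3
    assert np.abs(got[:, 1]).max() < 1e-6
    # away from one-sided boundary differences the recovery is O(h²)-tight
    import scipy.ndimage as ndi
    core = defined & ndi.binary_erosion(m2, iterations=2)
    assert np.abs(e[core][:, 0] - 0.05).max() < 1e-3 * 0.05


def test_single_montage_duplicate_is_rank_deficient():
    grid, eta, F1, _ = _exp_eta_fields()
    m2 = grid.slice_mask(0)
    e, defined = solve_gradient_slice([F1, F1], np.ones(m2.shape), m2,
                                      (1.0, 1.0))
    assert not defined.any()  # everywhere collinear -> rank-1 flagged


# --- log-η integration ---------------------------------------------------

def test_integrate_constant_eta_from_zero_gradient():
    mask = np.ones((12, 10), dtype=bool)
    e = np.zeros((12, 10, 2))
    eta = integrate_log_eta(e, 0.8, mask, (1.0, 1.0))
    assert np.allclose(eta[mask], 0.8, rtol=1e-12)


def test_integrate_recovers_harmonic_log_eta_exactly():
    """ln η = c(x²−y²) is discretely harmonic: exact recovery."""
    nx, ny = 16, 14
    mask = np.ones((nx, ny), dtype=bool)
    x, y = np.meshgrid(np.arange(nx, dtype=float),
                       np.arange(ny, dtype=float), indexing="ij")
    g = 0.004 * (x**2 - y**2)
    e = np.stack([0.008 * x, -0.008 * y], axis=-1)
    ring = boundary_ring(mask)
    eta_b = np.exp(g)
    eta = integrate_log_eta(e, eta_b, mask, (1.0, 1.0))
    assert np.allclose(eta[mask], np.exp(g)[mask], rtol=1e-10)


def test_integrate_smooth_eta_small_error():
    nx, ny = 32, 28
    mask = np.ones((nx, ny), dtype=bool)
    x, y = np.meshgrid(np.arange(nx, dtype=float),
                       np.arange(ny, dtype=float), indexing="ij")
    g = 0.3 * np.sin(2 * np.pi * x / nx) * np.cos(2 * np.pi * y / ny)
    gx = 0.3 * (2 * np.pi / nx) * np.cos(2 * np.pi * x / nx) \
        * np.cos(2 * np.pi * y / ny)
    gy = -0.3 * (2 * np.pi / ny) * np.sin(2 * np.pi * x / nx) \
        * np.sin(2 * np.pi * y / ny)
    e = np.stack([gx, gy], axis=-1)
    eta = integrate_log_eta(e, np.exp(g), mask, (1.0, 1.0))
    re = np.linalg.norm((eta - np.exp(g))[mask]) \
        / np.linalg.norm(np.exp(g)[mask])
    assert re < 1e-3


def test_divergence_annihilates_curl_component():
    """Adding a pure-curl field to e leaves η̃ almost unchanged."""
    nx, ny = 24, 20
    mask = np.ones((nx, ny), dtype=bool)
    x, y = np.meshgrid(np.arange(nx, dtype=float),
                       np.arange(ny, dtype=float), indexing="ij")
    e = np.stack([0.01 * np.ones_like(x), np.zeros_like(y)], axis=-1)
    phi = 0.2 * np.sin(2 * np.pi * x / nx) * np.sin(2 * np.pi * y / ny)
    curl = np.stack([np.gradient(phi, axis=1), -np.gradient(phi, axis=0)],
                    axis=-1)
    eta1 = integrate_log_eta(e, 1.0, mask, (1.0, 1.0))
    eta2 = integrate_log_eta(e + curl, 1.0, mask, (1.0, 1.0))
    inner = ~boundary_ring(mask)
    # the divergence kills the curl part up to one-sided edge differences
    assert np.abs(np.log(eta2[inner]) - np.log(eta1[inner])).max() < 2e-2


def test_nonpositive_boundary_eta_rejected():
    mask = np.ones((8, 8), dtype=bool)
    with pytest.raises(ValueError, match="positive"):
        integrate_log_eta(np.zeros((8, 8, 2)), -1.0, mask, (1.0, 1.0))


# --- end-to-end two-current ----------------------------------------------

def _two_montage_study():
    grid = VoxelGrid((20, 20, 1), (1.0, 1.0, 1.0))
    x, y, _ = grid.coordinates()
    eta = np.exp(0.04 * x[:, :, 0])
    D = TensorField.isotropic(grid, 1.0)
    def vf(Fxy):
        v = np.zeros(grid.shape + (3,))
        v[:, :, 0, :2] = Fxy
        return VectorField(grid, v)
    F1 = np.zeros((20, 20, 2))
    F1[..., 0] = eta
    F2 = np.zeros((20, 20, 2))
    F2[..., 1] = eta
    return grid, eta, D, vf(F1), vf(F2)


def test_two_current_reconstruction_and_montage_symmetry():
    """End-to-end: gradient solve + integration recovers exp(a·x) η, and
    the result is invariant to swapping the montages."""
    grid, eta, D, J1, J2 = _two_montage_study()
    m2 = grid.slice_mask(0)
    F1 = J1.values[:, :, 0, :2] / 1.0  # D = I
    F2 = J2.values[:, :, 0, :2]
    e12, d12 = solve_gradient_slice([F1, F2], np.ones(m2.shape), m2,
                                    (1.0, 1.0))
    e21, d21 = solve_gradient_slice([F2, F1], np.ones(m2.shape), m2,
                                    (1.0, 1.0))
    assert np.allclose(e12, e21, rtol=1e-9, atol=1e-12)
    out = integrate_log_eta(e12, eta, m2, (1.0, 1.0), defined=d12)
    re = np.linalg.norm((out - eta)[m2]) / np.linalg.norm(eta[m2])
    assert re < 1e-2
    # the smooth interior is recovered much more tightly
    import scipy.ndimage as ndi
    core = ndi.binary_erosion(m2, iterations=2)
    assert np.abs((out - eta) / eta)[core].max() < 2e-3


def test_output_eta_positive(cylinder_study):
    """η̃ > 0 everywhere by construction (exponentiated)."""
    grid, eta, D, J1, J2 = _two_montage_study()
    cfg = GradientSolveConfig(eta_boundary=0.7)
    out = reconstruct_two_current(D, J1, J2, 0, config=cfg)
    assert (out[grid.slice_mask(0)] > 0).all()
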