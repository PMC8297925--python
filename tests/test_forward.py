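"""Conduction solver and Biot-Savart oracles.

The analytic references are one-dimensional Ohm's-law solutions (uniform
and series-resistor slabs), linearity/reciprocity identities of the
Neumann problem, and the closed-form magnetic field of a finite straight
current segment.
"""

import numpy as np
import pytest

from dtmreit.forward import (ConductionSystem, biot_savart_bz,
                             current_density, plane_current,
                             solve_conduction, uniform_reference)
from dtmreit.grid import TensorField, VectorField, VoxelGrid

from conftest import plate_montage


def test_uniform_slab_is_one_dimensional_ohms_law(slab):
    """Uniform C + opposing plates: u linear along x, J uniform."""
    grid, C, montage = slab
    u = solve_conduction(grid, C, montage)
    J = current_density(u, C)
    # J should be I/area along -x ... sign: current enters at the +x patch
    area = montage.patch_area(grid, 0)
    j_expect = montage.current_ma * 1e-3 / area
    assert np.allclose(J.values[..., 0], -j_expect, rtol=1e-10)
    assert np.allclose(J.values[..., 1:], 0.0, atol=1e-10 * j_expect)
    # u linear: second difference along x vanishes
    du = np.diff(u.values, axis=0)
    assert np.allclose(du, du[0], rtol=1e-9)


def test_conductivity_scaling_leaves_current_invariant(slab):
    """C -> 2C: identical J, halved u (pure Neumann linearity)."""
    grid, C, montage = slab
    u1 = solve_conduction(grid, C, montage)
    u2 = solve_conduction(grid, C.scaled(2.0), montage)
    assert np.allclose(u2.values, 0.5 * u1.values, rtol=1e-10, atol=1e-14)
    J1 = current_density(u1, C)
    J2 = current_density(u2, C.scaled(2.0))
    assert np.allclose(J1.values, J2.values, rtol=1e-10)


def test_two_layer_slab_matches_series_resistor():
    """Interface voltage equals the hand-computed 1-D series solution."""
    grid = VoxelGrid((10, 6, 3), (1.0, 1.0, 1.0))
    sigma1, sigma2 = 2.0e-3, 0.5e-3  # S/mm
    comp = np.zeros(grid.shape + (6,))
    comp[:5, :, :, :3] = sigma1
    comp[5:, :, :, :3] = sigma2
    C = TensorField(grid, comp, units="S/mm")
    montage = plate_montage(grid, axis=0, current_ma=1.0)
    u = solve_conduction(grid, C, montage)
    area = 6.0 * 3.0  # mm²
    j = 1e-3 / area  # A/mm², flowing along -x (enters at +x plate)
    # 1-D finite-volume solution on the same grid: du across interior
    # faces = -(-j)*h/sigma_face with the harmonic face conductance
    du_exact = []
    for i in range(9):
        s_face = (2 * comp[i, 0, 0, 0] * comp[i + 1, 0, 0, 0]
                  / (comp[i, 0, 0, 0] + comp[i + 1, 0, 0, 0]))
        du_exact.append(j * 1.0 / s_face)
    u_line = u.values[:, 3, 1]
    assert np.allclose(np.diff(u_line), du_exact, rtol=1e-9)
    # series-resistor total voltage across the slab
    assert np.isclose(u_line[-1] - u_line[0], sum(du_exact), rtol=1e-9)


def test_current_conservation_on_phantom(cylinder_study):
    """|∮J·n - I|/I < 1% through planes separating the electrodes."""
    s = cylinder_study
    C = s.conductivity()
    u = solve_conduction(s.grid, C, s.montages["vertical"])
    J = current_density(u, C)
    I = s.montages["vertical"].current_ma * 1e-3
    for j_index in (20, 32, 44):
        I_plane = plane_current(J, 1, j_index)
        assert abs(abs(I_plane) - I) / I < 1e-2


def test_reciprocity_negates_fields(slab):
    grid, C, montage = slab
    u1 = solve_conduction(grid, C, montage)
    u2 = solve_conduction(grid, C, montage.reversed())
    assert np.allclose(u2.values, -u1.values, atol=1e-14)
    J1 = current_density(u1, C)
    J2 = current_density(u2, C)
    assert np.allclose(J2.values, -J1.values, atol=1e-20)


def test_anisotropic_diagonal_decouples_axes():
    """Diagonal C, u varying only along x: J_y = J_z = 0."""
    grid = VoxelGrid((10, 5, 3), (1.0, 1.0, 1.0))
    comp = np.zeros(grid.shape + (6,))
    comp[..., 0] = 2.0e-3
    comp[..., 1] = 1.0e-3
    comp[..., 2] = 0.5e-3
    C = TensorField(grid, comp, units="S/mm")
    u = solve_conduction(grid, C, plate_montage(grid, axis=0))
    J = current_density(u, C)
    j_scale = np.abs(J.values[..., 0]).max()
    assert np.allclose(J.values[..., 1], 0.0, atol=1e-10 * j_scale)
    assert np.allclose(J.values[..., 2], 0.0, atol=1e-10 * j_scale)


def test_cross_term_solver_bends_current_correctly():
    """Uniform full tensor in a long slab: mid-slab ∇u ∝ C⁻¹·(current dir).

    Conservation forces J ≈ (I/A)·x̂ far from the plates, so the measured
    voltage gradient must match -C⁻¹J including off-diagonal coupling.
    """
    grid = VoxelGrid((40, 7, 5), (1.0, 1.0, 1.0))
    mat = np.array([[2.0, 0.6, 0.3],
                    [0.6, 1.5, 0.2],
                    [0.3, 0.2, 1.0]]) * 1e-3
    comp = np.zeros(grid.shape + (6,))
    comp[..., :] = [mat[0, 0], mat[1, 1], mat[2, 2],
                    mat[0, 1], mat[0, 2], mat[1, 2]]
    C = TensorField(grid, comp, units="S/mm")
    montage = plate_montage(grid, axis=0, current_ma=1.0)
    u = solve_conduction(grid, C, montage)
    area = 7.0 * 5.0
    J_expect = np.array([-1e-3 / area, 0.0, 0.0])
    grad_expect = -np.linalg.solve(mat, J_expect)
    # central voxel line, away from the plates
    gx = (u.values[21, 3, 2] - u.values[19, 3, 2]) / 2.0
    gy = (u.values[20, 4, 2] - u.values[20, 2, 2]) / 2.0
    gz = (u.values[20, 3, 3] - u.values[20, 3, 1]) / 2.0
    got = np.array([gx, gy, gz])
    assert np.allclose(got, grad_expect, rtol=0.05)


def test_disconnected_mask_rejected():
    mask = np.zeros((8, 4, 3), dtype=bool)
    mask[:3] = True
    mask[5:] = True
    grid = VoxelGrid((8, 4, 3), (1.0, 1.0, 1.0), mask=mask)
    C = TensorField.isotropic(grid, 1e-3)
    with pytest.raises(ValueError, match="connected"):
        ConductionSystem(grid, C)


def test_non_positive_definite_tensor_rejected(slab):
    grid, C, montage = slab
    bad = C.copy()
    bad.values[..., 2] = -1e-3
    with pytest.raises(ValueError, match="positive definite"):
        solve_conduction(grid, bad, montage)


# --- Biot-Savart ---------------------------------------------------------

def test_biot_savart_zero_current_zero_field():
    grid = VoxelGrid((6, 6, 4), (1.0, 1.0, 1.0))
    J = VectorField(grid, np.zeros(grid.shape + (3,)))
    for method in ("direct", "fft"):
        bz = biot_savart_bz(J, grid, method=method, z_subdivide=1)
        assert np.all(bz.values == 0.0)


def test_biot_savart_fft_equals_direct():
    """Identical midpoint quadrature: fft and direct agree to 1e-10."""
    rng = np.random.default_rng(42)
    grid = VoxelGrid((16, 16, 4), (1.0, 1.2, 2.0))
    J = VectorField(grid, rng.normal(size=grid.shape + (3,)))
    bz_fft = biot_savart_bz(J, grid, method="fft", z_subdivide=1,
                            near_field_refine=0)
    bz_dir = biot_savart_bz(J, grid, method="direct")
    scale = np.abs(bz_dir.values).max()
    assert np.abs(bz_fft.values - bz_dir.values).max() < 1e-10 * scale


def test_in_plane_filament_bz_matches_finite_segment_formula():
    """A single y-directed filament: B_z from the analytic segment field."""
    grid = VoxelGrid((21, 21, 3), (1.0, 1.0, 1.0))
    J = np.zeros(grid.shape + (3,))
    I = 1e-3  # A; J_y = I / cross-section (1 mm²)
    J[10, :, 1, 1] = I / 1.0
    bz = biot_savart_bz(VectorField(grid, J), grid, method="direct")
    # analytic finite-segment field of the y-filament through (x0,z0) =
    # (10,1), spanning y in [-0.5, 20.5]; at a field point with dz = 0
    # the field is ±z-directed with B_z = -|B|·sign(dx)
    x, y, z = 16.0, 10.0, 1.0
    rho = np.hypot(x - 10.0, z - 1.0)
    l1, l2 = y - (-0.5), 20.5 - y
    sines = l1 / np.hypot(l1, rho) + l2 / np.hypot(l2, rho)
    b_mag = 1e-4 * I / rho * sines * 1e9  # μ0 I/(4πρ)(sinα1+sinα2), nT
    got = bz.values[16, 10, 1]
    # voxel quadrature vs line integral: agree to a few percent at 6 mm
    assert np.isclose(got, -b_mag, rtol=0.05)


def test_uniform_reference_invariances(cylinder_study):
    """J0, Bz0 invariant to C0; J0 mirror-symmetric about the montage axis."""
    s = cylinder_study
    grid = s.grid
    u1, J1, B1 = uniform_reference(grid, s.montages["vertical"], 1.0e-3)
    u2, J2, B2 = uniform_reference(grid, s.montages["vertical"], 2.0e-3)
    assert np.allclose(J1.values, J2.values, rtol=1e-9, atol=1e-18)
    assert np.allclose(B1.values, B2.values, rtol=1e-9, atol=1e-12)
    # mirror symmetry x -> -x for the vertical (±y) electrode pair
    jx = J1.values[:, :, 2, 0]
    jy = J1.values[:, :, 2, 1]
    assert np.abs(jx + jx[::-1, :]).max() < 1e-8 * np.abs(jy).max()
    assert np.abs(jy - jy[::-1, :]).max() < 1e-8 * np.abs(jy).max()
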