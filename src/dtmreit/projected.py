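"""Projected current density from measured B_z and a uniform-model prediction.

The in-plane, divergence-free part of the true current density that is
observable from B_z alone is recovered by solving, slice by slice,

    ∇²_xy ψ = ∇²B_z^m / μ0   in Ω_t,    ψ = 0 on ∂Ω_t,

and forming J^P = J0 + (∂ψ/∂y, −∂ψ/∂x, 0), where J0 is the current
density predicted by a homogeneous, isotropic model of the same domain
and montage.  The regional variant restricts the solve to a region
R_t ⊂ Ω_t with the inhomogeneous Dirichlet data ψ = (B_z^m − B_z,0)/μ0
on ∂R_t, valid because the normal current component is continuous across
the (interior) region boundary.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .forward import MU0_T_MM_PER_A
from .grid import ScalarField, VectorField, VoxelGrid

__all__ = [
    "SliceRegion",
    "SlicePoisson",
    "project_full",
    "project_regional",
    "laplacian_bz",
]

_NT_TO_T = 1e-9

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _check_simply_connected(mask2d: np.ndarray, what: str) -> None:
    _, n = ndi.label(mask2d, structure=_CROSS)
    if n != 1:
        raise ValueError(f"{what} is not connected ({n} components)")
    padded = np.pad(~mask2d, 1, constant_values=True)
    _, n_holes = ndi.label(padded, structure=_CROSS)
    if n_holes != 1:
        raise ValueError(f"{what} has holes (interior not simply connected)")


def boundary_ring(mask2d: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one 4-neighbour outside the mask."""
    eroded = ndi.binary_erosion(mask2d, structure=_CROSS, border_value=0)
    return mask2d & ~eroded


class SliceRegion:
    """A simply connected region R_t within one axial slice Ω_t."""

    def __init__(self, grid: VoxelGrid, k: int, region_mask: np.ndarray):
        region_mask = np.asarray(region_mask, dtype=bool)
        slice_mask = grid.slice_mask(k)
        if region_mask.shape != slice_mask.shape:
            raise ValueError("region mask shape mismatch")
        if not region_mask.any():
            raise ValueError("region is empty")
        if (region_mask & ~slice_mask).any():
            raise ValueError("region extends outside the slice mask")
        _check_simply_connected(region_mask, "region R_t")
        self.grid = grid
        self.k = int(k)
        self.mask = region_mask
        self.ring = boundary_ring(region_mask)

    def touches_domain_boundary(self) -> bool:
        return bool((self.mask & boundary_ring(self.grid.slice_mask(self.k))).any())


class SlicePoisson:
    """Prefactorised 5-point Dirichlet Poisson solver on a 2-D mask.

    Unknowns are the mask voxels strictly inside the boundary ring; the
    ring carries the Dirichlet data.  The sparse LU factorisation is kept
    so that many right-hand sides (e.g. one per training model) can be
    solved at negligible cost.
    """

    def __init__(self, mask2d: np.ndarray, spacing_xy: tuple[float, float]):
        _check_simply_connected(mask2d, "slice mask")
        self.mask = np.asarray(mask2d, dtype=bool)
        self.ring = boundary_ring(self.mask)
        self.interior = self.mask & ~self.ring
        self.hx, self.hy = spacing_xy
        if not self.interior.any():
            raise ValueError("mask has no interior voxels")
        nx, ny = self.mask.shape
        index = -np.ones((nx, ny), dtype=np.int64)
        n = int(self.interior.sum())
        index[self.interior] = np.arange(n)
        self.index = index
        rows, cols, vals = [], [], []
        ii, jj = np.nonzero(self.interior)
        cx = 1.0 / self.hx**2
        cy = 1.0 / self.hy**2
        diag = -2.0 * (cx + cy)
        # ring-neighbour coefficients are moved to the RHS at solve time
        self._ring_terms = []  # (row, ring_i, ring_j, coeff)
        for di, dj, c in ((1, 0, cx), (-1, 0, cx), (0, 1, cy), (0, -1, cy)):
            ni, nj = ii + di, jj + dj
            r = index[ii, jj]
            is_unknown = self.interior[ni, nj]
            rows.append(r[is_unknown])
            cols.append(index[ni[is_unknown], nj[is_unknown]])
            vals.append(np.full(int(is_unknown.sum()), c))
            on_ring = ~is_unknown  # by construction the neighbour is masked
            self._ring_terms.append((r[on_ring], ni[on_ring], nj[on_ring], c))
        rows.append(index[ii, jj])
        cols.append(index[ii, jj])
        vals.append(np.full(n, diag))
        A = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n)).tocsc()
        self._lu = spla.splu(A)

    def solve(self, rhs2d: np.ndarray,
              boundary2d: np.ndarray | float = 0.0) -> np.ndarray:
        """Solve ∇²_xy u = rhs with u = boundary on the ring; full 2-D out."""
        if np.isscalar(boundary2d):
            bvals = np.full(self.mask.shape, float(boundary2d))
        else:
            bvals = np.asarray(boundary2d, dtype=float)
        b = rhs2d[self.interior].astype(float).copy()
        for r, ni, nj, c in self._ring_terms:
            np.add.at(b, r, -c * bvals[ni, nj])
        x = self._lu.solve(b)
        out = np.zeros(self.mask.shape)
        out[self.interior] = x
        out[self.ring] = bvals[self.ring]
        return out


def _masked_smooth2d(vals: np.ndarray, mask: np.ndarray, sigma: float):
    """Gaussian smoothing renormalised to the mask (no bleed from outside)."""
    v = np.where(mask, vals, 0.0)
    num = ndi.gaussian_filter(v, sigma)
    den = ndi.gaussian_filter(mask.astype(float), sigma)
    out = np.divide(num, den, out=np.zeros_like(num), where=den > 1e-12)
    return np.where(mask, out, 0.0)


def laplacian_bz(bz: ScalarField, k: int, mode: str = "3d",
                 smooth_sigma: float = 0.5) -> np.ndarray:
    """Discrete Laplacian of B_z (nT/mm²) on slice k.

    In-plane: 5-point stencil.  ``mode="3d"`` adds the second z-difference
    where both neighbouring slices exist (the physically complete
    Laplacian, since ∇²B = −μ0∇×J); ``mode="2d"`` is in-plane only.
    An optional Gaussian pre-smoothing (σ in voxels, in-plane) tames the
    noise amplification of the second differences; set 0 to disable.
    """
    grid = bz.grid
    hx, hy, hz = grid.spacing
    m2 = grid.slice_mask(k)
    sl = bz.values[:, :, k]
    if smooth_sigma and smooth_sigma > 0:
        sl = _masked_smooth2d(sl, m2, smooth_sigma)
    lap = np.zeros_like(sl)
    interior = m2 & ndi.binary_erosion(m2, structure=_CROSS, border_value=0)
    ii, jj = np.nonzero(interior)
    lap[ii, jj] = ((sl[ii + 1, jj] - 2 * sl[ii, jj] + sl[ii - 1, jj]) / hx**2
                   + (sl[ii, jj + 1] - 2 * sl[ii, jj] + sl[ii, jj - 1]) / hy**2)
    if mode == "3d" and 0 < k < grid.shape[2] - 1:
        up = bz.values[:, :, k + 1]
        dn = bz.values[:, :, k - 1]
        if smooth_sigma and smooth_sigma > 0:
            up = _masked_smooth2d(up, grid.slice_mask(k + 1), smooth_sigma)
            dn = _masked_smooth2d(dn, grid.slice_mask(k - 1), smooth_sigma)
        ok = interior & grid.slice_mask(k + 1) & grid.slice_mask(k - 1)
        lap[ok] += (up[ok] - 2 * sl[ok] + dn[ok]) / hz**2
    elif mode not in ("2d", "3d"):
        raise ValueError(f"unknown Laplacian mode {mode!r}")
    return lap


def _masked_d1(vals: np.ndarray, mask2d: np.ndarray, axis: int,
               h: float) -> np.ndarray:
    """First derivative along an in-plane axis, central/one-sided in-mask."""
    v = np.where(mask2d, vals, 0.0)
    vp = np.zeros_like(v)
    vm = np.zeros_like(v)
    mp = np.zeros_like(mask2d)
    mm = np.zeros_like(mask2d)
    if axis == 0:
        vp[:-1] = v[1:]
        mp[:-1] = mask2d[1:]
        vm[1:] = v[:-1]
        mm[1:] = mask2d[:-1]
    else:
        vp[:, :-1] = v[:, 1:]
        mp[:, :-1] = mask2d[:, 1:]
        vm[:, 1:] = v[:, :-1]
        mm[:, 1:] = mask2d[:, :-1]
    out = np.zeros_like(v)
    both = mask2d & mp & mm
    out[both] = (vp[both] - vm[both]) / (2 * h)
    onlyp = mask2d & mp & ~mm
    out[onlyp] = (vp[onlyp] - v[onlyp]) / h
    onlym = mask2d & mm & ~mp
    out[onlym] = (v[onlym] - vm[onlym]) / h
    return out


def project_full(bz_m: ScalarField, J0: VectorField, k: int,
                 mode: str = "3d", smooth_sigma: float = 0.5,
                 poisson: SlicePoisson | None = None,
                 stray_bz: ScalarField | None = None) -> VectorField:
    """Full-domain projected current density on slice k.

    Returns a vector field populated on slice k only (other slices are
    flagged undefined).  ``stray_bz``, if given, is a precomputed stray
    magnetic field (e.g. from lead wires) subtracted from B_z^m first.
    ``poisson`` may carry a prefactorised solver for the slice mask.
    """
    grid = bz_m.grid
    grid.require_compatible(J0.grid)
    if stray_bz is not None:
        bz_m = ScalarField(grid, bz_m.values - stray_bz.values, bz_m.units,
                           bz_m.undefined)
    m2 = grid.slice_mask(k)
    hx, hy, _ = grid.spacing
    if poisson is None:
        poisson = SlicePoisson(m2, (hx, hy))
    lap = laplacian_bz(bz_m, k, mode=mode, smooth_sigma=smooth_sigma)
    rhs = lap * _NT_TO_T / MU0_T_MM_PER_A  # A/mm³
    psi = poisson.solve(rhs, 0.0)
    cx, cy = _curl_psi_fast(psi, m2, hx, hy)
    vals = np.zeros(grid.shape + (3,))
    vals[:, :, k, 0] = np.where(m2, J0.values[:, :, k, 0] + cx, 0.0)
    vals[:, :, k, 1] = np.where(m2, J0.values[:, :, k, 1] + cy, 0.0)
    vals[:, :, k, 2] = np.where(m2, J0.values[:, :, k, 2], 0.0)
    undef = np.ones(grid.shape, dtype=bool)
    undef[:, :, k] = ~m2
    return VectorField(grid, vals, units="A/mm^2", undefined=undef)


def project_regional(bz_m: ScalarField, bz0: ScalarField, J0: VectorField,
                     region: SliceRegion, mode: str = "3d",
                     smooth_sigma: float = 0.5,
                     stray_bz: ScalarField | None = None) -> VectorField:
    """Regional projected current density inside R_t on the region's slice.

    The Poisson problem carries the inhomogeneous Dirichlet data
    ψ = (B_z^m − B_z,0)/μ0 on ∂R_t; the region must not touch ∂Ω, where
    the normal-continuity assumption behind that data breaks down.
    """
    grid = bz_m.grid
    grid.require_compatible(bz0.grid)
    grid.require_compatible(J0.grid)
    if region.touches_domain_boundary():
        raise ValueError("region R_t touches the domain boundary ∂Ω; "
                         "regional projection is invalid there")
    if stray_bz is not None:
        bz_m = ScalarField(grid, bz_m.values - stray_bz.values, bz_m.units,
                           bz_m.undefined)
    k = region.k
    hx, hy, _ = grid.spacing
    poisson = SlicePoisson(region.mask, (hx, hy))
    lap = laplacian_bz(bz_m, k, mode=mode, smooth_sigma=smooth_sigma)
    rhs = lap * _NT_TO_T / MU0_T_MM_PER_A
    bdata = (bz_m.values[:, :, k] - bz0.values[:, :, k]) * _NT_TO_T \
        / MU0_T_MM_PER_A
    psi = poisson.solve(rhs, bdata)
    cx, cy = _curl_psi_fast(psi, region.mask, hx, hy)
    vals = np.zeros(grid.shape + (3,))
    vals[:, :, k, 0] = np.where(region.mask, J0.values[:, :, k, 0] + cx, 0.0)
    vals[:, :, k, 1] = np.where(region.mask, J0.values[:, :, k, 1] + cy, 0.0)
    vals[:, :, k, 2] = np.where(region.mask, J0.values[:, :, k, 2], 0.0)
    undef = np.ones(grid.shape, dtype=bool)
    undef[:, :, k] = ~region.mask
    return VectorField(grid, vals, units="A/mm^2", undefined=undef)


def _curl_psi_fast(psi: np.ndarray, mask2d: np.ndarray, hx: float, hy: float):
    """(∂ψ/∂y, −∂ψ/∂x) with vectorised masked differences."""
    return _masked_d1(psi, mask2d, 1, hy), -_masked_d1(psi, mask2d, 0, hx)
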