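"""Single-current scale-factor reconstruction via the dual-loop KVL network.

Since J = −ηD∇u, the quantity (D⁻¹J)/η equals the electric field, and the
Kirchhoff voltage law makes its line integral around any closed loop
vanish.  Discretising each axial slice as a rectangular node lattice,
every interior node (i, j) contributes two overlapping counter-clockwise
loops:

* a primary loop over the cell with corners (i−1,j−1), (i,j−1), (i,j),
  (i−1,j), whose edge terms are collapsed onto the nodes
  (i,j−1), (i,j), (i,j), (i−1,j);
* a secondary loop of the same size shifted by half a voxel so that it is
  centred on the node, with edge terms on (i,j), (i+1,j), (i,j+1), (i,j).

(D⁻¹J) components are evaluated at the loop-edge midpoints by linear
interpolation of the nodal values.  With η known on the slice-boundary
ring, the loops form an overdetermined sparse system A X = B — for a full
N_x×N_y rectangle, 2(N_x−2)(N_y−2) equations in (N_x−2)(N_y−2) unknowns —
where X holds the *inverse* scale factor 1/η at the interior nodes (the
KVL terms (D⁻¹J)·(1/η) are then voltage drops).  It is solved by
Tikhonov-regularised least squares, X = (AᵀA + λI)⁻¹AᵀB, and inverted
back to η.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import TensorField, VectorField
from .projected import boundary_ring

__all__ = [
    "dinv_j",
    "LoopSystem",
    "assemble_loop_system",
    "solve_loop_system",
    "reconstruct_dual_loop",
]

#: condition-number threshold above which a voxel's D is treated as singular
COND_LIMIT = 1e6


def dinv_j(D: TensorField, J: VectorField) -> VectorField:
    """Per-voxel D⁻¹J (the electric field scaled by η).

    Voxels where D is near-singular (condition number > 1e6) are flagged
    undefined and excluded from loop assembly downstream.
    """
    D.grid.require_compatible(J.grid)
    mask = D.defined_mask & J.defined_mask
    mats = D.as_matrices()[mask]
    rhs = J.values[mask]
    w = np.linalg.eigvalsh(mats)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.abs(w[:, 2]) / np.abs(w[:, 0])
    bad = ~np.isfinite(cond) | (cond > COND_LIMIT) | (w[:, 0] <= 0)
    sol = np.zeros_like(rhs)
    if (~bad).any():
        sol[~bad] = np.linalg.solve(mats[~bad], rhs[~bad][..., None])[..., 0]
    out = np.zeros(D.grid.shape + (3,))
    out[mask] = sol
    undefined = ~mask.copy()
    flat = np.argwhere(mask)
    undefined[tuple(flat[bad].T)] = True
    return VectorField(D.grid, out, units="A*s/mm^4",
                       undefined=undefined)


@dataclass
class LoopSystem:
    """Assembled dual-loop system for one slice."""

    A_p: sp.csr_matrix
    A_s: sp.csr_matrix
    B_p: np.ndarray
    B_s: np.ndarray
    node_index: np.ndarray       # 2-D map: interior node -> unknown column
    interior: np.ndarray         # unknown nodes
    ring: np.ndarray             # boundary nodes with known η
    eta_boundary: np.ndarray     # full 2-D array, valid on ring
    mask: np.ndarray             # slice mask

    @property
    def A(self) -> sp.csr_matrix:
        return sp.vstack([self.A_p, self.A_s]).tocsr()

    @property
    def B(self) -> np.ndarray:
        return np.concatenate([self.B_p, self.B_s])


def _mid(F: np.ndarray, i0, j0, i1, j1) -> np.ndarray:
    return 0.5 * (F[i0, j0] + F[i1, j1])


def assemble_loop_system(dinvJ: VectorField, eta_boundary, k: int,
                         drop_warn_fraction: float = 0.05,
                         scheme: str = "product") -> LoopSystem:
    """Build the dual-loop system for slice ``k``.

    ``eta_boundary`` is a scalar or a 2-D array giving η on the slice
    boundary ring.  Loops touching voxels flagged by :func:`dinv_j` are
    dropped; a warning is issued if more than ``drop_warn_fraction`` of
    the slice is affected.

    ``scheme`` selects how the edge voltage drops are discretised:

    * ``"product"`` (default): the integrand E = (D⁻¹J)·(1/η) is
      interpolated along each edge (trapezoid/midpoint rule on the
      product), which is O(h²) consistent and stays exact across
      piecewise-constant η interfaces, where the tangential electric
      field is continuous even though (D⁻¹J) and η both jump;
    * ``"node"``: (D⁻¹J) is interpolated to the edge midpoint and 1/η
      collapsed to a single adjacent node — the literal node-collapsed
      loop equations.  This variant is O(h) and inconsistent at tissue
      interfaces; it is retained for comparison.
    """
    grid = dinvJ.grid
    nx, ny, _ = grid.shape
    if nx < 3 or ny < 3:
        raise ValueError("slice must be at least 3x3 nodes")
    hx, hy, _ = grid.spacing
    m2 = grid.slice_mask(k)
    good = m2 & ~dinvJ.undefined[:, :, k]
    n_flagged = int((m2 & ~good).sum())
    if n_flagged > drop_warn_fraction * m2.sum():
        warnings.warn(f"{n_flagged} of {int(m2.sum())} voxels in slice {k} "
                      "flagged by dinv_j; their loops are dropped",
                      stacklevel=2)
    ring = boundary_ring(m2)
    interior = m2 & ~ring
    if not interior.any():
        raise ValueError("slice has no interior nodes")

    if np.isscalar(eta_boundary):
        eta_b = np.full((nx, ny), float(eta_boundary))
    else:
        eta_b = np.asarray(eta_boundary, dtype=float)
    if (eta_b[ring] <= 0).any():
        raise ValueError("boundary η must be positive")
    s_known = np.zeros((nx, ny))
    s_known[ring] = 1.0 / eta_b[ring]

    node_index = -np.ones((nx, ny), dtype=np.int64)
    n_unknown = int(interior.sum())
    node_index[interior] = np.arange(n_unknown)

    Fx = np.where(good, dinvJ.values[:, :, k, 0], np.nan)
    Fy = np.where(good, dinvJ.values[:, :, k, 1], np.nan)

    ii, jj = np.nonzero(interior)

    def in_good(i, j):
        ok = (i >= 0) & (i < nx) & (j >= 0) & (j < ny)
        out = np.zeros(i.shape, dtype=bool)
        out[ok] = good[i[ok], j[ok]]
        return out

    # loop-stencil availability: primary needs the cell to the lower-left,
    # secondary the half-shifted cell centred on the node
    prim_ok = (in_good(ii - 1, jj - 1) & in_good(ii, jj - 1)
               & in_good(ii - 1, jj) & in_good(ii, jj))
    sec_ok = (in_good(ii, jj - 1) & in_good(ii + 1, jj)
              & in_good(ii, jj + 1) & in_good(ii - 1, jj) & in_good(ii, jj))

    if scheme not in ("product", "node"):
        raise ValueError(f"unknown discretisation scheme {scheme!r}")

    def build_rows(which: str, sel: np.ndarray):
        i = ii[sel]
        j = jj[sel]
        if scheme == "node":
            if which == "primary":
                coeffs = [
                    (+hx * _mid(Fx, i - 1, j - 1, i, j - 1), i, j - 1),
                    (+hy * _mid(Fy, i, j - 1, i, j), i, j),
                    (-hx * _mid(Fx, i - 1, j, i, j), i, j),
                    (-hy * _mid(Fy, i - 1, j - 1, i - 1, j), i - 1, j),
                ]
            else:
                coeffs = [
                    (+hx * _mid(Fx, i, j - 1, i, j), i, j),
                    (+hy * _mid(Fy, i, j, i + 1, j), i + 1, j),
                    (-hx * _mid(Fx, i, j, i, j + 1), i, j + 1),
                    (-hy * _mid(Fy, i - 1, j, i, j), i, j),
                ]
        elif which == "primary":
            # trapezoid rule on E along the four cell edges (CCW)
            coeffs = [
                (+0.5 * hx * Fx[i - 1, j - 1], i - 1, j - 1),
                (+0.5 * hx * Fx[i, j - 1], i, j - 1),
                (+0.5 * hy * Fy[i, j - 1], i, j - 1),
                (+0.5 * hy * Fy[i, j], i, j),
                (-0.5 * hx * Fx[i, j], i, j),
                (-0.5 * hx * Fx[i - 1, j], i - 1, j),
                (-0.5 * hy * Fy[i - 1, j], i - 1, j),
                (-0.5 * hy * Fy[i - 1, j - 1], i - 1, j - 1),
            ]
        else:
            # midpoint rule on E along the half-shifted loop's edges,
            # each midpoint lying between two nodes
            coeffs = [
                (+0.5 * hx * Fx[i, j - 1], i, j - 1),
                (+0.5 * hx * Fx[i, j], i, j),
                (+0.5 * hy * Fy[i, j], i, j),
                (+0.5 * hy * Fy[i + 1, j], i + 1, j),
                (-0.5 * hx * Fx[i, j], i, j),
                (-0.5 * hx * Fx[i, j + 1], i, j + 1),
                (-0.5 * hy * Fy[i - 1, j], i - 1, j),
                (-0.5 * hy * Fy[i, j], i, j),
            ]
        n_rows = i.size
        rows_idx = np.arange(n_rows)
        r_list, c_list, v_list = [], [], []
        rhs = np.zeros(n_rows)
        for coeff, ci, cj in coeffs:
            col = node_index[ci, cj]
            unknown = col >= 0
            r_list.append(rows_idx[unknown])
            c_list.append(col[unknown])
            v_list.append(coeff[unknown])
            known = ~unknown
            # known boundary nodes move to the right-hand side
            np.subtract.at(rhs, rows_idx[known],
                           coeff[known] * s_known[ci[known], cj[known]])
        A = sp.coo_matrix(
            (np.concatenate(v_list),
             (np.concatenate(r_list), np.concatenate(c_list))),
            shape=(n_rows, n_unknown)).tocsr()
        return A, rhs

    A_p, B_p = build_rows("primary", prim_ok)
    A_s, B_s = build_rows("secondary", sec_ok)
    return LoopSystem(A_p, A_s, B_p, B_s, node_index, interior, ring,
                      eta_b, m2)


def solve_loop_system(system: LoopSystem, lam: float | None = None,
                      prior: str | float | None = "boundary") -> np.ndarray:
    """Regularised least-squares solve of the dual-loop system.

    X = (AᵀA + λI)⁻¹(AᵀB + λX₀) on the inverse scale factor; λ defaults
    to 10⁻³ · mean(diag(AᵀA)) (a scale-free Tikhonov floor).  The shift
    X₀ is the Tikhonov prior: ``"boundary"`` (default) pulls weakly
    constrained nodes toward the boundary inverse scale factor — the
    plain zero-shift form would pull 1/η toward 0, i.e. inflate η without
    bound along weakly-anchored equipotential chains; ``prior=None`` or
    ``0.0`` gives that unshifted form.  Returns the η̂ image for the
    slice as a 2-D array: interior nodes 1/X, ring nodes the supplied
    boundary η.  Interior nodes untouched by any loop (possible next to
    dropped voxels) are filled from their nearest reconstructed
    neighbour.
    """
    A = system.A.tocsc()
    B = system.B
    G = (A.T @ A).tocsc()
    diag = G.diagonal()
    if lam is None:
        lam = 1e-3 * float(diag.mean())
    if lam < 0:
        raise ValueError("regularisation parameter must be >= 0")
    touched = diag > 0
    if lam == 0 and not touched.all():
        raise ValueError("system is rank deficient with λ = 0; "
                         "use λ > 0")
    if prior == "boundary":
        x0 = float(np.mean(1.0 / system.eta_boundary[system.ring]))
    elif prior is None:
        x0 = 0.0
    else:
        x0 = float(prior)
    n = G.shape[0]
    H = G + lam * sp.identity(n, format="csc")
    try:
        X = spla.spsolve(H, A.T @ B + lam * x0)
    except Exception as exc:  # pragma: no cover
        raise ValueError(f"loop-system solve failed: {exc}") from exc
    if lam == 0 and not np.all(np.isfinite(X)):
        raise ValueError("singular normal equations with λ = 0; use λ > 0")

    eta = np.zeros(system.mask.shape)
    # invert back to η; guard non-positive inverse values
    with np.errstate(divide="ignore"):
        eta_int = np.where(X > 0, 1.0 / np.maximum(X, 1e-300), np.nan)
    eta[system.interior] = eta_int
    eta[system.ring] = system.eta_boundary[system.ring]
    bad = system.mask & ~np.isfinite(eta)
    untouched = np.zeros(system.mask.shape, dtype=bool)
    untouched[system.interior] = ~touched[system.node_index[system.interior]]
    bad |= untouched
    if bad.any():
        ok = system.mask & ~bad
        _, (inds_i, inds_j) = ndi.distance_transform_edt(
            ~ok, return_indices=True)
        eta[bad] = eta[inds_i[bad], inds_j[bad]]
    eta[~system.mask] = 0.0
    return eta


def reconstruct_dual_loop(D: TensorField, J: VectorField, k: int,
                          eta_boundary, lam: float | None = None,
                          scheme: str = "product",
                          prior: str | float | None = "boundary") -> np.ndarray:
    """η̂ on slice ``k`` from one montage's current density and D."""
    F = dinv_j(D, J)
    system = assemble_loop_system(F, eta_boundary, k, scheme=scheme)
    return solve_loop_system(system, lam, prior=prior)
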