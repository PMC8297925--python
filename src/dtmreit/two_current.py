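"""Two-current DT-MREIT reference algorithm.

The curl-free property of the electric field gives, per slice,

    ∇ln η × (D⁻¹J) = ∇ × (D⁻¹J),

whose z-component relates the unknown in-plane gradient
e = (∂ln η/∂x, ∂ln η/∂y) to the measurable fields.  With two
non-collinear injected currents, each voxel yields a well-posed 2-unknown
weighted least-squares problem assembled over a 3×3 window: rows
[w_i (D⁻¹J)_y, −w_i (D⁻¹J)_x] against w_i (∂_x(D⁻¹J)_y − ∂_y(D⁻¹J)_x),
with MR-magnitude weights w_i = e^{−h‖ρ_i−ρ_c‖}/Σ e^{−h‖ρ_j−ρ_c‖}.
The 2N×2 system is solved by SVD with Tikhonov filtering, the
regularisation constant ζ chosen per voxel by minimising the generalised
cross-validation function

    GCV(ζ) = Σ_i (b̂_i/(s_i²+ζ))² / (Σ_i 1/(s_i²+ζ))² ,

and ln η (relative to 1 S·s/mm³) is recovered from e by a Poisson solve
∇²_xy ln η = ∇_xy·e with the known boundary value as Dirichlet data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .grid import TensorField, VectorField
from .dual_loop import dinv_j
from .projected import SlicePoisson, boundary_ring, _masked_d1

__all__ = [
    "GradientSolveConfig",
    "magnitude_weights",
    "assemble_gradient_system",
    "gcv_function",
    "minimize_gcv",
    "solve_window_gcv",
    "integrate_log_eta",
    "reconstruct_two_current",
]


@dataclass
class GradientSolveConfig:
    """Settings for the windowed gradient solve and log-η integration."""

    window: int = 3
    h: float | None = None          # weight sharpness; None -> 1/sd(ρ)
    eta_boundary: float = 0.5       # S·s/mm³ on ∂Ω_t
    zeta_bracket: tuple[float, float] = (1e-12, 1e2)  # × s1²
    n_zeta_grid: int = 61
    rank1_tol: float = 1e-12        # s2²/s1² below which collinearity is flagged
    log_reference: float = 1.0      # ln η taken relative to 1 S·s/mm³

    def __post_init__(self):
        if self.window % 2 == 0 or self.window < 1:
            raise ValueError("window must be odd and positive")
        if self.h is not None and self.h < 0:
            raise ValueError("weight sharpness h must be >= 0")


def magnitude_weights(rho_window: np.ndarray, h: float,
                      center_index: int | None = None) -> np.ndarray:
    """Normalised MR-magnitude weights over a window (last axis).

    w_i = exp(−h‖ρ_i − ρ_c‖) / Σ_j exp(−h‖ρ_j − ρ_c‖); ρ_c is the centre
    pixel (middle of the window by default).  h = 0 or uniform ρ gives
    uniform weights.
    """
    rho = np.asarray(rho_window, dtype=float)
    n = rho.shape[-1]
    if n == 0:
        raise ValueError("empty window")
    c = n // 2 if center_index is None else center_index
    d = np.abs(rho - rho[..., c:c + 1])
    w = np.exp(-h * d)
    return w / w.sum(axis=-1, keepdims=True)


def gcv_function(b_hat: np.ndarray, s: np.ndarray, zeta, r2=0.0,
                 m=2) -> np.ndarray:
    """Generalised cross-validation function for the SVD data (b̂, s).

    GCV(ζ) = [Σᵢ(ζ b̂ᵢ/(sᵢ²+ζ))² + r²] / [(m−2) + Σᵢ ζ/(sᵢ²+ζ)]²

    where r² = ‖b̃‖² − ‖b̂‖² is the out-of-range residual and m the row
    count of the window system.  With the defaults r² = 0, m = 2 the ζ
    factors cancel and this reduces to the two-singular-value ratio
    Σᵢ(b̂ᵢ/(sᵢ²+ζ))² / (Σᵢ 1/(sᵢ²+ζ))²; the full form keeps the minimiser
    meaningful on consistent data, where the reduced ratio is degenerate.
    """
    b = np.asarray(b_hat, dtype=float)[..., None]
    sv = np.asarray(s, dtype=float)[..., None]
    z = np.atleast_1d(np.asarray(zeta, dtype=float))
    r2v = np.asarray(r2, dtype=float)[..., None]
    mv = np.asarray(m, dtype=float)[..., None]
    denom = sv**2 + z
    num = ((z * b / denom) ** 2).sum(axis=-2) + r2v
    den = ((mv - 2.0) + (z / denom).sum(axis=-2)) ** 2
    out = num / den
    return out if np.ndim(zeta) else out[..., 0]


def minimize_gcv(b_hat: np.ndarray, s: np.ndarray,
                 config: GradientSolveConfig | None = None,
                 r2=0.0, m=2) -> np.ndarray:
    """Per-voxel GCV minimiser over ζ.

    A log-spaced bracket [ζ_lo·s1², ζ_hi·s1²] is scanned, then refined by
    golden-section around the grid minimum; near-ties break toward the
    smallest ζ (the unregularised limit is correct on consistent data).
    Fully vectorised over leading axes; deterministic.
    """
    config = config or GradientSolveConfig()
    b = np.atleast_2d(np.asarray(b_hat, dtype=float))
    sv = np.atleast_2d(np.asarray(s, dtype=float))
    r2a = np.broadcast_to(np.asarray(r2, dtype=float), b.shape[:-1])
    ma = np.broadcast_to(np.asarray(m, dtype=float), b.shape[:-1])
    s1sq = np.maximum(sv[..., 0] ** 2, 1e-300)
    lo = np.log(config.zeta_bracket[0] * s1sq)
    hi = np.log(config.zeta_bracket[1] * s1sq)
    grid = np.linspace(0.0, 1.0, config.n_zeta_grid)
    logz = lo[..., None] + (hi - lo)[..., None] * grid  # (..., G)
    vals = np.stack([_gcv_at_log(b, sv, logz[..., g], r2a, ma)
                     for g in range(config.n_zeta_grid)], axis=-1)
    vmin = vals.min(axis=-1, keepdims=True)
    near = vals <= vmin * (1 + 1e-9) + 1e-300
    imin = np.argmax(near, axis=-1)
    a = np.take_along_axis(logz, np.maximum(imin - 1, 0)[..., None],
                           axis=-1)[..., 0]
    c = np.take_along_axis(logz,
                           np.minimum(imin + 1, config.n_zeta_grid - 1)[..., None],
                           axis=-1)[..., 0]
    # golden-section refinement on log ζ within the bracketing bins
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = c - invphi * (c - a)
    x2 = a + invphi * (c - a)
    f1 = _gcv_at_log(b, sv, x1, r2a, ma)
    f2 = _gcv_at_log(b, sv, x2, r2a, ma)
    for _ in range(40):
        take1 = f1 < f2
        c = np.where(take1, x2, c)
        a = np.where(take1, a, x1)
        x1n = np.where(take1, c - invphi * (c - a), x2)
        x2n = np.where(take1, x1, a + invphi * (c - a))
        f1n = np.where(take1,
                       _gcv_at_log(b, sv, np.where(take1, x1n, x1), r2a, ma),
                       f2)
        f2n = np.where(take1, f1,
                       _gcv_at_log(b, sv, np.where(take1, x2, x2n), r2a, ma))
        x1, x2, f1, f2 = x1n, x2n, f1n, f2n
    zeta = np.exp(0.5 * (a + c))
    return zeta if np.asarray(b_hat).ndim > 1 else zeta[0]


def _gcv_at_log(b, sv, logz, r2, m):
    """GCV at one log-ζ per leading-axis element."""
    z = np.exp(logz)[..., None]
    denom = sv**2 + z
    num = ((z * b / denom) ** 2).sum(axis=-1) + r2
    den = ((m - 2.0) + (z / denom).sum(axis=-1)) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    return np.where(den > 0, out, np.inf)


def assemble_gradient_system(F_star: np.ndarray, F_tilde: np.ndarray,
                             curl_star: np.ndarray, curl_tilde: np.ndarray,
                             weights: np.ndarray):
    """Explicit (2N×2, 2N) window system for one voxel.

    ``F_star``/``F_tilde`` are (N, 2) arrays of (D⁻¹J) x,y components over
    the window for the two montages; ``curl_*`` are the corresponding
    (N,) curl-z values; ``weights`` the (N,) magnitude weights.  Rows are
    interleaved per pixel (both montages for pixel i before pixel i+1);
    the ordering is irrelevant to the normal equations.  A ValueError is
    raised if the two current fields are collinear over the whole window
    (rank-1 system).
    """
    w = np.asarray(weights, dtype=float)
    n = w.size
    A = np.empty((2 * n, 2))
    b = np.empty(2 * n)
    A[0::2, 0] = w * F_star[:, 1]
    A[0::2, 1] = -w * F_star[:, 0]
    A[1::2, 0] = w * F_tilde[:, 1]
    A[1::2, 1] = -w * F_tilde[:, 0]
    b[0::2] = w * curl_star
    b[1::2] = w * curl_tilde
    s = np.linalg.svd(A, compute_uv=False)
    if s[0] == 0 or (s[1] / s[0]) ** 2 < 1e-12:
        raise ValueError("current fields are collinear over the window "
                         "(rank-1 gradient system)")
    return A, b


def solve_window_gcv(A_tilde: np.ndarray, b_tilde: np.ndarray,
                     config: GradientSolveConfig | None = None):
    """Solve one 2N×2 window system with SVD + GCV regularisation.

    Returns (e, ζ*) where e = V diag(s_i/(s_i²+ζ*)) Uᵀb̃ is the Tikhonov-
    filtered gradient of ln η at the window centre.
    """
    config = config or GradientSolveConfig()
    A = np.asarray(A_tilde, dtype=float)
    b = np.asarray(b_tilde, dtype=float)
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    if s[0] == 0:
        raise ValueError("zero stiff matrix: gradient undefined")
    b_hat = U.T @ b
    r2 = max(float(b @ b - b_hat @ b_hat), 0.0)
    zeta = float(minimize_gcv(b_hat, s, config, r2=r2, m=A.shape[0]))
    e = Vt.T @ (s / (s**2 + zeta) * b_hat)
    return e, zeta


def _window_offsets(window: int):
    r = window // 2
    return [(dx, dy) for dx in range(-r, r + 1) for dy in range(-r, r + 1)]


def _shift2d(a: np.ndarray, dx: int, dy: int, fill=0.0):
    out = np.full_like(a, fill)
    sx_src = slice(max(dx, 0), a.shape[0] + min(dx, 0))
    sx_dst = slice(max(-dx, 0), a.shape[0] + min(-dx, 0))
    sy_src = slice(max(dy, 0), a.shape[1] + min(dy, 0))
    sy_dst = slice(max(-dy, 0), a.shape[1] + min(-dy, 0))
    out[sx_dst, sy_dst] = a[sx_src, sy_src]
    return out


def solve_gradient_slice(F_fields: list[np.ndarray], rho: np.ndarray,
                         mask2d: np.ndarray, spacing_xy, config=None):
    """Vectorised windowed GCV solve of ∇ln η over a whole slice.

    ``F_fields`` is a list of (Nx, Ny, 2) in-plane (D⁻¹J) fields, one per
    montage.  Returns (e, defined) with e of shape (Nx, Ny, 2); voxels
    whose window system is degenerate are left undefined.
    """
    config = config or GradientSolveConfig()
    hx, hy = spacing_xy
    if config.h is None:
        sd = float(np.std(rho[mask2d])) if mask2d.any() else 0.0
        h = 1.0 / sd if sd > 0 else 0.0
    else:
        h = config.h
    curls = [
        _masked_d1(F[..., 1], mask2d, 0, hx) - _masked_d1(F[..., 0], mask2d, 1, hy)
        for F in F_fields
    ]
    centers = mask2d & ~boundary_ring(mask2d)
    # accumulate AᵀA (2×2 symmetric) and Aᵀb per voxel over window shifts
    g11 = np.zeros(mask2d.shape)
    g12 = np.zeros(mask2d.shape)
    g22 = np.zeros(mask2d.shape)
    r1 = np.zeros(mask2d.shape)
    r2 = np.zeros(mask2d.shape)
    bb = np.zeros(mask2d.shape)       # ‖b̃‖² per window
    mrows = np.zeros(mask2d.shape)    # row count per window
    wsum = np.zeros(mask2d.shape)
    rho_m = np.where(mask2d, rho, 0.0)
    # first pass: weight normalisation per centre
    shift_cache = []
    for (dx, dy) in _window_offsets(config.window):
        valid = _shift2d(mask2d.astype(float), dx, dy) > 0
        w_raw = np.where(valid, np.exp(-h * np.abs(
            _shift2d(rho_m, dx, dy) - rho_m)), 0.0)
        shift_cache.append(((dx, dy), valid, w_raw))
        wsum += w_raw
    for (dx, dy), valid, w_raw in shift_cache:
        w = np.divide(w_raw, wsum, out=np.zeros_like(w_raw), where=wsum > 0)
        w2 = w * w
        mrows += 2.0 * valid
        for F, curl in zip(F_fields, curls):
            fx = _shift2d(F[..., 0], dx, dy)
            fy = _shift2d(F[..., 1], dx, dy)
            cz = _shift2d(curl, dx, dy)
            g11 += w2 * fy * fy
            g12 += -w2 * fx * fy
            g22 += w2 * fx * fx
            r1 += w2 * fy * cz
            r2 += -w2 * fx * cz
            bb += w2 * cz * cz
    # eigen-decomposition of the 2×2 normal matrix -> singular values of Ã
    tr = g11 + g22
    det = g11 * g22 - g12 * g12
    disc = np.sqrt(np.maximum((0.5 * tr) ** 2 - det, 0.0))
    lam1 = 0.5 * tr + disc
    lam2 = np.maximum(0.5 * tr - disc, 0.0)
    defined = centers & (lam1 > 0) & (lam2 / np.maximum(lam1, 1e-300)
                                      > config.rank1_tol)
    idx = np.nonzero(defined)
    l1 = lam1[idx]
    l2 = lam2[idx]
    # eigenvectors of [[g11,g12],[g12,g22]]
    a12 = g12[idx]
    a11 = g11[idx]
    v1 = np.stack([a12, l1 - a11], axis=-1)
    nrm = np.linalg.norm(v1, axis=-1)
    small = nrm < 1e-30
    v1[small] = np.array([1.0, 0.0])
    v1 /= np.linalg.norm(v1, axis=-1, keepdims=True)
    v2 = np.stack([-v1[:, 1], v1[:, 0]], axis=-1)
    s = np.stack([np.sqrt(l1), np.sqrt(l2)], axis=-1)
    atb = np.stack([r1[idx], r2[idx]], axis=-1)
    # b̂_i = (1/s_i) v_iᵀ(Ãᵀb̃)
    proj = np.stack([np.einsum("ij,ij->i", v1, atb),
                     np.einsum("ij,ij->i", v2, atb)], axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        b_hat = np.where(s > 0, proj / np.maximum(s, 1e-300), 0.0)
    resid2 = np.maximum(bb[idx] - (b_hat**2).sum(axis=-1), 0.0)
    zeta = minimize_gcv(b_hat, s, config, r2=resid2, m=mrows[idx])
    filt = s / (s**2 + zeta[..., None])
    e_vec = (v1 * (filt[:, 0] * b_hat[:, 0])[:, None]
             + v2 * (filt[:, 1] * b_hat[:, 1])[:, None])
    e = np.zeros(mask2d.shape + (2,))
    e[idx[0], idx[1], :] = e_vec
    return e, defined


def integrate_log_eta(e: np.ndarray, eta_boundary, mask2d: np.ndarray,
                      spacing_xy, defined: np.ndarray | None = None,
                      poisson: SlicePoisson | None = None) -> np.ndarray:
    """η̃ from its log-gradient by a Dirichlet Poisson solve.

    Solves ∇²_xy ln η = ∇_xy·e with ln η = ln η_∂Ω on the slice boundary
    ring, then exponentiates.  Undefined e voxels are infilled from the
    nearest defined neighbour before the divergence is taken.
    """
    if np.isscalar(eta_boundary):
        if eta_boundary <= 0:
            raise ValueError("boundary η must be positive")
        eta_b = np.full(mask2d.shape, float(eta_boundary))
    else:
        eta_b = np.asarray(eta_boundary, dtype=float)
        if (eta_b[boundary_ring(mask2d)] <= 0).any():
            raise ValueError("boundary η must be positive")
    hx, hy = spacing_xy
    e = np.asarray(e, dtype=float)
    if defined is not None and (mask2d & ~defined).any():
        ok = mask2d & defined
        if not ok.any():
            raise ValueError("no defined gradient voxels to integrate")
        _, (pi, pj) = ndi.distance_transform_edt(~ok, return_indices=True)
        e = e.copy()
        fill = mask2d & ~defined
        e[fill] = e[pi[fill], pj[fill]]
    rhs = (_masked_d1(e[..., 0], mask2d, 0, hx)
           + _masked_d1(e[..., 1], mask2d, 1, hy))
    if poisson is None:
        poisson = SlicePoisson(mask2d, (hx, hy))
    log_eta = poisson.solve(rhs, np.log(eta_b, where=eta_b > 0,
                                        out=np.zeros_like(eta_b)))
    out = np.where(mask2d, np.exp(log_eta), 0.0)
    return out


def reconstruct_two_current(D: TensorField, JP_star: VectorField,
                            JP_tilde: VectorField, k: int,
                            rho: np.ndarray | None = None,
                            config: GradientSolveConfig | None = None,
                            poisson: SlicePoisson | None = None) -> np.ndarray:
    """Two-current DT-MREIT η̃ on slice ``k``.

    ``JP_star``/``JP_tilde`` are the projected current densities of the
    two montages.  Montage order is irrelevant (the normal equations are
    symmetric in the two blocks).
    """
    config = config or GradientSolveConfig()
    grid = D.grid
    m2 = grid.slice_mask(k)
    F1 = dinv_j(D, JP_star)
    F2 = dinv_j(D, JP_tilde)
    Fs = [np.where(m2[..., None], F.values[:, :, k, :2], 0.0) for F in (F1, F2)]
    rho = np.ones(m2.shape) if rho is None else rho
    e, defined = solve_gradient_slice(Fs, rho, m2, grid.spacing[:2], config)
    return integrate_log_eta(e, config.eta_boundary, m2, grid.spacing[:2],
                             defined=defined, poisson=poisson)
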