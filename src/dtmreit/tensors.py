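"""Diffusion-tensor estimation and conductivity-tensor algebra.

The water diffusion tensor D is fitted per voxel from diffusion-weighted
signals via (gʲ)ᵀD gʲ = −(1/b) ln(S_bʲ/S₀) over N_d ≥ 6 unit gradient
directions; the conductivity tensor is the DT-MREIT scaling C = ηD, which
shares D's eigenvectors and eigenvalue ratios.  Derived scalars follow
the conventions used for reporting muscle anisotropy: the anisotropic
ratio AR = 2λ₁/(λ₂+λ₃) and the isotropic equivalent √(C_l·C_t) with
C_l = λ₁ and C_t = (λ₂+λ₃)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import ScalarField, TensorField, VectorField, VoxelGrid

__all__ = [
    "DwiScheme",
    "dwi_design_matrix",
    "synthesize_dwi_signals",
    "fit_diffusion_tensor",
    "assemble_conductivity",
    "electric_field",
    "anisotropic_ratio",
    "isotropic_equivalent",
    "roi_summary",
    "SIX_DIRECTION_SCHEME",
]

#: classic six-direction DTI scheme (rows normalised below)
SIX_DIRECTION_SCHEME = np.array([
    [1, 1, 0], [0, 1, 1], [1, 0, 1], [1, -1, 0], [0, 1, -1], [1, 0, -1],
], dtype=float) / np.sqrt(2.0)


@dataclass
class DwiScheme:
    """Diffusion acquisition: directions, b-value and signal volumes."""

    directions: np.ndarray          # (N_d, 3) unit vectors
    b_value: float                  # s/mm²
    s0: np.ndarray                  # reference volume, b = 0
    signals: np.ndarray             # (..., N_d) diffusion-weighted volumes
    grid: VoxelGrid | None = None

    def __post_init__(self):
        g = np.asarray(self.directions, dtype=float)
        if g.ndim != 2 or g.shape[1] != 3:
            raise ValueError("directions must be (N_d, 3)")
        if g.shape[0] < 6:
            raise ValueError("at least six gradient directions are required")
        norms = np.linalg.norm(g, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("gradient directions must be unit vectors")
        if self.b_value <= 0:
            raise ValueError("b-value must be positive")
        self.directions = g

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]

    def condition_number(self) -> float:
        """Condition number of the tensor-fit design matrix.

        Reported so users can judge their scheme (e.g. ~4.7 for the
        classic six-direction scheme, ~1.3 for well-spread 15-direction
        sets); it is diagnostic only.
        """
        return float(np.linalg.cond(dwi_design_matrix(self.directions)))


def dwi_design_matrix(directions: np.ndarray) -> np.ndarray:
    """(N_d, 6) design matrix mapping tensor components to gᵀDg."""
    g = np.asarray(directions, dtype=float)
    return np.stack([
        g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ], axis=1)


def synthesize_dwi_signals(D: TensorField, directions: np.ndarray,
                           b_value: float, s0: float | np.ndarray = 1000.0):
    """Noise-free DWI magnitudes S_bʲ = S₀ exp(−b gʲᵀDgʲ)."""
    G = dwi_design_matrix(directions)
    expo = np.einsum("...c,jc->...j", D.values, G)
    s0 = np.broadcast_to(np.asarray(s0, dtype=float), D.grid.shape)
    sig = s0[..., None] * np.exp(-b_value * expo)
    sig[~D.grid.mask] = 0.0
    s0_vol = np.where(D.grid.mask, s0, 0.0)
    return s0_vol, sig


def fit_diffusion_tensor(scheme: DwiScheme, grid: VoxelGrid | None = None,
                         pd_floor: float = 1e-6) -> TensorField:
    """Least-squares tensor fit per voxel.

    Voxels with non-positive S₀ are flagged undefined.  Fits that come
    out non-positive-definite are clamped to PD by flooring eigenvalues
    at ``pd_floor``·λ₁ and flagged in ``TensorField.undefined``'s
    companion attribute ``clamped_`` on the returned field.
    """
    grid = grid or scheme.grid
    if grid is None:
        grid = VoxelGrid(scheme.s0.shape, (1.0, 1.0, 1.0))
    G = dwi_design_matrix(scheme.directions)
    s0 = np.asarray(scheme.s0, dtype=float)
    sig = np.asarray(scheme.signals, dtype=float)
    valid = grid.mask & (s0 > 0) & (sig > 0).all(axis=-1)
    y = np.zeros(grid.shape + (scheme.n_directions,))
    y[valid] = -np.log(sig[valid] / s0[valid, None]) / scheme.b_value
    pinv = np.linalg.pinv(G)
    comp = np.einsum("cj,...j->...c", pinv, y)
    comp[~valid] = 0.0
    out = TensorField(grid, comp, units="mm^2/s", undefined=~valid)
    # clamp non-PD fits
    mats = out.as_matrices()[valid]
    w, v = np.linalg.eigh(mats)
    need = w[:, 0] <= 0
    clamped = np.zeros(grid.shape, dtype=bool)
    if need.any():
        lam_max = w[:, 2][need]
        w_fixed = np.maximum(w[need], (pd_floor * np.abs(lam_max))[:, None])
        fixed = np.einsum("nij,nj,nkj->nik", v[need], w_fixed, v[need])
        mats[need] = fixed
        full = out.as_matrices()
        full[valid] = mats
        out = TensorField.from_matrices(grid, full, units="mm^2/s",
                                        undefined=~valid)
        idx = np.argwhere(valid)
        clamped[tuple(idx[need].T)] = True
    out.clamped_ = clamped
    return out


def assemble_conductivity(eta: ScalarField, D: TensorField) -> TensorField:
    """C = ηD (S/mm).  Voxels with η ≤ 0 inside the mask are flagged."""
    eta.grid.require_compatible(D.grid)
    bad = eta.grid.mask & (eta.values <= 0)
    C = D.scaled(np.where(bad, 0.0, eta.values))
    C.units = "S/mm"
    C.undefined |= bad | eta.undefined | D.undefined
    return C


def electric_field(C: TensorField, JP: VectorField) -> VectorField:
    """E = C⁻¹J^P (V/mm).  Singular-C voxels are flagged undefined."""
    C.grid.require_compatible(JP.grid)
    mask = C.defined_mask & JP.defined_mask
    mats = C.as_matrices()[mask]
    w = np.linalg.eigvalsh(mats)
    bad = w[:, 0] <= 0
    sol = np.zeros((mask.sum(), 3))
    if (~bad).any():
        sol[~bad] = np.linalg.solve(mats[~bad],
                                    JP.values[mask][~bad][..., None])[..., 0]
    out = np.zeros(C.grid.shape + (3,))
    out[mask] = sol
    undefined = ~mask.copy()
    idx = np.argwhere(mask)
    undefined[tuple(idx[bad].T)] = True
    return VectorField(C.grid, out, units="V/mm", undefined=undefined)


def _ordered_eigenvalues(T: TensorField) -> np.ndarray:
    return T.eigenvalues()  # already descending


def anisotropic_ratio(T: TensorField) -> ScalarField:
    """AR = 2λ₁/(λ₂+λ₃) of the ordered eigenvalues (≥ 1 for PD tensors)."""
    w = _ordered_eigenvalues(T)
    denom = w[..., 1] + w[..., 2]
    ar = np.divide(2 * w[..., 0], denom, out=np.zeros_like(denom),
                   where=denom != 0)
    ar[~T.defined_mask] = 0.0
    return ScalarField(T.grid, ar, units="", undefined=T.undefined.copy())


def isotropic_equivalent(T: TensorField) -> ScalarField:
    """C_i = √(C_l·C_t), C_l = λ₁, C_t = (λ₂+λ₃)/2 (same units as T)."""
    w = _ordered_eigenvalues(T)
    ci = np.sqrt(np.maximum(w[..., 0] * 0.5 * (w[..., 1] + w[..., 2]), 0.0))
    ci[~T.defined_mask] = 0.0
    return ScalarField(T.grid, ci, units=T.units, undefined=T.undefined.copy())


def roi_summary(field, labels: np.ndarray,
                names: dict[int, str] | None = None) -> pd.DataFrame:
    """Mean ± sd per tissue label for scalar or tensor fields.

    Tensor fields are summarised per component (S/m for conductivity if
    the caller pre-scales; values are reported in the field's own units).
    """
    rows = []
    labs = sorted(int(v) for v in np.unique(labels) if v >= 0)
    for lab in labs:
        sel = (labels == lab) & field.defined_mask
        name = (names or {}).get(lab, str(lab))
        if isinstance(field, TensorField):
            for ci, cname in enumerate(("Cxx", "Cyy", "Czz", "Cxy", "Cxz",
                                        "Cyz")):
                v = field.values[sel][:, ci]
                rows.append({"label": lab, "tissue": name, "component": cname,
                             "mean": float(v.mean()) if v.size else np.nan,
                             "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
                             "n": int(v.size)})
        else:
            v = field.values[sel]
            rows.append({"label": lab, "tissue": name, "component": "value",
                         "mean": float(v.mean()) if v.size else np.nan,
                         "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
                         "n": int(v.size)})
    return pd.DataFrame(rows)
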