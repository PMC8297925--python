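"""Voxel-grid geometry and field containers.

All volumes in the package live on a :class:`VoxelGrid`: a regular lattice
with per-axis spacing (mm), a world origin at the centre of voxel (0,0,0)
and a boolean mask marking the conductive domain Ω.  The z axis is the
slice axis — the imaged volume is treated as a stack of axial slices Ω_t.

Conventions: 0-based voxel indices, arrays indexed ``[ix, iy, iz]`` (x
fastest in memory for Fortran order is *not* assumed; plain C-order numpy
arrays with axis order x, y, z are used throughout).  World coordinates of
voxel ``(i, j, k)`` are ``origin + (i*hx, j*hy, k*hz)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "VoxelGrid",
    "ScalarField",
    "VectorField",
    "TensorField",
    "Montage",
    "TENSOR_COMPONENTS",
]

#: order of the six unique symmetric-tensor components in 4-D volumes
TENSOR_COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz")


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel lattice with a domain mask.

    Parameters
    ----------
    shape : (Nx, Ny, Nz) voxel counts.
    spacing : (hx, hy, hz) voxel edge lengths in mm.
    origin : world coordinates (mm) of the centre of voxel (0, 0, 0).
    mask : boolean array of ``shape``; True inside the conductive domain Ω.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mask: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(h) for h in self.spacing)
        if len(shape) != 3 or any(n < 1 for n in shape):
            raise ValueError(f"shape must be three positive ints, got {shape}")
        if len(spacing) != 3 or any(h <= 0 for h in spacing):
            raise ValueError(f"spacing must be three positive lengths, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        mask = self.mask
        if mask is None:
            mask = np.ones(shape, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != shape:
                raise ValueError("mask shape does not match grid shape")
            if not mask.any():
                raise ValueError("mask is empty")
        object.__setattr__(self, "mask", mask)

    # -- geometry helpers -------------------------------------------------
    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm³."""
        hx, hy, hz = self.spacing
        return hx * hy * hz

    def coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-coordinate arrays (mm), each of ``shape``."""
        ax = [self.origin[d] + self.spacing[d] * np.arange(self.shape[d])
              for d in range(3)]
        return tuple(np.meshgrid(*ax, indexing="ij"))  # type: ignore[return-value]

    def slice_mask(self, k: int) -> np.ndarray:
        """In-plane mask of axial slice Ω_t at index ``k`` (shape Nx×Ny)."""
        return self.mask[:, :, k]

    def compatible(self, other: "VoxelGrid") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin))

    def require_compatible(self, other: "VoxelGrid") -> None:
        if not self.compatible(other):
            raise ValueError("grids are incompatible (shape/spacing/origin mismatch)")


class _Field:
    """Shared machinery for fields defined on a grid.

    Voxels where a quantity is undefined are tracked in ``undefined`` —
    they are never silently zeroed, and propagate through evaluation.
    """

    def __init__(self, grid: VoxelGrid, values: np.ndarray, units: str = "",
                 undefined: np.ndarray | None = None):
        self.grid = grid
        self.values = np.asarray(values, dtype=float)
        self.units = units
        if undefined is None:
            undefined = np.zeros(grid.shape, dtype=bool)
        self.undefined = np.asarray(undefined, dtype=bool)
        if self.undefined.shape != grid.shape:
            raise ValueError("undefined-flag shape mismatch")
        self._check_shape()
        self._check_finite()

    def _check_shape(self):  # overridden
        raise NotImplementedError

    def _check_finite(self):
        ok = self.grid.mask & ~self.undefined
        vals = self.values[ok] if self.values.ndim == 3 else self.values[ok, :]
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("non-finite values inside mask; flag them undefined")

    @property
    def defined_mask(self) -> np.ndarray:
        return self.grid.mask & ~self.undefined


class ScalarField(_Field):
    """One number per voxel (e.g. u in V, B_z in nT, η in S·s/mm³)."""

    def _check_shape(self):
        if self.values.shape != self.grid.shape:
            raise ValueError("scalar field values must match grid shape")

    def copy(self) -> "ScalarField":
        return ScalarField(self.grid, self.values.copy(), self.units,
                           self.undefined.copy())


class VectorField(_Field):
    """Three components per voxel, last axis (x, y, z)."""

    def _check_shape(self):
        if self.values.shape != self.grid.shape + (3,):
            raise ValueError("vector field values must have shape grid+(3,)")

    def _check_finite(self):
        ok = self.grid.mask & ~self.undefined
        if ok.any() and not np.all(np.isfinite(self.values[ok])):
            raise ValueError("non-finite values inside mask; flag them undefined")

    def magnitude(self) -> ScalarField:
        return ScalarField(self.grid, np.linalg.norm(self.values, axis=-1),
                           self.units, self.undefined.copy())

    def copy(self) -> "VectorField":
        return VectorField(self.grid, self.values.copy(), self.units,
                           self.undefined.copy())


class TensorField(_Field):
    """Symmetric 3×3 tensor per voxel, stored as six components.

    Component order along the last axis is xx, yy, zz, xy, xz, yz
    (:data:`TENSOR_COMPONENTS`).  Used for the water diffusion tensor D
    (mm²/s) and the conductivity tensor C (S/mm).
    """

    def _check_shape(self):
        if self.values.shape != self.grid.shape + (6,):
            raise ValueError("tensor field values must have shape grid+(6,)")

    def _check_finite(self):
        ok = self.grid.mask & ~self.undefined
        if ok.any() and not np.all(np.isfinite(self.values[ok])):
            raise ValueError("non-finite values inside mask; flag them undefined")

    # -- algebra ----------------------------------------------------------
    @classmethod
    def from_matrices(cls, grid: VoxelGrid, mats: np.ndarray, units: str = "",
                      undefined: np.ndarray | None = None) -> "TensorField":
        """Build from full (..., 3, 3) symmetric matrices."""
        m = np.asarray(mats, dtype=float)
        comp = np.stack([m[..., 0, 0], m[..., 1, 1], m[..., 2, 2],
                         m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]], axis=-1)
        return cls(grid, comp, units, undefined)

    @classmethod
    def isotropic(cls, grid: VoxelGrid, value: float | np.ndarray,
                  units: str = "") -> "TensorField":
        comp = np.zeros(grid.shape + (6,))
        comp[..., :3] = np.asarray(value)[..., None] if np.ndim(value) else value
        return cls(grid, comp, units)

    def as_matrices(self) -> np.ndarray:
        """Full (..., 3, 3) symmetric matrices."""
        v = self.values
        m = np.empty(self.grid.shape + (3, 3))
        m[..., 0, 0] = v[..., 0]
        m[..., 1, 1] = v[..., 1]
        m[..., 2, 2] = v[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = v[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = v[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = v[..., 5]
        return m

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues per voxel, descending (λ1 ≥ λ2 ≥ λ3), shape grid+(3,)."""
        w = np.linalg.eigvalsh(self.as_matrices())
        return w[..., ::-1]

    def is_positive_definite(self, where: np.ndarray | None = None) -> bool:
        where = self.defined_mask if where is None else where
        if not where.any():
            return True
        w = np.linalg.eigvalsh(self.as_matrices()[where])
        return bool((w[..., 0] > 0).all())

    def scaled(self, factor: float | np.ndarray) -> "TensorField":
        f = np.asarray(factor)
        return TensorField(self.grid, self.values * f[..., None] if f.ndim else
                           self.values * f, self.units, self.undefined.copy())

    def copy(self) -> "TensorField":
        return TensorField(self.grid, self.values.copy(), self.units,
                           self.undefined.copy())


@dataclass
class Montage:
    """A pair of surface electrode patches and the injected current.

    Each patch is a list of boundary faces ``(i, j, k, axis, side)`` where
    ``axis`` ∈ {0,1,2} is the face normal direction and ``side`` ∈ {-1,+1}
    tells which neighbour of the masked voxel ``(i,j,k)`` is outside.
    Current ``current_ma`` (mA) enters through patch 0 and leaves through
    patch 1, so the net injected current is zero (∮ g dS = 0).
    """

    patches: Sequence[Sequence[tuple[int, int, int, int, int]]]
    current_ma: float
    role: str = "experimental"  # "experimental" (E_m) or "complementary" (E_c)
    label: str = ""

    def __post_init__(self):
        if len(self.patches) != 2:
            raise ValueError("a montage has exactly two electrode patches")
        if not all(len(p) > 0 for p in self.patches):
            raise ValueError("electrode patches must contain at least one face")

    def patch_area(self, grid: VoxelGrid, which: int) -> float:
        """Area (mm²) of one patch on the given grid."""
        h = grid.spacing
        face_area = {0: h[1] * h[2], 1: h[0] * h[2], 2: h[0] * h[1]}
        return float(sum(face_area[f[3]] for f in self.patches[which]))

    def reversed(self) -> "Montage":
        """Source and sink electrodes swapped (current direction negated)."""
        return Montage([self.patches[1], self.patches[0]], self.current_ma,
                       self.role, self.label + "-reversed")
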