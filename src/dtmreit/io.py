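"""NIfTI / YAML / JSON plumbing.

Scalar fields are one 3-D NIfTI volume each; vector fields a 4-D volume
with 3 components; tensor fields a 4-D volume with the six unique
components in xx, yy, zz, xy, xz, yz order.  The affine is diagonal in
the voxel spacing with the world origin in the translation column.
Masks travel as uint8 volumes.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .grid import ScalarField, TensorField, VectorField, VoxelGrid

__all__ = [
    "save_field", "load_scalar", "load_vector", "load_tensor",
    "save_mask", "load_grid", "write_manifest", "read_manifest",
    "load_config",
]


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def save_field(field, path: str | Path) -> Path:
    """Write a Scalar/Vector/TensorField as NIfTI-1."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(field.values, dtype=np.float64),
                          _affine(field.grid))
    img.header.set_xyzt_units("mm")
    if field.units:
        img.header["descrip"] = field.units.encode()[:79]
    nib.save(img, str(path))
    return path


def save_mask(grid: VoxelGrid, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(grid.mask.astype(np.uint8), _affine(grid))
    nib.save(img, str(path))
    return path


def load_grid(path: str | Path) -> VoxelGrid:
    """Grid (shape, spacing, origin, mask) from a mask NIfTI."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    aff = img.affine
    spacing = tuple(float(abs(aff[d, d])) for d in range(3))
    origin = tuple(float(aff[d, 3]) for d in range(3))
    return VoxelGrid(data.shape, spacing, origin, data > 0)


def _load(path, expect_last: int | None):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if expect_last is None:
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3-D scalar volume")
    else:
        if data.ndim != 4 or data.shape[-1] != expect_last:
            raise ValueError(f"{path}: expected a 4-D volume with "
                             f"{expect_last} components")
    aff = img.affine
    spacing = tuple(float(abs(aff[d, d])) for d in range(3))
    origin = tuple(float(aff[d, 3]) for d in range(3))
    return data, spacing, origin


def load_scalar(path: str | Path, grid: VoxelGrid | None = None,
                units: str = "") -> ScalarField:
    data, spacing, origin = _load(path, None)
    grid = grid or VoxelGrid(data.shape, spacing, origin)
    return ScalarField(grid, data, units=units)


def load_vector(path: str | Path, grid: VoxelGrid | None = None,
                units: str = "") -> VectorField:
    data, spacing, origin = _load(path, 3)
    grid = grid or VoxelGrid(data.shape[:3], spacing, origin)
    return VectorField(grid, data, units=units)


def load_tensor(path: str | Path, grid: VoxelGrid | None = None,
                units: str = "") -> TensorField:
    data, spacing, origin = _load(path, 6)
    grid = grid or VoxelGrid(data.shape[:3], spacing, origin)
    return TensorField(grid, data, units=units)


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def load_config(path: str | Path) -> dict:
    """YAML study/acquisition configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a YAML mapping")
    return cfg
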