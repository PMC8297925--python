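"""Shared fixtures: small grids, slab conductors, and plate montages."""

from __future__ import annotations

import numpy as np
import pytest

from dtmreit.grid import Montage, TensorField, VoxelGrid


def plate_montage(grid: VoxelGrid, axis: int = 0, current_ma: float = 1.0,
                  label: str = "plates") -> Montage:
    """Full-face plate electrodes on the two ends of ``axis``."""
    mask = grid.mask
    faces_hi, faces_lo = [], []
    it = np.argwhere(mask)
    for (i, j, k) in it:
        idx = (i, j, k)
        if idx[axis] == grid.shape[axis] - 1 or not _nbr(mask, idx, axis, +1):
            faces_hi.append((int(i), int(j), int(k), axis, +1))
        if idx[axis] == 0 or not _nbr(mask, idx, axis, -1):
            faces_lo.append((int(i), int(j), int(k), axis, -1))
    return Montage([faces_hi, faces_lo], current_ma, label=label)


def _nbr(mask, idx, axis, side):
    n = list(idx)
    n[axis] += side
    if not (0 <= n[axis] < mask.shape[axis]):
        return False
    return bool(mask[tuple(n)])


@pytest.fixture
def slab():
    """Homogeneous rectangular slab with x-axis plate electrodes."""
    grid = VoxelGrid((12, 8, 4), (1.0, 1.0, 1.0))
    C = TensorField.isotropic(grid, 1.0e-3, units="S/mm")  # 1 S/m
    montage = plate_montage(grid, axis=0, current_ma=2.0)
    return grid, C, montage


@pytest.fixture(scope="session")
def cylinder_study():
    """Default cylindrical phantom (session-wide, read-only)."""
    from dtmreit.phantom import make_cylinder_phantom

    return make_cylinder_phantom()
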