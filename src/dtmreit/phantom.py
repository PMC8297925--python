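"""Synthetic-study generators: cylindrical tissue phantom and head-like domain.

The cylindrical phantom emulates a 55 mm diameter, 50 mm tall agarose
cylinder carrying four boundary electrodes (two orthogonal 10×10 mm²
pairs), three anisotropic muscle cubes with fibres along x, y and z, and
one isotropic potato cube.  The head-like domain is an extruded ellipse
with scalp and skull shells, a CSF rim and an anisotropic brain interior,
driven by Fpz–Oz and T7–T8 style montages.

Tissue electrical properties are expressed as the DT-MREIT pair
(η, D): the conductivity tensor is C = ηD with η in S·s/mm³ and D in
mm²/s, so e.g. the agar background (η = 0.50, isotropic D = 2.0×10⁻³)
has isotropic conductivity 1.0 S/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Montage, ScalarField, TensorField, VoxelGrid

__all__ = [
    "AcquisitionParams",
    "SyntheticStudy",
    "TissueSpec",
    "make_cylinder_phantom",
    "make_head_like_domain",
    "GAMMA_RAD_PER_T_S",
]

#: proton gyromagnetic ratio, rad/(T·s)
GAMMA_RAD_PER_T_S = 26.75e7


@dataclass
class AcquisitionParams:
    """MR acquisition settings for B_z synthesis."""

    tc_ms: tuple[float, ...] = (20.0,)  # cumulative injection time per echo
    n_echoes: int = 1
    gamma: float = GAMMA_RAD_PER_T_S
    noise_sd_nt: float = 0.18
    seed: int = 0

    def __post_init__(self):
        if self.n_echoes < 1 or len(self.tc_ms) != self.n_echoes:
            raise ValueError("need one cumulative T_c per echo, N_E >= 1")
        if any(np.diff(self.tc_ms) < 0):
            raise ValueError("cumulative injection times must be non-decreasing")


@dataclass
class TissueSpec:
    """Piecewise tissue definition: label id, η and diffusion eigenstructure."""

    name: str
    eta: float  # S·s/mm³
    d_eigenvalues: tuple[float, float, float]  # mm²/s, principal first
    fiber_axis: int | None = None  # 0/1/2 → principal eigenvector along x/y/z

    def tensor(self) -> np.ndarray:
        """3×3 diffusion tensor for this tissue."""
        lam = np.asarray(self.d_eigenvalues, dtype=float)
        if self.fiber_axis is None:
            if not np.allclose(lam, lam[0]):
                raise ValueError(f"{self.name}: anisotropic tissue needs a "
                                 "fiber_axis")
            return np.eye(3) * lam[0]
        order = [self.fiber_axis] + [a for a in range(3) if a != self.fiber_axis]
        d = np.zeros((3, 3))
        for axis, ev in zip(order, lam):
            d[axis, axis] = ev
        return d


@dataclass
class SyntheticStudy:
    """A fully specified synthetic imaging study (ground truth + montages)."""

    grid: VoxelGrid
    labels: np.ndarray  # int per voxel; -1 outside mask
    tissues: dict[int, TissueSpec]
    true_eta: ScalarField
    D: TensorField
    montages: dict[str, Montage]
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)

    def __post_init__(self):
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape mismatch")
        inside = self.labels[self.grid.mask]
        if (inside < 0).any():
            raise ValueError("labels must partition the mask")
        C = self.conductivity()
        if not C.is_positive_definite(self.grid.mask):
            raise ValueError("true conductivity C = ηD is not positive definite")

    def conductivity(self, eta: ScalarField | None = None) -> TensorField:
        """C = ηD (S/mm); defaults to the ground-truth η."""
        eta = self.true_eta if eta is None else eta
        C = self.D.scaled(eta.values)
        C.units = "S/mm"
        return C

    def eta_for_levels(self, levels: dict[int, float]) -> ScalarField:
        """Piecewise-constant η image with one level per tissue label."""
        vals = np.zeros(self.grid.shape)
        for lab, lev in levels.items():
            vals[self.labels == lab] = lev
        return ScalarField(self.grid, vals, units="S*s/mm^3")


def _boundary_faces(mask: np.ndarray, axis: int, side: int):
    """Faces (i,j,k,axis,side) of masked voxels whose ``side`` neighbour
    along ``axis`` is outside the domain."""
    nbr = np.zeros_like(mask)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if side > 0:
        src[axis] = slice(1, None)
        dst[axis] = slice(0, -1)
    else:
        src[axis] = slice(0, -1)
        dst[axis] = slice(1, None)
    nbr[tuple(dst)] = mask[tuple(src)]
    edge = [slice(None)] * 3
    edge[axis] = -1 if side > 0 else 0
    on_array_edge = np.zeros_like(mask)
    on_array_edge[tuple(edge)] = True
    # voxels at the array edge count as boundary there
    is_face = mask & (~nbr | on_array_edge)
    idx = np.argwhere(is_face)
    return [(int(i), int(j), int(k), axis, side) for i, j, k in idx]


def _select_patch(faces, grid: VoxelGrid, center_mm, width_axis: int,
                  half_width: float, half_depth: float):
    """Faces whose centres fall within a width × depth window (mm)."""
    out = []
    for (i, j, k, axis, side) in faces:
        pos = (grid.origin[0] + i * grid.spacing[0],
               grid.origin[1] + j * grid.spacing[1],
               grid.origin[2] + k * grid.spacing[2])
        if abs(pos[width_axis] - center_mm[width_axis]) <= half_width + 1e-9 \
                and abs(pos[2] - center_mm[2]) <= half_depth + 1e-9:
            out.append((i, j, k, axis, side))
    return out


def make_cylinder_phantom(
    diameter_mm: float = 55.0,
    height_mm: float = 50.0,
    grid_res: tuple[int, int, int] = (64, 64, 5),
    in_plane_spacing_mm: float = 1.0,
    background_eta: float = 0.50,
    muscle_eta: float = 0.60,
    potato_eta: float = 0.15,
    muscle_d_eigenvalues: tuple[float, float, float] = (1.4e-3, 1.1e-3, 1.1e-3),
    background_d: float = 2.0e-3,
    potato_d: float = 1.2e-3,
    muscle_size_mm: float = 15.0,
    potato_size_mm: tuple[float, float, float] = (8.0, 8.0, 15.0),
    electrode_mm: float = 10.0,
    current_ma: float = 10.0,
    acquisition: AcquisitionParams | None = None,
    inserts: list[tuple[TissueSpec, tuple[float, float, float]]] | None = None,
) -> SyntheticStudy:
    """Cylindrical tissue phantom with four inserts and two montages.

    The default layout: agar background; ~15 mm muscle cubes left
    (fibres ∥ x), right (∥ y) and top (∥ z) of centre; an 8×8×15 mm
    potato cube below centre; 10×10 mm² electrode pairs on the vertical
    (±y) and horizontal (±x) perimeter, injecting ``current_ma``.
    Custom ``inserts`` (TissueSpec, centre offset in mm) replace the defaults.
    """
    nx, ny, nz = grid_res
    hxy = in_plane_spacing_mm
    hz = height_mm / nz
    cx = (nx - 1) / 2.0 * hxy
    cy = (ny - 1) / 2.0 * hxy
    cz = (nz - 1) / 2.0 * hz
    radius = diameter_mm / 2.0
    if radius > min(nx, ny) * hxy / 2.0:
        raise ValueError("cylinder does not fit in the grid")

    x = np.arange(nx) * hxy
    y = np.arange(ny) * hxy
    z = np.arange(nz) * hz
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    mask = (X - cx) ** 2 + (Y - cy) ** 2 <= radius**2
    grid = VoxelGrid((nx, ny, nz), (hxy, hxy, hz), mask=mask)

    tissues = {
        0: TissueSpec("agar", background_eta, (background_d,) * 3),
        1: TissueSpec("muscle_left", muscle_eta, muscle_d_eigenvalues, 0),
        2: TissueSpec("muscle_right", muscle_eta, muscle_d_eigenvalues, 1),
        3: TissueSpec("muscle_top", muscle_eta, muscle_d_eigenvalues, 2),
        4: TissueSpec("potato", potato_eta, (potato_d,) * 3),
    }
    offset = muscle_size_mm  # centre offset of the inserts from the axis
    m = muscle_size_mm
    placements = {
        1: ((-offset, 0.0, 0.0), (m, m, m)),
        2: ((+offset, 0.0, 0.0), (m, m, m)),
        3: ((0.0, +offset, 0.0), (m, m, m)),
        4: ((0.0, -offset, 0.0), potato_size_mm),
    }
    if inserts is not None:
        tissues = {0: tissues[0]}
        placements = {}
        for lab, (spec, centre) in enumerate(inserts, start=1):
            size = getattr(spec, "size_mm", (m, m, m))
            tissues[lab] = spec
            placements[lab] = (centre, size)

    labels = np.where(mask, 0, -1)
    for lab, (centre, size) in placements.items():
        lo = [centre[d] - size[d] / 2.0 for d in range(3)]
        hi = [centre[d] + size[d] / 2.0 for d in range(3)]
        # half-open boxes so adjacent inserts never share edge voxels
        box = ((X - cx >= lo[0]) & (X - cx < hi[0])
               & (Y - cy >= lo[1]) & (Y - cy < hi[1])
               & (Z - cz >= lo[2]) & (Z - cz <= hi[2]))
        box &= mask
        if not box.any():
            raise ValueError(f"insert {tissues[lab].name} lies outside the "
                             "cylinder")
        if (labels[box] > 0).any():
            raise ValueError(f"insert {tissues[lab].name} overlaps another "
                             "insert")
        labels[box] = lab

    eta_vals = np.zeros(grid.shape)
    d_comp = np.zeros(grid.shape + (6,))
    for lab, spec in tissues.items():
        sel = labels == lab
        eta_vals[sel] = spec.eta
        t = spec.tensor()
        d_comp[sel] = [t[0, 0], t[1, 1], t[2, 2], t[0, 1], t[0, 2], t[1, 2]]
    true_eta = ScalarField(grid, eta_vals, units="S*s/mm^3")
    D = TensorField(grid, d_comp, units="mm^2/s")

    centre_mm = (cx, cy, cz)
    half_w = electrode_mm / 2.0
    half_d = electrode_mm / 2.0
    vert = Montage(
        [_select_patch(_boundary_faces(mask, 1, +1), grid, centre_mm, 0,
                       half_w, half_d),
         _select_patch(_boundary_faces(mask, 1, -1), grid, centre_mm, 0,
                       half_w, half_d)],
        current_ma, role="experimental", label="vertical")
    horiz = Montage(
        [_select_patch(_boundary_faces(mask, 0, +1), grid, centre_mm, 1,
                       half_w, half_d),
         _select_patch(_boundary_faces(mask, 0, -1), grid, centre_mm, 1,
                       half_w, half_d)],
        current_ma, role="complementary", label="horizontal")

    return SyntheticStudy(grid, labels, tissues, true_eta, D,
                          {"vertical": vert, "horizontal": horiz},
                          acquisition or AcquisitionParams())


def make_head_like_domain(
    semi_axes_mm: tuple[float, float] = (80.0, 64.0),
    grid_res: tuple[int, int, int] = (48, 48, 3),
    in_plane_spacing_mm: float = 4.0,
    slice_thickness_mm: float = 10.0,
    scalp_conductivity_s_per_m: float = 0.43,
    skull_conductivity_s_per_m: float = 0.015,
    csf_eta: float = 0.772,
    brain_eta: float = 0.40,
    brain_d_eigenvalues: tuple[float, float, float] = (1.0e-3, 0.7e-3, 0.7e-3),
    shell_fraction: tuple[float, float, float] = (0.10, 0.10, 0.08),
    electrode_mm: float = 20.0,
    current_ma: float = 1.5,
    acquisition: AcquisitionParams | None = None,
) -> SyntheticStudy:
    """Elliptical head-like volume conductor with shells and two montages.

    Scalp and skull are isotropic shells (0.43 and 0.015 S/m by default),
    a CSF-like rim surrounds an anisotropic brain interior (fibres ∥ y).
    Montage "fpz_oz" injects front–back (±y), "t7_t8" left–right (±x).
    The brain + CSF region is the reconstruction region R_t, strictly
    inside the skull shell.
    """
    nx, ny, nz = grid_res
    h = in_plane_spacing_mm
    hz = slice_thickness_mm
    a, b = semi_axes_mm
    cx = (nx - 1) / 2.0 * h
    cy = (ny - 1) / 2.0 * h
    x = np.arange(nx) * h
    y = np.arange(ny) * h
    X, Y = np.meshgrid(x, y, indexing="ij")
    r = np.sqrt(((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2)
    f1, f2, f3 = shell_fraction
    shells2d = np.full((nx, ny), -1)
    shells2d[r <= 1.0] = 1                      # scalp
    shells2d[r <= 1.0 - f1] = 2                 # skull
    shells2d[r <= 1.0 - f1 - f2] = 3            # CSF rim
    shells2d[r <= 1.0 - f1 - f2 - f3] = 4       # brain
    for lab, name in ((1, "scalp"), (2, "skull"), (3, "CSF")):
        if not (shells2d == lab).any():
            raise ValueError(f"{name} shell is thinner than one voxel")
    labels = np.repeat(shells2d[:, :, None], nz, axis=2)
    mask = labels > 0
    grid = VoxelGrid((nx, ny, nz), (h, h, hz), mask=mask)

    # shells carry isotropic D = 1e-3 mm²/s so that η = C[S/mm]/D
    d_shell = 1.0e-3
    tissues = {
        1: TissueSpec("scalp", scalp_conductivity_s_per_m * 1e-3 / d_shell,
                      (d_shell,) * 3),
        2: TissueSpec("skull", skull_conductivity_s_per_m * 1e-3 / d_shell,
                      (d_shell,) * 3),
        3: TissueSpec("csf", csf_eta, (d_shell,) * 3),
        4: TissueSpec("brain", brain_eta, brain_d_eigenvalues, 1),
    }
    eta_vals = np.zeros(grid.shape)
    d_comp = np.zeros(grid.shape + (6,))
    for lab, spec in tissues.items():
        sel = labels == lab
        eta_vals[sel] = spec.eta
        t = spec.tensor()
        d_comp[sel] = [t[0, 0], t[1, 1], t[2, 2], t[0, 1], t[0, 2], t[1, 2]]

    centre_mm = (cx, cy, (nz - 1) / 2.0 * hz)
    half_w = electrode_mm / 2.0
    half_d = hz  # full slab depth
    fpz_oz = Montage(
        [_select_patch(_boundary_faces(mask, 1, +1), grid, centre_mm, 0,
                       half_w, half_d),
         _select_patch(_boundary_faces(mask, 1, -1), grid, centre_mm, 0,
                       half_w, half_d)],
        current_ma, role="experimental", label="fpz_oz")
    t7_t8 = Montage(
        [_select_patch(_boundary_faces(mask, 0, +1), grid, centre_mm, 1,
                       half_w, half_d),
         _select_patch(_boundary_faces(mask, 0, -1), grid, centre_mm, 1,
                       half_w, half_d)],
        current_ma, role="complementary", label="t7_t8")

    acq = acquisition or AcquisitionParams(tc_ms=(32.0,), noise_sd_nt=0.21)
    return SyntheticStudy(grid, labels, tissues,
                          ScalarField(grid, eta_vals, units="S*s/mm^3"),
                          TensorField(grid, d_comp, units="mm^2/s"),
                          {"fpz_oz": fpz_oz, "t7_t8": t7_t8}, acq)


def region_of(study: SyntheticStudy, labels: tuple[int, ...]) -> np.ndarray:
    """Boolean volume selecting the given tissue labels."""
    out = np.zeros(study.grid.shape, dtype=bool)
    for lab in labels:
        out |= study.labels == lab
    return out
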