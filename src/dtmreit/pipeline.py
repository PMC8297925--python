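"""End-to-end pipelines: training-set generation and phantom emulation.

This module wires the forward model, projected-current recovery, the
dual-loop reconstructor, the two-current reference algorithm and the
GRNN corrector into the complete single-current workflow:

1. simulate "measured" B_z for the experimental montage E_m (and, for
   the reference, the complementary montage E_c) with Gaussian noise;
2. build the factorial training set: for every combination of
   piecewise-constant tissue η levels, forward-solve both montages,
   add independent noise, recover projected currents, and reconstruct a
   dual-loop row U_k (from E_m alone) and a two-current row V_k;
3. fit the GRNN on (U, V), tune its spread by leave-one-out holdout, and
   correct the measured dual-loop image;
4. evaluate against the two-current reconstruction of the measured data.

Expensive pieces are shared: the homogeneous reference (u₀, J₀, B_z,0)
per montage, the Biot-Savart FFT kernels, and the prefactorised slice
Poisson operators are computed once and reused for every model.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field

import numpy as np

from .dual_loop import assemble_loop_system, dinv_j, solve_loop_system
from .forward import BiotSavartPlan, ConductionSystem, biot_savart_bz, \
    current_density, uniform_reference
from .grid import ScalarField, VectorField
from .grnn import GRNNRegressor, TrainingSet, correct_eta
from .metrics import mssim, relative_error, ssim
from .mr import add_noise
from .phantom import SyntheticStudy, make_cylinder_phantom
from .projected import SlicePoisson, project_full
from .tensors import assemble_conductivity, electric_field
from .two_current import GradientSolveConfig, reconstruct_two_current

__all__ = [
    "MontageReference",
    "simulate_montage_bz",
    "build_training_set",
    "PhantomEmulationResult",
    "run_phantom_emulation",
]

#: default per-tissue η level ranges (S·s/mm³) for the factorial training
#: models of the cylindrical phantom: agar background, chicken muscle
#: (all three cubes share a level) and potato
PHANTOM_ETA_RANGES = {
    "agar": (0.1, 1.0),
    "muscle": (0.2, 1.25),
    "potato": (0.01, 0.3),
}
#: map tissue-group name -> phantom label ids sharing one η level
PHANTOM_TISSUE_GROUPS = {
    "agar": (0,),
    "muscle": (1, 2, 3),
    "potato": (4,),
}


@dataclass
class MontageReference:
    """Homogeneous-model bundle reused across all training models."""

    name: str
    u0: ScalarField
    J0: VectorField
    Bz0: ScalarField


def simulate_montage_bz(study: SyntheticStudy, montage_name: str,
                        eta: ScalarField | None = None,
                        system: ConductionSystem | None = None,
                        plan: BiotSavartPlan | None = None):
    """Noise-free B_z (and true J) for one montage and η distribution."""
    C = study.conductivity(eta)
    if system is None:
        system = ConductionSystem(study.grid, C, check_pd=False)
    u = system.solve(study.montages[montage_name])
    J = current_density(u, C)
    bz = biot_savart_bz(J, study.grid, method="fft", plan=plan)
    return bz, J


def _phantom_eta_levels(n_levels: int) -> dict[str, np.ndarray]:
    return {g: np.linspace(lo, hi, n_levels)
            for g, (lo, hi) in PHANTOM_ETA_RANGES.items()}


def phantom_eta_levels(n_levels: int = 10) -> dict[str, np.ndarray]:
    """Linearly spaced per-tissue η levels for the phantom training models."""
    return _phantom_eta_levels(n_levels)


def factorial_combinations(eta_levels: dict[str, np.ndarray]) -> list[dict]:
    """All tissue-η combinations the factorial generator enumerates.

    The training set contains exactly one model per combination, so
    ``len(factorial_combinations(levels))`` is the training sample count M.
    """
    groups = list(eta_levels.keys())
    return [dict(zip(groups, combo))
            for combo in itertools.product(*(eta_levels[g] for g in groups))]


def build_training_set(
    study: SyntheticStudy,
    montage_pair: tuple[str, str],
    eta_levels: dict[str, np.ndarray],
    tissue_groups: dict[str, tuple[int, ...]],
    noise_sd_nt: float,
    seed: int,
    k: int,
    eta_boundary_group: str = "agar",
    config: GradientSolveConfig | None = None,
    smooth_sigma: float = 0.5,
    lam: float | None = None,
    progress: bool = False,
) -> TrainingSet:
    """Factorial (U, V) training set for the GRNN.

    For each of the M = Π(levels) combinations: both montages are
    forward-solved with piecewise-constant η, B_z is simulated by
    Biot-Savart and perturbed with independent Gaussian noise (seeds
    ``seed + 2m`` and ``seed + 2m + 1``), projected current densities are
    recovered against the shared homogeneous reference, and slice ``k``
    is reconstructed by the dual-loop network (experimental montage only,
    row of U) and the two-current algorithm (both montages, row of V).
    The boundary η handed to both reconstructions is the model's own
    background level — known by construction for simulated models.
    """
    em, ec = montage_pair
    grid = study.grid
    plan = BiotSavartPlan(grid)
    refs = {name: MontageReference(name, *uniform_reference(
        grid, study.montages[name], 1.0e-3, plan=plan)) for name in (em, ec)}
    m2 = grid.slice_mask(k)
    poisson = SlicePoisson(m2, grid.spacing[:2])
    groups = list(eta_levels.keys())
    combos = [tuple(c.values()) for c in factorial_combinations(eta_levels)]
    U_rows, V_rows = [], []
    manifest = {
        "montage_pair": [em, ec],
        "eta_levels": {g: [float(v) for v in eta_levels[g]] for g in groups},
        "tissue_groups": {g: list(tissue_groups[g]) for g in groups},
        "noise_sd_nt": noise_sd_nt,
        "seed": int(seed),
        "slice": int(k),
        "smooth_sigma": smooth_sigma,
    }
    t0 = time.time()
    for m_idx, combo in enumerate(combos):
        levels = {}
        for g, lev in zip(groups, combo):
            for lab in tissue_groups[g]:
                levels[lab] = float(lev)
        eta = study.eta_for_levels(levels)
        eta_b = levels[tissue_groups[eta_boundary_group][0]]
        try:
            C = study.conductivity(eta)
            system = ConductionSystem(grid, C, check_pd=False)
            bz_star, _ = simulate_montage_bz(study, em, eta, system, plan)
            bz_tilde, _ = simulate_montage_bz(study, ec, eta, system, plan)
        except Exception as exc:
            raise RuntimeError(
                f"forward model failed for combination {m_idx} "
                f"({dict(zip(groups, combo))}): {exc}") from exc
        bz_star = add_noise(bz_star, noise_sd_nt, seed + 2 * m_idx)
        bz_tilde = add_noise(bz_tilde, noise_sd_nt, seed + 2 * m_idx + 1)
        jp_star = project_full(bz_star, refs[em].J0, k,
                               smooth_sigma=smooth_sigma, poisson=poisson)
        jp_tilde = project_full(bz_tilde, refs[ec].J0, k,
                                smooth_sigma=smooth_sigma, poisson=poisson)
        # row of U: dual-loop from the experimental montage alone
        F = dinv_j(study.D, jp_star)
        loop = assemble_loop_system(F, eta_b, k)
        eta_hat = solve_loop_system(loop, lam)
        # row of V: two-current reference from both montages
        cfg = config or GradientSolveConfig()
        cfg_m = GradientSolveConfig(window=cfg.window, h=cfg.h,
                                    eta_boundary=eta_b,
                                    zeta_bracket=cfg.zeta_bracket,
                                    n_zeta_grid=cfg.n_zeta_grid,
                                    rank1_tol=cfg.rank1_tol)
        eta_tilde = reconstruct_two_current(study.D, jp_star, jp_tilde, k,
                                            config=cfg_m, poisson=poisson)
        U_rows.append(eta_hat[m2])
        V_rows.append(eta_tilde[m2])
        if progress and (m_idx + 1) % 100 == 0:
            rate = (m_idx + 1) / (time.time() - t0)
            print(f"  training model {m_idx + 1}/{len(combos)} "
                  f"({rate:.1f} models/s)")
    manifest["n_models"] = len(combos)
    return TrainingSet(np.asarray(U_rows), np.asarray(V_rows), m2, k, manifest)


@dataclass
class PhantomEmulationResult:
    """Everything the phantom emulation produces, plus summary metrics."""

    study: SyntheticStudy
    training: TrainingSet
    model: GRNNRegressor
    eta_dual_loop: np.ndarray        # uncorrected η̂, centre slice
    eta_corrected: np.ndarray        # GRNN-corrected η, centre slice
    eta_two_current: np.ndarray      # reference η̃, centre slice
    e_single_mag: np.ndarray         # |E| from the corrected reconstruction
    e_two_mag: np.ndarray            # |E| from the two-current reconstruction
    slice_index: int
    metrics: dict = field(default_factory=dict)


def run_phantom_emulation(
    seed: int,
    n_levels: int = 10,
    grid_res: tuple[int, int, int] = (64, 64, 5),
    noise_sd_nt: float = 0.18,
    eta_boundary: float = 0.50,
    smooth_sigma: float = 0.5,
    experimental: str = "vertical",
    complementary: str = "horizontal",
    progress: bool = False,
) -> PhantomEmulationResult:
    """Full single-current phantom study against the two-current reference.

    Builds the cylindrical tissue phantom, simulates measured B_z for the
    vertical (experimental) and horizontal (complementary) montages with
    0.18 nT Gaussian noise, trains the GRNN on the factorial training set
    (``n_levels`` per tissue group → M = n_levels³ models), reconstructs
    the centre slice by dual-loop + GRNN correction and by the
    two-current algorithm, and reports RE / MSSIM between the two η
    images and between the derived |E| images (experimental montage).
    """
    seed = int(seed)
    study = make_cylinder_phantom(grid_res=grid_res)
    k = grid_res[2] // 2
    grid = study.grid
    m2 = grid.slice_mask(k)
    poisson = SlicePoisson(m2, grid.spacing[:2])

    plan = BiotSavartPlan(grid)
    refs = {name: MontageReference(name, *uniform_reference(
        grid, study.montages[name], 1.0e-3, plan=plan))
        for name in (experimental, complementary)}

    # --- measured data: true η, independent measurement noise ------------
    C_true = study.conductivity()
    system = ConductionSystem(grid, C_true, check_pd=False)
    meas_seed = seed + 10_000_000
    bz_m = {}
    for off, name in enumerate((experimental, complementary)):
        bz, _ = simulate_montage_bz(study, name, None, system, plan)
        bz_m[name] = add_noise(bz, noise_sd_nt, meas_seed + off)
    jp = {name: project_full(bz_m[name], refs[name].J0, k,
                             smooth_sigma=smooth_sigma, poisson=poisson)
          for name in (experimental, complementary)}

    # --- training set + GRNN ---------------------------------------------
    training = build_training_set(
        study, (experimental, complementary), _phantom_eta_levels(n_levels),
        PHANTOM_TISSUE_GROUPS, noise_sd_nt, seed, k,
        smooth_sigma=smooth_sigma, progress=progress)
    model = GRNNRegressor(spread="holdout").fit(training.U, training.V)

    # --- single-current reconstruction + correction ----------------------
    F = dinv_j(study.D, jp[experimental])
    loop = assemble_loop_system(F, eta_boundary, k)
    eta_hat = solve_loop_system(loop)
    eta_corr = correct_eta(eta_hat, model, m2)

    # --- two-current reference -------------------------------------------
    cfg = GradientSolveConfig(eta_boundary=eta_boundary)
    eta_tilde = reconstruct_two_current(
        study.D, jp[experimental], jp[complementary], k,
        config=cfg, poisson=poisson)

    # --- electric fields (experimental montage) --------------------------
    def emag(eta2d: np.ndarray) -> np.ndarray:
        vol = np.zeros(grid.shape)
        vol[:, :, k] = eta2d
        eta_f = ScalarField(grid, vol, units="S*s/mm^3",
                            undefined=~grid.mask)
        C = assemble_conductivity(eta_f, study.D)
        E = electric_field(C, jp[experimental])
        return np.linalg.norm(E.values[:, :, k, :], axis=-1)

    e_single = emag(eta_corr)
    e_two = emag(eta_tilde)

    metrics = {
        "re_eta_dual_loop": relative_error(eta_tilde, eta_hat, m2),
        "mssim_eta_dual_loop": mssim(ssim(eta_tilde, eta_hat, m2), m2),
        "re_eta_corrected": relative_error(eta_tilde, eta_corr, m2),
        "mssim_eta_corrected": mssim(ssim(eta_tilde, eta_corr, m2), m2),
        "re_efield": relative_error(e_two, e_single, m2),
        "mssim_efield": mssim(ssim(e_two, e_single, m2), m2),
        "re_eta_corrected_vs_truth": relative_error(
            study.true_eta.values[:, :, k], eta_corr, m2),
        "re_eta_dual_loop_vs_truth": relative_error(
            study.true_eta.values[:, :, k], eta_hat, m2),
        "re_eta_two_current_vs_truth": relative_error(
            study.true_eta.values[:, :, k], eta_tilde, m2),
        "alpha_hat": model.spread_,
        "n_training_models": training.n_samples,
    }
    return PhantomEmulationResult(study, training, model, eta_hat, eta_corr,
                                  eta_tilde, e_single, e_two, k, metrics)
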