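"""MR signal synthesis, B_z recovery, noise injection and echo combination.

The spin-echo MREIT signal with current injected for a duration T_c is

    S±(r) = ρ(r) e^{iδ(r)} e^{±iγ B_z(r) T_c}

where ρ is the MR magnitude, δ a systematic phase and γ the proton
gyromagnetic ratio.  B_z is recovered from the positive/negative current
pair as arg(S⁺ conj(S⁻)) / (2γT_c); the systematic phase cancels in the
ratio.  The recovery is valid only while the accumulated phase difference
stays within (−π, π); voxels at the wrap boundary are flagged undefined
rather than unwrapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import ScalarField, VoxelGrid
from .phantom import GAMMA_RAD_PER_T_S

__all__ = [
    "synthesize_signal",
    "recover_bz",
    "EchoSet",
    "combine_echoes",
    "add_noise",
    "bz_noise_sd_theory",
]

_NT_TO_T = 1e-9
_MS_TO_S = 1e-3


def synthesize_signal(rho: np.ndarray, delta: np.ndarray, bz: ScalarField,
                      tc_ms: float, gamma: float = GAMMA_RAD_PER_T_S):
    """Complex MR signals (S⁺, S⁻) for ±current injections.

    ``rho`` is the magnitude image (≥ 0), ``delta`` the systematic phase
    (rad), ``bz`` the flux density in nT and ``tc_ms`` the current
    injection duration in ms.
    """
    rho = np.asarray(rho, dtype=float)
    if (rho < 0).any():
        raise ValueError("MR magnitude must be non-negative")
    phase = gamma * bz.values * _NT_TO_T * tc_ms * _MS_TO_S
    base = rho * np.exp(1j * np.asarray(delta, dtype=float))
    return base * np.exp(1j * phase), base * np.exp(-1j * phase)


def recover_bz(s_plus: np.ndarray, s_minus: np.ndarray, tc_ms: float,
               grid: VoxelGrid, gamma: float = GAMMA_RAD_PER_T_S) -> ScalarField:
    """B_z (nT) from the ±current signal pair.

    Zero-magnitude voxels and voxels whose phase difference reaches the ±π
    wrap boundary are flagged undefined.
    """
    if tc_ms <= 0:
        raise ValueError("current injection time must be positive")
    prod = np.asarray(s_plus) * np.conj(np.asarray(s_minus))
    phase = np.angle(prod)
    undefined = (np.abs(prod) == 0.0) | (np.abs(phase) >= np.pi * (1 - 1e-12))
    bz = phase / (2.0 * gamma * tc_ms * _MS_TO_S) / _NT_TO_T
    bz[undefined] = 0.0
    return ScalarField(grid, bz, units="nT", undefined=undefined)


def bz_noise_sd_theory(snr: float, tc_ms: float,
                       gamma: float = GAMMA_RAD_PER_T_S) -> float:
    """Predicted sd of recovered B_z (nT) at magnitude SNR Υ_ρ.

    Independent complex noise of sd ρ/Υ per channel on S⁺ and S⁻ gives a
    phase-difference sd of √2/Υ, hence sd(B_z) = 1/(√2 γ T_c Υ_ρ).
    """
    return 1.0 / (np.sqrt(2.0) * gamma * tc_ms * _MS_TO_S * snr) / _NT_TO_T


@dataclass
class EchoSet:
    """Per-echo B_z images with magnitudes and cumulative injection times."""

    bz: list[ScalarField]
    rho: list[np.ndarray]
    tc_ms: list[float]

    def __post_init__(self):
        n = len(self.bz)
        if n < 1 or len(self.rho) != n or len(self.tc_ms) != n:
            raise ValueError("echo lists must be non-empty and aligned")
        if any(np.diff(self.tc_ms) < 0):
            raise ValueError("cumulative injection times must be "
                             "non-decreasing across echoes")
        g = self.bz[0].grid
        for f in self.bz[1:]:
            g.require_compatible(f.grid)


def combine_echoes(echoes: EchoSet) -> ScalarField:
    """SNR-optimal weighted echo combination.

    W_l = (ρ_l T_{c,l})² / Σ_k (ρ_k T_{c,k})²;  B_z^m = Σ_l W_l B_{z,l}.
    Voxels where every weight vanishes are flagged undefined.
    """
    grid = echoes.bz[0].grid
    if len(echoes.bz) == 1:  # single echo: exact identity
        out = echoes.bz[0].copy()
        out.undefined |= np.asarray(echoes.rho[0]) * echoes.tc_ms[0] == 0.0
        return out
    num = np.zeros(grid.shape)
    den = np.zeros(grid.shape)
    undef = np.zeros(grid.shape, dtype=bool)
    for bz_l, rho_l, tc_l in zip(echoes.bz, echoes.rho, echoes.tc_ms):
        w = (np.asarray(rho_l, dtype=float) * tc_l) ** 2
        num += w * bz_l.values
        den += w
        undef |= bz_l.undefined
    zero = den == 0.0
    out = np.divide(num, den, out=np.zeros_like(num), where=~zero)
    return ScalarField(grid, out, units="nT", undefined=undef | zero)


def add_noise(bz: ScalarField, sd_nt: float,
              seed: int | np.random.Generator) -> ScalarField:
    """Seeded i.i.d. Gaussian perturbation of a B_z image (mask only)."""
    if sd_nt < 0:
        raise ValueError("noise sd must be non-negative")
    if sd_nt == 0:
        return bz.copy()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    vals = bz.values.copy()
    m = bz.grid.mask
    vals[m] = vals[m] + rng.normal(0.0, sd_nt, size=int(m.sum()))
    return ScalarField(bz.grid, vals, units=bz.units, undefined=bz.undefined.copy())
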