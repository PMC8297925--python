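"""GRNN artifact correction of dual-loop scale-factor images.

A generalised regression neural network is a kernel regressor: for an
input image X (vectorised over the P mask voxels) and training pairs
(U_k, V_k), the prediction is the Gaussian-weighted mean

    Y(X) = Σ_k V_k exp(−D_k²/2α²) / Σ_k exp(−D_k²/2α²),
    D_k² = (X − U_k)ᵀ(X − U_k),

with a single spread constant α.  Here U_k are dual-loop reconstructions
(streak-artifacted) and V_k the matching two-current reconstructions
(artifact-free), so the network learns the artifact map.  α is tuned by
leave-one-out holdout: minimise the mean over k of
MSE_k = (1/P)‖V_k − Ŷ_k‖² where Ŷ_k is predicted from the set minus
sample k, over 10⁻³ < α < 10³.

Exponentials are evaluated with a shift by the per-row minimum distance
(a log-sum-exp guard): the nearest neighbour always receives weight 1,
so the α → 0 limit degrades gracefully to nearest-neighbour regression
instead of 0/0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "TrainingSet",
    "GRNNRegressor",
    "grnn_predict",
    "holdout_mse",
    "optimize_spread",
    "correct_eta",
]


@dataclass
class TrainingSet:
    """Row-aligned training matrices for GRNN correction.

    ``U`` holds M vectorised dual-loop η images, ``V`` the matching M
    two-current η images, both over the same P voxels in the same order
    (``voxel_mask`` + C-order).  ``manifest`` records how the rows were
    generated (η levels, seeds, noise sd) so they can be regenerated
    exactly.
    """

    U: np.ndarray
    V: np.ndarray
    voxel_mask: np.ndarray
    slice_index: int
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.U.ndim != 2 or self.U.shape != self.V.shape:
            raise ValueError("U and V must be equal-shape (M, P) matrices")
        if self.U.shape[0] < 1:
            raise ValueError("need at least one training sample")
        if int(np.asarray(self.voxel_mask).sum()) != self.U.shape[1]:
            raise ValueError("voxel mask does not match column count")

    @property
    def n_samples(self) -> int:
        return self.U.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.U.shape[1]

    def subsample(self, m: int, seed: int = 0) -> "TrainingSet":
        """Random row subset (for sample-size studies)."""
        if not 1 <= m <= self.n_samples:
            raise ValueError("invalid subsample size")
        rng = np.random.default_rng(seed)
        idx = rng.choice(self.n_samples, size=m, replace=False)
        return TrainingSet(self.U[idx], self.V[idx], self.voxel_mask,
                           self.slice_index,
                           {**self.manifest, "subsample": [int(i) for i in idx]})


def _kernel_weights(d2: np.ndarray, alpha: float) -> np.ndarray:
    """Row-normalised Gaussian weights with a min-shift underflow guard."""
    shift = d2.min(axis=-1, keepdims=True)
    w = np.exp(-(d2 - shift) / (2.0 * alpha**2))
    total = w.sum(axis=-1, keepdims=True)
    # the shift guarantees the row max is exp(0)=1, so total >= 1; the
    # nearest-neighbour fallback below only triggers on pathological input
    bad = ~np.isfinite(total) | (total <= 0)
    if bad.any():  # pragma: no cover - defensive
        nn = np.argmin(d2, axis=-1)
        w = np.zeros_like(w)
        w[np.arange(w.shape[0]), nn] = 1.0
        total = np.ones_like(total)
    return w / total


def grnn_predict(X: np.ndarray, U: np.ndarray, V: np.ndarray,
                 alpha: float) -> np.ndarray:
    """GRNN prediction for one or more input rows."""
    if alpha <= 0:
        raise ValueError("spread constant must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d2 = ((X[:, None, :] - U[None, :, :]) ** 2).sum(axis=-1)
    W = _kernel_weights(d2, alpha)
    Y = W @ V
    return Y[0] if np.asarray(X).ndim == 1 else Y


def holdout_mse_per_sample(alpha: float, U: np.ndarray,
                           V: np.ndarray) -> np.ndarray:
    """Leave-one-out MSE_k for every sample at spread ``alpha``."""
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    m = U.shape[0]
    if m < 2:
        raise ValueError("leave-one-out requires at least two samples")
    if alpha <= 0:
        raise ValueError("spread constant must be positive")
    sq = (U * U).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (U @ U.T)
    np.fill_diagonal(d2, np.inf)
    d2 = np.maximum(d2, 0.0)
    shift = d2.min(axis=1, keepdims=True)
    w = np.exp(-(d2 - shift) / (2.0 * alpha**2))
    w /= w.sum(axis=1, keepdims=True)
    pred = w @ V
    return ((V - pred) ** 2).mean(axis=1)


def holdout_mse(alpha: float, U: np.ndarray, V: np.ndarray) -> float:
    """Mean leave-one-out MSE of the GRNN at spread ``alpha``.

    For each sample k the network is built from all other samples and
    asked to predict V_k from U_k; MSE_k = (1/P)‖V_k − Ŷ_k‖², and the
    mean over all M samples is returned.
    """
    return float(holdout_mse_per_sample(alpha, U, V).mean())


def optimize_spread(U: np.ndarray, V: np.ndarray,
                    bounds: tuple[float, float] = (1e-3, 1e3),
                    xatol: float = 1e-4):
    """α̂ minimising the leave-one-out MSE over the bounded range.

    Bounded scalar minimisation (the fminbnd analogue); deterministic
    given the training matrices.  Returns (α̂, mse(α̂), probe curve).
    """
    curve: list[tuple[float, float]] = []

    def objective(a: float) -> float:
        v = holdout_mse(a, U, V)
        curve.append((float(a), v))
        return v

    res = minimize_scalar(objective, bounds=bounds, method="bounded",
                          options={"xatol": xatol})
    alpha_hat = float(res.x)
    values = np.array([v for _, v in curve])
    if values.size > 3 and np.ptp(values) <= 1e-15 * max(1.0, values.max()):
        warnings.warn("holdout MSE is flat in α; returning the smallest "
                      "bracketing value", stacklevel=2)
        alpha_hat = bounds[0]
    return alpha_hat, float(res.fun), curve


class GRNNRegressor(BaseEstimator, RegressorMixin):
    """Generalised regression neural network with holdout spread tuning.

    Parameters
    ----------
    spread : float or "holdout"
        Gaussian spread constant α.  ``"holdout"`` (default) tunes α by
        leave-one-out MSE minimisation over ``spread_bounds`` at fit time.
    spread_bounds : (float, float)
        Search range for the holdout optimisation.

    Attributes
    ----------
    U_, V_ : (M, P) training matrices.
    spread_ : float — the spread in use after ``fit``.
    holdout_mse_ : float — leave-one-out MSE at ``spread_`` (when tuned).
    mse_curve_ : list of (α, MSE) probes from the optimiser (when tuned).
    """

    def __init__(self, spread="holdout", spread_bounds=(1e-3, 1e3)):
        self.spread = spread
        self.spread_bounds = spread_bounds

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.shape != X.shape:
            raise ValueError("X and y must be matching (M, P) matrices")
        self.U_ = X
        self.V_ = y
        if self.spread == "holdout":
            self.spread_, self.holdout_mse_, self.mse_curve_ = \
                optimize_spread(X, y, bounds=tuple(self.spread_bounds))
            self.optimized_ = True
        else:
            a = float(self.spread)
            if a <= 0:
                raise ValueError("spread constant must be positive")
            self.spread_ = a
            self.optimized_ = False
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        if not hasattr(self, "U_"):
            raise AttributeError("GRNNRegressor is not fitted")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        Y = grnn_predict(np.atleast_2d(X), self.U_, self.V_, self.spread_)
        return Y[0] if single else Y


def correct_eta(eta_hat: np.ndarray, model: GRNNRegressor,
                voxel_mask: np.ndarray) -> np.ndarray:
    """GRNN-correct one η̂ slice image.

    The image is vectorised over the training voxel map, corrected, and
    written back; out-of-mask voxels pass through bit-identically.
    """
    voxel_mask = np.asarray(voxel_mask, dtype=bool)
    if eta_hat.shape != voxel_mask.shape:
        raise ValueError("image and voxel map shapes differ")
    if int(voxel_mask.sum()) != model.n_features_in_:
        raise ValueError("voxel map does not match the training voxel count")
    x = eta_hat[voxel_mask]
    y = model.predict(x)
    out = eta_hat.copy()
    out[voxel_mask] = y
    return out
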