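# dtmreit

Conductivity-tensor, current-density and electric-field imaging from a
**single** injected current, using diffusion-tensor MREIT with a
machine-learning artifact correction.

## The problem

Magnetic resonance electrical impedance tomography (MREIT) recovers
electrical properties of tissue from the one component of the
current-induced magnetic flux density, B_z, that an MR scanner can
measure.  Diffusion-tensor MREIT (DT-MREIT) assumes the low-frequency
conductivity tensor is a position-dependent scalar times the water
diffusion tensor,

    C(r) = η(r) · D(r),

so that imaging conductivity reduces to imaging the scale factor η
(S·s/mm³).  Standard DT-MREIT needs **two** independent current
injections for a unique reconstruction — but transcranial electrical
stimulation (tES) and similar neuromodulation settings typically offer
only one electrode pair.  This package implements a single-current
pipeline:

1. **Projected current density.**  A homogeneous model of the domain
   predicts J0; the measured B_z adds the in-plane curl correction via
   ∇²_xy ψ = ∇²B_z/μ0, giving J^P = J0 + (∂ψ/∂y, −∂ψ/∂x, 0)
   (full-domain and brain-region variants).
2. **Dual-loop reconstruction.**  Since (D⁻¹J)/η is the electric field,
   Kirchhoff's voltage law around two overlapping loops per interior
   node yields a sparse overdetermined system A X = B for the inverse
   scale factor X = 1/η, solved by regularised least squares with a
   known boundary η.
3. **GRNN correction.**  The dual-loop image carries streak artifacts
   (noise propagating along equipotentials).  A generalised regression
   neural network, Y(X) = Σ_k V_k e^{−D_k²/2α²} / Σ_k e^{−D_k²/2α²},
   trained on M = 1000 factorial forward simulations — inputs U_k from
   the dual-loop, targets V_k from the two-current reference algorithm
   run on a simulated complementary montage — maps the artifacted image
   to an artifact-free one.  The spread α is tuned by leave-one-out
   holdout.
4. **Derived fields.**  C = ηD, J^P, and E = C⁻¹J^P, with per-tissue
   summaries (anisotropic ratio AR = 2λ₁/(λ₂+λ₃), isotropic equivalent
   √(C_l·C_t)) and evaluation metrics (relative L² error, windowed
   SSIM/MSSIM).

The two-current reference algorithm (curl-based ∇ln η solve with
SVD + generalised cross-validation per 3×3 window, then a Poisson
integration of ln η) is implemented alongside and serves as both the
training-target generator and the validation standard.  Everything runs
on synthetic studies generated in-repo: a cylindrical tissue phantom
(agar background, three anisotropic muscle cubes, one potato cube, two
orthogonal 10 mA electrode pairs) and an elliptical head-like domain
with scalp/skull shells and tES-style montages.  See
`docs/methods.md` for the numerical details.

## Worked example

```python
from dtmreit.pipeline import run_phantom_emulation

result = run_phantom_emulation(seed=1, n_levels=10)
for key in ("re_eta_dual_loop", "re_eta_corrected",
            "mssim_eta_corrected", "re_efield", "alpha_hat"):
    print(f"{key:22s} {result.metrics[key]:.4f}")
```

prints (seed 1):

```
re_eta_dual_loop       0.1285
re_eta_corrected       0.0107
mssim_eta_corrected    0.9935
re_efield              0.0109
alpha_hat              0.5484
```

Reading: against the two-current reference on the phantom's centre
slice, the raw single-current dual-loop η̂ differs by 12.9% in relative
L² norm; after GRNN correction the difference drops to 1.1% with a mean
structural similarity of 0.993, and the electric-field magnitudes
derived from the two reconstructions agree to 1.1%.  The optimised GRNN
spread constant was α̂ ≈ 0.55.

The same workflow is scriptable from the shell:

```sh
dtmreit simulate --domain cylinder --noise-nt 0.18 --seed 5 --out study/
dtmreit dualloop --study study/ --montage vertical --eta-boundary 0.5 --out eta_hat.nii
dtmreit two-current --study study/ --montages vertical horizontal --out eta_tilde.nii
dtmreit evaluate --truth study/true_eta.nii --recon eta_tilde.nii \
    --mask study/mask.nii --slice 2 --report report.json
```

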