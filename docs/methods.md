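# Methods

`dtmreit` reconstructs the position-dependent scale factor η that links
the low-frequency conductivity tensor to the water diffusion tensor,
C = ηD, from the MR-measurable magnetic flux density component B_z of a
*single* injected current, and derives conductivity tensors, current
densities and electric fields from it.  A standard two-current DT-MREIT
algorithm is implemented alongside as the reference against which the
single-current result is corrected and validated.  This note records
the model, the numerical choices, and what the synthetic studies do and
do not establish.

## Physical model and units

Current injected through a pair of surface electrodes drives a static
conduction problem ∇·(C∇u) = 0 with Neumann data g = ±I/A on the
electrode patches.  All lengths are mm, conductivity S/mm (reported as
S/m where conventional), η in S·s/mm³, D in mm²/s, current density
A/mm², electric field V/mm, and B_z in nT.  The proton gyromagnetic
ratio is γ = 26.75×10⁷ rad/(T·s).

With C = ηD, the quantity (D⁻¹J)/η is the electric field, which is the
lever for single-current reconstruction: D is measured independently by
diffusion MRI, J is estimated from B_z, and Kirchhoff's voltage law
constrains 1/η around closed loops.

## Forward model

**Conduction.** Voxel-centred finite volumes with a 7-point stencil.
Face conductances take the harmonic mean of the normal tensor component
of the two adjacent voxels (exact for 1-D layered media); off-diagonal
tensor components enter as cross-fluxes with centrally differenced
tangential gradients averaged onto the face, one-sided at mask edges.
The discrete fluxes telescope, so total current is conserved exactly
across any voxel-aligned cut.  The pure-Neumann system is gauged by
anchoring u = 0 at the first masked voxel; every downstream quantity is
gradient-based.  Systems are factorised once per conductivity
distribution (SuperLU) and reused across montages.

**Biot-Savart.** B_z(r) = (μ0/4π)∫[(y−y′)J_x − (x−x′)J_y]/|r−r′|³ dr′
evaluated by midpoint quadrature over voxels, with the self-voxel
excluded (its kernel integral vanishes by antisymmetry).  The default
FFT path zero-pads each dimension ×2, so the circular convolution
equals the linear sum; kernel FFTs are precomputed per grid and reused.
On thick-slice grids each source voxel is subdivided along z
(`z_subdivide="auto"`: round(hz/hxy), capped at 10).  Without this the
discrete identity ∇²B_z = −μ0(∇×J)_z — which the projected-current
solve inverts — fails badly (a factor ≈ 4 on a 1×1×10 mm grid); with it
the identity holds to ≈ 10% in L², limited by unresolved tissue
interfaces rather than quadrature.  An O(N²) direct summation with the
identical quadrature serves as the FFT oracle (agreement to 1e-10).

**MR signal chain.** S± = ρe^{iδ}e^{±iγB_zT_c}; B_z is recovered as
arg(S⁺conj(S⁻))/(2γT_c) with the systematic phase δ cancelling.  No
phase unwrapping is attempted: voxels at the ±π wrap boundary are
flagged undefined.  Multi-echo data combine with weights
W_l ∝ (ρ_l T_{c,l})².  Training and measurement noise is i.i.d.
Gaussian added to B_z images (not raw k-space), seeded and
reproducible; the recovered-B_z noise sd follows 1/(√2 γT_cΥ_ρ) at
magnitude SNR Υ_ρ, verified by Monte Carlo.

## Projected current density

Per axial slice, ∇²_xy ψ = ∇²B_z^m/μ0 with ψ = 0 on ∂Ω_t and
J^P = J0 + (∂ψ/∂y, −∂ψ/∂x, 0), where J0 comes from a homogeneous,
isotropic model of the same domain and montage (J0 is invariant to the
chosen C0 because the problem is Neumann-driven).  The z-component of
J^P is J0's — the stream-function correction is purely in-plane.
Numerical choices:

* ∇²B_z uses the in-plane 5-point stencil plus, by default, the second
  z-difference where both neighbouring slices exist (the physically
  complete Laplacian; `mode="2d"` restricts to in-plane).
* A Gaussian pre-smoothing of σ = 0.5 voxel (configurable, off in all
  oracle tests) tames the noise amplification of second differences.
* The Dirichlet Poisson solves use a 5-point Laplacian on the mask
  interior with the boundary ring carrying the data, prefactorised once
  per slice mask and reused across the training set.

The regional variant solves the same Poisson problem inside a region
R_t strictly interior to Ω (e.g. the brain inside the skull) with the
inhomogeneous boundary data ψ = (B_z^m − B_z,0)/μ0 on ∂R_t, which is
valid because the normal current component is continuous across an
interior boundary; regions touching ∂Ω are rejected.  A precomputed
stray-field volume (e.g. from lead wires) can be subtracted from B_z^m
before projection; nothing more is modelled.

On resolved (smoothly varying) conductivity the full-domain projection
recovers the true in-plane current to ≈ 2%; across sub-voxel sharp
interfaces the unresolved curl sheets limit it to ≈ 15–20% locally.

## Dual-loop single-current reconstruction

Each interior node (i, j) of a slice contributes two counter-clockwise
KVL loops: the cell loop with corners (i−1,j−1)…(i−1,j), and a
half-voxel-shifted loop centred on the node.  The unknown vector X
holds the *inverse* scale factor 1/η at interior nodes (the loop terms
(D⁻¹J)·(1/η) are then voltage drops); boundary-ring η is a required
input and moves to the right-hand side.  For a full N_x×N_y rectangle
this gives 2(N_x−2)(N_y−2) equations in (N_x−2)(N_y−2) unknowns.

Two discretisations of the edge voltage drops are provided:

* `scheme="product"` (default): the integrand E = (D⁻¹J)/η is
  interpolated along each edge — trapezoid rule on the cell loop,
  midpoint rule (with the midpoint between two nodes) on the shifted
  loop.  Because the tangential electric field is continuous across
  conductivity interfaces, this stays exact for layered media and is
  O(h²) elsewhere.
* `scheme="node"`: (D⁻¹J) interpolated to edge midpoints and 1/η
  collapsed to one adjacent node per term.  This literal node-collapsed
  form is O(h) and inconsistent where η jumps; it is kept for
  comparison, and its own exactness tests restrict to uniform η.

The overdetermined system is solved by Tikhonov-regularised least
squares X = (AᵀA+λI)⁻¹(AᵀB + λX₀) with λ = 10⁻³·mean(diag(AᵀA)) by
default (scale-free floor; the appropriate value is data-dependent and
configurable).  The shift X₀ defaults to the boundary inverse scale
factor: a zero shift pulls 1/η toward 0 — i.e. inflates η without
bound along weakly-anchored chains perpendicular to the current — while
the boundary prior leaves unconstrained nodes at the known boundary
value.  `prior=None` restores the unshifted form.  Voxels whose D is
near-singular (condition number > 1e6) are flagged and their loops
dropped, with a warning if more than 5% of a slice is lost; interior
nodes untouched by any surviving loop are infilled from their nearest
reconstructed neighbour.

Noise propagates along equipotential lines through the loop chains, so
the raw dual-loop η̂ shows streak artifacts; removing them is the GRNN
corrector's job, not the solver's.

## Two-current reference algorithm

The curl-free property of E gives, per voxel, a 2-unknown system for
e = ∇ln η assembled over a 3×3 window from both montages' (D⁻¹J)
fields, with rows [w(D⁻¹J)_y, −w(D⁻¹J)_x] against the windowed curl and
MR-magnitude weights w_i = e^{−h‖ρ_i−ρ_c‖}/Σe^{−h‖ρ_j−ρ_c‖}
(h defaults to 1/sd(ρ); windows at mask edges renormalise over the
in-mask pixels).  The 2N×2 system is solved through its SVD with a
Tikhonov filter s_i/(s_i²+ζ), ζ chosen per voxel by minimising the
generalised cross-validation function

GCV(ζ) = [Σᵢ(ζb̂ᵢ/(sᵢ²+ζ))² + r²] / [(m−2) + Σᵢ ζ/(sᵢ²+ζ)]²

where r² is the out-of-range residual and m the row count.  Setting
r = 0, m = 2 cancels the ζ factors and yields the reduced
two-singular-value ratio Σ(b̂ᵢ/(sᵢ²+ζ))²/(Σ1/(sᵢ²+ζ))²; that reduced
form is degenerate on exactly consistent data (constant or even
decreasing in ζ, so it can select maximal regularisation for perfect
inputs), which is why the implementation keeps the residual and trace
terms.  The minimiser scans 61 log-spaced ζ in [10⁻¹²s₁², 10²s₁²] and
refines by golden section, breaking near-ties toward the smallest ζ;
everything is vectorised over the slice and deterministic.  Windows
where the two current fields are collinear (s₂²/s₁² < 10⁻¹²) are
flagged rank-1 and later infilled by nearest defined neighbour.

ln η̃ (relative to 1 S·s/mm³) is then integrated by solving
∇²_xy ln η = ∇_xy·e with the known boundary value as Dirichlet data and
exponentiated, so η̃ > 0 by construction; a curl-only component added
to e is annihilated by the divergence up to edge effects.

## GRNN artifact correction

`GRNNRegressor` is a scikit-learn-style estimator implementing the
kernel regression Y(X) = ΣV_k exp(−D_k²/2α²)/Σexp(−D_k²/2α²) with
D_k² = ‖X−U_k‖².  All M training samples sit in the pattern unit (no
cluster reduction).  Exponentials are shifted by the per-row minimum
distance, so the nearest neighbour always carries weight 1 and the
α → 0 limit degrades to nearest-neighbour regression instead of 0/0.
The spread α is tuned by all-M leave-one-out holdout MSE minimisation
(bounded scalar search in 10⁻³ < α < 10³, deterministic given the
training matrices); a flat objective returns the lower bound with a
warning.  Predictions are convex combinations of training rows, so the
corrected image is bounded by the training η̃ range per voxel.

## Training-set generation

For the phantom, the three tissue groups (agar background, chicken
muscle — all three cubes share one level — and potato) are each swept
over 10 linearly spaced η levels: agar 0.1–1, muscle 0.2–1.25, potato
0.01–0.3 S·s/mm³, giving M = 10³ factorial models.  Per model: one
conduction factorisation serves both montages; B_z* and B̃_z come from
the shared Biot-Savart plan; independent noise (seeds `seed+2m`,
`seed+2m+1`) is added; projected currents are recovered against the
shared homogeneous reference; the dual-loop network on the experimental
montage alone yields the row of U and the two-current algorithm the row
of V.  The boundary η handed to both reconstructions is the model's own
background level — known by construction for simulated models — while
the measured study uses the assumed boundary value (0.50 S·s/mm³ for
the phantom, from the agar conductivity and diffusivity; 0.40 for
head-like studies).  Rows are vectorised over the centre-slice mask;
the full multi-slice workflow trains one network per slice, and the
shipped studies reconstruct the centre slice, where the electrodes are
centred and J_z is smallest.  All seeds, levels and noise levels live in the
training manifest, so U and V regenerate bit-identically.

## Synthetic studies: what they emulate, and what they do not

`make_cylinder_phantom` builds a 55 mm diameter, 50 mm tall cylinder on
a 64×64×5 grid (1 mm in-plane; 10 mm slabs — a desk-scale version of
the 128×128 acquisition, which remains available by configuration) with
three ~15 mm muscle cubes (fibres along x, y, z), an 8×8×15 mm potato
cube, agar background, and 10×10 mm² vertical/horizontal electrode
pairs at 10 mA.  True tissue parameters are configuration, not
measurement: agar η = 0.50, D = 2.0×10⁻³ mm²/s isotropic (1.0 S/m);
muscle η = 0.60 with eigenvalues (1.4, 1.1, 1.1)×10⁻³ mm²/s (AR ≈ 1.2,
matching the anisotropy and conductivity ranges reported for chicken
muscle); potato η = 0.15, D = 1.2×10⁻³ isotropic (0.18 S/m).  The
default noise sd is 0.18 nT (phantom regime) and 0.21 nT for the
head-like domain, whose elliptical scalp (0.43 S/m) and skull
(0.015 S/m) shells, CSF rim (η ∈ [0.700, 0.844]) and anisotropic brain
interior support the regional-projection path with Fpz–Oz / T7–T8
style montages at 1.5 mA.

The generators do not emulate k-space acquisition, EPI distortion,
lead-wire stray fields, scanner drift, partial-volume averaging or
anatomical geometry.  Because training models and "measured" data come
from the same forward discretisation, shared systematic errors cancel
in the corrected-vs-reference comparisons; passing tests therefore
demonstrate the internal consistency and noise behaviour of the
algorithm chain at the stated geometry and noise levels, not scanner
performance.

## Degenerate inputs and tie-breaks

Disconnected masks, non-positive-definite tensors, regions touching
∂Ω, empty electrode patches, non-monotone echo times, zero-magnitude
voxels and λ = 0 on rank-deficient systems all raise explicit errors.
Eigenvalues are ordered descending; fitted diffusion tensors that come
out non-PD are clamped to an eigenvalue floor of 10⁻⁶λ₁ and flagged.
SSIM uses the 5×5 uniform window with C1 = 1e-4, C2 = 9e-4 on raw η
units (a normalisation flag exists, default off), sample (N−1)
variance normalisation, and in-mask renormalisation at mask edges.

## Known limitations

* The finite-volume forward model replaces a finite-element solver;
  electrode patches are uniform-current-density Neumann faces without
  complete-electrode contact impedance.
* The dual-loop and projection accuracy is interface-limited on
  piecewise-constant media at 1 mm resolution; real diffusion data are
  smoother, so the streak structure of η̂ differs in detail from
  scanner data.
* The GRNN is subject-specific: it corrects toward the two-current
  reconstructions of its own training geometry and cannot generalise
  across domains.
* Reconstruction quality degrades as the out-of-plane current J_z
  grows; the shipped montages keep current nearly in-plane.
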