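# Methods

`oaflux` simulates quantitative optoacoustic (photoacoustic) tomography end
to end and trains convolutional networks to undo the light-fluence
corruption that makes reconstructed images disagree with the underlying
optical absorption. This note records the models, the numerical choices,
and what the synthetic data does and does not represent.

## Physical model

An optoacoustic image is, up to the Grüneisen efficiency Γ (taken as 1
throughout), the absorbed optical energy density

    P0(r) = Γ H(r),   H(r) = μa(r) φ(r),

where μa is the optical absorption coefficient (mm⁻¹) and φ the light
fluence. Because φ decays with depth, P0 under-represents deep absorbers;
recovering μa from a reconstruction of P0 is the fluence-compensation
problem. The pipeline has four stages.

### 1. Absorption phantoms (`phantom`)

**2-D vessel networks.** A random-walk branching tree is rendered as dark
curvilinear vessels (Gaussian cross-section, widths 1–6 px, tapering along
each branch) on a bright smoothly-textured background — the contrast
polarity of retinal fundus imagery. The image is then pushed through the
extraction chain a practitioner would use on real fundus data: CLAHE
contrast enhancement (8×8 tiles, clip limit 0.01), wide mean-filter
smoothing of the enhanced image (25 px window, ~4× the maximum vessel
width, so it estimates the local background), absolute difference of
enhanced and smoothed images, isodata thresholding (iterate
t ← (mean(v≤t)+mean(v>t))/2 from the global mean until |Δt| < 10⁻⁶), a 3×3
morphological closing, removal of connected components below
`min_object_px` (30 px at 256², scaled with area), and removal of isolated
pixels. The closing step is needed for the network to survive thresholding
as a single connected component; without it CLAHE tile boundaries fragment
it. Absorption is then assigned per pixel: vessels draw i.i.d. uniform
values from [0.03, 0.0438] cm⁻¹ and background from [0, 0.001] cm⁻¹
(stored in the canonical unit mm⁻¹).

**3-D breast.** A hemispherical dome with a 2-voxel skin shell (closed by a
base plate), interior fat, 3–6 random ellipsoidal fibroglandular lobes and
2–5 random-walk vessel tubes. Classes are hole-filled and carry
μa = 0.016 (fibroglandular), 0.024 (fat), 0.032 (skin), 0.04 (vessel), 0
(background) mm⁻¹. Geometry parameters other than the class values are the
package's own choices.

### 2. Fluence (`optical`)

The continuous-wave diffusion approximation

    −∇·(D ∇φ) + μa φ = q,   D = 1 / (3 (μa + μs′)),

is discretized with 5-point (2-D) / 7-point (3-D) finite differences on the
phantom grid itself, harmonic averaging of D at faces, and the Robin
partial-current boundary condition D ∂φ/∂n + φ/(2A) = 0 with
A = (1+R_eff)/(1−R_eff) and the Groenhuis polynomial for R_eff at
refractive index n = 1.33 (A ≈ 2.79; A = 1 available for matched
boundaries). The SPD system is solved by diagonally preconditioned
conjugate gradients, relative residual 10⁻⁸, max 10⁵ iterations. On a 31×31
grid the CG solution matches a dense direct solve to 10⁻⁸; in a homogeneous
3-D medium the solution matches the infinite-medium Green's function
exp(−μ_eff r)/(4πDr) within 10% for r in 2–10 transport mean free paths,
and discrete energy balance (absorbed + boundary outflow = source power)
holds to machine precision.

Illumination: collimated line illumination is modelled as 10 isotropic
point sources equispaced along the illuminated (top) edge, placed one
transport step 1/μs′ below the surface but never deeper than 10% of the
domain — with the default μs′ = 0.1 mm⁻¹ (1 cm⁻¹, deliberately low to match
the simulated tissue regime) the literal transport depth would exceed the
domain. For the 3-D dome, 10 sources are spread over the surface on a
golden-angle spiral. Wavelength dependence uses a small lookup table:
700 nm → (μa × 1.0, μs′ = 0.10 mm⁻¹) is the identity entry; 600 nm →
(×1.6, 0.13) and 800 nm → (×0.8, 0.09) encode the qualitative trend of
stronger absorption/scattering at the short end of the NIR window. The
table values are package defaults, declared in config so experiments are
reproducible.

### 3. Acoustics (`acoustic`, `recon`)

The lossless homogeneous wave equation with initial conditions p(0) = P0,
∂p/∂t(0) = 0 is integrated with the first-order pressure/velocity k-space
pseudospectral scheme on a staggered grid, with the exact dispersion
correction κ = sinc(c k Δt/2) (the scheme is then exact for homogeneous
media, which permits CFL numbers near 0.5). A split-field PML with a
quartic absorption ramp (default 20 cells full scale, 8 at desk scale,
peak 2 Np/cell) absorbs outgoing waves; the velocity profile is sampled at
staggered (x+Δx/2) positions so left- and right-going waves see identical
ramps — sampling both fields at integer positions breaks mirror symmetry
at the percent level. Measured normal-incidence reflection is < 0.1%.

Detection: point detectors with multilinear interpolation each step; a
zero-phase Gaussian amplitude response centred at 5 MHz whose −6 dB full
width is 90% of the centre frequency (the DC bin is zeroed — AC-coupled
detector); additive white Gaussian noise at a prescribed sinogram-global
SNR, defined as mean-square signal over noise variance (10 log₁₀ ratio in
dB).

Reconstruction runs on a grid twice as coarse as the forward grid so the
inverse problem never sees its own discretization. Time reversal replays
the recorded traces backwards, *replacing* the field at each detector's
nearest cell (Dirichlet enforcement) before every reversed step; the field
after the final step is the P0 estimate, with no positivity constraint.
Universal-backprojection-style delay-and-sum (each pixel accumulates
p(t) − t ∂p/∂t at its time of flight, uniform ring weights) is provided as
the conventional baseline.

Acquisition presets: `paper2d` (801×801 @ 0.05 mm forward, 401×401 @ 0.1 mm
inverse, 256 detectors on a 19 mm ring, Δt 50 ns, 2048 steps → 524,288
samples) and `paper3d` (131³ @ 0.19 mm, 64×64 planar array, 2391 steps →
9,793,536 samples) carry the full-scale geometry; `desk2d` (64×64 phantom
@ 0.2 mm circumscribed by a 9.6 mm ring of 64 detectors, forward
224×224 @ 0.1 mm, Δt 30 ns, 448 steps) preserves every structural feature —
ring circumscribing the phantom, 2:1 grid refinement, band-limited noisy
detection — at a size a single CPU handles in seconds, and is the default
for datasets and tests.

### 4. Learned fluence correction (`models`, `nn`)

Six image-to-image architectures map the normalized TR reconstruction
(plus the normalized sinogram for the Y-variants) to the normalized μa
map: U-Net, fully dense (FD) U-Net (each conv in a block sees the
concatenation of all previous block outputs), Y-Net and FD Y-Net (a second
strided-conv encoder ingests the sinogram, resized to the image frame, and
fuses at the bottleneck), deep residual U-Net (residual units in place of
plain conv pairs), and a least-squares GAN (U-Net generator, strided-conv
patch discriminator, adversarial + λ·NRMSE loss with λ = 100). Defaults:
depth 4, 32 base channels doubling per level, 3×3 kernels, batch-norm +
ReLU, 2×2 max-pool down, transposed-conv up, skip concatenation. Training
minimizes

    NRMSE(y, ŷ) = √mean((y−ŷ)²) / √mean(y²)

with Adam (lr 10⁻⁴ full scale), batch 6, early stopping on validation NRMSE
with patience 12, best-validation weights restored. Normalization is
per-dataset min–max (not per-image) so intensities stay comparable;
predictions are mapped back through the stored (min, max).

The layers run on a compact NumPy reverse-mode autodiff library
(`oaflux.nn`): im2col/col2im convolutions backed by BLAS matmuls, verified
against central-difference gradients. Everything is float32 and
deterministic for a fixed seed.

Datasets are split 80/10/10 by phantom; the training split is quadrupled by
one horizontal flip and 90°/270° rotations. For the Y-variants the
sinogram of an augmented image is approximated by the corresponding
permutation of the detector axis of the circular array (flip ↔ reversed
ring order, 90° rotation ↔ quarter-ring roll); this is exact only for an
ideally symmetric ring and is treated as an augmentation heuristic.

**Desk-scale training protocol** (the default `ExperimentConfig`): 60
phantoms (48 train × 4 augmentation = 192 pairs, 6 val, 6 test), FD U-Net
depth 3 with 8 base channels, Adam lr 10⁻³, batch 6, 20 epochs, patience 12.
A feasibility pilot showed the corrected images gain far more than the
headline margin, so the small network is not the bottleneck; the sizes are
chosen so dataset synthesis plus three training runs complete in minutes on
one CPU.

## Metrics (`metrics`)

* PSNR = 20 log₁₀(max_I/√MSE), max_I = 1 on normalized images (configurable);
  +∞ for identical images.
* SSIM: by default the global single-window formula with population
  variances and k₁ = 0.01, k₂ = 0.03; a sliding-window variant (11×11
  Gaussian, σ 1.5) is available behind a flag and the mode is recorded in
  reports.
* gCNR = 1 − Σ min(hᵢ, hₒ) over 256 shared bins spanning the pooled
  min–max of both ROIs; for vessel phantoms the default ROI pair is a
  deep-region target box and a shallow background box.
* CNR = |μ_t − μ_b| / √(σ²_t + σ²_b), population variances, with a ±∞/0
  sentinel convention when both variances vanish.
* NRMSE as in the training loss.

## What the synthetic data does not capture

The vessel phantoms reproduce the statistics that matter for fluence
correction — connected curvilinear absorbers, heterogeneous foreground and
background levels, depth-dependent illumination — but not the anatomy,
scale distribution or imaging artifacts of real retinal or in-vivo
vasculature. The acoustic model is homogeneous and lossless (no speed-of-
sound heterogeneity, attenuation, or transducer directivity), the detector
is a point with a Gaussian EIR of zero phase, and the 2-D desk geometry is
a scaled version of the full acquisition rather than a replica. Passing
tests therefore demonstrate that the method recovers absorption from
self-consistently simulated data under realistic corruption mechanisms;
they say nothing about transfer to measured data.

## Degenerate inputs and tie-breaks

Constant images make the isodata threshold undefined and raise; masks
lacking either class, all-zero sinograms and all-zero NRMSE references
raise degenerate-input errors. Isodata iterates from the global mean and
stops at |Δt| < 10⁻⁶. CNR with two zero-variance ROIs returns +∞ when the
means differ and 0 otherwise. PSNR of identical images returns +∞. TR
requires the sinogram and reconstruction grid to share Δt exactly.
Backprojection zeroes contributions whose flight time exceeds the recorded
window and warns.

## Known limitations

* The diffusion approximation is used at μs′ = 0.1 mm⁻¹, a weakly
  scattering regime where its accuracy is marginal; it is retained as the
  forward model of record and the networks learn its fluence, not a
  radiative-transfer fluence.
* The 600/800 nm lookup-table entries are plausibility values, not
  measured spectra.
* 3-D correction is slice-wise with a 2-D network; fully 3-D networks and
  3-D acoustic datasets at full scale are out of scope.
* The GAN recipe (LSGAN + λ NRMSE on a patch discriminator) is a standard
  choice; no architecture search was performed.
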