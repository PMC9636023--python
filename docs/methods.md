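# Methods

This note documents the models, algorithms, parameter choices and numerical
decisions in `rlnet`, and what the synthetic-data experiments do and do not
demonstrate.

## Image-formation model

A fluorescence acquisition is modeled as `I = (GT ∗ f) + noise`, where `GT`
is the underlying intensity distribution, `f` a shift-invariant point-spread
function normalized to unit sum, `∗` linear convolution with zero padding,
and noise a combination of Poisson photon statistics and additive Gaussian
read noise. Volumes use the (z, y, x) axis convention (TIFF pages map to z)
and all internal computation runs on a continuous float scale; quantization
happens only when writing 16-bit output.

## Classic Richardson–Lucy baseline (`rlnet.deconv`)

The multiplicative update `E_{k+1} = E_k · ((I/(E_k ∗ f)) ∗ b)` starts from
`E_0 = I`. The division is guarded by an additive `eps` (default 1e-6 —
small relative to raw counts, so bright regions are unbiased; configurable
because published values for this guard are typically unstated). Boundary
handling is selectable: zero-padded convolution (default; realistic for
finite stacks) or periodic (used by flux-conservation tests, where
`sum(E_{k+1}) = sum(I)` holds to float precision). Back projectors:

* `matched-transpose` — `b(x) = f(−x)`; the maximum-likelihood choice for
  Poisson noise. Default 10 iterations.
* `gaussian` — a rendered Gaussian of configurable sd.
* `butterworth` — the flipped PSF filtered in frequency space by a
  Butterworth low-pass `1/sqrt(1 + (ρ/ρ_c)^{2n})` (cutoff ρ_c in
  cycles/voxel, order n). This is a simplified stand-in for full
  Wiener–Butterworth back-projector designs: it captures the
  pass-band-boosting idea that makes one-iteration deconvolution useful
  (default 1 iteration) without reproducing the full filter derivation.

## The RL network (`rlnet.network`)

Architecture as in the README: H1 (2× pooled estimation with dense 3-layer
FP/BP conv blocks, division guarded by α = 0.001, transpose-conv upsampling),
H2 (original scale, 2-layer blocks), H3 (dense 3-layer merge). Channel
widths: 4 (forward projector), 8 (back projector), 8 (merge). The merge
width is a design choice made here — with it the total parameter count is
15,692, consistent with the design goal of a ~16k-parameter network; it is
configurable. Specific wiring decisions that the architecture description
leaves open, resolved as follows:

* Residual-then-average in FP: the pooled input is broadcast-added to every
  channel of the FP block output, then channels are averaged. This
  guarantees `FP1 > 0` for nonnegative inputs (softplus activations are
  strictly positive), which together with α makes the division safe.
* Dense connections (3-layer blocks): layer 3 receives the channel
  concatenation of layers 1 and 2; layer 2 receives layer 1 only.
* Order per layer: convolution → batch normalization → softplus. Batch-norm
  eps 1e-3, running-statistics momentum 0.9; inference uses running
  averages.
* Odd input dims are zero-padded to even before pooling and the outputs
  cropped back, preserving the shape contract.
* The transpose convolution keeps the BP stream width (8 in, 8 out),
  kernel 2×2×2, stride 2.
* Dual-input mode averages the two registered views before H1, which makes
  the forward pass symmetric in its inputs and exactly reduces to the
  single-view network when both views agree.
* H2's correction multiplies E1 (not I): `E2 = E1 × correction2`.
* RLN-a (ablation): identical layer inventory with the division and
  multiplicative-update nodes removed, so each stage's channel-averaged
  BP output (upsampled in H1) is itself the stage estimate. The parameter
  count is identical because the removed nodes are parameter-free.

Initialization: FP-block conv kernels are Gaussians with per-output-channel
sd cycling through 0.5, 1, 1.5, 2 and amplitude drawn uniformly from
[0.5, 1] per kernel (a bank of plausible blur kernels); all other weights
are drawn from a unit normal (a fan-in-scaled variant is available but off
by default), biases start at zero.

The network is executed by a small reverse-mode autodiff engine
(`rlnet.nn`) written on numpy, with the 3×3×3 convolutions and softplus
compiled by numba as direct loop kernels (the input gradient reuses the
forward gather kernel with a flipped, channel-transposed weight). At ~16k
parameters and a dozen layers this engine trains the network in minutes on
one CPU core; float32 throughout.

## Training (`rlnet.train`)

Loss `L = mse(E1, ITM) + mse(O, GT) − ln((1 + SSIM(O, GT))/2)` with
`ITM = 0.8·GT + 0.2·I`. The SSIM inside the loss is the single global value
computed from whole-volume means, variances and covariance with C1 = 1e-4,
C2 = 9e-4; the `(1+SSIM)/2` argument is clamped at 1e-7 before the log.
Windowed SSIM (below) is deliberately reserved for evaluation; both variants
are exposed. Optimization is Adam (framework-default moments 0.9/0.999)
with learning rate `r = r0 · dr^(step/decay_step)`. Inputs and targets are
percentile-normalized per volume: exact min–max (p = 0, 100) for simulated
data; for real data p_low ∈ (0, 1), p_high ∈ (99, 100) to suppress hot
pixels (values outside the percentile range are not clipped). Each training
sample is an aligned random block cut from a random pair (uniform offsets,
no intensity-based rejection); batch size 4. Flip/rotation augmentation is
off by default.

Schedule defaults are r0 = 1e-3, dr = 0.95, decay_step = 1000 — a smooth
decay over a full-length run of 200 epochs × 100 iterations. For the
scaled-down studies in the test suite (a few thousand steps) the start rate
is raised to r0 = 2e-2 and kept nearly flat over the shorter run; among the
candidate schedules this one reached the lowest, most stable training loss
at equal step budget. An aggressive early decay was measurably worse: the
slowest-converging mode (driving the softplus background pedestal toward
zero) needs sustained large steps.

## Synthetic data (`rlnet.phantoms`)

Mixed-structure phantoms: solid spheres (diameter 4–8 voxels), hollow
ellipsoid shells (axis diameters 4–8, thickness 1–2, kept as the set of
voxels whose normalized ellipsoid radius lies within the sampled thickness
of the surface), and small axis-aligned box "dots" (1–3 voxels per axis),
at uniform random intensities 50–850 counts on a constant 30-count
background; defaults 100 + 100 + 400 objects in 128³. Overlapping objects
overwrite (later object wins), keeping every voxel's value either
background or a sampled intensity. Bead phantoms: random spheres (radius
≤ 7, intensity 80–255) smoothed with an isotropic Gaussian (sd 2). PSFs are
parametric anisotropic Gaussians — the light-sheet-like kind has a 3× larger
axial than lateral extent (default lateral sd 1 voxel, axial 3, kernel dims
2·ceil(4·sd)+1); iSIM-like and widefield-like kinds are configurable
Gaussian stand-ins (axial ratios 1.5 and 4), as published parameter values
for those systems are not available here. Noise: Poisson resampling at a
configurable photons-per-count (default 1), then additive Gaussian whose sd
is solved so the realized variance-ratio SNR `10·log10(Var(S)/Var(N))`
meets the target; if expected shot-noise variance alone exceeds the target
budget an error is raised. Poisson-before-Gaussian matches the physical
ordering (photon statistics, then read noise).

What the simulator does **not** emulate: spatially varying PSFs, scattering
and depth-dependent background, camera fixed-pattern noise, registration
errors between views, and realistic biological texture. Passing the
synthetic studies therefore demonstrates the correctness of the method's
machinery and its behavior in a controlled forward model, not performance
on any particular microscope.

## Tiled inference (`rlnet.tiling`)

Tile depth `d = min(D, 1600)` planes; lateral size
`w = h = floor(sqrt((B/4)·1024²/d))` with B the memory budget for 32-bit
data in MB (default 320; the 4 is bytes per voxel). Neighboring tiles
overlap by 24 voxels; the final tile along each axis is clamped to the
volume edge (so edge overlaps can exceed 24). Blending uses separable
linear ramps over each interior overlap, and per-voxel weights are
renormalized to sum to one — stitching a constant field is then exact, and
an identity operator round-trips through `predict_tiled` up to float
arithmetic. Seam differences between tiled and untiled network predictions
are real (receptive-field truncation at tile borders) and are measured, not
hidden, in the tests.

## Evaluation (`rlnet.metrics`)

Reported SSIM is the standard windowed form (11-voxel Gaussian window,
sd 1.5, K1 = 0.01, K2 = 0.03) on normalized volumes; PSNR uses the
normalized ground-truth maximum as peak. Network outputs and ground truths
are each normalized before comparison (outputs are already on the
normalized input scale; ground truths by min–max), mirroring evaluation on
normalized outputs and ground truths. The photon-statistics SNR
`S/sqrt(S + N_r²)` takes gain (default 0.46 photoelectrons/count) and read
noise (default 1.3 e⁻) as camera parameters.

## Scaled-down studies in the test suite

The bead-generalization study trains on four 64³ mixed phantoms (object
counts scaled with volume: 12 spheres, 12 shells, 50 dots) blurred with the
light-sheet-like PSF, noiseless; tests on three held-out 64³ bead phantoms.
RLN trains for 1,600 steps and RLN-a for 1,000 steps (batch 4, 24³ blocks),
against a full-length budget of 20,000 steps. The noisy-phantom comparison
trains a model at 10 dB input SNR for a few hundred steps and compares it
with one-iteration Butterworth-back-projector RL deconvolution. These sizes
keep the complete suite in the tens of minutes on one CPU core.

## Known limitations

* The engine targets this architecture; it is not a general-purpose
  framework (no GPU, no mixed precision, limited op set).
* Batch-norm inference uses running statistics collected on training
  blocks; applying a model to data with very different intensity
  statistics shifts its operating point (true of the original batch-norm
  design as well).
* The Butterworth back projector is a simplified design, not a full
  Wiener–Butterworth filter; no multi-view joint deconvolution and no
  spatially varying PSF support.
* Softplus outputs are strictly positive, so a trained network approaches
  but never exactly reaches zero background; training drives this pedestal
  below ~1e-3 of the dynamic range in the scaled-down studies.
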