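# Methods

This note documents the models, numerical choices and limitations behind
`lfrecon`, in the order data flows through the pipeline.

## Light-field forward model

A microlens array at the native image plane divides the sensor into
lenslets of N×N pixels; pixel (i, j) under a lenslet samples one angular
component. The imaging operator is linear and shift-invariant over integer
lenslet pitches only, so it is represented as a kernel bank
`H[d, i, j, Δy, Δx]`: the sensor response of a unit point source at depth
`z_planes[d]` and sub-lenslet phase (i, j), stamped at the source's lenslet
position. Projection is a sum of strided convolutions, one per
(depth, phase); the adjoint is the matching strided correlation and is
verified against the inner-product identity ⟨P(V), L⟩ = ⟨V, Pᵀ(L)⟩ to 1e-6.

**Normalization.** Each (depth, phase) kernel is truncated at
`kernel_halfwidth` lenslet pitches and renormalized to unit mass, so every
point source delivers its full intensity to the sensor and projection
conserves energy exactly for sources whose kernel support lies on the
sensor (border sources lose the off-sensor part, as a real camera does).

**Two PSF models.**

* `wave_optics` — scalar diffraction: the pupil-limited angular spectrum of
  a defocused point source is propagated to the native image plane,
  multiplied by the tiled quadratic lenslet phase (focal length
  f_l = pitch/2NA, which maps the NA cone across one lenslet), Fresnel-
  propagated to the sensor, squared, and binned 4×-oversampled into pixels.
  Vectorial/high-NA polarization effects and aberrations are not modeled.
* `gaussian_defocus` — a fast surrogate for unit tests: angular component
  (a, b) of a source at depth z lands at lenslet disparity
  s·z·(a−c, b−c) (plus the sub-lenslet source offset) with a Gaussian
  footprint of width σ₀ + σ′·|z| lenslets. The disparity slope s defaults
  to NA/(n·(N/2)·pitch) lenslets per μm — the marginal-ray walk-off per μm
  of defocus divided across the N/2 angular pixels — and the same law
  drives the refocusing baseline, so the surrogate and the baseline are
  geometrically consistent. Near focus, the kernel's second moment is
  dominated by the angular fine structure rather than σ(z), so only the
  far-defocus width comparison is treated as a contract.

Coordinates are fixed for exact round-trips: depth index 0 is
`z_planes[0]`, lenslet phase (i, j) = (row, col), view order row-major;
sub-voxel source positions are placed at the nearest voxel so the projector
stays exactly linear.

## Phantoms

All generators are pure functions of their spec (seed included) and return
machine-readable ground truth.

* **Tubulin**: cubic splines through k uniform control points, rasterized
  as dense polylines and blurred to the requested cross-section FWHM.
  Filament density is a free parameter (counts per volume).
* **Beads**: analytically rasterized Gaussian spots (σ = FWHM/2.355, floor
  0.6 voxel so the spot is resolvable on the grid) at rejection-sampled
  positions with a minimum separation; returned sub-voxel positions are the
  localization ground truth.
* **Cortical volumes**: soma ellipsoids with per-frame brightness following
  GCaMP-style traces — Poisson spikes convolved with a single-exponential
  kernel (τ = 1 s at 10 Hz by default) plus optional Gaussian noise —
  over optional neuropil haze (smoothed random field) and dark vessel
  tubes. This reproduces only the statistical structure a mesoscale
  reconstruction test needs; it is not a tissue simulation (no
  hemodynamics, scattering, or depth-dependent background).
* **Particle pairs**: frame-1 counts are Poisson with mean
  density × lenslet count (the PPM convention, default 0.03); frame-2
  positions are advected exactly by the analytic flow (uniform; shear with
  u_x ∝ z, a lid-driven-cavity-like profile; solid-body vortex in the x–z
  plane). The flow sampled on the voxel grid is the PIV ground truth.
* A Poisson + read-noise hook for projected light fields exists but is off
  by default; all tests run noiseless.

## Classical reconstructions

Refocusing shifts each sub-aperture view by its depth disparity and
averages. Shifts are applied at sensor resolution (views are expanded
N-fold first) with linear interpolation and edge clamping — shifting at
view resolution washes out point images whose disparity is a fraction of a
lenslet. The refocused stack of a projected point source peaks at the true
depth plane; this oracle underlies the localization comparisons.

LFD is Richardson–Lucy with the light-field projector:
`V ← V · Pᵀ(LF / P(V)) / Pᵀ(1)`, uniform positive initialization, ε = 1e-12
division guard, optional relative-change early stop. The data-fit KL
divergence is monitored and is non-increasing on noiseless input.

## Network

The generator consumes the N² views as input channels at view resolution
(no downsampling inside the encoder; light-field views are already small).
Encoder: three 3×3 conv + batch-norm + ReLU blocks widening
C → 2C → 4C (C = `base_channels`, default 64). Decoder mirrors it. Skip
connections concatenate the *even-indexed channels* of encoder stages 1 and
3 onto the matching decoder inputs (`skip_channel_rule="even_channels"`;
`"all"` selects plain concatenation). The upsampling head computes
features at a reduced width C/4, then averages two paths to the N-fold
lateral target: a 3×3 conv to C/4·N² channels followed by pixel shuffle,
and a 1×1 conv followed by separable bicubic resizing (Catmull-Rom,
a = −0.5, implemented as two fixed linear maps so the adjoint is exact).
Averaged over seeds, the blend puts measurably less spectral power at the
shuffle period than the pixel-shuffle path alone — the motivation for
combining them. A final 3×3 conv emits the D output slices (linear
activation; targets live in (−1, 1)).

The discriminator uses five blocks of two 3×3 conv + BN + ReLU layers (the
second strided 2), with channel widths [D, 40, 80, 160, 320] (20·2^k from
the second block, k = 1…4 — the first block is pinned to the slice count),
then global average pooling, a 20-unit ReLU dense layer and a sigmoid.
The discriminator scores volumes alone (it is not conditioned on the input
light field), matching the unconditioned score form of the objective. No
dropout anywhere; batch normalization plus AdamW weight decay (1e-2)
provide the regularization.

**Autodiff.** No GPU tensor framework is a dependency; `lfrecon.nn` is a
small reverse-mode autodiff engine on float64 numpy arrays (im2col
convolutions, broadcasting-aware arithmetic, batch-norm with running
statistics, pixel shuffle, fixed-matrix bicubic resize). Every operation is
gradient-checked against central finite differences at 1e-6 relative.
Determinism is exact: seeded initialization, no threading nondeterminism,
eval-mode batch norm at prediction time.

**Losses.** BerHu is implemented as the printed per-pixel sum (the
closed-form checks exercise that form) with a `reduction="mean"` option
that the training objective uses so the three terms stay commensurate at
desk scale. MS-SSIM uses Gaussian-window (11, σ = 1.5) local statistics,
dyadic scales linked by 2× average pooling, the standard scale exponents
[0.0448, 0.2856, 0.3001, 0.2363, 0.1333] (renormalized when fewer levels
are used), C1 = (0.01R)², C2 = (0.03R)², C3 = C2/2; contrast/structure
terms are clamped at 1e-7 before fractional powers. For volumes it is
applied per slice and averaged, since the definition is 2D. The similarity
enters the objective as 1 − MS-SSIM. The adversarial pair is
½log(1−D(G(x))) + ½log D(y) for the discriminator (maximized) and the
non-saturating −log D(G(x)) for the generator; scores are ε-clamped at
1e-7 inside logs.

**Training.** Per batch: one discriminator step toward hard labels 1/0
with the generator frozen (its output detached), then one generator step on
the composite loss with the discriminator frozen (ratio configurable).
"Every 5 calendar elements" in the decay schedule is read as every 5
epochs. A NaN loss aborts the run and restores the last epoch snapshot.
Checkpoints are HDF5 files embedding the spec, seed and a version field;
save → load → predict is bit-identical. Training runs for a fixed epoch or
step budget; no early stopping is applied (the per-step history lets a
caller implement their own rule). `kfold_split` provides the 5-fold
1600/400 protocol used for generalization studies.

## Metrics

PSNR is 10·log10(MAX²/MSE) with MSE the *mean* squared error — the printed
sum form would contradict both the 8-bit closed-form value
20·log10(255) ≈ 48.13 dB at unit error and the magnitude of reported MSE
values on unit-normalized data. Identical inputs are reported as a 99 dB
sentinel with a flag rather than +∞ so JSON reports aggregate cleanly.
SSIM defaults to the global-statistics form (the windowless printed
formula); a sliding-window mode is provided and cross-checked against
scikit-image. The LPIPS-style distance runs a seeded random conv pyramid
with per-pixel channel-unit-normalized features and unit layer weights: it
is a deterministic, download-free pseudometric (non-negative, symmetric,
zero on identical inputs) whose *absolute* values are not comparable to any
pretrained-backbone numbers; a pretrained extractor can be plugged in.

The decorrelation cut-off k_c cross-correlates the phase-normalized
spectrum with radially masked spectra over 50 mask radii, repeated for a
series of 10 Gaussian high-pass filters with log-spaced widths (0.08–0.8 in
Nyquist units) plus the unfiltered image; the reported k_c is the radius of
the highest peak across the family, parabolic-refined when interior. An
end-of-curve maximum is accepted (white noise decorrelates at Nyquist).
Hann windowing suppresses FFT edge leakage.

FWHM uses cubic-spline root-finding for the half-level crossings (plain
linear interpolation biases a σ = 2 px Gaussian by ≈ 0.05 px, more than the
0.01 px contract). ΔF/F₀ is (F − F₀)/F₀ with F₀ the time-average of the
per-frame ROI mean — "averaged over time" is read as the baseline
definition, with F itself kept per-frame, since a single scalar F would
admit no dynamics.

## PIV

Localization: local maxima above a relative threshold with a minimum
separation, refined to intensity-weighted centroids over a ±2 voxel window.
Position errors use one-shot greedy nearest-neighbor matching with a
maximum-distance gate; unmatched detections and unmatched truth particles
are reported separately, never silently dropped. Optical flow is
Horn–Schunck in 3D — fixed-point iteration on
∫(I_t + u·∇I)² + λ|∇u|² with a 6-neighbor average, coarse-to-fine over a
dyadic pyramid with intermediate warping (defaults λ = 0.05,
300 iterations/level, 2 levels, 4 warps, chosen on the vortex phantom for
sub-voxel displacements of sparse particle images). scikit-image's TV-L1
solver serves as an independent cross-check in the tests, not as the
implementation. Velocities carry explicit units (voxels/frame, converted
only at reporting).

## Desk-scale experiment sizes

The acceptance experiments (in `lfrecon.experiments`) run on one CPU in
about a minute total, with sizes chosen to keep each probe sharp rather
than large: toy GAN training uses N = 4 optics, 8+1 bead phantoms of
5×64×64 voxels (16×16 views), 200 alternating steps at learning rates
2e-3/2e-4 — a few-hundred-step run needs larger steps than a
hundreds-of-hours schedule; the axial-localization probe uses 5 beads
staggered in depth and x over 11 planes with 60 RL iterations; the
flow probes use 16–24-plane volumes with ~25–300 particles. Passing these
shows the operators, objective, optimization loop and analysis stages are
correct and internally consistent on clean synthetic data; it does not
show noise robustness or full-scale image quality, which require real
acquisitions and long training.

## Known limitations

* The wave-optics model is scalar and aberration-free; absolute PSF shapes
  at NA 1.4 are approximate even though the qualitative structure
  (defocus broadening, disparity) is right.
* The Gaussian surrogate's kernels are separable products and ignore
  diffraction side lobes.
* Training at desk scale demonstrates optimization behavior, not
  generalization; the k-fold utilities support larger studies but none are
  bundled.
* The LPIPS feature stack is random: use it for rankings under a fixed
  seed, not absolute perceptual scores.
* Horn–Schunck flow underestimates large displacements (> a few voxels per
  frame) unless the pyramid is deepened.
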