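# Methods

This note documents the models, the numerical choices, and the
limitations of the package, in the order data flows through it.

## Volume conventions

A volume is a real 3D array with axes ordered (FE, PE, SL) —
frequency-, phase- and slice-encoding — and intensities affinely
rescaled to [0, 1]. A constant volume rescales to all zeros (the
degenerate zero-dynamic-range case is resolved toward background rather
than raising). Plane semantics follow a sagittally acquired brain
volume: *sagittal* slices stack along SL (axis 2) with in-plane axes
(FE, PE); *axial* slices stack along PE (axis 1) with in-plane axes
(FE, SL). SRR defaults to sagittal processing, MAR to axial.

## Synthetic phantoms

`generate_phantom` builds anatomy-like test volumes as a sum of nested
soft-edged ellipsoids (sigmoid falloff across the shell boundary,
alternating shell contrast, small seeded center jitter) plus a
band-limited Gaussian random texture field (white noise smoothed with a
Gaussian of width `texture_scale` voxels, modulated by the anatomy
envelope so texture lives mostly inside the "head") and optional
additive Gaussian noise. Identical specs give bit-identical volumes.

The phantoms emulate exactly the features the pipeline needs from real
T1-weighted brains — smooth nested tissue-like layers (low spatial
frequencies), recoverable high-frequency texture, [0, 1] intensities,
anisotropic matrix sizes — and nothing else. They have no MR contrast
physics, bias fields, coil profiles or realistic noise statistics, so
passing tests demonstrate the correctness and trainability of the
machinery, not clinical performance on real brains.

## Low-resolution simulation

FFT conventions: forward 3D FFT with the DC component shifted to the
array center; truncation keeps the centered block of size `dim/s` per
axis, `[dim/2 − dim/(2s), dim/2 + dim/(2s))` in 0-based half-open
indexing for even dims. `keep_matrix=True` zero-fills the discarded
region (LR content on the original grid), `keep_matrix=False` returns
the reduced matrix — the true LR acquisition with proportionally larger
voxels, which is what the network consumes (in-plane resolution is
restored by learned sub-pixel upsampling, not by input interpolation).

After the inverse FFT the real part is taken. On even grids the
retained central block keeps one unpaired Nyquist plane per truncated
axis, so the complex image carries an imaginary residue at the percent
level; taking the real part is mathematically identical to
Hermitian-symmetrizing the truncated spectrum and discards exactly that
asymmetric component. For full (untruncated) spectra the inverse is
real to machine precision and `from_kspace` enforces a 1e-8 residue
bound.

Accounting: acceleration = s_PE · s_SL (scan time follows encoding
steps), discarded fraction = 1 − 1/(s_FE · s_PE · s_SL); both are
verified against brute-force coefficient counts.

## Motion-artifact simulation

The 7-step periodic schedule (in echo-group units, EG = 80 echoes by
default): rest Ts → 2 EG rotate left → 5 EG hold → 2 EG rotate back →
rest Ts → 9 EG mirrored right sequence → rest Ts, repeated until
k-space is full. One period of steps 2–7 spans 18 EG displaced +
2·Ts at rest, so the corruption ratio is 18EG/(18EG + 2Ts). The 2-EG
rotation ramps are modeled at the full displaced angle (the schedule
gives no intra-ramp sampling); they count as displaced. The reported
periodic ratio excludes the initial step-1 rest block; the finite-fill
ratio including it is logged alongside.

Splicing is done per acquisition-plane slice: the 2D spectra of the
original volume and of one precomputed rotated volume per distinct pose
(left/right; in-plane rotation about the through-plane axis, optional
through-plane "nodding" composed on top; trilinear resampling,
zero fill outside the field) are computed, phase-encode lines are
visited in centric (center-out, ties to the lower index) order, and
each line is copied from the pose active at its acquisition time. The
timeline advances continuously across slices by default (3D-acquisition
semantics; a per-slice restart mode exists). The magnitude of the
inverse FFT is taken and the volume rescaled to [0, 1].

Not modeled (by design): translations and drifts, random motion
patterns, raw multi-coil k-space.

## Thin-slab geometry

Patches follow the 128/32 high-resolution grid: LR patches are
`128/r` pixels with `32/r` overlap for in-plane scale r (64/16 at
scale 2, 32/8 at scale 4), overridable. Grids that do not tile exactly
snap the final patch to the boundary (its overlap grows locally).
Slabs of M ∈ {1, 3, 5} slices advance at stride 1, so consecutive slabs
share M−1 slices and interior slices appear in exactly M slabs.

Stitching discards patch borders: each in-plane overlap is cut at its
midpoint, which equals discarding overlap/2 per side on a regular grid
while edge patches keep their outer borders. Through-plane, a slab
starting at LR slice s writes output slices s·s_SL … s·s_SL+N−1; the
self-ensemble averages all candidates covering a slice (boundary slices
average over however many exist — no padding), computed as the
center-slab candidate plus the mean deviation of the others so that
identical candidates reproduce the input bit-exactly. With the
ensemble off, each slice comes from the slab in which it sits most
centrally. Feathered blending and flip/rotation test-time augmentation
are deliberately absent — the ensemble here is slab-position averaging
only.

## Network

RCAN-style backbone: shallow 3×3 convolution (M → F channels), `n_rg`
residual groups of `n_rcab` residual channel-attention blocks
(conv–ReLU–conv, then a squeeze-excitation gate: global average pool →
1×1 conv to F/reduction → ReLU → 1×1 conv to F → sigmoid), a group-level
and a global skip, one ×2 pixel-shuffle stage per factor of 2 of
in-plane scale, and a final 3×3 convolution to N (or 4N evidential)
channels. Defaults: 5 groups × 5 blocks × 64 filters; reduction 16
(RCAN's canonical value, giving a 4-channel bottleneck at 64 filters);
3×3 kernels everywhere except the 1×1 attention bottleneck; He
initialization from a generator seeded by the config.

Evidential head link functions: v = softplus + 1e-6,
α = 1 + softplus + 1e-6, β = softplus + 1e-6; γ unconstrained. The
1e-6 floor keeps the domain constraints strict even where softplus
underflows to zero in float64. The restored image is the γ map.

The whole network runs on the package's own reverse-mode autodiff
(float64 throughout); every primitive's gradient — including 2D
convolution, separable filtering, pixel shuffle and log-gamma — is
tested against central finite differences.

## Losses

Charbonnier uses ε = 1e-4 *inside the root un-squared*, exactly as
specified: identical images score √ε = 1e-2, and the loss approaches L1
for large residuals. The SSIM loss squares the per-patch mean SSIM
(11×11 Gaussian window, σ = 1.5, K1 = 0.01, K2 = 0.03, data range 1,
zero-padded borders) and averages 1 − SSIM² over the batch. The
combined objective is L_Char + w1·L_SSIM with w1 = 0.5, plus
w2·L_NIG (w2 = 1) in evidential mode. The NIG regulariser weight λ has
no canonical value in the evidential-regression setting used here;
the default is 0.01 (the scale customary in that literature) and it is
exposed in `LossWeights`. The NIG implementation is cross-checked to
1e-10 against an independent scalar evaluation.

## Training and inference

Defaults reproduce the reference recipe: 50 epochs, batches of 8
randomly drawn patches (uniform over the precomputed patch list with
per-epoch reshuffle), ADAM (β1 = 0.9, β2 = 0.999, ε = 1e-8), cosine
learning-rate decay from 1e-4 at step 0 to 1e-8 at the final step.
Training aborts with diagnostics on a non-finite loss. The run log
serializes the full config (round-trip parseable) plus loss/lr traces
and optional per-epoch validation PSNR on held-out patches. Runs are
deterministic given the seed on a fixed platform; cross-platform
floating-point drift means comparisons should use tolerances, not
bit-exactness.

### Scaled-down study sizes

The self-contained training studies (used by the test suite and the
worked example) shrink the problem until a CPU run takes about a
minute, while keeping every structural element of the full recipe:

* SRR: 1×1×2 down-sampling, M = 3, tiny network (1 group, 2 blocks,
  16 filters, reduction 4), 500 steps, 24-pixel patches with 8-pixel
  overlap, four 48×48×24 phantoms (3 train / 1 test), base learning
  rate 2e-3. The paper-scale 1e-4 schedule is the package default but
  barely moves a freshly initialized network within 500 steps; the
  scaled-down preset raises it so the comparison against tricubic
  interpolation is meaningful at this budget.
* MAR: Ts = 9 EG with EG = 8 lines, 5° in-plane plus 5° through-plane
  rotation (the severest study condition), M = 3, same tiny network,
  96×24×64 noiseless phantoms. The larger in-plane matrix matters: a
  5° rotation displaces only ~1–2 voxels on a very small matrix, which
  leaves the corrupted input's SSIM nearly perfect and the comparison
  vacuous; at 96×64 in-plane the corrupted input lands in the intended
  severity range.

## Uncertainty calibration

Slice-mean epistemic uncertainty is regressed against slice quality:
SSIM linearly (ordinary least squares; classical prediction intervals
t·s·√(1 + 1/n + (u−ū)²/Sxx)), PSNR as c·e^{d·u} + e (nonlinear least
squares with log-linear initialization; a 2-parameter variant without
the offset is selectable). The exponential form nests a flat asymptote
and matches PSNR's logarithmic character; its prediction intervals use
the delta method (gradient–covariance–gradient plus residual variance,
t-scaled). Predictions more than one fitted-range width outside the
data warn about extrapolation. Calibrations serialize to JSON and
round-trip exactly. Observations are pooled per slice across volumes;
the grouping is recorded in the serialized output.

## Metrics

PSNR with peak 1.0 (identical volumes report an `inf` sentinel,
rendered as the string "inf" in JSON reports). SSIM is computed per 2D
slice of the evaluation plane with the standard constants and averaged;
the per-slice score is defined as the mean of the full local-SSIM map,
so the map's mean equals the scalar by construction. 2D-per-plane SSIM
(rather than 3D windows) matches per-direction reporting of 3D
reconstructions.

## Known limitations

* Phantoms are geometric, not physical; absolute PSNR/SSIM levels on
  them do not transfer to clinical data.
* The numpy network is CPU-bound and float64; it is sized for
  correctness and desk-scale studies, not for full-resolution training.
* Motion simulation covers periodic rigid rotations only.
* The evidential λ and the exponential-regression functional form are
  package choices where the setting is underdetermined; both are
  configurable and serialized with results.
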