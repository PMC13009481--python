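# slabrestore

Pseudo-3D restoration of 3D MR magnitude volumes: super-resolution
reconstruction (SRR) of retrospectively down-sampled acquisitions and
motion-artifact reduction (MAR), with per-voxel evidential uncertainty
that calibrates against image quality.

The package is aimed at MR-reconstruction researchers who want a fully
self-contained, CPU-testable implementation of the thin-slab approach:
every experiment runs on deterministic synthetic phantoms, so no
clinical data download is required, and real volumes can be supplied
through the generic NIfTI path.

## What it implements

**Degradation simulators.** A low-resolution acquisition is simulated
in the frequency domain: 3D FFT, symmetric central truncation by an
integer scale-factor triple ordered FE × PE × SL, inverse FFT, rescale
to [0, 1]. The acceleration equals s_PE · s_SL and the discarded
fraction is 1 − 1/(s_FE · s_PE · s_SL) — e.g. 2×2×1 discards 75% of
k-space while 1×1×2 reaches the same ×2 acceleration discarding only
50%. Motion artifacts are generated by splicing k-space lines from
rigidly rotated copies of the volume following a deterministic periodic
schedule in echo-group (EG) units — rotate over 2 EG, hold 5 EG, rotate
back over 2 EG, rest Ts, mirror to the other side, rest Ts — giving a
closed-form corruption ratio 18·EG / (18·EG + 2·Ts): 50%, 33%, 20% and
11% for Ts = 9, 18, 36, 72 EG. Lines are filled along a centric
(center-out) trajectory.

**Thin-slab network.** A 2D residual channel-attention network (RCAN
backbone: residual groups of residual channel-attention blocks with a
global skip) whose input channels carry an M-slice slab (M ≤ 5), so the
first convolution acts as a pseudo-3D kernel; the output channels carry
N = M · s_SL restored slices (N = M for MAR), with sub-pixel
(pixel-shuffle) in-plane upsampling. At inference every slice is
reconstructed by up to M overlapping slab positions and the
*self-ensemble* averages those candidates voxel-wise. The network and
its training loop (ADAM, cosine learning-rate decay 1e-4 → 1e-8) are
implemented on a small numpy reverse-mode autodiff core bundled with
the package (`slabrestore.nn`), with gradients validated against finite
differences.

**Objectives.** Charbonnier loss √((HR−SR)² + ε) with ε = 1e-4, a
squared-SSIM structure loss 1 − SSIM², combined as
L = L_Char + 0.5·L_SSIM, plus (when the evidential head is active) the
Normal-Inverse-Gamma loss L_NLL + λ·|y−γ|(2v+α) with Ω = 2β(1+v).

**Uncertainty and calibration.** The evidential head predicts per-voxel
NIG hyperparameters (γ, v, α, β), giving the prediction E[μ] = γ,
aleatoric uncertainty E[σ²] = β/(α−1) and epistemic uncertainty
Var[μ] = β/(v(α−1)). Slice-mean epistemic uncertainty is regressed
against SSIM (linear) and PSNR (exponential, c·e^{d·u}+e), yielding 95%
prediction intervals that estimate reconstruction quality when no
ground truth exists.

## Worked example

A scaled-down SRR study — tiny network (1 residual group, 2 blocks,
16 filters), 500 steps on three 48×48×24 phantoms, 1×1×2 through-plane
down-sampling, evaluated on a held-out phantom against tricubic
interpolation:

```python
import numpy as np
from scipy import ndimage
from slabrestore import (PhantomSpec, generate_phantom, degrade_lr, rescale01,
                         TrainConfig, train, restore_volume, psnr, ssim)

vols = [generate_phantom(PhantomSpec(shape=(48, 48, 24), seed=s)) for s in range(4)]

cfg = TrainConfig(task="srr", scale=(1, 1, 2), M=3, lr_size=24, lr_overlap=8,
                  epochs=5, steps_per_epoch=100, n_rg=1, n_rcab=2, n_feat=16,
                  reduction=4, lr=2e-3, seed=0)
model, history = train(cfg, vols[:3])

hr = rescale01(vols[3])
lr = degrade_lr(hr, (1, 1, 2))                      # (48, 48, 12), 50% of k-space
sr = restore_volume(model, lr, cfg.geometry)        # thin-slab inference + ensemble
tricubic = np.clip(ndimage.zoom(lr, (1, 1, 2), order=3), 0, 1)

print(f"training loss: {history['loss'][0]:.3f} -> {np.mean(history['loss'][-20:]):.3f}")
print(f"network : PSNR {psnr(sr, hr):.2f} dB  SSIM {ssim(sr, hr):.4f}")
print(f"tricubic: PSNR {psnr(tricubic, hr):.2f} dB  SSIM {ssim(tricubic, hr):.4f}")
```

Output (about one minute on one CPU core):

```
training loss: 1.755 -> 0.059
network : PSNR 39.61 dB  SSIM 0.9724
tricubic: PSNR 31.38 dB  SSIM 0.9666
```

The network recovers the through-plane detail removed by k-space
truncation and beats tricubic interpolation by ~8 dB PSNR on this
phantom family. The same interfaces drive MAR
(`TrainConfig(task="mar", motion=MotionSchedule(ts_in_eg=9, ...))`) and
the evidential variant (`evidential=True`), whose uncertainty maps feed
`QualityCalibrator`.

A scikit-learn style front end wraps the same pipeline:

```python
from slabrestore import SlabRestorer
est = SlabRestorer(task="srr", scale=(1, 1, 2), M=3, epochs=5,
                   steps_per_epoch=100, n_rg=1, n_rcab=2, n_feat=16,
                   reduction=4, lr_size=24, lr_overlap=8, lr=2e-3)
est.fit(vols[:3])
sr = est.transform(lr)
```

There is also a CLI (`slabrestore phantom|degrade|motionsim|train|infer|
evaluate|calibrate`) for shell-driven use with NIfTI volumes.

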