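# scos — multi-channel speckle contrast optical spectroscopy

`scos` is a processing toolkit for camera-based cerebral blood flow
measurements by speckle contrast optical spectroscopy (SCOS): a coherent
laser illuminates the scalp, diffusely reflected light forms speckle
patterns on CMOS cameras, and the blurring of those patterns over the
exposure encodes how fast scatterers (red blood cells) move.  The package
covers the full chain from raw multiplexed speckle frames to activation
maps, together with a physics-based synthetic instrument so every stage is
testable without hardware:

- **simcam** — synthetic speckle frame stacks with known ground truth
  (coherence parameter β, decorrelation time τc, photon flux, camera gain /
  read noise / quantization), a 7-source temporal-multiplexing schedule, and
  the spiral→line→grid galvanometer coupling search.
- **probe** — the 76 × 66 mm high-density layout (7 sources, 17 detectors)
  with 19 mm / 33 mm channel classes and the 8 mm short-separation channel.
- **preprocess** — missed-frame repair, dark subtraction, and 7×7-pixel
  windowed mean/variance (a ≥24-fold data reduction).
- **contrast** — noise-corrected fundamental contrast, ΔOD, relative
  blood-flow index, and photon-transfer-curve gain calibration.
- **analysis** — channel QC, motion-block masking, short-separation and
  PCA common-mode regression, 0.2 Hz low-pass, block averaging, and group
  statistics with a 1.96·SE significance rule.
- **recon** — Tikhonov image reconstruction with a toy "banana" sensitivity
  generator.
- **workbench / CLI** — one-config, reproducible end-to-end runs.

## The model

The spatial speckle contrast of a window of pixels is `K = std(I)/⟨I⟩`.
For an exposure `T` and field decorrelation time `τc` (single-exponential
field correlation), the fundamental contrast squared is

    K_f²(x) = β · (e^(−2x) − 1 + 2x) / (2x²),   x = T/τc,

where β is the source/detection coherence parameter, fixed for unpolarized
light by the polarization ratio: `β = (s/p)² / (2(1+(s/p)²))` — the
instrument's measured s/p ≈ 0.69 gives β ≈ 0.16.  The raw windowed contrast
of a real camera additionally contains shot, read, quantization, and
illumination-heterogeneity terms, removed window-by-window:

    K_raw² = σ²_win/⟨I⟩²
    K_f²   = K_raw² − G/⟨I⟩ − (⟨σ²_dark⟩ − 1/12)/⟨I⟩² − (1/12)/⟨I⟩² − K_sp²

with `G` the camera gain (ADU/e⁻, from a photon transfer curve).  Windows
are combined weighted by `⟨I⟩²`.  Channel time courses then yield the
optical-density change `ΔOD = −ln(I/I₀)` and the fractional blood-flow-index
change `rDB − 1 = K_f,0²/K_f² − 1` relative to a baseline interval.
Channel data `y` map to a vertex image `x` through a sensitivity matrix `A`
and the regularized inverse `x = Aᵀ(AAᵀ + λI)⁻¹y`, `λ = 0.05·b` with `b`
the largest eigenvalue of `AAᵀ`.

## Worked example

Run the bundled synthetic Stroop-like scenario (a 7-source acquisition with
a flow response of amplitude 0.40 planted in source channels 0 and 1, plus a
shared scalp oscillation that short-separation regression removes):

```python
import dataclasses
from scos.workbench import demo_config, run_pipeline

cfg = dataclasses.replace(demo_config(), duration_s=120.0, n_blocks=4, seed=2)
res = run_pipeline(cfg, "runs/demo")
g = res["group"]
for c, wm, se, sig in zip(g.channel_ids, g.window_mean, g.window_se,
                          g.significant):
    print(f"channel {c}: window_mean={wm:+.3f}  se={se:.3f}  significant={sig}")
```

prints

```
channel 0: window_mean=+0.348  se=0.005  significant=True
channel 1: window_mean=+0.362  se=0.016  significant=True
channel 2: window_mean=-0.021  se=0.016  significant=False
channel 3: window_mean=-0.027  se=0.012  significant=False
channel 4: window_mean=-0.022  se=0.015  significant=False
channel 5: window_mean=-0.020  se=0.005  significant=False
channel 6: window_mean=-0.005  se=0.021  significant=False
```

`window_mean` is the block-averaged rDB−1 in the 10–15 s post-onset window:
the two planted channels are recovered at 0.35–0.36 (the ≈10% compression
relative to the planted 0.40 is the expected finite-`x` response of the
contrast model plus low-pass smoothing) and flagged significant; the
unplanted channels are flat.  The run directory contains a `manifest.yaml`
echoing every parameter, per-stage outputs, and `qc_report.json`.

The same pipeline is available from the shell:

```sh
scos simulate --out stack.tiff --dark-out dark.tiff
scos preprocess stack.tiff --dark dark.tiff --out ws.h5
scos contrast ws.h5 --dark dark.tiff --out series.h5
scos run --out runs/demo        # full end-to-end run
```

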