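# Methods

This note documents the models implemented in `scos`, the design decisions
taken where the methodology was genuinely open, the synthetic instrument and
what passing tests do and do not demonstrate, and known limitations.

## Speckle contrast model

The package assumes a single-exponential field correlation
`g1(t) = exp(−t/τc)`, the community-standard model for diffuse dynamic
speckle.  The exposure-integrated spatial contrast squared is then

    K²(x) = β (e^(−2x) − 1 + 2x) / (2x²),  x = T/τc,

implemented in `simcam.expected_contrast` with an `expm1` formulation that
is stable at small `x` (limit β) and has the `β/x` tail at large `x`.  The
coherence parameter β and the polarization amplitude ratio s/p are tied by
the unpolarized-light relation `β = (s/p)²/(2(1+(s/p)²))`, with exact
inverse `s/p = √(2K²/(1−2K²))`; both directions are exposed and are exact
inverses to 1e-12.

## Synthetic instrument (`simcam`)

Defaults emulate the hardware the pipeline is designed for: 10-bit cameras
at gain 0.5 ADU/e⁻ with black level 25 ADU and read noise 2.1 e⁻; a single
laser multiplexed over 7 source fibers, 10 ms per slot with 5.2 ms
illumination and 4 ms exposures at a 100 Hz camera rate (7.4% per-source
duty cycle, 14.3 Hz full-array rate); β = 0.16 (s/p = 0.69); smooth
low-order-polynomial illumination heterogeneity of 5% RMS emulating
defocused fiber-bundle illumination.  The analog-gain dB setting of a real
camera is *not* converted automatically — `gain_G` is specified directly in
ADU/e⁻, because dB-to-gain conversion is camera-specific.

Two speckle generators share one camera noise chain (Poisson
photoelectrons → gain → Gaussian read noise → black level →
round-to-nearest quantization → clipping):

- **gamma** (default): per-pixel intensities drawn i.i.d. from a Gamma
  distribution whose contrast equals `expected_contrast` at the frame's
  current `x`.  Fast; no temporal field dynamics inside the exposure.
- **field** (gold standard): per pixel, M independent complex circular-
  Gaussian speckle modes evolve as an AR(1) process with field correlation
  `exp(−Δt/τc)` between sub-steps and intensity integrated over the
  exposure (rectangle rule, ≥20 sub-steps, more at large `x`).  Mode powers
  are M−1 units plus one fractional weight solved in closed form so the
  short-exposure contrast equals β *exactly* for any β ∈ (0, 0.5].  This
  weighted-mode construction was chosen over a literal two-polarization
  sum because two fully-developed components cannot reach β below 0.5·
  (component contrast); mode mixing is the mechanism that actually lowers β
  in a fiber-bundle instrument, and s/p remains the calibration parameter
  through the relation above.

`expected_contrast_discrete` gives the exact second-moment expectation of
the rectangle-rule integral, so tests can separate discretization from
estimator effects.  A *static* scene (τc = ∞) is simulated as an ensemble of
independent frozen patterns — each frame a fresh speckle realization that
does not decorrelate within its exposure.  This makes static stacks
ergodic: the temporal mean image converges to the illumination profile, so
the heterogeneity term K_sp² is estimable.  (A physically frozen pattern
repeated across frames, as on a real static phantom, would make the mean
image the speckle pattern itself; for that case the correction offers
`include_sp=False`, and the static-phantom tests use it.)

Frames are generated independently per exposure; this is exact whenever
τc ≪ the 70 ms revisit time of a source, which holds for every scenario
simulated here (τc ≤ 4 ms).

The galvanometer coupling search reproduces the staged structure of the
alignment protocol: an outward Archimedean spiral (5 µm arc step, bounded
at 500 µm radius) until a power threshold is reached, alternating ±20 µm
line scans per axis repeated until no improvement, and a final 40 × 40 µm
grid refinement; ties break toward the earlier-scanned coordinate, and an
exhausted spiral raises a search-failure error.  The exact spiral geometry
of the real instrument is unspecified; only the staged structure is
asserted (recovery within one grid step on a unimodal landscape).

## Windowed statistics (`preprocess`)

Pixels are grouped into 7×7 windows; per frame and window the spatial mean
and **unbiased** (n−1) variance are stored — 2 values per 49 pixels, a
24.5-fold reduction.  The unbiased divisor is a documented choice (the
source methodology does not state one); with 49 samples the difference is
2%, which the shot-noise term would otherwise absorb incorrectly.  Edge
pixels beyond the largest 7-divisible region are discarded because partial
windows have different sampling statistics.  Missed frames are re-aligned
to the nominal camera-period grid by timestamp, inserted as invalid
markers, never interpolated, and excluded from all downstream averages;
more than 10% missing frames is a hard error.  Dark stacks provide the
per-pixel temporal mean (subtracted from every frame) and the windowed
mean of the per-pixel temporal variance used by the read-noise term.

## Noise-corrected contrast (`contrast`)

The decomposition subtracts, per window, shot noise `G/⟨I⟩`, read noise
`(⟨σ²_dark⟩ − 1/12)/⟨I⟩²`, quantization `(1/12)/⟨I⟩²`, and spatial
heterogeneity (windowed contrast of the per-source temporal-mean image).
Windows with non-positive mean are invalid and excluded from weighting.
Per-window values are combined with weights ∝ ⟨I⟩², normalized over valid
windows.  By default the weights come from the per-source *mean image*
(stable, no noise-induced weight jitter); per-frame weighting is available
as an option — the weighting timing is ambiguous in the source methodology
and both interpretations are implemented.  Negative per-window corrected
values are retained in the weighted sum (they are unbiased under zero-mean
noise); a channel-frame is missing only if the aggregate is non-positive.

ΔOD uses the natural logarithm (fixed by the `e^−ΔOD` convention of the
methodology).  rDB − 1 = K_f,0²/K_f² − 1 with K_f,0² the **arithmetic**
temporal mean of K_f² over the baseline interval; note that with this
definition the baseline mean of rDB − 1 is zero only to O(cv²) (Jensen), a
property of the definition, not of the implementation.  Baseline defaults:
whole run for I₀; for runs with a task, the pre-task rest interval for
K_f,0² (a baseline before activation); block averaging additionally
re-references each epoch to its −2..0 s pre-stimulus mean.

The photon-transfer-curve fit is inverse-variance weighted least squares of
mean windowless per-pixel temporal variance vs dark-subtracted mean over a
flux ladder (≥8 levels, log-spaced); levels with >1% clipped pixels are
excluded, fewer than 3 usable levels is a calibration error.  The intercept
is read-plus-quantization variance.  Quantization contributes 1/12 ADU²
only for a *dithered* (continuous) pre-quantization signal; with zero read
noise and integer gain the quantizer is a no-op, and with fractional gain
the rounding residual correlates with the signal so the floor is only of
order 1/12.  Tests assert this true behavior.

### Known small-sample property

The plain ratio estimator `σ̂²/⟨I⟩²` over 49-pixel windows carries an
intrinsic O(1/49) small-sample bias — ≈ −0.4% relative on pure speckle at
β = 0.16 (denominator Jensen inflation minus the numerator–denominator
covariance through the speckle third moment), and an additional positive
contribution from the noise-term ratios below ~4 ADU mean counts (the same
nonlinearity that motivates the 4-DU channel-pruning rule).  The estimator
is implemented exactly as the methodology prints it, with no debiasing; the
acceptance tests validate the noise correction against a second-order
delta-method expectation of the windowed estimator, which isolates what the
correction claims to remove from what 49-sample statistics can ever give.

## Channel-space analysis (`analysis`)

Order of operations for task data: channel pruning (mean dark-subtracted
counts < 4 ADU), motion-block masking, short-separation regression on the
continuous series, zero-phase 5th-order Butterworth low-pass at 0.2 Hz,
block averaging −2..38 s with per-epoch baseline shift, then group
statistics.  Zero-phase (forward–backward) filtering is chosen because the
10–15 s significance window depends on response timing and the methodology
does not specify phase handling.  An optional second, epoch-level
short-separation pass exists but is off by default (the source describes
regression both on continuous and block-averaged signals; neither intent is
guessed).

Motion detection is an automated stand-in for a manual procedure: blocks
whose high-pass (>0.5 Hz) amplitude exceeds 5 robust (MAD) z-scores in any
channel are masked; a manual mask always takes precedence; subjects with
>50% masked blocks are flagged excluded.  With few blocks the MAD scale is
itself noisy, so occasional false masks occur — acceptable for a
conservative artifact screen.

PCA common-mode regression (for phantom runs): within the channels sharing
one source, principal components whose loading coefficient of variation
across channels is < 1 are projected out.  Groups of fewer than two
channels are untouched.

Group statistics: weighted mean over subjects with weights ∝ valid blocks
(normalized); SE is the unweighted sample SD across subjects / √n; a
channel is significant when its weighted 10–15 s window mean exceeds
1.96·SE — a one-sided rule, as the criterion is "mean activation greater
than 1.96 standard errors" — and a two-tailed one-sample t-test supplies
p-values.  The weighted mean is used in the significance rule, consistent
with the averaging convention.

### Synthetic cohort

`simulate_cohort` generates block-averaged epochs directly at the channel
level: 15 subjects, 50 channels, 18 blocks with ~17% random loss (mirroring
motion pruning), a canonical trapezoidal response whose 10–15 s window mean
equals the subject amplitude, amplitudes drawn independently per planted
channel from N(3.5, 5.03²) percent — calibrated to a 3.5 ± 1.3% group
effect at n = 15 — and white measurement noise attenuated by the block
count.  Independence of amplitudes across channels represents
channel-specific coupling/partial-volume variability.  At this calibration
the per-channel detection power of the 1.96·SE rule is the noncentral-t
value ≈ 0.77 — a property of the effect size, not of the pipeline — so
cohort validation asserts (i) replicate-level detection of the planted
activation ≥ 90%, (ii) per-channel false-positive rate ≤ 5%, and (iii)
agreement of the measured per-channel sensitivity with the closed-form
power.  The cohort generator does not model serial correlation of
physiological noise, channel covariance, or motion artifacts surviving the
mask, so passing it demonstrates the statistics machinery, not robustness
to structured real-world noise.  The frame-level path is validated
separately by one end-to-end reduced run (simulate → preprocess →
contrast → analyze) with planted flow and absorption responses.

## Image reconstruction (`recon`)

`x = Aᵀ(AAᵀ + λI)⁻¹y` with λ = α·b, α = 0.05, and b the largest eigenvalue
of AAᵀ (symmetric eigensolver); the SPD system is solved by Cholesky
factorization, matching a dense ridge oracle to 1e-8.  Missing channels and
zero-sensitivity rows are dropped jointly from A and y; b is recomputed
from the retained rows and stored with the image.  ΔOD images use the same
operator and α.  Channel data are not variance-weighted before inversion.

The toy sensitivity matrix is explicitly *not* photon transport: each
channel's row is a product of Gaussians centered on source and detector
(hence peaking laterally at the midpoint) times a depth Gaussian centered
at separation/2.5, on a 2 mm vertex lattice over a flat slab (0–24 mm
deep), rows scaled by separation.  Only topology is asserted: midpoint
peak, deeper sampling for larger separations, negligible overlap of
distant channels, and <10 mm point-perturbation localization inside the
array footprint.  Vertices with column mass below 5% of the maximum are
outside the field of view and localization there is flagged, not scored.

## Numerical choices and problem sizes

Validation simulations are sized for single-CPU runs: static-contrast
recovery uses 10⁴ windows per flux level (Monte Carlo SE ≈ 0.3–0.8% of β),
dynamic-field runs use 2.5–5×10³ windows with sub-step counts ≥ 10·x so
discretization error in K² stays below half a percent, and the cohort
Monte Carlo uses 200 replicates.  Random draws are `numpy.random.Generator`
streams fully determined by explicit seeds; identical seeds give
bit-identical frame stacks.

## Known limitations

- No absorption-dependent correction of the contrast or the sensitivity
  matrix (a higher-order effect, negligible for few-percent absorption
  changes).
- No GLM/HRF regression, no g2(τ) estimation, no Monte Carlo photon
  transport, no hardware control — all out of scope.
- The canonical probe layout is *a* solution consistent with the published
  footprint, spacings, and channel-class counts (28/22); the true optode
  assignment of the physical cap may differ in detail.
- The simulator treats frames as independent exposures and speckle pixels
  as spatially uncorrelated; real speckle has finite spatial grain
  (speckle-to-pixel size ratio effects fold into β here).
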