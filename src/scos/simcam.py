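"""Synthetic speckle camera: ground-truth dynamics plus a realistic noise chain.

This module generates multi-source speckle frame stacks with *known*
fundamental contrast so that every downstream stage (windowing, noise
correction, flow-index estimation, channel statistics) can be validated
without hardware.  The instrument emulated is a temporally multiplexed,
fiber-based SCOS system: one laser steered by a galvanometer across 7 source
fibers (10 ms per slot, 5.2 ms illumination), detector fiber bundles imaged
onto 10-bit CMOS cameras (black level 25 ADU, read noise ~2.1 e-).

Two speckle generators are provided:

``gamma``
    Per-pixel intensities are drawn i.i.d. from a Gamma distribution whose
    spatial contrast equals the closed-form exposure-integrated speckle
    contrast.  Fast; the default for pipeline and end-to-end tests.

``field``
    N weighted complex-Gaussian speckle modes evolve as a first-order
    autoregressive process with field correlation exp(-dt/tau_c); intensity
    is integrated over the exposure in sub-steps.  This is the physical gold
    standard used in the contrast-recovery tests.

Both feed the same camera noise chain: Poisson photoelectrons, analog gain,
Gaussian read noise, black-level offset, rounding quantization, and clipping
to the bit depth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "CameraSpec",
    "SpeckleGroundTruth",
    "MultiplexSchedule",
    "FrameStack",
    "SimScenario",
    "GalvoSearchError",
    "expected_contrast",
    "expected_contrast_discrete",
    "beta_from_sp",
    "sp_from_contrast",
    "simulate_frames",
    "simulate_dark_frames",
    "galvo_search",
    "smooth_heterogeneity",
    "activation_waveform",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CameraSpec:
    """Camera model parameters.

    Parameters
    ----------
    gain_G : float
        Conversion gain in ADU per photoelectron.  This is the quantity G of
        the shot-noise contrast correction; analog gain settings expressed in
        dB are camera-specific and must be converted by the caller.
    black_level : float
        ADU offset added to every pixel.
    bit_depth : int
        Digitizer resolution; full scale is ``2**bit_depth - 1`` ADU.
    read_noise_e : float or ndarray
        RMS read noise in electrons, scalar or per-pixel map.
    """

    gain_G: float = 0.5
    black_level: float = 25.0
    bit_depth: int = 10
    read_noise_e: float | np.ndarray = 2.1

    def __post_init__(self) -> None:
        if self.gain_G <= 0:
            raise ValueError("gain_G must be positive")
        if self.bit_depth not in (8, 10, 12, 16):
            raise ValueError("bit_depth must be one of 8, 10, 12, 16")
        if self.black_level < 0:
            raise ValueError("black_level must be non-negative")
        if np.any(np.asarray(self.read_noise_e) < 0):
            raise ValueError("read_noise_e must be non-negative")

    @property
    def saturation(self) -> int:
        """Full-scale ADU value."""
        return 2 ** self.bit_depth - 1

    def to_dict(self) -> dict:
        rn = self.read_noise_e
        return {
            "gain_G": self.gain_G,
            "black_level": self.black_level,
            "bit_depth": self.bit_depth,
            "read_noise_e": rn.tolist() if isinstance(rn, np.ndarray) else rn,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CameraSpec":
        rn = d["read_noise_e"]
        if isinstance(rn, list):
            rn = np.asarray(rn)
        return cls(gain_G=d["gain_G"], black_level=d["black_level"],
                   bit_depth=int(d["bit_depth"]), read_noise_e=rn)


@dataclass(frozen=True)
class SpeckleGroundTruth:
    """Ground-truth optical state of one source-detector channel.

    ``beta`` is the coherence parameter (maximum attainable contrast
    squared); ``sp_ratio`` the polarization amplitude ratio fixing beta
    through the unpolarized-light relation; ``tau_c`` the speckle
    decorrelation time in seconds (``inf`` for a static scene); ``mean_flux``
    the mean photoelectrons per pixel per exposure.
    """

    beta: float | None = None
    sp_ratio: float | None = None
    tau_c: float = math.inf
    mean_flux: float = 50.0
    heterogeneity_rms: float = 0.05

    def __post_init__(self) -> None:
        beta, sp = self.beta, self.sp_ratio
        if beta is None and sp is None:
            raise ValueError("specify beta or sp_ratio")
        if beta is None:
            object.__setattr__(self, "beta", beta_from_sp(sp))
        elif sp is None:
            object.__setattr__(self, "sp_ratio", sp_from_contrast(beta))
        else:
            if abs(beta - beta_from_sp(sp)) > 1e-9:
                raise ValueError("beta and sp_ratio are inconsistent")
        if not (0 < self.beta <= 0.5):
            raise ValueError("beta must lie in (0, 0.5]")
        if self.sp_ratio < 0:
            raise ValueError("sp_ratio must be non-negative")
        if self.tau_c <= 0:
            raise ValueError("tau_c must be positive")
        if self.mean_flux <= 0:
            raise ValueError("mean_flux must be positive")


@dataclass(frozen=True)
class MultiplexSchedule:
    """Temporal multiplexing of one laser over several source fibers.

    The instrument default is 7 sources, a 10 ms galvanometer slot with
    5.2 ms illumination, a 4 ms camera exposure, and a 100 Hz camera rate,
    giving a 5.2/70 = 7.4% per-source duty cycle and a 14.3 Hz full-array
    rate.
    """

    n_sources: int = 7
    slot_ms: float = 10.0
    on_ms: float = 5.2
    exposure_ms: float = 4.0
    camera_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        if self.on_ms > self.slot_ms:
            raise ValueError("on_ms cannot exceed slot_ms")
        if self.exposure_ms > self.on_ms:
            raise ValueError("exposure_ms cannot exceed on_ms")
        if self.n_sources < 1:
            raise ValueError("need at least one source")

    @property
    def duty_cycle(self) -> float:
        """Per-source illumination duty cycle, on_ms / (n_sources * slot_ms)."""
        return self.on_ms / (self.n_sources * self.slot_ms)

    @property
    def full_array_rate_hz(self) -> float:
        """Rate at which the full source cycle repeats."""
        return self.camera_rate_hz / self.n_sources

    def average_power(self, peak_power: float) -> float:
        """Time-averaged optical power per source for a given peak power."""
        return peak_power * self.duty_cycle

    @property
    def exposure_s(self) -> float:
        return self.exposure_ms * 1e-3


@dataclass
class FrameStack:
    """A stack of camera frames with acquisition metadata.

    ``frames`` is (time, rows, cols); integer ADU straight off the simulated
    camera, or float after dark subtraction.  ``valid`` marks frames that
    were actually acquired (missed frames repaired into the nominal grid are
    present but invalid).
    """

    frames: np.ndarray
    timestamps: np.ndarray
    source_ids: np.ndarray
    exposure_s: float
    camera: CameraSpec
    valid: np.ndarray | None = None
    saturated: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.source_ids = np.asarray(self.source_ids, dtype=int)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (time, rows, cols)")
        n = self.frames.shape[0]
        if len(self.timestamps) != n or len(self.source_ids) != n:
            raise ValueError("metadata length mismatch")
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def copy(self) -> "FrameStack":
        return FrameStack(self.frames.copy(), self.timestamps.copy(),
                          self.source_ids.copy(), self.exposure_s,
                          self.camera, self.valid.copy(), self.saturated)


Timecourse = Callable[[np.ndarray], np.ndarray]


@dataclass
class SimScenario:
    """Everything that determines a simulated acquisition for one detector.

    ``ground_truth`` maps source index -> SpeckleGroundTruth (a single value
    applies to all sources).  ``flow_timecourse`` multiplies tau_c over time
    (values < 1 mean faster dynamics, i.e. higher flow); ``absorption_timecourse``
    multiplies the photon flux (drives optical-density changes).  Both may be
    per-source mappings.  ``seed`` fully determines the output.
    """

    ground_truth: SpeckleGroundTruth | Mapping[int, SpeckleGroundTruth]
    flow_timecourse: Timecourse | Mapping[int, Timecourse] | None = None
    absorption_timecourse: Timecourse | Mapping[int, Timecourse] | None = None
    seed: int = 0

    def gt_for(self, source: int) -> SpeckleGroundTruth:
        if isinstance(self.ground_truth, SpeckleGroundTruth):
            return self.ground_truth
        return self.ground_truth[source]

    @staticmethod
    def _mod(tc, source: int, t: np.ndarray) -> np.ndarray:
        if tc is None:
            return np.ones_like(t)
        if callable(tc):
            out = np.asarray(tc(t), dtype=float)
        else:
            f = tc.get(source)
            out = np.ones_like(t) if f is None else np.asarray(f(t), dtype=float)
        if np.any(out <= 0):
            raise ValueError("timecourse modulations must be positive")
        return out

    def tau_mod(self, source: int, t: np.ndarray) -> np.ndarray:
        return self._mod(self.flow_timecourse, source, t)

    def flux_mod(self, source: int, t: np.ndarray) -> np.ndarray:
        return self._mod(self.absorption_timecourse, source, t)


# --------------------------------------------------------------------------
# closed-form contrast model and polarization calibration
# --------------------------------------------------------------------------

def expected_contrast(beta, x):
    """Exposure-integrated speckle contrast squared.

    For a single-exponential field correlation g1(t) = exp(-t/tau_c) the
    spatial contrast squared of an exposure-integrated speckle pattern is

        K^2(x) = beta * (exp(-2x) - 1 + 2x) / (2 x^2),   x = T / tau_c.

    Monotonically decreasing in x; tends to ``beta`` as x -> 0 and to
    ``beta/x`` for x >> 1.
    """
    beta = np.asarray(beta, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(beta <= 0) or np.any(x <= 0):
        raise ValueError("beta and x must be positive")
    # expm1 keeps the numerator accurate at small x where e^-2x - 1 + 2x ~ 2x^2
    out = beta * (np.expm1(-2.0 * x) + 2.0 * x) / (2.0 * x * x)
    return out if out.ndim else float(out)

def expected_contrast_discrete(beta: float, x: float, n_sub: int) -> float:
    """Contrast squared of a rectangle-rule exposure integral with n_sub steps.

    The autoregressive field generator integrates intensity as a finite sum;
    this is the exact second-moment expectation of that sum, used as the
    oracle for recovery tests so that discretization is not mistaken for
    estimator bias.  Converges to :func:`expected_contrast` as n_sub grows.
    """
    if n_sub < 1:
        raise ValueError("n_sub must be >= 1")
    if x == 0 or math.isinf(x) is False and x < 0:
        raise ValueError("x must be positive")
    rho = math.exp(-2.0 * x / n_sub)
    d = np.arange(1, n_sub)
    s = n_sub + 2.0 * np.sum((n_sub - d) * rho ** d)
    return beta * s / n_sub ** 2


def beta_from_sp(sp_ratio: float) -> float:
    """Coherence parameter from the polarization ratio (unpolarized light).

    beta = (s/p)^2 / (2 (1 + (s/p)^2)); beta lies in [0, 0.5).
    """
    sp = float(sp_ratio)
    if sp < 0:
        raise ValueError("sp_ratio must be non-negative")
    return sp * sp / (2.0 * (1.0 + sp * sp))


def sp_from_contrast(kf2_static: float) -> float:
    """Polarization ratio from static-scene fundamental contrast.

    s/p = sqrt(2 K^2 / (1 - 2 K^2)); exact inverse of :func:`beta_from_sp`
    on [0, 0.5).
    """
    k = float(kf2_static)
    if k < 0 or k >= 0.5:
        raise ValueError("static contrast must lie in [0, 0.5) for unpolarized light")
    return math.sqrt(2.0 * k / (1.0 - 2.0 * k))


def _mode_weights(beta: float) -> np.ndarray:
    """Power weights of independent speckle modes realizing contrast beta.

    A sum of independent fully-developed speckle intensities with powers w_m
    has short-exposure contrast sum(w^2)/sum(w)^2.  Using M-1 unit modes plus
    one fractional mode of power a solves this exactly for any beta in
    (0, 0.5] (and down to arbitrarily small beta).
    """
    if not 0 < beta <= 1:
        raise ValueError("beta must lie in (0, 1]")
    m = math.ceil(1.0 / beta) - 1  # number of unit-power modes
    if m == 0:
        return np.array([1.0])
    disc = beta * beta * m * m - (1.0 - beta) * m * (1.0 - beta * m)
    a = (beta * m - math.sqrt(max(disc, 0.0))) / (1.0 - beta)
    weights = np.ones(m + 1)
    weights[-1] = a
    return weights


# --------------------------------------------------------------------------
# heterogeneity and waveform helpers
# --------------------------------------------------------------------------

def smooth_heterogeneity(shape: tuple[int, int], rms: float = 0.05,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Smooth multiplicative illumination map with unit mean and given RMS.

    A low-order 2-D polynomial surface emulating the residual non-uniformity
    of defocused fiber-bundle illumination on the sensor.
    """
    if rms < 0:
        raise ValueError("rms must be non-negative")
    if rms == 0:
        return np.ones(shape)
    rng = np.random.default_rng(0) if rng is None else rng
    r, c = shape
    y = np.linspace(-1, 1, r)[:, None]
    x = np.linspace(-1, 1, c)[None, :]
    basis = [y, x, y * x, y * y - 1 / 3, x * x - 1 / 3, y * y * x, x * x * y]
    coef = rng.standard_normal(len(basis))
    surf = sum(co * b for co, b in zip(coef, basis))
    surf -= surf.mean()
    s = surf.std()
    if s > 0:
        surf *= rms / s
    return np.clip(1.0 + surf, 0.05, None)


def activation_waveform(t: np.ndarray, onset_ramp: float = 5.0,
                        plateau_end: float = 18.0, fall: float = 7.0) -> np.ndarray:
    """Canonical task-response shape, 0 before onset, ~1 over the 10-15 s window.

    Piecewise-smooth trapezoid: cosine rise over ``onset_ramp`` seconds,
    plateau at 1 until ``plateau_end``, cosine fall over ``fall`` seconds.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    rise = (t >= 0) & (t < onset_ramp)
    out[rise] = 0.5 * (1 - np.cos(np.pi * t[rise] / onset_ramp))
    out[(t >= onset_ramp) & (t <= plateau_end)] = 1.0
    dec = (t > plateau_end) & (t < plateau_end + fall)
    out[dec] = 0.5 * (1 + np.cos(np.pi * (t[dec] - plateau_end) / fall))
    return out


# --------------------------------------------------------------------------
# frame simulation
# --------------------------------------------------------------------------

def _field_intensity(rng: np.random.Generator, n_frames: int, n_px: int,
                     x: float, weights: np.ndarray, n_sub: int) -> np.ndarray:
    """Unit-mean exposure-integrated intensity of weighted AR(1) speckle modes.

    Each mode is an independent complex circular-Gaussian field per pixel,
    evolving with field correlation exp(-dt/tau_c) between sub-steps; the
    returned (n_frames, n_px) intensity is the rectangle-rule average of
    |E|^2 over the exposure.  Frames are independent realizations (exposures
    are far shorter than the inter-frame gap relative to tau_c).  For a
    static scene (x = 0) a single sample per frame is drawn.
    """
    n_modes = len(weights)
    shape = (n_frames, n_modes, n_px)

    def _cplx():
        return (rng.standard_normal(shape) +
                1j * rng.standard_normal(shape)) / np.sqrt(2.0)

    e = _cplx()
    if x == 0:
        acc = np.abs(e) ** 2
    else:
        rho = math.exp(-x / n_sub)  # field correlation between sub-steps
        sig = math.sqrt(1.0 - rho * rho)
        acc = np.abs(e) ** 2
        for _ in range(n_sub - 1):
            e *= rho
            e += sig * _cplx()
            acc += np.abs(e) ** 2
        acc /= n_sub
    return (acc * weights[None, :, None]).sum(axis=1) / weights.sum()


def _camera_chain(rng: np.random.Generator, photoelectrons: np.ndarray,
                  camera: CameraSpec) -> np.ndarray:
    """Poisson shot noise -> gain -> read noise -> black level -> quantize/clip."""
    n_e = rng.poisson(photoelectrons).astype(float)
    read = np.asarray(camera.read_noise_e) * rng.standard_normal(photoelectrons.shape)
    adu = camera.black_level + camera.gain_G * (n_e + read)
    return np.clip(np.round(adu), 0, camera.saturation)


def simulate_frames(scenario: SimScenario, schedule: MultiplexSchedule,
                    camera: CameraSpec, shape: tuple[int, int],
                    duration: float, method: str = "gamma",
                    n_sub: int | None = None) -> FrameStack:
    """Simulate a multiplexed speckle acquisition for one detector camera.

    Frames are generated at ``schedule.camera_rate_hz`` with the source index
    cycling deterministically; each frame's speckle statistics follow the
    scenario's per-source ground truth, with tau_c and flux modulated by the
    scenario time courses.  Output is quantized ADU clipped to the camera bit
    depth; the stack is flagged ``saturated`` if any frame's expected signal
    level reaches 90% of full scale.

    ``method`` selects the speckle generator ("gamma" fast / "field"
    physical); ``n_sub`` overrides the number of exposure sub-steps of the
    field method (default: enough that discretization error in K^2 is well
    below a percent, at least 20).
    """
    if method not in ("gamma", "field"):
        raise ValueError("method must be 'gamma' or 'field'")
    rng = np.random.default_rng(scenario.seed)
    dt = 1.0 / schedule.camera_rate_hz
    n_frames = int(round(duration / dt))
    times = np.arange(n_frames) * dt
    source_ids = np.arange(n_frames) % schedule.n_sources
    n_px = shape[0] * shape[1]
    frames = np.empty((n_frames, shape[0], shape[1]), dtype=np.uint16)
    saturated = False
    t_exp = schedule.exposure_s

    # per-source precomputation
    per_source = {}
    for s in range(schedule.n_sources):
        gt = scenario.gt_for(s)
        het = smooth_heterogeneity(shape, gt.heterogeneity_rms,
                                   np.random.default_rng(scenario.seed + 7 * s + 1))
        idx = np.nonzero(source_ids == s)[0]
        tau = gt.tau_c * scenario.tau_mod(s, times[idx])
        flux = gt.mean_flux * scenario.flux_mod(s, times[idx])
        per_source[s] = (gt, het.ravel(), idx, tau, flux)

    for s in range(schedule.n_sources):
        gt, het, idx, tau, flux = per_source[s]
        weights = _mode_weights(gt.beta) if method == "field" else None
        xs = np.where(np.isinf(tau), 0.0, t_exp / tau)
        if method == "gamma":
            for k, fi in enumerate(idx):
                x = xs[k]
                k2 = gt.beta if x == 0 else expected_contrast(gt.beta, x)
                inten = rng.gamma(1.0 / k2, k2 * flux[k] * het)
                if camera.black_level + camera.gain_G * inten.max() \
                        > 0.9 * camera.saturation:
                    saturated = True
                frames[fi] = _camera_chain(rng, inten, camera).reshape(shape)
        else:
            # batch frames sharing the same decorrelation ratio x
            for x in np.unique(xs):
                grp = idx[xs == x]
                ns = n_sub if n_sub is not None else max(20, int(math.ceil(10 * x)))
                chunk = max(1, int(2e7 // (len(weights) * n_px)))
                for lo in range(0, len(grp), chunk):
                    sub = grp[lo:lo + chunk]
                    pos = np.searchsorted(idx, sub)
                    inten = flux[pos, None] * het[None, :] * _field_intensity(
                        rng, len(sub), n_px, x, weights, ns)
                    if camera.black_level + camera.gain_G * inten.max() \
                            > 0.9 * camera.saturation:
                        saturated = True
                    frames[sub] = _camera_chain(rng, inten, camera).reshape(
                        (len(sub),) + shape)

    if saturated:
        warnings.warn("simulated signal approaches camera saturation", RuntimeWarning)
    return FrameStack(frames, times, source_ids, t_exp, camera,
                      saturated=saturated)


def simulate_dark_frames(camera: CameraSpec, n: int, shape: tuple[int, int],
                         seed: int = 0) -> FrameStack:
    """Simulate laser-off frames: black level, read noise, and quantization only.

    Temporal mean per pixel is ~black_level; temporal variance is
    ~(gain_G * read_noise_e)^2 + 1/12 ADU^2.
    """
    rng = np.random.default_rng(seed)
    zero = np.zeros((n,) + tuple(shape))
    frames = _camera_chain(rng, zero, camera).astype(np.uint16)
    dt = 0.01
    return FrameStack(frames, np.arange(n) * dt, np.zeros(n, dtype=int),
                      4e-3, camera)


# --------------------------------------------------------------------------
# galvanometer coupling search
# --------------------------------------------------------------------------

class GalvoSearchError(RuntimeError):
    """Raised when the spiral stage never reaches the power threshold."""


def _argmax_first(values: Sequence[float]) -> int:
    """Index of the maximum, ties broken toward the earlier-scanned point."""
    arr = np.asarray(values)
    return int(np.argmax(arr))  # np.argmax returns the first maximum


def galvo_search(coupling_landscape: Callable[[float, float], float],
                 start: tuple[float, float], threshold: float,
                 spiral_step: float = 5.0, spiral_max_radius: float = 500.0,
                 line_half: float = 20.0, line_step: float = 5.0,
                 grid_size: float = 40.0, grid_step: float = 5.0,
                 max_line_rounds: int = 50) -> tuple[float, float]:
    """Locate the fiber-coupling optimum on a 2-D efficiency landscape.

    Three stages mirror the instrument's alignment protocol: (1) a spiral
    radiating outward from ``start`` until the measured power first exceeds
    ``threshold``; (2) alternating +-``line_half`` um line scans along x then
    y, moving to the peak of each scan, repeated until neither axis improves;
    (3) a final ``grid_size`` x ``grid_size`` um grid refinement around the
    best point.  Raises :class:`GalvoSearchError` if the spiral exhausts
    ``spiral_max_radius`` without reaching the threshold.
    """
    x0, y0 = float(start[0]), float(start[1])

    # stage 1: outward Archimedean spiral, ~spiral_step arc length per sample
    found = None
    if coupling_landscape(x0, y0) >= threshold:
        found = (x0, y0)
    else:
        b = spiral_step / (2.0 * math.pi)  # r = b * theta
        theta = 0.0
        while True:
            r = b * theta
            if r > spiral_max_radius:
                raise GalvoSearchError(
                    f"threshold {threshold} not reached within "
                    f"{spiral_max_radius} um spiral radius")
            x = x0 + r * math.cos(theta)
            y = y0 + r * math.sin(theta)
            if coupling_landscape(x, y) >= threshold:
                found = (x, y)
                break
            theta += spiral_step / max(r, spiral_step)

    # stage 2: alternating line scans until no improvement on either axis
    cx, cy = found
    offsets = np.arange(-line_half, line_half + 0.5 * line_step, line_step)
    for _ in range(max_line_rounds):
        moved = False
        xs = cx + offsets
        best = _argmax_first([coupling_landscape(x, cy) for x in xs])
        if xs[best] != cx:
            cx, moved = float(xs[best]), True
        ys = cy + offsets
        best = _argmax_first([coupling_landscape(cx, y) for y in ys])
        if ys[best] != cy:
            cy, moved = float(ys[best]), True
        if not moved:
            break

    # stage 3: square grid refinement
    g = np.arange(-grid_size / 2, grid_size / 2 + 0.5 * grid_step, grid_step)
    pts = [(cx + dx, cy + dy) for dy in g for dx in g]
    best = _argmax_first([coupling_landscape(px, py) for px, py in pts])
    return pts[best]
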