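"""Noise-corrected fundamental contrast, optical density, and flow index.

The raw windowed contrast squared K_raw^2 = var/mean^2 of a dark-subtracted
speckle frame mixes the tissue-dynamics signal with camera noise.  The
correction subtracts, window by window, the contrast contributed by shot
noise (G/<I>), read noise ((<sigma_dark^2> - 1/12)/<I>^2), quantization
noise ((1/12)/<I>^2), and static spatial heterogeneity of the illumination
(windowed contrast of the per-source temporal-mean image):

    K_f^2 = K_raw^2 - K_s^2 - K_r^2 - K_q^2 - K_sp^2

Window values are combined into one per-frame K_f^2 with weights
proportional to <I_window>^2, so photon-rich windows dominate.  From the
channel time series follow the optical-density change dOD = -ln(I/I0) and
the fractional blood-flow-index change rDB - 1 = K_f0^2 / K_f^2 - 1 relative
to a baseline interval.

Camera gain and read noise enter the corrections; they are calibrated from
a photon transfer curve (temporal variance vs mean over a flux ladder).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import DarkStats, WindowStats
from .simcam import CameraSpec, FrameStack, MultiplexSchedule

__all__ = ["ContrastComponents", "ChannelSeries", "GainCalibration",
           "contrast_components", "weighted_kf2", "demultiplex",
           "frame_intensity", "delta_od", "rdb_minus_one",
           "estimate_gain_ptc"]

QUANT_VAR = 1.0 / 12.0  # ADU^2 variance of round-to-nearest quantization


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class ContrastComponents:
    """Per-frame, per-window contrast-squared decomposition (all dimensionless)."""

    k_raw2: np.ndarray
    k_s2: np.ndarray
    k_r2: np.ndarray
    k_q2: np.ndarray
    k_sp2: np.ndarray
    k_f2_window: np.ndarray
    valid: np.ndarray           # (n_frames, n_windows) usable windows


@dataclass
class ChannelSeries:
    """Per-channel time courses at the full-array rate.

    ``values`` is (n_channels, n_time); ``kind`` is one of ``kf2``,
    ``intensity``, ``delta_od``, ``rdb_minus_one``.  Missing samples are NaN.
    """

    time: np.ndarray
    values: np.ndarray
    channel_ids: list
    kind: str
    rate_hz: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.time):
            raise ValueError("values and time length mismatch")
        if len(self.channel_ids) != self.values.shape[0]:
            raise ValueError("channel_ids length mismatch")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def baseline_slice(self, baseline: tuple[float, float] | None) -> np.ndarray:
        if baseline is None:
            return np.ones(len(self.time), dtype=bool)
        t0, t1 = baseline
        return (self.time >= t0) & (self.time < t1)

    def with_values(self, values: np.ndarray, kind: str | None = None
                    ) -> "ChannelSeries":
        return ChannelSeries(self.time.copy(), values, list(self.channel_ids),
                             kind or self.kind, self.rate_hz)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, channel, kind, value) DataFrame."""
        n_c, n_t = self.values.shape
        return pd.DataFrame({
            "time": np.tile(self.time, n_c),
            "channel": np.repeat([str(c) for c in self.channel_ids], n_t),
            "kind": self.kind,
            "value": self.values.ravel(),
        })


# --------------------------------------------------------------------------
# contrast decomposition
# --------------------------------------------------------------------------

def contrast_components(ws: WindowStats, dark: DarkStats, camera: CameraSpec,
                        include_sp: bool = True) -> ContrastComponents:
    """Decompose windowed contrast into signal and noise terms.

    ``ws`` must come from dark-subtracted frames and carry
    ``mean_image_stats`` (unless ``include_sp`` is False, appropriate for
    static scenes where the temporal mean image *is* the speckle pattern and
    would wrongly absorb the signal).  Windows with non-positive mean
    intensity are flagged invalid and excluded from weighting.
    """
    if dark.window_size != ws.window_size:
        raise ValueError("dark and signal window grids differ")
    mean = ws.mean
    var = ws.var
    valid = (mean > 0) & ws.valid[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        m2 = mean ** 2
        k_raw2 = np.where(valid, var / m2, np.nan)
        k_s2 = np.where(valid, camera.gain_G / mean, np.nan)
        k_r2 = np.where(valid, (dark.windowed_dark_tvar[None, :] - QUANT_VAR) / m2,
                        np.nan)
        k_q2 = np.where(valid, QUANT_VAR / m2, np.nan)
    if include_sp:
        if ws.mean_image_stats is None:
            raise ValueError("mean_image_stats required for the spatial-"
                             "heterogeneity term; set include_sp=False for "
                             "static scenes")
        mis = ws.mean_image_stats
        src_row = np.searchsorted(mis.sources, ws.source_ids)
        with np.errstate(divide="ignore", invalid="ignore"):
            k_sp2_src = mis.var / mis.mean ** 2
        k_sp2 = np.where(valid, k_sp2_src[src_row], np.nan)
    else:
        k_sp2 = np.where(valid, 0.0, np.nan)
    k_f2 = k_raw2 - k_s2 - k_r2 - k_q2 - k_sp2
    return ContrastComponents(k_raw2, k_s2, k_r2, k_q2, k_sp2, k_f2, valid)


def weighted_kf2(components: ContrastComponents, ws: WindowStats,
                 weighting: str = "mean_image") -> np.ndarray:
    """Intensity-squared-weighted fundamental contrast per frame.

    Window weights are <I_window>^2 normalized over the valid windows of the
    frame.  ``weighting="mean_image"`` (default) takes the intensities from
    the per-source temporal-mean image, which keeps the weights free of
    frame-to-frame noise; ``"per_frame"`` uses each frame's own window means.
    Negative per-window corrected values are retained in the sum (they are
    unbiased under zero-mean noise); a frame with no valid windows, or whose
    aggregate comes out non-positive, is returned as NaN.
    """
    if weighting not in ("mean_image", "per_frame"):
        raise ValueError("weighting must be 'mean_image' or 'per_frame'")
    if weighting == "mean_image":
        if ws.mean_image_stats is None:
            raise ValueError("mean_image_stats required for mean-image weighting")
        mis = ws.mean_image_stats
        src_row = np.searchsorted(mis.sources, ws.source_ids)
        base = mis.mean[src_row]
    else:
        base = ws.mean
    w = np.where(components.valid, base ** 2, 0.0)
    norm = w.sum(axis=1)
    kf2 = np.full(ws.mean.shape[0], np.nan)
    ok = norm > 0
    num = np.nansum(w * np.where(components.valid, components.k_f2_window, 0.0),
                    axis=1)
    kf2[ok] = num[ok] / norm[ok]
    kf2[kf2 <= 0] = np.nan
    return kf2


def frame_intensity(ws: WindowStats) -> np.ndarray:
    """Mean dark-subtracted intensity per frame (ADU), NaN for invalid frames."""
    out = ws.mean.mean(axis=1)
    out[~ws.valid] = np.nan
    return out


def demultiplex(per_frame: np.ndarray, ws: WindowStats,
                schedule: MultiplexSchedule, kind: str,
                detector: int | None = None) -> ChannelSeries:
    """Split a per-frame quantity into per-source channels at the array rate.

    Frames are grouped into complete source cycles; channel ids are
    ``(source, detector)`` tuples when a detector index is given, else the
    source index.  The time axis is the cycle start time.
    """
    n = schedule.n_sources
    n_cyc = len(per_frame) // n
    vals = np.full((n, n_cyc), np.nan)
    for cyc in range(n_cyc):
        sl = slice(cyc * n, (cyc + 1) * n)
        vals[ws.source_ids[sl], cyc] = per_frame[sl]
    time = ws.timestamps[np.arange(n_cyc) * n]
    ids = [(int(s), int(detector)) if detector is not None else int(s)
           for s in range(n)]
    return ChannelSeries(time, vals, ids, kind, schedule.full_array_rate_hz)


# --------------------------------------------------------------------------
# derived series
# --------------------------------------------------------------------------

def delta_od(intensity: ChannelSeries,
             baseline: tuple[float, float] | None = None) -> ChannelSeries:
    """Optical-density change -ln(I/I0).

    I0 is the per-channel mean intensity over ``baseline`` (whole run if
    None, matching a continuous-measurement reference).
    """
    if intensity.kind != "intensity":
        raise ValueError("expected an intensity series")
    sel = intensity.baseline_slice(baseline)
    i0 = np.nanmean(intensity.values[:, sel], axis=1, keepdims=True)
    if np.any(~np.isfinite(i0)) or np.any(i0 <= 0):
        raise ValueError("baseline intensity must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = -np.log(intensity.values / i0)
    return intensity.with_values(vals, "delta_od")


def rdb_minus_one(kf2: ChannelSeries,
                  baseline: tuple[float, float] | None = None) -> ChannelSeries:
    """Fractional blood-flow-index change (K_f0^2 / K_f^2) - 1.

    The reciprocal fundamental contrast squared is proportional to the
    apparent diffusion coefficient of the scatterers in the fast-dynamics
    regime; normalizing by the baseline interval mean K_f0^2 yields the
    relative flow index.  Non-positive contrast samples propagate as NaN.
    """
    if kf2.kind != "kf2":
        raise ValueError("expected a kf2 series")
    sel = kf2.baseline_slice(baseline)
    kf0 = np.nanmean(kf2.values[:, sel], axis=1, keepdims=True)
    vals = np.where(kf2.values > 0, kf0 / kf2.values - 1.0, np.nan)
    return kf2.with_values(vals, "rdb_minus_one")


# --------------------------------------------------------------------------
# photon transfer curve
# --------------------------------------------------------------------------

@dataclass
class GainCalibration:
    """Result of a photon-transfer-curve fit."""

    gain_adu_per_e: float
    intercept_adu2: float        # read + quantization variance, ADU^2
    level_mean: np.ndarray
    level_var: np.ndarray
    level_used: np.ndarray

    @property
    def read_var_adu2(self) -> float:
        return self.intercept_adu2 - QUANT_VAR


def estimate_gain_ptc(stacks: Sequence[FrameStack], dark: DarkStats,
                      max_clip_fraction: float = 0.01) -> GainCalibration:
    """Fit camera gain and read noise from a flux ladder.

    For uniform illumination at several flux levels the per-pixel temporal
    variance is linear in the dark-subtracted mean: slope G (ADU/e-),
    intercept the read-plus-quantization variance.  Levels where more than
    ``max_clip_fraction`` of samples sit at full scale are excluded
    (clipping bends the curve down).  The fit is inverse-variance weighted
    least squares, the variance of a level's sample variance scaling as
    2 sigma^4 / (n_frames - 1) per pixel.
    """
    means, vars_, used, wts = [], [], [], []
    for st in stacks:
        frames = st.frames[st.valid].astype(float)
        n, r, c = frames.shape
        clip_frac = np.mean(frames >= st.camera.saturation)
        mu = (frames - dark.mean_dark).mean(axis=0).mean()
        tv = frames.var(axis=0, ddof=1).mean()
        ok = clip_frac <= max_clip_fraction and n >= 2
        means.append(mu)
        vars_.append(tv)
        used.append(ok)
        wts.append(r * c * (n - 1) / (2.0 * max(tv, 1e-12) ** 2))
    means, vars_ = np.asarray(means), np.asarray(vars_)
    used, wts = np.asarray(used), np.asarray(wts)
    if used.sum() < 3:
        raise ValueError("fewer than 3 usable flux levels; cannot calibrate")
    # weighted least squares on the usable levels
    x, y, w = means[used], vars_[used], wts[used]
    coef = np.polyfit(x, y, 1, w=np.sqrt(w))
    if coef[0] <= 0:
        warnings.warn("non-positive fitted gain; check flux ladder", RuntimeWarning)
    return GainCalibration(float(coef[0]), float(coef[1]), means, vars_, used)
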