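"""Raw frame stacks -> windowed statistics.

The raw data rate of a multi-camera speckle system is prohibitive (terabytes
per session), so all downstream math consumes a reduced representation: the
spatial mean and unbiased variance of every 7x7 pixel window of every frame,
together with dark-frame statistics and per-source temporal-mean-image
statistics needed by the noise corrections.  Storing 2 values per 49 pixels
reduces data volume 24.5-fold.

Stages: missed-frame repair against the nominal multiplexing grid, dark
subtraction, windowing.  Missing frames are carried as invalid markers and
excluded - never interpolated - from every downstream average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .simcam import CameraSpec, FrameStack, MultiplexSchedule

__all__ = ["DarkStats", "WindowStats", "MeanImageStats", "RepairReport",
           "dark_stats", "repair_frames", "subtract_dark",
           "window_statistics", "per_source_baseline_images",
           "reduction_factor"]


def _window_grid(shape: tuple[int, int], window: int) -> tuple[int, int]:
    return shape[0] // window, shape[1] // window


def _windowed(frames: np.ndarray, window: int) -> np.ndarray:
    """View frames as (n, wr, wc, window*window), truncating edge pixels."""
    n, r, c = frames.shape
    wr, wc = r // window, c // window
    if wr == 0 or wc == 0:
        raise ValueError("frame smaller than one window")
    v = frames[:, :wr * window, :wc * window]
    v = v.reshape(n, wr, window, wc, window).swapaxes(2, 3)
    return v.reshape(n, wr, wc, window * window)


def reduction_factor(window: int = 7) -> float:
    """Stored-value reduction of the windowed representation (49 px -> 2 values)."""
    return window * window / 2.0


@dataclass
class DarkStats:
    """Dark-frame statistics on the same window grid as the signal data.

    ``mean_dark`` is the per-pixel temporal mean (subtracted from every
    frame); ``windowed_dark_tvar`` is the spatial mean, within each window,
    of the per-pixel temporal variance of the dark frames - the quantity
    entering the read-noise contrast correction.
    """

    mean_dark: np.ndarray
    windowed_dark_tvar: np.ndarray
    window_size: int = 7

    def __post_init__(self) -> None:
        if np.any(self.windowed_dark_tvar < 0):
            raise ValueError("dark temporal variance must be non-negative")


def dark_stats(stack: FrameStack, window: int = 7) -> DarkStats:
    """Compute dark statistics from a laser-off stack."""
    frames = stack.frames[stack.valid].astype(float)
    if len(frames) < 2:
        raise ValueError("need at least 2 dark frames")
    mean_dark = frames.mean(axis=0)
    tvar = frames.var(axis=0, ddof=1)
    wtv = _windowed(tvar[None], window)[0].mean(axis=-1).ravel()
    return DarkStats(mean_dark, wtv, window)


@dataclass
class MeanImageStats:
    """Per-source, per-window statistics of the temporal-mean image.

    For each source illumination the temporal mean of its frames is a static
    image whose windowed contrast estimates the spatial heterogeneity of the
    illumination (the K_sp^2 correction).
    """

    sources: np.ndarray          # (S,)
    mean: np.ndarray             # (S, n_windows) spatial window means
    var: np.ndarray              # (S, n_windows) unbiased spatial window variances
    n_frames: np.ndarray         # (S,) frames averaged per source


@dataclass
class WindowStats:
    """Windowed mean/variance per frame - the reduced data representation."""

    mean: np.ndarray             # (n_frames, n_windows) ADU
    var: np.ndarray              # (n_frames, n_windows) ADU^2, unbiased
    timestamps: np.ndarray
    source_ids: np.ndarray
    valid: np.ndarray
    window_size: int
    grid: tuple[int, int]
    exposure_s: float
    camera: CameraSpec | None = None
    mean_image_stats: MeanImageStats | None = None

    @property
    def n_windows(self) -> int:
        return self.mean.shape[1]


@dataclass
class RepairReport:
    """Slots inserted by missed-frame repair."""

    inserted_slots: list[int]
    n_nominal: int

    @property
    def missing_fraction(self) -> float:
        return len(self.inserted_slots) / max(self.n_nominal, 1)


def repair_frames(stack: FrameStack, schedule: MultiplexSchedule,
                  max_missing: float = 0.10) -> tuple[FrameStack, RepairReport]:
    """Re-align frames to the nominal acquisition grid using timestamps.

    Each frame is assigned to its nearest nominal slot (camera period
    ``1/camera_rate_hz`` from the first timestamp); slots with no frame are
    filled with invalid marker frames and the source index sequence is
    re-synchronized to the multiplexing cycle.  Gaps are never interpolated.
    Raises if timestamps are non-monotonic or more than ``max_missing`` of
    the nominal slots are empty.  Idempotent on an already-repaired stack.
    """
    ts = stack.timestamps
    if np.any(np.diff(ts) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    dt = 1.0 / schedule.camera_rate_hz
    slots = np.round((ts - ts[0]) / dt).astype(int)
    if np.any(np.diff(slots) < 1):
        raise ValueError("timestamps collide onto the same nominal slot")
    n_nominal = slots[-1] + 1
    missing = sorted(set(range(n_nominal)) - set(slots.tolist()))
    if len(missing) / n_nominal > max_missing:
        raise ValueError(
            f"{len(missing)}/{n_nominal} frames missing exceeds "
            f"{max_missing:.0%}; stack unusable")

    frames = np.zeros((n_nominal,) + stack.shape, dtype=stack.frames.dtype)
    valid = np.zeros(n_nominal, dtype=bool)
    frames[slots] = stack.frames
    valid[slots] = stack.valid
    timestamps = ts[0] + np.arange(n_nominal) * dt
    s0 = int(stack.source_ids[0])
    source_ids = (s0 + np.arange(n_nominal)) % schedule.n_sources
    repaired = FrameStack(frames, timestamps, source_ids, stack.exposure_s,
                          stack.camera, valid, stack.saturated)
    return repaired, RepairReport(missing, n_nominal)


def subtract_dark(stack: FrameStack, dark: DarkStats) -> FrameStack:
    """Subtract the temporal mean dark image from every frame (signed output)."""
    if dark.mean_dark.shape != stack.shape:
        raise ValueError(
            f"dark image shape {dark.mean_dark.shape} does not match "
            f"frames {stack.shape}")
    frames = stack.frames.astype(float) - dark.mean_dark
    return FrameStack(frames, stack.timestamps.copy(), stack.source_ids.copy(),
                      stack.exposure_s, stack.camera, stack.valid.copy(),
                      stack.saturated)


def window_statistics(stack: FrameStack, window: int = 7) -> WindowStats:
    """Spatial mean and unbiased variance of each window of each frame.

    Edge pixels beyond the largest window-divisible region are discarded;
    partial windows would carry different sampling statistics.
    """
    w = _windowed(stack.frames.astype(float), window)
    grid = w.shape[1:3]
    mean = w.mean(axis=-1).reshape(stack.n_frames, -1)
    var = w.var(axis=-1, ddof=1).reshape(stack.n_frames, -1)
    return WindowStats(mean, var, stack.timestamps.copy(),
                       stack.source_ids.copy(), stack.valid.copy(), window,
                       grid, stack.exposure_s, stack.camera)


def per_source_baseline_images(stack: FrameStack, window: int = 7
                               ) -> tuple[dict[int, np.ndarray], MeanImageStats]:
    """Temporal-mean image per source and its windowed spatial statistics.

    The mean image of a given source illumination averages away the dynamic
    speckle, leaving the static illumination profile; its windowed contrast
    is the spatial-heterogeneity correction term.  Invalid frames are
    excluded from the averages.
    """
    sources = np.unique(stack.source_ids)
    images: dict[int, np.ndarray] = {}
    means, vars_, counts = [], [], []
    for s in sources:
        sel = (stack.source_ids == s) & stack.valid
        if not np.any(sel):
            raise ValueError(f"no valid frames for source {s}")
        img = stack.frames[sel].astype(float).mean(axis=0)
        images[int(s)] = img
        w = _windowed(img[None], window)[0]
        means.append(w.mean(axis=-1).ravel())
        vars_.append(w.var(axis=-1, ddof=1).ravel())
        counts.append(int(sel.sum()))
    stats = MeanImageStats(sources.astype(int), np.asarray(means),
                           np.asarray(vars_), np.asarray(counts))
    return images, stats
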