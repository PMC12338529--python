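"""File formats: TIFF frame stacks with JSON sidecars, HDF5 intermediates.

Frame stacks travel as multi-page 16-bit TIFF plus a JSON sidecar carrying
timestamps, per-frame source indices, exposure, validity, and the camera
spec.  Windowed statistics, channel series, and sensitivity matrices use
HDF5; channel series can also be exported as tidy CSV; probe layouts as
JSON and channel tables as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .contrast import ChannelSeries
from .preprocess import MeanImageStats, WindowStats
from .recon import SensitivityMatrix
from .simcam import CameraSpec, FrameStack

__all__ = ["write_stack", "read_stack", "write_window_stats",
           "read_window_stats", "write_series", "read_series",
           "write_sensitivity", "read_sensitivity"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write frames as multi-page TIFF with a JSON metadata sidecar."""
    path = Path(path)
    frames = stack.frames
    if not np.issubdtype(frames.dtype, np.integer):
        raise ValueError("only integer ADU stacks are written as TIFF")
    tifffile.imwrite(path, frames.astype(np.uint16))
    meta = {
        "timestamps": stack.timestamps.tolist(),
        "source_ids": stack.source_ids.tolist(),
        "valid": stack.valid.astype(int).tolist(),
        "exposure_s": stack.exposure_s,
        "saturated": bool(stack.saturated),
        "camera": stack.camera.to_dict(),
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_stack(path: str | Path) -> FrameStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(_sidecar(path).read_text())
    return FrameStack(frames, np.asarray(meta["timestamps"]),
                      np.asarray(meta["source_ids"]),
                      meta["exposure_s"], CameraSpec.from_dict(meta["camera"]),
                      np.asarray(meta["valid"], dtype=bool),
                      meta.get("saturated", False))


def write_window_stats(ws: WindowStats, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f["mean"] = ws.mean
        f["var"] = ws.var
        f["timestamps"] = ws.timestamps
        f["source_ids"] = ws.source_ids
        f["valid"] = ws.valid.astype(np.uint8)
        f.attrs["window_size"] = ws.window_size
        f.attrs["grid"] = ws.grid
        f.attrs["exposure_s"] = ws.exposure_s
        if ws.camera is not None:
            f.attrs["camera"] = json.dumps(ws.camera.to_dict())
        if ws.mean_image_stats is not None:
            g = f.create_group("mean_image_stats")
            g["sources"] = ws.mean_image_stats.sources
            g["mean"] = ws.mean_image_stats.mean
            g["var"] = ws.mean_image_stats.var
            g["n_frames"] = ws.mean_image_stats.n_frames


def read_window_stats(path: str | Path) -> WindowStats:
    with h5py.File(path, "r") as f:
        camera = None
        if "camera" in f.attrs:
            camera = CameraSpec.from_dict(json.loads(f.attrs["camera"]))
        mis = None
        if "mean_image_stats" in f:
            g = f["mean_image_stats"]
            mis = MeanImageStats(g["sources"][()], g["mean"][()],
                                 g["var"][()], g["n_frames"][()])
        return WindowStats(f["mean"][()], f["var"][()], f["timestamps"][()],
                           f["source_ids"][()], f["valid"][()].astype(bool),
                           int(f.attrs["window_size"]),
                           tuple(int(v) for v in f.attrs["grid"]),
                           float(f.attrs["exposure_s"]), camera, mis)


def write_series(series: ChannelSeries, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        series.to_frame().to_csv(path, index=False)
        return
    with h5py.File(path, "w") as f:
        f["time"] = series.time
        f["values"] = series.values
        f["channel_ids"] = json.dumps(series.channel_ids)
        f.attrs["kind"] = series.kind
        f.attrs["rate_hz"] = series.rate_hz


def read_series(path: str | Path) -> ChannelSeries:
    with h5py.File(path, "r") as f:
        ids = json.loads(f["channel_ids"][()].decode()
                         if isinstance(f["channel_ids"][()], bytes)
                         else f["channel_ids"][()])
        ids = [tuple(c) if isinstance(c, list) else c for c in ids]
        return ChannelSeries(f["time"][()], f["values"][()], ids,
                             f.attrs["kind"], float(f.attrs["rate_hz"]))


def write_sensitivity(sens: SensitivityMatrix, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f["A"] = sens.A
        f["vertex_positions"] = sens.vertex_positions
        f["channel_ids"] = json.dumps([list(c) if isinstance(c, tuple) else c
                                       for c in sens.channel_ids])


def read_sensitivity(path: str | Path) -> SensitivityMatrix:
    with h5py.File(path, "r") as f:
        raw = f["channel_ids"][()]
        ids = json.loads(raw.decode() if isinstance(raw, bytes) else raw)
        ids = [tuple(c) if isinstance(c, list) else c for c in ids]
        return SensitivityMatrix(f["A"][()], f["vertex_positions"][()], ids)
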