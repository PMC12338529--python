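"""End-to-end orchestration: one config, one run directory, reproducible runs.

``run_pipeline`` ties the stages together on a simulated acquisition:
simulate (main detector + short-separation detector + dark stack) ->
preprocess (missed-frame repair, dark subtraction, windowing) -> contrast
(noise-corrected K_f^2, intensity, dOD, rDB-1) -> analyze (QC, short-
separation regression, low-pass, block average, window statistics) ->
reconstruct (toy sensitivity, Tikhonov).  Every effective parameter is
echoed into the run manifest and a machine-readable QC report is written.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import analysis, contrast, preprocess, probe, recon, simcam
from .io import write_series, write_stack

__all__ = ["RunConfig", "run_pipeline", "build_scenario", "demo_config"]


@dataclass
class RunConfig:
    """Serializable parameters of a full synthetic run.

    Defaults describe a reduced Stroop-like activation run: a 7-source
    multiplexed acquisition on one detector camera, flow (rDB-1) and
    absorption (dOD) responses planted in two source channels, a shared
    scalp oscillation removed later by short-separation regression.
    """

    seed: int = 1
    # acquisition
    duration_s: float = 160.0
    rows: int = 28
    cols: int = 28
    n_sources: int = 7
    slot_ms: float = 10.0
    on_ms: float = 5.2
    exposure_ms: float = 4.0
    camera_rate_hz: float = 100.0
    # camera
    gain_G: float = 0.5
    black_level: float = 25.0
    bit_depth: int = 10
    read_noise_e: float = 2.1
    # optics / dynamics
    beta: float = 0.16
    tau_c_s: float = 4.0e-4          # x = exposure/tau_c = 10 at 4 ms
    mean_flux: float = 80.0
    heterogeneity_rms: float = 0.05
    # planted activation
    planted_sources: tuple[int, ...] = (0, 1)
    rdb_amplitude: float = 0.40
    od_amplitude: float = 0.02
    scalp_rdb: float = 0.10
    scalp_od: float = 0.01
    scalp_freq_hz: float = 0.08
    # task design
    first_onset_s: float = 20.0
    block_period_s: float = 25.0
    n_blocks: int = 5
    stim_duration_s: float = 18.0
    epoch_start_s: float = -2.0
    epoch_end_s: float = 20.0
    # analysis
    window_px: int = 7
    prune_threshold: float = 4.0
    motion_z: float = 5.0
    lowpass_hz: float = 0.2
    lowpass_order: int = 5
    sig_window: tuple[float, float] = (10.0, 15.0)
    alpha: float = 0.05
    n_dark: int = 300

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["planted_sources"] = list(d["planted_sources"])
        d["sig_window"] = list(d["sig_window"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["planted_sources"] = tuple(d["planted_sources"])
        d["sig_window"] = tuple(d["sig_window"])
        return cls(**d)


def demo_config() -> RunConfig:
    """The bundled synthetic Stroop-like demo scenario."""
    return RunConfig()


def _response(cfg: RunConfig):
    onsets = cfg.first_onset_s + cfg.block_period_s * np.arange(cfg.n_blocks)

    def resp(t: np.ndarray) -> np.ndarray:
        out = np.zeros_like(t)
        for o in onsets:
            out += simcam.activation_waveform(t - o)
        return np.clip(out, 0.0, 1.0)

    return onsets, resp


def build_scenario(cfg: RunConfig):
    """Scenarios, schedule, and camera for the configured run."""
    schedule = simcam.MultiplexSchedule(cfg.n_sources, cfg.slot_ms, cfg.on_ms,
                                        cfg.exposure_ms, cfg.camera_rate_hz)
    camera = simcam.CameraSpec(cfg.gain_G, cfg.black_level, cfg.bit_depth,
                               cfg.read_noise_e)
    gt = simcam.SpeckleGroundTruth(beta=cfg.beta, tau_c=cfg.tau_c_s,
                                   mean_flux=cfg.mean_flux,
                                   heterogeneity_rms=cfg.heterogeneity_rms)
    onsets, resp = _response(cfg)

    def scalp_rdb(t):
        return cfg.scalp_rdb * np.sin(2 * np.pi * cfg.scalp_freq_hz * t)

    def scalp_od(t):
        return cfg.scalp_od * np.sin(2 * np.pi * cfg.scalp_freq_hz * t)

    def tau_mod_for(source):
        planted = source in cfg.planted_sources

        def tau_mod(t):
            r = cfg.rdb_amplitude * resp(t) if planted else 0.0
            return 1.0 / (1.0 + r + scalp_rdb(t))

        return tau_mod

    def flux_mod_for(source):
        planted = source in cfg.planted_sources

        def flux_mod(t):
            od = (cfg.od_amplitude * resp(t) if planted else 0.0) + scalp_od(t)
            return np.exp(-od)

        return flux_mod

    main = simcam.SimScenario(
        ground_truth=gt,
        flow_timecourse={s: tau_mod_for(s) for s in range(cfg.n_sources)},
        absorption_timecourse={s: flux_mod_for(s) for s in range(cfg.n_sources)},
        seed=cfg.seed)

    # short-separation camera: scalp signal only, sampled at the array rate
    short_schedule = simcam.MultiplexSchedule(
        1, cfg.slot_ms * cfg.n_sources, cfg.on_ms, cfg.exposure_ms,
        cfg.camera_rate_hz / cfg.n_sources)
    short = simcam.SimScenario(
        ground_truth=gt,
        flow_timecourse={0: lambda t: 1.0 / (1.0 + scalp_rdb(t))},
        absorption_timecourse={0: lambda t: np.exp(-scalp_od(t))},
        seed=cfg.seed + 1)
    design = analysis.BlockDesign(onsets, np.full(cfg.n_blocks,
                                                  cfg.stim_duration_s),
                                  np.array(["task"] * cfg.n_blocks),
                                  (cfg.epoch_start_s, cfg.epoch_end_s))
    return main, short, schedule, short_schedule, camera, design


def _stack_to_series(stack, schedule, dark, include_sp=True):
    ws = preprocess.window_statistics(stack)
    _, mis = preprocess.per_source_baseline_images(stack)
    ws.mean_image_stats = mis
    comp = contrast.contrast_components(ws, dark, stack.camera,
                                        include_sp=include_sp)
    kf2 = contrast.demultiplex(contrast.weighted_kf2(comp, ws), ws, schedule,
                               "kf2")
    inten = contrast.demultiplex(contrast.frame_intensity(ws), ws, schedule,
                                 "intensity")
    return ws, kf2, inten


def run_pipeline(cfg: RunConfig, outdir: str | Path,
                 write_frames: bool = False) -> dict:
    """Execute the full synthetic pipeline into one run directory.

    Returns a result dict (series, group result, image, QC report); writes
    a manifest echoing every parameter, stage outputs, and ``qc_report.json``.
    Deterministic given ``cfg.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "manifest.yaml")
    qc: dict = {}

    main, short, schedule, short_schedule, camera, design = build_scenario(cfg)

    # --- simulate ---------------------------------------------------------
    stage = outdir / "simulate"
    stage.mkdir(exist_ok=True)
    shape = (cfg.rows, cfg.cols)
    stack = simcam.simulate_frames(main, schedule, camera, shape,
                                   cfg.duration_s)
    short_stack = simcam.simulate_frames(short, short_schedule, camera, shape,
                                         cfg.duration_s)
    dark_stack = simcam.simulate_dark_frames(camera, cfg.n_dark, shape,
                                             seed=cfg.seed + 2)
    if write_frames:
        write_stack(stack, stage / "main.tiff")
        write_stack(short_stack, stage / "short.tiff")
        write_stack(dark_stack, stage / "dark.tiff")

    # --- preprocess -------------------------------------------------------
    dark = preprocess.dark_stats(dark_stack, cfg.window_px)
    stack, report = preprocess.repair_frames(stack, schedule)
    qc["frames_repaired"] = len(report.inserted_slots)
    stack = preprocess.subtract_dark(stack, dark)
    short_stack = preprocess.subtract_dark(short_stack, dark)

    # --- contrast ---------------------------------------------------------
    ws, kf2, inten = _stack_to_series(stack, schedule, dark)
    _, short_kf2, short_int = _stack_to_series(short_stack, short_schedule,
                                               dark)
    qc["windows_invalid"] = int(np.sum(ws.mean <= 0))
    # pre-task rest period anchors the flow-index baseline
    rest = (0.0, cfg.first_onset_s)
    rdb = contrast.rdb_minus_one(kf2, baseline=rest)
    dod = contrast.delta_od(inten)
    short_rdb = contrast.rdb_minus_one(short_kf2, baseline=rest)
    n = min(rdb.values.shape[1], short_rdb.values.shape[1])
    stage = outdir / "contrast"
    stage.mkdir(exist_ok=True)
    write_series(rdb, stage / "rdb.h5")
    write_series(dod, stage / "delta_od.h5")

    # --- analyze ----------------------------------------------------------
    prune = analysis.prune_low_flux(inten, cfg.prune_threshold)
    qc["channels_pruned"] = int(np.sum(~prune.keep))
    rdb_kept = analysis.ChannelSeries(
        rdb.time[:n], rdb.values[prune.keep, :n],
        [c for c, k in zip(rdb.channel_ids, prune.keep) if k],
        rdb.kind, rdb.rate_hz)
    motion = analysis.detect_motion_blocks(rdb_kept, design,
                                           z_threshold=cfg.motion_z)
    qc["blocks_masked"] = int(motion.block_mask.sum())
    qc["subject_excluded"] = motion.subject_excluded
    clean = analysis.short_sep_regress(rdb_kept, short_rdb.values[0, :n])
    clean = analysis.lowpass(clean, cfg.lowpass_hz, cfg.lowpass_order)
    epochs = analysis.block_average(clean, design, motion.block_mask)
    block_avgs = [epochs.epochs[:, b, :] for b in range(design.n_blocks)
                  if epochs.valid_blocks[b]]
    group = analysis.group_stats(block_avgs, [1] * len(block_avgs),
                                 epochs.time,
                                 channel_ids=rdb_kept.channel_ids,
                                 window=cfg.sig_window)
    stage = outdir / "analyze"
    stage.mkdir(exist_ok=True)
    group.to_frame().to_csv(stage / "channel_stats.csv", index=False)

    # --- reconstruct ------------------------------------------------------
    layout = probe.high_density_layout()
    sens = recon.toy_sensitivity(layout)
    y = np.full(sens.n_channels, np.nan)
    for i, cid in enumerate(sens.channel_ids):
        for c, wm in zip(group.channel_ids, group.window_mean):
            if cid == (c, 0) or cid == c:
                y[i] = wm
    image = None
    if np.any(np.isfinite(y)):
        image = recon.tikhonov_reconstruct(y, sens, cfg.alpha)
        stage = outdir / "recon"
        stage.mkdir(exist_ok=True)
        image.to_frame().to_csv(stage / "image.csv", index=False)

    (outdir / "qc_report.json").write_text(json.dumps(qc, indent=1))
    return {"rdb": rdb, "delta_od": dod, "group": group, "image": image,
            "qc": qc, "prune": prune, "motion": motion, "design": design}
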