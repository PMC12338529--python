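import numpy as np
import pytest

from scos import preprocess, simcam


@pytest.fixture(scope="session")
def camera():
    return simcam.CameraSpec()  # 0.5 ADU/e-, black 25, 10-bit, 2.1 e- read


@pytest.fixture(scope="session")
def schedule():
    return simcam.MultiplexSchedule()  # 7 sources, 10 ms slots, 100 Hz


@pytest.fixture(scope="session")
def single_source_schedule():
    """One source at the full-array rate (70 ms effective slot)."""
    return simcam.MultiplexSchedule(n_sources=1, slot_ms=70.0,
                                    camera_rate_hz=100.0 / 7.0)


@pytest.fixture(scope="session")
def dark35(camera):
    """Dark statistics for 35x35 frames, shared across recovery tests."""
    stack = simcam.simulate_dark_frames(camera, 800, (35, 35), seed=901)
    return preprocess.dark_stats(stack)


def corrected_kf2_windows(stack, dark, include_sp=False):
    """Full correction pipeline down to per-window fundamental contrast."""
    from scos import contrast
    sub = preprocess.subtract_dark(stack, dark)
    ws = preprocess.window_statistics(sub)
    if include_sp:
        _, ws.mean_image_stats = preprocess.per_source_baseline_images(sub)
    comp = contrast.contrast_components(ws, dark, stack.camera,
                                        include_sp=include_sp)
    return comp, ws


def mean_and_se(values):
    v = np.asarray(values)
    v = v[np.isfinite(v)]
    return v.mean(), v.std(ddof=1) / np.sqrt(v.size)
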