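from __future__ import annotations

import numpy as np
import pytest

from sonoreach.engine import TrialConfig, run_stream
from sonoreach.pose import Calibration, DEFAULT_BODYPARTS, PoseStream


@pytest.fixture
def calibration() -> Calibration:
    return Calibration()


@pytest.fixture
def trial_cfg() -> TrialConfig:
    return TrialConfig()


def stream_from_displacement(
    disp_left: np.ndarray,
    disp_right: np.ndarray | None = None,
    calibration: Calibration | None = None,
    fps: float = 70.0,
    likelihood: float = 0.99,
) -> PoseStream:
    """Build a pose stream whose paw displacements are exactly as given."""
    cal = calibration or Calibration()
    disp_left = np.asarray(disp_left, dtype=float)
    if disp_right is None:
        disp_right = np.zeros_like(disp_left)
    n = disp_left.size
    k = len(DEFAULT_BODYPARTS)
    x = np.zeros((n, k))
    y = np.empty((n, k))
    lik = np.full((n, k), likelihood)
    for j, name in enumerate(DEFAULT_BODYPARTS):
        if name.startswith("left"):
            y[:, j] = cal.rest_y_left - disp_left / cal.mm_per_pixel
        else:
            y[:, j] = cal.rest_y_right - disp_right / cal.mm_per_pixel
        x[:, j] = 10.0 * j
    return PoseStream(DEFAULT_BODYPARTS, x, y, lik, fps=fps)


def run_displacement(disp_left, cfg: TrialConfig | None = None, **kwargs):
    """Replay a displacement trace through the full closed loop."""
    cal = Calibration()
    stream = stream_from_displacement(disp_left, calibration=cal)
    return run_stream(stream, cal, cfg, **kwargs)
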