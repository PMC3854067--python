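import numpy as np
import pytest

from fmposthoc import (
    AcquisitionTiming,
    SimulationConfig,
    TimeLapseStack,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def default_experiment():
    """One default-scale simulated experiment shared across tests."""
    config = SimulationConfig(seed=11, n_boutons=60)
    return config, simulate_experiment(config)


@pytest.fixture(scope="session")
def clean_experiment():
    """Noise-free, background-free, sparse experiment for exactness checks."""
    config = SimulationConfig(
        seed=5,
        n_boutons=20,
        noise_model="none",
        background_level=0.0,
        background_gradient=0.0,
        bleach_rate_per_frame=0.0,
        channel_shift_px=(0, 0),
        min_separation_sigma=10.0,
    )
    return config, simulate_experiment(config)


def make_trace_stack(traces: dict[tuple[int, int], np.ndarray], shape=(16, 16),
                     baseline_value: float = 0.0, timing: AcquisitionTiming | None = None):
    """Build a stack whose listed pixels follow given per-frame traces.

    ``traces`` maps (row, col) -> 1-D per-frame values; all other pixels
    hold ``baseline_value`` in every frame.
    """
    n_frames = len(next(iter(traces.values())))
    frames = np.full((n_frames,) + shape, baseline_value, dtype=np.float64)
    for (r, c), tr in traces.items():
        frames[:, r, c] = tr
    return TimeLapseStack(frames, timing or AcquisitionTiming())
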