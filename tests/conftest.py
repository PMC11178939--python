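import numpy as np
import pytest

from flagwave import RunConfig, WaveParams, render_trace_set


@pytest.fixture
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def clean_wave_params() -> WaveParams:
    """Noiseless, short recording: 20 frames spanning exactly one 2 Hz cycle."""
    return WaveParams(
        kappa0=0.05,
        amp=0.10,
        freq_hz=2.0,
        fps=40.0,
        duration_s=0.5,
        noise_sigma_um=0.0,
        seed=7,
    )


@pytest.fixture
def noisy_trace_set():
    """Default-noise rendered recording of an asymmetric beat."""
    params = WaveParams(kappa0=0.05, amp=0.10, freq_hz=2.0, duration_s=1.0, seed=11)
    ts, gt = render_trace_set(
        params, flagellum_id="fx", genotype="WT", condition="pCa4"
    )
    return ts, gt


def circle_arc_points(radius: float, angle: float, n: int, theta0: float = 0.0,
                      center=(0.0, 0.0)) -> np.ndarray:
    """Dense points on a circular arc, head at angular position theta0."""
    t = theta0 + np.linspace(0.0, angle, n)
    return np.column_stack(
        [center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)]
    )
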