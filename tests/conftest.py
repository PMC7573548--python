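import numpy as np
import pytest

from lumirhythm import LuminescenceTrace, SimulationParams


@pytest.fixture
def time_72h() -> np.ndarray:
    """Standard recording design: 72 h sampled every 0.2 h (361 points)."""
    return np.arange(0.0, 72.0 + 1e-9, 0.2)


@pytest.fixture
def make_sine(time_72h):
    """Factory for noiseless sinusoid traces on the standard time axis."""

    def _make(period=24.0, amplitude=5.0, const=0.0, phase_h=0.0,
              well="W1", t=None):
        tt = time_72h if t is None else t
        y = const + amplitude * np.sin(2 * np.pi * (tt - phase_h) / period)
        return LuminescenceTrace(well, tt, y)

    return _make


def clean_params(**overrides) -> SimulationParams:
    """Deterministic oscillation with every noise source switched off."""
    defaults = dict(
        period_h=24.0, amplitude0=5.0, damping_per_h=0.0,
        baseline0=0.0, baseline_floor=0.0, noise_sd=0.0,
        phase_jitter_sd_h=0.0, phase_diffusion_sd_h_per_sqrt_h=0.0,
        duration_h=72.0, dt_h=0.2, seed=1,
    )
    defaults.update(overrides)
    return SimulationParams(**defaults)
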