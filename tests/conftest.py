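import pytest
from hypothesis import settings

from binimpute import SyntheticConfig, generate_heart_like

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_grid():
    """6 complete days at 10-min step (144 slots) with mild structure."""
    cfg = SyntheticConfig(n_days=6, step="10min", seed=11)
    grid, _ = generate_heart_like(cfg)
    return grid


@pytest.fixture
def quiet_grid():
    """Deterministic grid: every day equals the diurnal profile exactly."""
    cfg = SyntheticConfig(
        n_days=5,
        step="10min",
        seed=0,
        day_offset_sd=0.0,
        noise_sd=0.0,
        active_burst_amplitude=0.0,
    )
    grid, _ = generate_heart_like(cfg)
    return grid
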