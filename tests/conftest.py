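import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def arc_scene():
    """A single gently curved filament well separated from itself,
    spanning an 8 um field — the controlled geometry for localization
    oracles (no self-approach within the PSF range)."""
    from anetsr.synthetic_phantom import FilamentScene

    t = np.linspace(0.15, 0.85, 200)
    x = t * 8000.0
    y = 4000.0 + 1200.0 * np.sin(np.pi * (t - 0.15) / 0.7)
    return FilamentScene(curves=[np.column_stack([x, y])], field_nm=8000.0)
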