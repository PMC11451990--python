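import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def disk_mask(radius: int, pad: int = 5, label: int = 1) -> np.ndarray:
    """Filled disk label mask (single cell, no bud)."""
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[0:n, 0:n]
    c = radius + pad
    mask = np.zeros((n, n), dtype=np.int32)
    mask[(yy - c) ** 2 + (xx - c) ** 2 <= radius**2] = label
    return mask


@pytest.fixture
def disk20():
    return disk_mask(20)


@pytest.fixture
def small_sim():
    """A small, quick budded-cell simulation shared across tests."""
    from cmekymo.synthetic_movie import SimulationConfig, simulate

    cfg = SimulationConfig(seed=11, duration_s=60.0)
    return simulate(cfg)
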