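import numpy as np
import pytest

from rdisc import (
    DiscreteSpectrum,
    Peak,
    RamanSpectrum,
)


@pytest.fixture
def simple_spectrum() -> RamanSpectrum:
    """Three broad Gaussians on a 1024-channel grid, no noise, no baseline."""
    x = np.linspace(400.0, 3200.0, 1024)
    y = (
        1.0 * np.exp(-0.5 * ((x - 1000) / 30) ** 2)
        + 0.6 * np.exp(-0.5 * ((x - 1600) / 40) ** 2)
        + 0.8 * np.exp(-0.5 * ((x - 2900) / 25) ** 2)
    )
    return RamanSpectrum(x, y, {"cell_id": "smooth"})


def make_discrete(positions, intensities=None, n_source=2048) -> DiscreteSpectrum:
    positions = list(positions)
    if intensities is None:
        intensities = [1.0] * len(positions)
    return DiscreteSpectrum(
        [Peak(float(p), float(v), 0.01) for p, v in zip(positions, intensities)],
        n_source,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
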