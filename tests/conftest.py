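import numpy as np
import pytest

from porinflux import FES1D, TransportConfig, reference_to_bulk


def gaussian_profile(
    barrier: float = 3.0,
    wells: list[tuple[float, float]] | None = None,
    z_half: float = 25.0,
    n: int = 501,
    barrier_sigma: float = 3.0,
    well_sigma: float = 2.0,
    temperature: float = 300.0,
) -> FES1D:
    """Bulk-referenced profile: Gaussian barrier at z=0 plus optional wells,
    smoothly masked to exactly 0 over the outer 20% of the z range."""
    z = np.linspace(-z_half, z_half, n)
    F = barrier * np.exp(-(z**2) / (2 * barrier_sigma**2))
    for depth, zw in wells or []:
        F -= depth * np.exp(-((z - zw) ** 2) / (2 * well_sigma**2))
    t = np.clip((z_half - np.abs(z)) / (0.2 * z_half), 0, 1)
    mask = t * t * (3 - 2 * t)
    return reference_to_bulk(FES1D(z, F * mask, temperature=temperature))


@pytest.fixture
def flat_profile() -> FES1D:
    z = np.linspace(-20.0, 20.0, 401)
    return reference_to_bulk(FES1D(z, np.zeros_like(z)))


@pytest.fixture
def default_config() -> TransportConfig:
    return TransportConfig()


@pytest.fixture
def barrier_well_profile() -> FES1D:
    return gaussian_profile(barrier=3.0, wells=[(2.0, 5.0)])
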