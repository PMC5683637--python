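import numpy as np
import pytest

from virtualsdm import (
    EnvStack,
    GridSpec,
    NicheParams,
    Raster,
    VirtualSpecies,
    default_correlation,
    generate_env_stack,
    make_species,
    threshold_range,
)


@pytest.fixture(scope="session")
def small_stack() -> EnvStack:
    """50x50, 6-layer collinear stack shared by most tests."""
    return generate_env_stack(
        GridSpec(50, 50),
        6,
        target_correlation=default_correlation(6, 2),
        seed=7,
    )


@pytest.fixture(scope="session")
def niche_stack(small_stack) -> EnvStack:
    return small_stack.subset(small_stack.names[:4])


@pytest.fixture(scope="session")
def generalist(niche_stack) -> VirtualSpecies:
    return make_species(niche_stack, "generalist")


@pytest.fixture(scope="session")
def specialist(niche_stack) -> VirtualSpecies:
    return make_species(niche_stack, "specialist")


@pytest.fixture
def toy_species():
    """Factory building a species directly from a grid of suitabilities."""

    def build(values, threshold: float = 0.2) -> VirtualSpecies:
        values = np.asarray(values, dtype=float)
        spec = GridSpec(*values.shape)
        suitability = Raster(spec, values)
        params = NicheParams(sigma1=0.5, sigma2=0.5, threshold=threshold)
        return VirtualSpecies(
            params=params,
            suitability=suitability,
            true_range=threshold_range(suitability, threshold),
        )

    return build
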