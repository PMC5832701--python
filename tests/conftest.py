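import numpy as np
import pytest

from migrasim import FlightParams, SpeciesTraits, flight_range
from migrasim.synthetic import BlobSpec, SyntheticScenario


@pytest.fixture(scope="session")
def params() -> FlightParams:
    return FlightParams()


@pytest.fixture(scope="session")
def small_bird() -> SpeciesTraits:
    """A 20 g passerine-scale bird used across the suite."""
    return SpeciesTraits("test_passerine", 0.02, 0.25, 0.01)


@pytest.fixture(scope="session")
def small_bird_ranges(small_bird, params):
    """Pre-computed (initial, post-stopover) flight performances."""
    return (flight_range(small_bird, params.fat_fraction_initial, params),
            flight_range(small_bird, params.fat_fraction_stopover, params))


@pytest.fixture(scope="session")
def tiny_scenario() -> SyntheticScenario:
    """Small-window scenario keeping grids cheap for unit tests."""
    return SyntheticScenario(
        seed=7,
        n_species=4,
        lon_min=0.0, lon_max=16.0, lat_min=-5.0, lat_max=62.0,
        breeding=BlobSpec(8.0, 50.0, 200.0, 0.95, 1.0, 1.0),
        nonbreeding_long=BlobSpec(8.0, 5.0, 200.0, 0.95, 1.0, 1.0),
        nonbreeding_short=BlobSpec(8.0, 38.0, 200.0, 0.95, 1.0, 1.0),
        n_reps=200,
    )


def random_traits(rng: np.random.Generator, species_id: str = "rnd",
                  strategy: str = "long_distance") -> SpeciesTraits:
    """One random but physically plausible trait draw."""
    m = float(np.exp(rng.uniform(np.log(0.008), np.log(0.3))))
    b = float(1.05 * m ** 0.36 * np.exp(rng.normal(0, 0.06)))
    ar = float(np.clip(np.exp(rng.normal(np.log(7.0), 0.13)), 4.5, 12.0))
    return SpeciesTraits(species_id, m, b, b ** 2 / ar, strategy=strategy)
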