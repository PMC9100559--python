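import hypothesis
import pandas as pd
import pytest

from treerisk.synthetic import (
    ContaminationConfig,
    WorldConfig,
    generate_occurrences,
    generate_species,
    generate_world,
)

hypothesis.settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def world():
    """Default toy world: 14 biome bands, 12 countries, 70% land, 1 deg cells."""
    return generate_world(WorldConfig())


@pytest.fixture(scope="session")
def species(world):
    return generate_species(80, world=world, seed=11)


@pytest.fixture(scope="session")
def contaminated_dataset(world, species):
    """Occurrences with every error class injected, plus hidden truth."""
    occ, sidecar, counts = generate_occurrences(species, world, ContaminationConfig(seed=7))
    return occ, sidecar, counts


@pytest.fixture(scope="session")
def clean_dataset(world, species):
    """Occurrences with no injected errors."""
    occ, sidecar, counts = generate_occurrences(species, world, ContaminationConfig.none(seed=13))
    return occ, sidecar, counts


def make_records(rows):
    """Occurrence table from (species, lon, lat, unc, basis) tuples."""
    return pd.DataFrame(
        [
            {
                "record_id": f"r{i}",
                "species": sp,
                "decimalLatitude": lat,
                "decimalLongitude": lon,
                "coordinateUncertaintyInMeters": unc,
                "basisOfRecord": basis,
            }
            for i, (sp, lon, lat, unc, basis) in enumerate(rows)
        ]
    )


@pytest.fixture
def records_factory():
    return make_records
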