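import pytest

from nutrisupply import WorldConfig, analyze_world, generate_world


@pytest.fixture(scope="session")
def small_config():
    """A quick 8-country world used by unit tests."""
    return WorldConfig(
        n_countries=8,
        n_species=40,
        taxonomy_shape={"class": 2, "order": 4, "family": 8, "genus": 14},
        grid_cells_per_country=12,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)


@pytest.fixture(scope="session")
def small_results(small_world):
    return analyze_world(small_world)
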