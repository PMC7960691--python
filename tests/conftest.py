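import pytest

import hearburden as hb


@pytest.fixture(scope="session")
def small_world() -> hb.WorldConfig:
    return hb.WorldConfig(n_regions=2, locations_per_region=2, years=(1990, 2019))


@pytest.fixture(scope="session")
def truth(small_world) -> hb.EpidemicTruth:
    return hb.make_truth(small_world, seed=11)


@pytest.fixture(scope="session")
def population(truth):
    return hb.make_population(truth, seed=12)


@pytest.fixture(scope="session")
def records(truth):
    return hb.simulate_microdata(truth, n_per_stratum=2000, seed=13)


@pytest.fixture(scope="session")
def tiny_config() -> hb.RunConfig:
    return hb.RunConfig(
        world=hb.WorldConfig(n_regions=2, locations_per_region=2, years=(1990, 2000, 2019)),
        seed=7,
        draws=100,
        n_per_stratum=300,
        forecast_resamples=50,
    )


@pytest.fixture(scope="session")
def tiny_result(tiny_config) -> hb.PipelineResult:
    """One full desk-scale pipeline run shared across tests."""
    return hb.run_pipeline(tiny_config)
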