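import pytest

from bactarget import pipeline, synthdata


@pytest.fixture(scope="session")
def study():
    """One full simulated study at the default desk scale (50 kb, 50x, 10 mutants)."""
    return pipeline.run_simulated_study(pipeline.RunConfig(seed=1))


@pytest.fixture(scope="session")
def genome():
    return synthdata.build_genome(seed=11)


@pytest.fixture()
def fixture_records():
    return synthdata.make_difference_fixture()
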