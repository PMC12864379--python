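import pytest

from esbastats import counts_to_long, table4_fixture, fit_proportional
from esbastats.ordinal import ModelSpec


@pytest.fixture(scope="session")
def fixture_tables():
    return table4_fixture()


@pytest.fixture(scope="session")
def fixture_long(fixture_tables):
    """The 255 phase-level rows reconstructed from the count fixture."""
    return counts_to_long(list(fixture_tables))


@pytest.fixture(scope="session")
def final_model_spec():
    return ModelSpec(("Phase", "Init.Rating"))


@pytest.fixture(scope="session")
def final_fit(fixture_long, final_model_spec):
    """The two-predictor proportional-odds fit on the reconstructed data."""
    return fit_proportional(final_model_spec, fixture_long)
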