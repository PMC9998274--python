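import numpy as np
import pytest

from pollinet import nullmodels, pipeline, synth


@pytest.fixture(scope="session")
def mech_system():
    """One default-scale mechanistic study system shared across tests."""
    config = synth.GeneratorConfig(seed=11)
    records, attributes = synth.generate_mechanistic_system(config)
    return config, records, attributes


@pytest.fixture(scope="session")
def mech_records(mech_system):
    return mech_system[1]


@pytest.fixture(scope="session")
def reference_pool(mech_records):
    return nullmodels.build_reference_pool(mech_records)


@pytest.fixture(scope="session")
def design_table(mech_system):
    _, records, attributes = mech_system
    return pipeline.build_design(records, attributes, n_restarts=8, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
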