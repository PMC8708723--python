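import numpy as np
import pytest

from regnet.simulate import SimConfig, simulate_annotation


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def annotation(sim_config):
    """One deterministic synthetic genome/TSS/cCRE landscape for the session."""
    return simulate_annotation(sim_config, np.random.default_rng(0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, sim_config):
    """A full synthetic dataset written to disk once per session."""
    from regnet.simulate import write_dataset

    out = tmp_path_factory.mktemp("dataset")
    paths = write_dataset(sim_config, out)
    return paths
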