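import pytest

from discqc import io as qio
from discqc.synthetic import SimulationConfig


@pytest.fixture(scope="session")
def table3_records():
    """The packaged reference cohort: 28 AF + 28 NP scored samples."""
    return qio.load_table3()


@pytest.fixture(scope="session")
def table5_profiles():
    """The packaged unknown-sample marker call table: 16 profiles."""
    return qio.load_table5()


@pytest.fixture(scope="session")
def small_sim_config():
    """A reduced simulation for fast per-module tests."""
    return SimulationConfig(
        seed=7, n_genes=200, n_af_up=10, n_np_up=6, n_af_chips=5, n_np_chips=4,
        probes_per_set=7,
    )
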