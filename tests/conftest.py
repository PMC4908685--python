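import pytest

from l1asp.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition synthetic cohort shared across tests."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_written(sim_default, tmp_path_factory):
    """The same cohort written to disk once."""
    out = tmp_path_factory.mktemp("sim") / "cohort"
    sim_default.write(out)
    return out
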