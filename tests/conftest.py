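import pytest

from poolsex.simulate import SimConfig, simulate

#: desk-scale config for fast unit/CLI tests (study-condition rates kept,
#: genome shrunk); acceptance tests use the full default config.
SMALL_SIM = SimConfig(
    genome=(("sim1", 600_000),),
    sdr_start=250_000,
    sdr_length=66_000,
    n_divergent_sites=100,
    y_insertion_length=55_000,
)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(SMALL_SIM, seed=7)


@pytest.fixture(scope="session")
def default_sim():
    """One full-scale simulation under the default study conditions."""
    return simulate(SimConfig(), seed=1)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, small_sim):
    """Small simulation written to disk once for CLI/IO tests."""
    out = tmp_path_factory.mktemp("simout")
    small_sim.write(out)
    return out
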