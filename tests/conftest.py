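import pytest

from metstab.blup import fit_all_experiments
from metstab.simulate import SimConfig, simulate_trial


@pytest.fixture(scope="session")
def default_sim():
    """Default 23-genotype, 15-environment, 3-block simulation (seed 1)."""
    config = SimConfig(seed=1)
    records, weather, truth = simulate_trial(config)
    return config, records, weather, truth


@pytest.fixture(scope="session")
def eps_fits_seed1(default_sim):
    """Per-experiment REML fits for flowering duration and grain weight."""
    config, records, _, _ = default_sim
    return fit_all_experiments(records, ["days_ef", "gw_mg"], config.genotypes)
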