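import pytest

from mhcloci.pipeline import RunConfig, run_pipeline
from mhcloci.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def sim42():
    """One simulated dataset at the default study conditions."""
    return simulate(SimConfig(seed=42))


@pytest.fixture(scope="session")
def summary42(sim42):
    """Full pipeline summary for the seed-42 dataset."""
    return run_pipeline(sim42.clones, RunConfig(seed=42, n_bootstrap=300))
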