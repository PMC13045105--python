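import warnings

import pytest

from afepi import simulate as sim
from afepi.pipeline import PipelineConfig, run_all

warnings.filterwarnings("ignore", category=RuntimeWarning,
                        message=".*near-singular DMR covariance.*")


@pytest.fixture(scope="session")
def study():
    """One simulated toy study at the reference conditions (seed 7)."""
    return sim.simulate_study(sim.SimConfig(seed=7))


@pytest.fixture(scope="session")
def pipeline_results():
    """Full end-to-end pipeline results on the seed-7 study."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_all(PipelineConfig(seed=7))
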