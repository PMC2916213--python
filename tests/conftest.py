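import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, max_examples=50)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def arisa_study():
    """One full synthetic ARISA study run end to end (seed 0)."""
    from icefp.config import RunConfig
    from icefp.study import run_synthetic_study

    return run_synthetic_study(RunConfig(assay="ARISA", seed=0),
                               run_simprof=False)


@pytest.fixture(scope="session")
def trflp_study():
    """One full synthetic T-RFLP study run end to end (seed 0)."""
    from icefp.config import RunConfig
    from icefp.study import run_synthetic_study

    return run_synthetic_study(RunConfig(assay="TRFLP", seed=0),
                               run_simprof=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
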