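import numpy as np
import pytest

import sifibci as sb


@pytest.fixture(scope="session")
def ref_params() -> sb.ModelParams:
    """Group-mean observer parameters used as generating truth throughout."""
    return sb.default_observer_params()


@pytest.fixture(scope="session")
def small_cohort() -> list[sb.ObserverDataset]:
    """Two synthetic observers over the full 200-trial design."""
    design = sb.build_design(seed=3)
    return sb.generate_cohort(sb.CohortSpec(n_observers=2, master_seed=3), design)


@pytest.fixture(scope="session")
def quick_fit_config() -> sb.FitConfig:
    """Cheap fit settings for smoke-level fitting tests."""
    return sb.FitConfig(n_mc=2000, restarts=2, seed=17, maxfev=150)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
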