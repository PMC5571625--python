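import numpy as np
import pytest

from toricpred.cohort import CohortConfig, generate_cohort
from toricpred.io import cohort_records
from toricpred.pipeline import run_study


@pytest.fixture(scope="session")
def noise_free_cfg():
    return CohortConfig(seed=20, n_eyes=24).noise_free()


@pytest.fixture(scope="session")
def noise_free_cohort(noise_free_cfg):
    return generate_cohort(noise_free_cfg)


@pytest.fixture(scope="session")
def noise_free_results(noise_free_cfg, noise_free_cohort):
    cohort, _ = noise_free_cohort
    return run_study(cohort_records(cohort), noise_free_cfg.analysis_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
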