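import numpy as np
import pandas as pd
import pytest

from ppsbound import GeneratorParams, StimulusConfig, simulate_cohort


@pytest.fixture(scope="session")
def cfg() -> StimulusConfig:
    return StimulusConfig()


@pytest.fixture(scope="session")
def noiseless_params() -> GeneratorParams:
    return GeneratorParams(sd_trial=0.0, sd_between=0.0, sd_pse_between=0.0, miss_rate=0.0)


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_params) -> pd.DataFrame:
    return simulate_cohort(noiseless_params.replace(n_subjects=3), seed=7)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Default-noise cohort, few subjects, for pipeline-level tests."""
    return simulate_cohort(GeneratorParams(n_subjects=6), seed=11)
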