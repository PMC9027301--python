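import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from ecistools import SyntheticConfig, simulate_experiment
from ecistools.io import RunConfig
from ecistools.pipeline import run_pipeline

#: One seed for every stochastic fixture in the suite.
SUITE_SEED = 1234


@pytest.fixture(scope="session")
def experiment():
    """Default synthetic dose-response experiment (noisy, seeded)."""
    return simulate_experiment(SyntheticConfig(), seed=SUITE_SEED)


@pytest.fixture(scope="session")
def noiseless_config():
    """Generator configuration with every noise source switched off."""
    return SyntheticConfig(noise_fraction=0.0, well_variability=0.0,
                           drift_per_h=0.0, ocr_noise_sd=0.0,
                           seed=SUITE_SEED)


@pytest.fixture(scope="session")
def pipeline_summary(tmp_path_factory):
    """One full pipeline run (simulate -> deconvolve -> analyze), shared."""
    out = tmp_path_factory.mktemp("pipeline_run")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(RunConfig(seed=SUITE_SEED, outdir=str(out)))
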