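import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_methylome():
    """One small fully simulated library shared by read-based tests."""
    from temeth.experiments import demo_config, run_methylome_experiment

    cfg = demo_config(1, genome_length=60_000, n_genes=8, coverage=30.0,
                      lambda_length=10_000)
    return run_methylome_experiment(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
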