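import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """One modest synthetic dataset shared across tests (noise-free)."""
    from dwdkit.synthetic import SimConfig, generate_dataset

    outdir = tmp_path_factory.mktemp("simdata")
    cfg = SimConfig(seed=4242, n_wd40_per_species=60)
    return generate_dataset(cfg, outdir)
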