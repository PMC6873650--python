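import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tevkit.synthetic_data import SimulationConfig, write_fixture_bundle

settings.register_profile(
    "tevkit", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("tevkit")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down study used by fast structural tests (the calibration
    tests build their own cohorts at the sizes they need)."""
    return SimulationConfig(
        n_samples=60, n_alu=40, n_l1=10, n_sva=8, n_genes=40,
        chrom_sizes={"chr1": 9_000_000, "chr2": 6_000_000},
        n_planted=3, n_transcribed=8, n_false_calls=6, seed=11)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(small_config, str(out), overwrite=True)
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
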