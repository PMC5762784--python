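from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import mirprof as m

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_reference() -> m.MatureReference:
    return m.generate_reference(50, seed=1)


@pytest.fixture(scope="session")
def mini_config() -> m.SimConfig:
    """Desk-scale-but-small experiment shared by integration tests."""
    return m.SimConfig(n_mirnas=100, reads_per_library=20_000, seed=3)


@pytest.fixture(scope="session")
def mini_experiment(tmp_path_factory, mini_config):
    ref = m.generate_reference(mini_config.n_mirnas, mini_config.length_weights,
                               seed=mini_config.seed)
    outdir = tmp_path_factory.mktemp("mini_experiment")
    result = m.generate_experiment(ref, mini_config, outdir)
    return ref, mini_config, result


def make_read(read_id: str, bases: str, quality: int = 35) -> m.SmallRNARead:
    return m.SmallRNARead(read_id=read_id, bases=bases,
                          qual=chr(quality + 33) * len(bases))
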