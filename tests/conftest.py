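import numpy as np
import pytest

from dyadsynch.synthetic_data import GeneratorConfig, simulate_chain_session


def fast_generator_config(**overrides) -> GeneratorConfig:
    """Structurally faithful config at reduced signal scale for quick tests."""
    base = dict(
        sampling_rate=50.0,
        fau_rate=20.0,
        fixation_s=1.0,
        cue_s=3.0,
        expectancy_s=2.0,
        iti1_range=(2.0, 3.0),
        post_heat_s=2.0,
        rating_s=2.0,
        iti2_s=3.0,
        tail_s=5.0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def fast_cfg() -> GeneratorConfig:
    return fast_generator_config()


@pytest.fixture(scope="session")
def tiny_session(fast_cfg):
    return simulate_chain_session(fast_cfg, 42, session_id="S042")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
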