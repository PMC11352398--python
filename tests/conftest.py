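import dataclasses

import numpy as np
import pytest

from serpbci import ProtocolConfig, generate_session, train_bci
from serpbci.synthdata import NoiseModel, default_templates


@pytest.fixture(scope="session")
def config() -> ProtocolConfig:
    return ProtocolConfig()


@pytest.fixture(scope="session")
def small_config() -> ProtocolConfig:
    """Reduced protocol (6 blocks, 4 trials) for fast plumbing tests."""
    return ProtocolConfig(
        n_training_blocks=6, blocks_per_task=3,
        n_test_trials=4, trials_per_target=2,
    )


@pytest.fixture(scope="session")
def quiet_noise() -> NoiseModel:
    """Low-amplitude background, no injected artifacts."""
    return NoiseModel(background_std=1.0, blink_rate=0.0, drift_rate=0.0,
                      seed=11)


@pytest.fixture(scope="session")
def default_session(config):
    """One full synthetic session at protocol defaults (seed 7)."""
    return generate_session(config, noise=NoiseModel(seed=7))


@pytest.fixture(scope="session")
def trained_default(config, default_session):
    trained, report = train_bci(default_session.signal,
                                default_session.events, config)
    return trained, report


@pytest.fixture(scope="session")
def small_session(small_config, quiet_noise):
    tpl = default_templates(small_config, attention_gain=3.0)
    return generate_session(small_config, templates=tpl, noise=quiet_noise)


def replace(cfg: ProtocolConfig, **kw) -> ProtocolConfig:
    return dataclasses.replace(cfg, **kw)
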