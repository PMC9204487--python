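import numpy as np
import pytest

from mmgesture.synth import ImpairmentProfile, SynthConfig, generate_trial


@pytest.fixture(scope="session")
def default_cfg() -> SynthConfig:
    return SynthConfig(seed=12345)


@pytest.fixture(scope="session")
def trial(default_cfg):
    """One default synthetic trial (12 movements, 116 s)."""
    return generate_trial(default_cfg, trial_id=0)


@pytest.fixture(scope="session")
def five_trials(default_cfg):
    """A full unimpaired subject: 5 trials."""
    return [generate_trial(default_cfg, trial_id=t) for t in range(5)]


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
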