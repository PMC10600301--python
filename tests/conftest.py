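"""Shared fixtures and deterministic hypothesis configuration."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import wavefusion as wf
from tests_helpers import random_tensor_dataset

# Deterministic property testing: fixed seed database disabled, no deadline
# (CI machines vary), explicit derandomization so reruns are bit-identical.
settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


#: A small architecture (3 leads, default 39x11 input) used wherever the
#: full 17-lead bank would only slow the test down.
SMALL_CONFIG = wf.WaveFusionConfig(n_leads=3, sen_bottleneck=2,
                                   encoder_dim=16, embed_dim=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_config():
    return SMALL_CONFIG


@pytest.fixture()
def small_net():
    return wf.WaveFusionNet(SMALL_CONFIG, seed=0)


@pytest.fixture()
def toy_dataset():
    return random_tensor_dataset()


@pytest.fixture()
def separable_dataset():
    return random_tensor_dataset(per_class=8, class_shift=1.5, seed=1)
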