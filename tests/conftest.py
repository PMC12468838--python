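"""Shared fixtures.

``desk_runs`` performs the three scaled-down federated trainings (n=600,
tiny encoders, K=10, T=10, no DP noise, plaintext aggregation) once per
session; the end-to-end convergence, fusion-benefit and ablation tests all
read from it.  ``micro_profile`` is a much smaller configuration for tests
that only exercise plumbing (determinism, encryption equivalence, CLI).
"""

from __future__ import annotations

import numpy as np
import pytest

from qavfl.encoders import EncoderConfig
from qavfl.features import SGConfig
from qavfl.federation import FedConfig
from qavfl.fusion import FusionConfig, LossConfig
from qavfl.model import QAVFL, Profile
from qavfl.privacy import PrivacyConfig
from qavfl.synthdata import SynthConfig

E2E_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def desk_runs():
    """Three scaled-down end-to-end federated fits, one per seed."""
    runs = {}
    for seed in E2E_SEEDS:
        runs[seed] = QAVFL.desk_scale(n=600, seed=seed).fit()
    return runs


def micro_profile(seed: int = 0, T: int = 2, encrypt: bool = False,
                  key_bits: int = 256) -> Profile:
    """A tiny federation profile for plumbing tests (seconds, not minutes)."""
    return Profile(
        synth=SynthConfig(n=80, pos_fraction=0.5, image_size=64,
                          signal_length=48, seed=seed),
        fed=FedConfig(T=T, E=1, local_lr=3e-3, eta=1.0, aggregation="role",
                      batch=16, w2v_epochs=4, seed=seed),
        privacy=PrivacyConfig(noise=False, encrypt=encrypt, key_bits=key_bits),
        encoder=EncoderConfig(backbone="tiny-cnn", image_size=16, text_in=16,
                              text_out=12, image_out=12, signal_out=8,
                              conv1d_filters=8, seed=seed),
        fusion=FusionConfig(d_f=8, seed=seed),
        loss=LossConfig(),
        sg=SGConfig(),
    )


@pytest.fixture()
def small_cohort():
    """A 60-record cohort with small images, for feature-level tests."""
    from qavfl.synthdata import generate_cohort

    cfg = SynthConfig(n=60, pos_fraction=0.5, image_size=64,
                      signal_length=48, seed=42)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
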