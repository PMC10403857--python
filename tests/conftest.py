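"""Shared fixtures.

The expensive fixtures — the 2000-window synthetic dataset and the reduced
model trained on it — are session-scoped and shared by the training-recovery,
attribution and variant tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from clipnet.model import ProfileNet
from clipnet.simulate import SyntheticConfig, simulate_windows

SIM_SEED = 11
TRAIN_SEED = 7


@pytest.fixture(scope="session")
def sim_data():
    """2000 synthetic windows with planted ACUAAC target and U-rich bias."""
    return simulate_windows(SyntheticConfig(n_windows=2000, seed=SIM_SEED))


@pytest.fixture(scope="session")
def sim_splits(sim_data):
    """(train, validation, held-out) subsets of the synthetic windows."""
    return (sim_data.subset(range(1600)),
            sim_data.subset(range(1600, 1800)),
            sim_data.subset(range(1800, 2000)))


@pytest.fixture(scope="session")
def trained_model(sim_splits):
    """Reduced paired model (32 filters, 4 residual blocks) fit on synthetic
    windows; the model every downstream recovery test interrogates."""
    train, val, _ = sim_splits
    net = ProfileNet(filters=32, n_blocks=4, max_epochs=20, batch_size=64,
                     random_state=TRAIN_SEED)
    net.fit(train.sequences, train.stacked_counts(),
            validation_data=(val.sequences, val.stacked_counts()))
    return net


@pytest.fixture(scope="session")
def tiny_model():
    """Small untrained paired model for shape/identity contracts."""
    net = ProfileNet(filters=8, n_blocks=2, random_state=3)
    rng = np.random.default_rng(3)
    net.network_ = net._init_network(rng)
    net.config_ = net._model_config()
    net.n_features_in_ = 4
    return net


@pytest.fixture(scope="session")
def tiny_single_model():
    """Small untrained single-track model."""
    net = ProfileNet(filters=8, n_blocks=2, paired=False, random_state=4)
    net.network_ = net._init_network(np.random.default_rng(4))
    net.config_ = net._model_config()
    net.n_features_in_ = 4
    return net


def random_sequence(rng, length: int) -> str:
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=length))
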