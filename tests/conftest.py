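"""Shared fixtures.

The expensive fixtures (trained prototypical networks) are session-scoped
and shared between the learning-recovery, interpretability and
model-hierarchy tests. Study conditions for the learning tests:
well-separated phantoms (high lesion contrast, low noise) at 96 px,
40 slices/class per pool, and a short desk-scale Adam schedule.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from protoshot.episodes import EpisodeSpec
from protoshot.phantoms import PhantomSpec, generate_dataset
from protoshot.protonet import BackboneConfig, TrainConfig, train_protonet

WELL_SEPARATED = dict(lesion_contrast=1.2, noise_sd=0.03)
# standard difficulty: off the performance ceiling, where generic random
# features no longer saturate and model ordering is meaningful
STANDARD = dict(lesion_contrast=0.6, noise_sd=0.15)
DESK_TRAIN = dict(learning_rate=1e-3, epochs=10, episodes_per_epoch=10, episode_batch=2)


@pytest.fixture(scope="session")
def phantom_spec() -> PhantomSpec:
    return PhantomSpec(**WELL_SEPARATED, seed=100)


@pytest.fixture(scope="session")
def train_pool(phantom_spec):
    phantoms = generate_dataset(phantom_spec, 40)
    X = np.stack([p.image for p in phantoms])
    y = np.array([p.label for p in phantoms])
    return phantoms, X, y


@pytest.fixture(scope="session")
def test_pool():
    phantoms = generate_dataset(PhantomSpec(**WELL_SEPARATED, seed=200), 40)
    X = np.stack([p.image for p in phantoms])
    y = np.array([p.label for p in phantoms])
    return phantoms, X, y


@pytest.fixture(scope="session")
def standard_train_pool():
    phantoms = generate_dataset(PhantomSpec(**STANDARD, seed=300), 40)
    X = np.stack([p.image for p in phantoms])
    y = np.array([p.label for p in phantoms])
    return phantoms, X, y


@pytest.fixture(scope="session")
def standard_test_pool():
    phantoms = generate_dataset(PhantomSpec(**STANDARD, seed=400), 40)
    X = np.stack([p.image for p in phantoms])
    y = np.array([p.label for p in phantoms])
    return phantoms, X, y


@pytest.fixture(scope="session")
def trained_standard_model(standard_train_pool):
    """One prototypical network trained at standard difficulty."""
    _, X, y = standard_train_pool
    ep = EpisodeSpec(k_shot=5, q_query=5, n_episodes=1, seed=0)
    model, curve = train_protonet(
        X, y, ep, BackboneConfig(), TrainConfig(**DESK_TRAIN, seed=0)
    )
    return model, curve


@pytest.fixture(scope="session")
def trained_models(train_pool):
    """Prototypical networks trained from three seeds (desk scale)."""
    _, X, y = train_pool
    models = {}
    for seed in (0, 1, 2):
        ep = EpisodeSpec(k_shot=5, q_query=5, n_episodes=1, seed=seed)
        model, curve = train_protonet(
            X, y, ep, BackboneConfig(), TrainConfig(**DESK_TRAIN, seed=seed)
        )
        models[seed] = (model, curve)
    return models
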