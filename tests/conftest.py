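"""Shared fixtures: toy grids, tiny corpora, and one trained synthetic model.

The expensive fixture — training on the default synthetic recovery scenario
(4 symmetric topics, 300 documents, 500 sweeps) — is session-scoped and
shared by the recovery, decoding and evaluation tests.
"""

import numpy as np
import pytest

from braintopics import (
    BrainGrid,
    Corpus,
    Document,
    FittedModel,
    HyperParams,
    SpatialParams,
    TopicWordMatrix,
    default_recovery_truth,
    generate_corpus,
    recovery_grid,
    train,
    voxelize_topics,
)


@pytest.fixture
def toy_grid():
    return BrainGrid.toy(shape=(8, 8, 8), spacing=6.0)


@pytest.fixture
def tiny_corpus(toy_grid):
    """Two documents, three word types, three peaks."""
    docs = [
        Document("d1", [0, 1], [[-10.0, 4.0, 2.0], [8.0, -2.0, 6.0]]),
        Document("d2", [2], [[12.0, -6.0, 0.0]]),
    ]
    return Corpus(docs, ["alpha_w", "beta_w", "gamma_w"], toy_grid)


def make_fitted(T=2, seed=0, exclusive=0.97, spacing=6.0, shape=(8, 8, 8)):
    """Hand-built fitted model with well-separated topics and near-exclusive words.

    Word ``2 * t`` loads with probability ``exclusive`` on topic t; remaining
    mass is spread uniformly.  Topic t's single spatial component sits at a
    distinct corner of a toy grid.
    """
    grid = BrainGrid.toy(shape=shape, spacing=spacing)
    W = 2 * T
    phi = np.full((W, T), (1.0 - exclusive) / (W - 1))
    for t in range(T):
        phi[2 * t, t] = exclusive
    rng = np.random.default_rng(seed)
    lim = spacing * (np.array(shape) - 1) / 2.0 - spacing
    corners = np.array([[-1, -1, -1], [1, 1, 1], [-1, 1, 1], [1, -1, -1]])[:T] * lim
    mu = corners[:, None, :].astype(float)
    sigma = np.full((T, 1, 3), 16.0)
    pi = np.ones((T, 1))
    spatial = SpatialParams(mu, sigma, pi)
    vocab = [f"w{i}" for i in range(W)]
    return FittedModel(
        vocabulary=vocab,
        grid=grid,
        phi=TopicWordMatrix(phi),
        topic_voxel=voxelize_topics(spatial, grid, smoothing_sigma=0.0),
        spatial=spatial,
    )


@pytest.fixture
def toy_fitted():
    return make_fitted(T=2)


@pytest.fixture(scope="session")
def recovery_truth():
    return default_recovery_truth(seed=1)


@pytest.fixture(scope="session")
def recovery_corpus(recovery_truth):
    return generate_corpus(recovery_truth, n_docs=300, grid=recovery_grid(), seed=1)


@pytest.fixture(scope="session")
def trained_default(recovery_truth, recovery_corpus):
    """The default recovery scenario trained for 500 sweeps (shared)."""
    return train(recovery_corpus, recovery_truth.params, n_iter=500, log_every=100)


@pytest.fixture(scope="session")
def fitted_default(trained_default):
    return FittedModel.from_state(trained_default.state)
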