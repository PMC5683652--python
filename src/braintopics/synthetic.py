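"""Synthetic corpora and annotated image sets with known ground truth.

Everything downstream — the sampler, the decoder, the evaluation harness —
is testable against corpora generated from known topic parameters by running
the model's own generative process forward: per document, a topic mixture
theta_d, peak draws (topic -> subregion -> Gaussian coordinate), then word
draws with topics proportional to the realized peak-topic counts.  The
default recovery scenario uses four well-separated symmetric topics with
near-exclusive word blocks, small enough to train in minutes yet separated
enough that a recovery failure indicates a bug rather than ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import Corpus, Document
from .grid import BrainGrid
from .model import HyperParams, SpatialParams, TopicWordMatrix, voxelize_topics

#: Right-hemisphere subregion means of the default recovery topics (mm).
_DEFAULT_MEANS = np.array(
    [
        [38.0, -62.0, 22.0],
        [44.0, 12.0, 30.0],
        [28.0, 22.0, -14.0],
        [10.0, -80.0, 2.0],
    ]
)
#: Right-subregion weights: one bilateral, one right-, one left-lateralized, one mild.
_DEFAULT_PI_RIGHT = np.array([0.5, 0.8, 0.2, 0.65])


@dataclass
class SyntheticGroundTruth:
    """Known generating parameters for a synthetic corpus.

    Holds everything needed to regenerate the corpus bit-exactly: the
    hyperparameters (whose ``seed`` drives generation), the spatial mixture,
    the topic-word matrix with its vocabulary, and optionally fixed
    per-document topic mixtures ``theta`` (otherwise drawn from
    Dirichlet(alpha)).
    """

    params: HyperParams
    spatial: SpatialParams
    phi: TopicWordMatrix
    vocabulary: list
    theta: np.ndarray | None = None

    def __post_init__(self):
        T = self.params.n_topics
        if self.spatial.n_topics != T or self.phi.phi.shape[1] != T:
            raise ValueError("component topic counts disagree")
        if len(self.vocabulary) != self.phi.phi.shape[0]:
            raise ValueError("vocabulary length disagrees with phi")


def default_recovery_truth(seed: int = 0) -> SyntheticGroundTruth:
    """The default recovery scenario: T = 4 symmetric topics, W = 40.

    Topic means are pairwise >= 30 mm apart with 6 mm per-axis standard
    deviations; each topic owns a block of 10 high-probability words (0.85
    of its mass) plus a thin uniform floor over the rest, giving strongly
    identifiable word distributions.  Subregion weights span bilateral to
    strongly lateralized so lateralization recovery is exercised.
    """
    T, W = 4, 40
    params = HyperParams(n_topics=T, n_regions=2, symmetric=True, seed=seed)
    mu = np.zeros((T, 2, 3))
    mu[:, 1] = _DEFAULT_MEANS
    mu[:, 0] = _DEFAULT_MEANS * np.array([-1.0, 1.0, 1.0])
    sigma = np.full((T, 2, 3), 36.0)
    pi = np.stack([1.0 - _DEFAULT_PI_RIGHT, _DEFAULT_PI_RIGHT], axis=1)
    phi = np.full((W, T), 0.15 / (W - 10))
    block = W // T
    for t in range(T):
        phi[t * block : (t + 1) * block, t] = 0.85 / block
    vocabulary = [f"term{t:02d}_{k:02d}" for t in range(T) for k in range(block)]
    return SyntheticGroundTruth(
        params=params,
        spatial=SpatialParams(mu, sigma, pi),
        phi=TopicWordMatrix(phi),
        vocabulary=vocabulary,
    )


def recovery_grid() -> BrainGrid:
    """An 8 mm whole-head grid covering MNI extents, for synthetic maps."""
    shape = (23, 29, 23)
    grid = BrainGrid.toy(shape=shape, spacing=8.0)
    grid.affine[:3, 3] = [-88.0, -124.0, -70.0]
    return BrainGrid(shape=shape, affine=grid.affine, mask=grid.mask)


def generate_corpus(
    truth: SyntheticGroundTruth,
    n_docs: int = 300,
    peaks_per_doc: float = 10.0,
    words_per_doc: float = 20.0,
    grid: BrainGrid | None = None,
    seed: int | None = None,
) -> Corpus:
    """Sample a corpus from the generative process at the true parameters.

    Per document: theta_d ~ Dirichlet(alpha * 1) (or ``truth.theta[d]``);
    peak counts ~ Poisson(peaks_per_doc) floored at 1 and word counts ~
    Poisson(words_per_doc) floored at 1; each peak draws topic ~ theta_d,
    subregion ~ pi_t, coordinate ~ N(mu_tr, sigma_tr); each word token draws
    its topic with probability proportional to the document's realized
    peak-topic counts plus gamma, then a word type from phi.  Fully
    deterministic given the seed (defaults to ``truth.params.seed``).
    """
    p = truth.params
    T, R = p.n_topics, p.n_regions
    rng = np.random.default_rng(p.seed if seed is None else seed)
    if p.gamma <= 0:
        raise ValueError("word generation requires gamma > 0 for peak-free topics")
    grid = grid if grid is not None else recovery_grid()
    phi = truth.phi.phi
    docs = []
    for d in range(n_docs):
        if truth.theta is not None:
            theta = truth.theta[d]
        else:
            theta = rng.dirichlet(np.full(T, p.alpha))
        n_x = max(1, int(rng.poisson(peaks_per_doc)))
        n_w = max(1, int(rng.poisson(words_per_doc)))
        topics = rng.choice(T, size=n_x, p=theta)
        peaks = np.empty((n_x, 3))
        for j, t in enumerate(topics):
            r = rng.choice(R, p=truth.spatial.pi[t])
            peaks[j] = rng.normal(truth.spatial.mu[t, r], np.sqrt(truth.spatial.sigma[t, r]))
        nx_t = np.bincount(topics, minlength=T).astype(float)
        word_topic_p = (nx_t + p.gamma) / (nx_t.sum() + T * p.gamma)
        word_topics = rng.choice(T, size=n_w, p=word_topic_p)
        tokens = np.array(
            [rng.choice(len(truth.vocabulary), p=phi[:, t]) for t in word_topics],
            dtype=np.int64,
        )
        docs.append(Document(doc_id=f"synth{d:05d}", word_tokens=tokens, peaks=peaks))
    return Corpus(documents=docs, vocabulary=list(truth.vocabulary), grid=grid)


def generate_annotated_images(
    truth: SyntheticGroundTruth,
    grid: BrainGrid,
    n_images: int = 50,
    noise_sd: float = 0.1,
    seed: int = 0,
    smoothing_sigma: float = 4.0,
):
    """Synthetic annotated image set for decoder evaluation.

    Image i is the voxelized map of one true topic t_i (scaled to unit
    maximum) plus i.i.d. Gaussian noise of standard deviation ``noise_sd``
    (default 0.1, i.e. 10% of the peak amplitude — mild map-level noise);
    its annotation is topic t_i's single top word.  Returns
    ``(images, annotations)`` where ``images`` is (n_images, V) in
    masked-voxel order and ``annotations`` is a DataFrame with columns
    (image, topic, term).
    """
    rng = np.random.default_rng(seed)
    tvm = voxelize_topics(truth.spatial, grid, smoothing_sigma)
    a = tvm.a / tvm.a.max(axis=1, keepdims=True)
    T = truth.params.n_topics
    phi = truth.phi.phi
    top_words = [truth.vocabulary[int(np.argmax(phi[:, t]))] for t in range(T)]
    topics = rng.integers(T, size=n_images)
    images = a[topics] + rng.normal(0.0, noise_sd, size=(n_images, a.shape[1]))
    annotations = pd.DataFrame(
        {
            "image": np.arange(n_images),
            "topic": topics,
            "term": [top_words[t] for t in topics],
        }
    )
    return images, annotations
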