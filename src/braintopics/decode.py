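"""Bidirectional text/brain-image decoding on a fitted topic model.

Given the fitted topic-word matrix Phi (W x T) and the voxelized topic maps
A (T x V), the decoder supports:

* text -> image: Bayes-invert Phi into P_TxW, sum the columns of the input's
  tokens into topic weights tau, and project tau . A into voxel space;
* coordinates -> text: map each peak to its masked voxel, sum the matching
  columns of P_TxV into tau, and project tau . Phi^T into word space;
* continuous image -> text: tau = P_TxV . I_V followed by tau . Phi^T —
  rank-interpretable only, since input images have arbitrary scale;
* prior seeding: a two-pass scheme in which a seed text or image is decoded
  under a uniform prior, its normalized tau blended with uniform, and the
  result used as the topic prior p(t) for the main decoding pass;
* topic-basis reconstruction: a non-negative least-squares fit of an image
  on the T topic maps, reported with its coefficient of determination.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
import numpy as np
from scipy.optimize import nnls

from .grid import BrainGrid
from .model import (
    ModelState,
    SpatialParams,
    TopicVoxelMatrix,
    TopicWordMatrix,
    estimate_phi,
    voxelize_topics,
)

logger = logging.getLogger(__name__)

#: Radius (mm) within which an out-of-mask peak is snapped to the mask.
SNAP_RADIUS_MM = 6.0


@dataclass
class TopicPrior:
    """A probability vector over topics used to contextualize decoding."""

    p_t: np.ndarray
    strength: float = 1.0

    def __post_init__(self):
        self.p_t = np.asarray(self.p_t, dtype=float)
        if (self.p_t < 0).any() or abs(self.p_t.sum() - 1.0) > 1e-8:
            raise ValueError("prior must be a probability vector")

    @classmethod
    def uniform(cls, n_topics: int) -> "TopicPrior":
        return cls(np.full(n_topics, 1.0 / n_topics), strength=0.0)


@dataclass
class DecodingResult:
    """Topic weights tau plus either word weights or a voxel image.

    ``arbitrary_scale`` flags outputs whose values are rank-interpretable
    only (continuous-image inputs); coordinate decoding yields genuine word
    probabilities.  For text and coordinate inputs tau is non-negative; a
    real-valued input image (a t or z map, say) can legitimately drive
    topic weights negative, so only finiteness is required there.
    """

    tau: np.ndarray
    word_weights: np.ndarray | None = None
    voxel_values: np.ndarray | None = None
    arbitrary_scale: bool = False

    def __post_init__(self):
        if (self.word_weights is None) == (self.voxel_values is None):
            raise ValueError("exactly one of word_weights / voxel_values must be set")
        if not np.isfinite(self.tau).all():
            raise ValueError("tau must be finite")
        if not self.arbitrary_scale and (self.tau < 0).any():
            raise ValueError("tau must be non-negative for probabilistic inputs")

    def top_words(self, vocabulary, n=10):
        order = np.argsort(-self.word_weights)[:n]
        return [(vocabulary[i], float(self.word_weights[i])) for i in order]


@dataclass
class FittedModel:
    """The decoder-facing artifacts of a trained model.

    Bundles the vocabulary, the analysis grid, the topic-word matrix and the
    voxelized topic maps; built from a sampler state with
    :meth:`from_state`.
    """

    vocabulary: list
    grid: BrainGrid
    phi: TopicWordMatrix
    topic_voxel: TopicVoxelMatrix
    spatial: SpatialParams | None = None
    _vocab_index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self._vocab_index = {w: i for i, w in enumerate(self.vocabulary)}

    @property
    def n_topics(self) -> int:
        return self.phi.phi.shape[1]

    @classmethod
    def from_state(
        cls, state: ModelState, grid: BrainGrid | None = None, smoothing_sigma: float = 4.0
    ) -> "FittedModel":
        grid = grid if grid is not None else state.corpus.grid
        return cls(
            vocabulary=list(state.corpus.vocabulary),
            grid=grid,
            phi=estimate_phi(state),
            topic_voxel=voxelize_topics(state.spatial, grid, smoothing_sigma),
            spatial=state.spatial.copy(),
        )


def tokenize(text, vocabulary) -> list:
    """Map free text to vocabulary type ids, bigrams before unigrams.

    Input is lowercased and split on non-word characters; at each position a
    two-word type (longest match first) is preferred over a one-word type.
    Out-of-vocabulary words are skipped with a logged warning.  Accepts a
    pre-split word list as well as a string.
    """
    if isinstance(text, str):
        words = re.findall(r"[a-z0-9_']+", text.lower())
    else:
        words = [str(w).lower() for w in text]
    index = {w: i for i, w in enumerate(vocabulary)}
    tokens = []
    skipped = []
    i = 0
    while i < len(words):
        if i + 1 < len(words) and f"{words[i]} {words[i + 1]}" in index:
            tokens.append(index[f"{words[i]} {words[i + 1]}"])
            i += 2
        elif words[i] in index:
            tokens.append(index[words[i]])
            i += 1
        else:
            skipped.append(words[i])
            i += 1
    if skipped:
        logger.warning("skipped %d out-of-vocabulary words: %s", len(skipped), skipped[:10])
    return tokens


def topic_given_word(phi: TopicWordMatrix, prior: TopicPrior | None = None) -> np.ndarray:
    """T x W matrix P[t, w] = p(t | w) under the given (default uniform) prior.

    With a uniform prior this is phi[w, t] / sum_t' phi[w, t'] — Bayes' rule
    with the word marginal cancelled.  Degenerate zero-mass columns (possible
    only with unsmoothed input) are set uniform and logged.
    """
    m = phi.phi.T  # (T, W)
    T = m.shape[0]
    if prior is not None:
        m = m * prior.p_t[:, None]
    colsum = m.sum(axis=0)
    dead = colsum <= 0
    if dead.any():
        logger.warning("%d word types have zero mass under the prior; set uniform", dead.sum())
    return np.where(dead[None, :], 1.0 / T, m / np.where(dead, 1.0, colsum)[None, :])


def topic_given_voxel(tvm: TopicVoxelMatrix, prior: TopicPrior | None = None) -> np.ndarray:
    """T x V matrix p(t | v), re-inverting the topic maps under ``prior``."""
    if prior is None:
        return tvm.p_tv
    m = tvm.a * prior.p_t[:, None]
    T = m.shape[0]
    colsum = m.sum(axis=0)
    dead = colsum <= 0
    return np.where(dead[None, :], 1.0 / T, m / np.where(dead, 1.0, colsum)[None, :])


def encode_text(text, model: FittedModel, prior: TopicPrior | None = None) -> DecodingResult:
    """Project text into voxel space: tau_t = sum_tokens P[t, w]; image = tau . A."""
    tokens = tokenize(text, model.vocabulary)
    if not tokens:
        raise ValueError("no input token matches the vocabulary")
    p_tw = topic_given_word(model.phi, prior)
    # canonical (sorted) summation order: bag-of-words inputs give
    # bit-identical output regardless of word order
    tau = p_tw[:, np.sort(tokens)].sum(axis=1)
    voxel_values = tau @ model.topic_voxel.a
    return DecodingResult(tau=tau, voxel_values=voxel_values)


def decode_coordinates(
    peaks, model: FittedModel, prior: TopicPrior | None = None
) -> DecodingResult:
    """Decode a list of MNI-mm coordinates into word probabilities.

    Each peak is mapped to its containing masked voxel (snapped to the
    nearest masked voxel within 6 mm if it falls outside the mask, otherwise
    skipped with a warning); tau sums the matching columns of p(t | v) and is
    normalized, so the projected word weights tau . Phi^T form a genuine
    probability distribution over word types.
    """
    peaks = np.atleast_2d(np.asarray(peaks, dtype=float))
    vox = model.grid.mm_to_masked_index(peaks, snap_mm=SNAP_RADIUS_MM)
    kept = vox[vox >= 0]
    if (vox < 0).any():
        logger.warning("%d peaks fell outside the mask (snap radius %.0f mm); skipped",
                       int((vox < 0).sum()), SNAP_RADIUS_MM)
    if kept.size == 0:
        raise ValueError("no input peak maps to a masked voxel")
    p_tv = topic_given_voxel(model.topic_voxel, prior)
    tau = p_tv[:, kept].sum(axis=1)
    tau = tau / tau.sum()
    word_weights = model.phi.phi @ tau
    return DecodingResult(tau=tau, word_weights=word_weights)


def decode_image(image, model: FittedModel, prior: TopicPrior | None = None) -> DecodingResult:
    """Decode a continuous masked-voxel image into word weights.

    tau = P_TxV . I_V and word_weights = tau . Phi^T.  The input's scale is
    arbitrary, so the outputs are rank-interpretable only (flagged on the
    result); tau is deliberately not renormalized.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != (model.grid.n_voxels,):
        raise ValueError(f"expected a length-{model.grid.n_voxels} masked image vector")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    if not image.any():
        raise ValueError("image is all zero")
    p_tv = topic_given_voxel(model.topic_voxel, prior)
    tau = p_tv @ image
    word_weights = model.phi.phi @ tau
    return DecodingResult(tau=tau, word_weights=word_weights, arbitrary_scale=True)


def seed_prior(seed, model: FittedModel, strength: float) -> TopicPrior:
    """Build an informative topic prior from a seed text or image.

    First pass: the seed is decoded under a uniform prior to get topic
    weights tau, normalized to a distribution q.  The returned prior blends
    linearly with uniform, p = (1 - strength) * uniform + strength * q, so
    strength 0 is exactly uniform and strength 1 exactly the seed posterior.
    The output composes: it can feed any decode operation, including another
    seeding pass (chaining is not idempotent).
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    if isinstance(seed, (str, list, tuple)):
        tau = encode_text(seed, model).tau
    else:
        tau = decode_image(np.asarray(seed, dtype=float), model).tau
    total = tau.sum()
    if total <= 0:
        raise ValueError("seed produced no topic mass")
    q = tau / total
    T = model.n_topics
    return TopicPrior((1.0 - strength) / T + strength * q, strength=strength)


def reconstruct_image(image, model: FittedModel):
    """Non-negative least-squares fit of an image on the topic-map basis.

    Returns ``(coefficients, fitted_image, r_squared)`` where the fit is
    sum_t coef_t * A[t, :] with coef >= 0 and R^2 = 1 - SS_res / SS_tot over
    masked voxels (SS_tot about the image mean).  All-zero topic maps are
    excluded from the basis with a logged warning.
    """
    image = np.asarray(image, dtype=float)
    a = model.topic_voxel.a
    if image.shape != (a.shape[1],):
        raise ValueError("image length does not match the topic maps")
    usable = np.flatnonzero(a.any(axis=1))
    if usable.size < a.shape[0]:
        logger.warning("%d all-zero topic maps excluded from the basis",
                       a.shape[0] - usable.size)
    coef_usable, _ = nnls(a[usable].T, image)
    coef = np.zeros(a.shape[0])
    coef[usable] = coef_usable
    fitted = coef @ a
    ss_res = float(((image - fitted) ** 2).sum())
    ss_tot = float(((image - image.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return coef, fitted, r2
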