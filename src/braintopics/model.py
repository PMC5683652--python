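"""The generalized correspondence LDA model.

Each of ``T`` latent topics pairs (i) a spatial probability distribution over
brain locations — a single 3-D Gaussian, a mixture of two free Gaussians, or
a mixture of two Gaussians whose means are mirrored across the midsagittal
plane (x = 0) — with (ii) a multinomial distribution over word types.  A
document draws a topic mixture theta_d from a Dirichlet(alpha) prior, samples
each activation peak by picking a topic then a subregion then a Gaussian
draw, and samples each word token from a topic chosen *proportionally to the
document's realized peak-topic counts* (smoothed by ``gamma``) — the
correspondence that couples the linguistic and spatial modalities.

This module holds the model state (latent assignments + sufficient
statistics), the joint log-probability under the collapsed parameterization,
the point estimators for the word and spatial distributions, voxelization of
topics onto an analysis grid, and the per-topic lateralization coefficient.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.special import gammaln

from .corpus import Corpus
from .grid import BrainGrid

logger = logging.getLogger(__name__)

LOG_2PI = math.log(2.0 * math.pi)

#: Per-axis variance floor (mm^2) preventing collapse onto duplicated peaks.
VARIANCE_FLOOR = 4.0


@dataclass
class HyperParams:
    """Model hyperparameters.

    Parameters
    ----------
    n_topics : int
        Number of latent topics T.
    n_regions : int
        Gaussian subregions per topic (1 or 2).
    symmetric : bool
        Constrain the two subregion means to mirror across x = 0
        (requires ``n_regions == 2``).
    alpha : float
        Dirichlet concentration of the per-document peak-topic mixture.
    beta : float
        Dirichlet concentration of the topic-word multinomials.
    gamma : float
        Smoothing of the word-to-peak-count correspondence: a word token's
        topic is drawn with probability (N^x_dt + gamma)/(N^x_d + T*gamma).
    delta : float
        Dirichlet concentration of the per-topic subregion weights.
    roi_sigma : float
        Initial / fallback spatial standard deviation in mm; empty
        subregions keep variance roi_sigma**2 on every axis.
    seed : int
        RNG seed recorded in model metadata.
    """

    n_topics: int = 10
    n_regions: int = 2
    symmetric: bool = True
    alpha: float = 0.1
    beta: float = 0.01
    gamma: float = 0.01
    delta: float = 1.0
    roi_sigma: float = math.sqrt(50.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.symmetric and self.n_regions != 2:
            raise ValueError("symmetric mode requires exactly 2 subregions")
        for name in ("alpha", "beta", "gamma", "delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.roi_sigma <= 0:
            raise ValueError("roi_sigma must be > 0")


@dataclass
class SpatialParams:
    """Per-topic spatial Gaussian mixture parameters.

    ``mu``/``sigma`` are (T, R, 3) arrays of component means (mm) and
    diagonal variances (mm^2); ``pi`` is the (T, R) subregion weight table.
    In symmetric mode component 0 is the left-hemisphere (x < 0) subregion
    and component 1 its mirror image on the right.
    """

    mu: np.ndarray
    sigma: np.ndarray
    pi: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        T, R, _ = self.mu.shape
        if self.sigma.shape != (T, R, 3) or self.pi.shape != (T, R):
            raise ValueError("inconsistent spatial parameter shapes")

    @property
    def n_topics(self):
        return self.mu.shape[0]

    @property
    def n_regions(self):
        return self.mu.shape[1]

    def copy(self) -> "SpatialParams":
        return SpatialParams(self.mu.copy(), self.sigma.copy(), self.pi.copy())


@dataclass
class TopicWordMatrix:
    """Column-stochastic W x T matrix: phi[w, t] = p(word = w | topic = t)."""

    phi: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        colsums = self.phi.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-8):
            raise ValueError("phi columns must sum to 1")
        if (self.phi <= 0).any():
            raise ValueError("phi must be strictly positive (Dirichlet-smoothed)")


@dataclass
class TopicVoxelMatrix:
    """Voxelized topic maps and their Bayes inversion.

    ``a`` is the T x V matrix of p(voxel | topic), each row summing to 1;
    ``p_tv`` the T x V matrix of p(topic | voxel) under a uniform topic
    prior, each column summing to 1.
    """

    a: np.ndarray
    p_tv: np.ndarray

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.p_tv = np.asarray(self.p_tv, dtype=float)
        if not np.allclose(self.a.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("rows of a must sum to 1")
        if not np.allclose(self.p_tv.sum(axis=0), 1.0, atol=1e-8):
            raise ValueError("columns of p_tv must sum to 1")


class CountIntegrityError(RuntimeError):
    """Sufficient-statistic tables disagree with the assignment vectors."""


@dataclass
class ModelState:
    """Latent assignments plus sufficient statistics for a corpus.

    Token data are stored flat and document-contiguous: ``w_doc``/``w_type``
    index word tokens, ``x_doc``/``x_coord`` peaks, with per-document slices
    given by ``w_offsets``/``x_offsets``.  The count tables are exact tallies
    of the assignment vectors at all times.
    """

    corpus: Corpus
    params: HyperParams
    # flat token data
    w_doc: np.ndarray
    w_type: np.ndarray
    x_doc: np.ndarray
    x_coord: np.ndarray
    w_offsets: np.ndarray
    x_offsets: np.ndarray
    # latent assignments
    z: np.ndarray
    y: np.ndarray
    c: np.ndarray
    # count tables
    nwt: np.ndarray  # (W, T) word-type x topic
    nt_w: np.ndarray  # (T,) word tokens per topic
    nxd: np.ndarray  # (D, T) per-document peak-topic
    nzd: np.ndarray  # (D, T) per-document word-topic
    ntr: np.ndarray  # (T, R) topic x subregion
    nt_x: np.ndarray  # (T,) peaks per topic
    spatial: SpatialParams
    rng: np.random.Generator
    iteration: int = 0
    last_sweep_ops: int = 0

    @property
    def n_word_tokens(self):
        return int(self.w_type.size)

    @property
    def n_peaks(self):
        return int(self.x_doc.size)

    def tally_counts(self):
        """Recompute all count tables from the assignment vectors."""
        T, R = self.params.n_topics, self.params.n_regions
        W, D = self.corpus.n_word_types, len(self.corpus)
        nwt = np.zeros((W, T), dtype=np.int64)
        np.add.at(nwt, (self.w_type, self.z), 1)
        nzd = np.zeros((D, T), dtype=np.int64)
        np.add.at(nzd, (self.w_doc, self.z), 1)
        nxd = np.zeros((D, T), dtype=np.int64)
        np.add.at(nxd, (self.x_doc, self.y), 1)
        ntr = np.zeros((T, R), dtype=np.int64)
        np.add.at(ntr, (self.y, self.c), 1)
        return nwt, nwt.sum(axis=0), nxd, nzd, ntr, ntr.sum(axis=1)

    def check_counts(self):
        """Raise :class:`CountIntegrityError` if counts are not exact tallies."""
        tallies = self.tally_counts()
        stored = (self.nwt, self.nt_w, self.nxd, self.nzd, self.ntr, self.nt_x)
        for got, want in zip(stored, tallies):
            if not np.array_equal(got, want):
                raise CountIntegrityError("count tables disagree with assignments")
        if self.nwt.sum() != self.n_word_tokens or self.ntr.sum() != self.n_peaks:
            raise CountIntegrityError("count totals do not conserve token counts")

    # -- serialization ------------------------------------------------------

    def save(self, directory) -> None:
        """Write a versioned JSON-metadata + array bundle."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format": "braintopics-model-v1",
            "hyperparams": asdict(self.params),
            "iteration": self.iteration,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=1))
        np.savez(
            directory / "state.npz",
            z=self.z,
            y=self.y,
            c=self.c,
            mu=self.spatial.mu,
            sigma=self.spatial.sigma,
            pi=self.spatial.pi,
            rng_state=np.frombuffer(
                json.dumps(self.rng.bit_generator.state).encode(), dtype=np.uint8
            ),
        )
        self.corpus.save(directory / "corpus")

    @classmethod
    def load(cls, directory) -> "ModelState":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        if meta.get("format") != "braintopics-model-v1":
            raise ValueError("not a braintopics model bundle")
        corpus = Corpus.load(directory / "corpus")
        params = HyperParams(**meta["hyperparams"])
        arrays = np.load(directory / "state.npz")
        state = build_state(
            corpus,
            params,
            z=arrays["z"],
            y=arrays["y"],
            c=arrays["c"],
            rng=np.random.default_rng(params.seed),
        )
        state.spatial = SpatialParams(arrays["mu"], arrays["sigma"], arrays["pi"])
        state.iteration = int(meta["iteration"])
        state.rng.bit_generator.state = json.loads(arrays["rng_state"].tobytes().decode())
        return state


def build_state(corpus: Corpus, params: HyperParams, z, y, c, rng) -> ModelState:
    """Assemble a :class:`ModelState` from a corpus and given assignments."""
    w_doc, w_type, x_doc, x_coord = [], [], [], []
    w_offsets = [0]
    x_offsets = [0]
    for d, doc in enumerate(corpus.documents):
        w_doc.extend([d] * doc.word_tokens.size)
        w_type.extend(doc.word_tokens.tolist())
        x_doc.extend([d] * len(doc.peaks))
        x_coord.extend(doc.peaks.tolist())
        w_offsets.append(len(w_type))
        x_offsets.append(len(x_doc))
    state = ModelState(
        corpus=corpus,
        params=params,
        w_doc=np.asarray(w_doc, dtype=np.int64),
        w_type=np.asarray(w_type, dtype=np.int64),
        x_doc=np.asarray(x_doc, dtype=np.int64),
        x_coord=np.asarray(x_coord, dtype=float).reshape(-1, 3),
        w_offsets=np.asarray(w_offsets, dtype=np.int64),
        x_offsets=np.asarray(x_offsets, dtype=np.int64),
        z=np.asarray(z, dtype=np.int64),
        y=np.asarray(y, dtype=np.int64),
        c=np.asarray(c, dtype=np.int64),
        nwt=np.empty(0, dtype=np.int64),
        nt_w=np.empty(0, dtype=np.int64),
        nxd=np.empty(0, dtype=np.int64),
        nzd=np.empty(0, dtype=np.int64),
        ntr=np.empty(0, dtype=np.int64),
        nt_x=np.empty(0, dtype=np.int64),
        spatial=SpatialParams(
            np.zeros((params.n_topics, params.n_regions, 3)),
            np.full((params.n_topics, params.n_regions, 3), params.roi_sigma**2),
            np.full((params.n_topics, params.n_regions), 1.0 / params.n_regions),
        ),
        rng=rng,
    )
    (state.nwt, state.nt_w, state.nxd, state.nzd, state.ntr, state.nt_x) = state.tally_counts()
    state.spatial = estimate_spatial(state)
    return state


def _gaussian_logpdf(x, mu, sigma):
    """Diagonal-covariance Gaussian log density; broadcasts over leading axes."""
    return -0.5 * (((x - mu) ** 2) / sigma + np.log(sigma) + LOG_2PI).sum(axis=-1)


def log_joint(state: ModelState, check: bool = True) -> float:
    """Joint log-probability of the data and latent assignments.

    The collapsed factorization integrates out the Dirichlet-distributed
    multinomial parameters and conditions on the current point-estimated
    Gaussian parameters:

    * word emission: per-topic Dirichlet-multinomial with concentration beta;
    * peak-topic choice: per-document Dirichlet-multinomial (alpha);
    * subregion choice: per-topic Dirichlet-multinomial (delta);
    * word-topic correspondence: each token's topic drawn with probability
      (N^x_dt + gamma)/(N^x_d + T*gamma);
    * spatial term: Gaussian log densities at the assigned components.

    Both Gibbs conditionals in :mod:`braintopics.inference` are exact ratios
    of this quantity over candidate assignments.
    """
    if check:
        state.check_counts()
    p = state.params
    T, R, W = p.n_topics, p.n_regions, state.corpus.n_word_types
    nxd, nzd = state.nxd, state.nzd
    nx_doc = nxd.sum(axis=1)
    nz_doc = nzd.sum(axis=1)

    # correspondence: word topics given peak-topic counts
    lp = float(
        (nzd * np.log(nxd + p.gamma)).sum() - (nz_doc * np.log(nx_doc + T * p.gamma)).sum()
    )
    # collapsed topic-word multinomials
    lp += float(
        T * gammaln(W * p.beta)
        - gammaln(state.nt_w + W * p.beta).sum()
        + gammaln(state.nwt + p.beta).sum()
        - T * W * gammaln(p.beta)
    )
    # collapsed per-document peak-topic mixtures
    D = len(state.corpus)
    lp += float(
        D * gammaln(T * p.alpha)
        - gammaln(nx_doc + T * p.alpha).sum()
        + gammaln(nxd + p.alpha).sum()
        - D * T * gammaln(p.alpha)
    )
    # collapsed subregion mixtures
    lp += float(
        T * gammaln(R * p.delta)
        - gammaln(state.nt_x + R * p.delta).sum()
        + gammaln(state.ntr + p.delta).sum()
        - T * R * gammaln(p.delta)
    )
    # spatial likelihood at the assigned components
    if state.n_peaks:
        mu = state.spatial.mu[state.y, state.c]
        sigma = state.spatial.sigma[state.y, state.c]
        lp += float(_gaussian_logpdf(state.x_coord, mu, sigma).sum())
    if not np.isfinite(lp):
        raise CountIntegrityError("log joint is not finite")
    return lp


def estimate_phi(state: ModelState) -> TopicWordMatrix:
    """Posterior-mean topic-word matrix: (N^WT + beta) / (N_t + W*beta)."""
    p = state.params
    W = state.corpus.n_word_types
    phi = (state.nwt + p.beta) / (state.nt_w + W * p.beta)
    return TopicWordMatrix(phi)


def estimate_spatial(state: ModelState) -> SpatialParams:
    """Point-estimate the per-topic Gaussian mixture from current assignments.

    Non-symmetric mode: per (topic, subregion), the mean and diagonal sample
    variance of assigned peaks, variance floored at ``VARIANCE_FLOOR``.
    Symmetric mode: left-subregion peaks are reflected across x = 0, pooled
    with right-subregion peaks, a single mean/variance is estimated from the
    pool, and the two constrained components are produced by mirroring (so
    the mixture is mirror-symmetric to machine precision and the covariance
    is shared).  Empty subregions keep their previous mean and fall back to
    the prior variance roi_sigma**2 (logged).  Subregion weights are
    pi[t, r] = (N_tr + delta) / (N_t + R*delta).
    """
    p = state.params
    T, R = p.n_topics, p.n_regions
    old = state.spatial
    mu = old.mu.copy()
    sigma = np.empty_like(old.sigma)
    pi = (state.ntr + p.delta) / (state.nt_x + R * p.delta)[:, None]

    prior_var = p.roi_sigma**2
    for t in range(T):
        if p.symmetric:
            sel_l = (state.y == t) & (state.c == 0)
            sel_r = (state.y == t) & (state.c == 1)
            pts = np.concatenate(
                [state.x_coord[sel_l] * np.array([-1.0, 1.0, 1.0]), state.x_coord[sel_r]]
            )
            if len(pts) == 0:
                sigma[t] = prior_var
                logger.debug("topic %d empty; spatial fallback to prior", t)
                continue
            m = pts.mean(axis=0)
            v = np.maximum(pts.var(axis=0), VARIANCE_FLOOR)
            mu[t, 1] = m
            mu[t, 0] = m * np.array([-1.0, 1.0, 1.0])
            sigma[t, 0] = v
            sigma[t, 1] = v
        else:
            for r in range(R):
                sel = (state.y == t) & (state.c == r)
                pts = state.x_coord[sel]
                if len(pts) == 0:
                    sigma[t, r] = prior_var
                    logger.debug("topic %d subregion %d empty; fallback to prior", t, r)
                    continue
                mu[t, r] = pts.mean(axis=0)
                sigma[t, r] = np.maximum(pts.var(axis=0), VARIANCE_FLOOR)
    return SpatialParams(mu, sigma, pi)


def voxelize_topics(
    spatial: SpatialParams, grid: BrainGrid, smoothing_sigma: float = 4.0
) -> TopicVoxelMatrix:
    """Evaluate each topic's spatial mixture on the masked voxel grid.

    Row t of ``a`` is the mixture density (with an extra isotropic smoothing
    variance ``smoothing_sigma**2`` added to each component) evaluated at
    masked voxel centers and normalized to sum 1.  ``p_tv`` is the Bayes
    inversion under a uniform topic prior; voxels where every topic has
    (numerically) zero density get a uniform column, logged.
    """
    centers = grid.masked_coordinates()  # (V, 3)
    T, R = spatial.n_topics, spatial.n_regions
    V = centers.shape[0]
    a = np.zeros((T, V))
    s2 = float(smoothing_sigma) ** 2
    for t in range(T):
        logd = np.full(V, -np.inf)
        for r in range(R):
            var = spatial.sigma[t, r] + s2
            comp = _gaussian_logpdf(centers, spatial.mu[t, r], var)
            comp = comp + np.log(spatial.pi[t, r]) if spatial.pi[t, r] > 0 else comp - np.inf
            logd = np.logaddexp(logd, comp)
        dens = np.exp(logd - logd.max())
        a[t] = dens / dens.sum()
    colsum = a.sum(axis=0)
    dead = colsum <= 0
    if dead.any():
        logger.warning("%d voxels have zero density under all topics; set uniform", dead.sum())
    p_tv = np.where(dead[None, :], 1.0 / T, a / np.where(dead, 1.0, colsum)[None, :])
    return TopicVoxelMatrix(a=a, p_tv=p_tv)


def lateralization(state_or_spatial) -> np.ndarray:
    """Per-topic probability of drawing an activation from the right subregion.

    Only defined for the symmetry-constrained model.  Values below 0.5 mark
    left-lateralized topics, above 0.5 right-lateralized; the coefficient is
    the smoothed right-component weight (N_t,right + delta)/(N_t + 2*delta),
    i.e. pi of the right component.
    """
    if isinstance(state_or_spatial, ModelState):
        if not state_or_spatial.params.symmetric:
            raise ValueError("lateralization requires the symmetric model variant")
        return state_or_spatial.spatial.pi[:, 1].copy()
    spatial = state_or_spatial
    if spatial.n_regions != 2:
        raise ValueError("lateralization requires the symmetric model variant")
    return spatial.pi[:, 1].copy()
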