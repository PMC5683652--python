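"""Collapsed Gibbs sampling for the correspondence topic model.

Word-token topics ``z`` and peak (topic, subregion) pairs ``(y, c)`` are
resampled from their collapsed conditionals — multinomial parameters
integrated out, Gaussian spatial parameters held at their current point
estimates and re-estimated after every sweep.  Both conditionals are exact
ratios of :func:`braintopics.model.log_joint` over candidate assignments,
which the test suite pins to 1e-10.

Per-sweep cost is O(T * (N_W + N_X * R)): every word token scores T topic
candidates and every peak scores T*R (topic, subregion) candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus
from .model import (
    HyperParams,
    ModelState,
    build_state,
    estimate_spatial,
    log_joint,
    _gaussian_logpdf,
)

logger = logging.getLogger(__name__)

#: Sweeps over which the early spatial-variance annealing floor decays.
ANNEAL_SWEEPS = 50


def initialize(corpus: Corpus, params: HyperParams) -> ModelState:
    """Random initial state, fully determined by ``params.seed``.

    Word and peak topics are uniform over T.  In symmetric mode the
    subregion of each peak is set by its hemisphere (x < 0 -> left, x > 0 ->
    right, x = 0 random); otherwise subregions are uniform over R.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    rng = np.random.default_rng(params.seed)
    n_w = corpus.n_word_tokens
    n_x = corpus.n_peaks
    z = rng.integers(params.n_topics, size=n_w)
    y = rng.integers(params.n_topics, size=n_x)
    if params.symmetric:
        xs = np.concatenate([d.peaks[:, 0] for d in corpus.documents]) if n_x else np.empty(0)
        c = np.where(xs > 0, 1, 0).astype(np.int64)
        ties = xs == 0
        c[ties] = rng.integers(2, size=int(ties.sum()))
    else:
        c = rng.integers(params.n_regions, size=n_x)
    return build_state(corpus, params, z=z, y=y, c=c, rng=rng)


def word_conditional(state: ModelState, d: int, i: int) -> np.ndarray:
    """Collapsed conditional over topics for word token ``i`` of document ``d``.

    p(z = t) is proportional to (N^x_dt + gamma) * (N^WT_wt,-i + beta) /
    (N_t,-i + W*beta); the returned vector is normalized.  The state is not
    modified.
    """
    p = state.params
    g = int(state.w_offsets[d]) + int(i)
    if not (state.w_offsets[d] <= g < state.w_offsets[d + 1]):
        raise IndexError("token index outside document")
    w = state.w_type[g]
    t_old = state.z[g]
    W = state.corpus.n_word_types
    nwt_w = state.nwt[w].astype(float).copy()
    nt = state.nt_w.astype(float).copy()
    nwt_w[t_old] -= 1
    nt[t_old] -= 1
    probs = (state.nxd[d] + p.gamma) * (nwt_w + p.beta) / (nt + W * p.beta)
    return probs / probs.sum()


def peak_conditional(state: ModelState, d: int, j: int) -> np.ndarray:
    """Collapsed conditional over (topic, subregion) pairs for peak ``j`` of doc ``d``.

    Computed in log space; returns a normalized (T, R) array.  The factors
    are the per-document peak-topic prior (alpha), the subregion weight
    (delta), the Gaussian density at the current component parameters, and
    the correspondence factor — how moving the peak to topic t raises the
    probability of the document's word-topic counts:

        CF(d, t) = ((N^x_dt,-j + 1 + gamma) / (N^x_dt,-j + gamma)) ** N^z_dt

    In symmetric mode both mirrored components remain candidates.
    """
    p = state.params
    g = int(state.x_offsets[d]) + int(j)
    if not (state.x_offsets[d] <= g < state.x_offsets[d + 1]):
        raise IndexError("peak index outside document")
    T, R = p.n_topics, p.n_regions
    t_old, r_old = state.y[g], state.c[g]
    nxd_d = state.nxd[d].astype(float).copy()
    ntr = state.ntr.astype(float).copy()
    nt_x = state.nt_x.astype(float).copy()
    nxd_d[t_old] -= 1
    ntr[t_old, r_old] -= 1
    nt_x[t_old] -= 1

    logdens = _gaussian_logpdf(
        state.x_coord[g][None, None, :], state.spatial.mu, state.spatial.sigma
    )  # (T, R)
    if not np.isfinite(logdens).all():
        raise RuntimeError("non-finite spatial density in peak conditional")
    log_cf = state.nzd[d] * (np.log(nxd_d + 1 + p.gamma) - np.log(nxd_d + p.gamma))
    logp = (
        np.log(nxd_d + p.alpha)[:, None]
        + np.log(ntr + p.delta)
        - np.log(nt_x + R * p.delta)[:, None]
        + logdens
        + log_cf[:, None]
    )
    logp -= logp.max()
    probs = np.exp(logp)
    return probs / probs.sum()


def _sample(rng, probs):
    """Draw an index from an unnormalized probability vector."""
    cdf = np.cumsum(probs)
    return int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))


def gibbs_sweep(state: ModelState, update_spatial: bool = True) -> ModelState:
    """One full pass: resample every word token and peak, then re-estimate
    the spatial parameters (unless ``update_spatial`` is False).

    Documents are visited in corpus order, word tokens before peaks within
    each document.  Counts remain exact tallies throughout; the state is
    modified in place and returned.  ``state.last_sweep_ops`` records the
    number of candidate evaluations, T*N_W + T*R*N_X.
    """
    p = state.params
    T, R = p.n_topics, p.n_regions
    W = state.corpus.n_word_types
    rng = state.rng
    z, y, c = state.z, state.y, state.c
    nwt, nt_w = state.nwt, state.nt_w
    nxd, nzd = state.nxd, state.nzd
    ntr, nt_x = state.ntr, state.nt_x
    w_type = state.w_type
    gamma, alpha, beta, delta = p.gamma, p.alpha, p.beta, p.delta
    w_beta = W * beta
    r_delta = R * delta

    # Gaussian log densities of every peak under every component, at the
    # spatial parameters current for this sweep.
    if state.n_peaks:
        logdens = _gaussian_logpdf(
            state.x_coord[:, None, None, :], state.spatial.mu[None], state.spatial.sigma[None]
        )  # (N_X, T, R)
    ops = 0

    for d in range(len(state.corpus)):
        nxd_d = nxd[d]
        nzd_d = nzd[d]
        # -- word tokens --
        for g in range(state.w_offsets[d], state.w_offsets[d + 1]):
            w = w_type[g]
            t_old = z[g]
            nwt_w = nwt[w]
            nwt_w[t_old] -= 1
            nt_w[t_old] -= 1
            nzd_d[t_old] -= 1
            probs = (nxd_d + gamma) * (nwt_w + beta) / (nt_w + w_beta)
            t_new = _sample(rng, probs)
            z[g] = t_new
            nwt_w[t_new] += 1
            nt_w[t_new] += 1
            nzd_d[t_new] += 1
            ops += T
        # -- peaks: joint (topic, subregion) draw --
        for g in range(state.x_offsets[d], state.x_offsets[d + 1]):
            t_old, r_old = y[g], c[g]
            nxd_d[t_old] -= 1
            ntr[t_old, r_old] -= 1
            nt_x[t_old] -= 1
            log_cf = nzd_d * (np.log(nxd_d + 1 + gamma) - np.log(nxd_d + gamma))
            logp = (
                np.log(nxd_d + alpha)[:, None]
                + np.log(ntr + delta)
                - np.log(nt_x + r_delta)[:, None]
                + logdens[g]
                + log_cf[:, None]
            )
            logp -= logp.max()
            k = _sample(rng, np.exp(logp).ravel())
            t_new, r_new = divmod(k, R)
            y[g] = t_new
            c[g] = r_new
            nxd_d[t_new] += 1
            ntr[t_new, r_new] += 1
            nt_x[t_new] += 1
            ops += T * R
    state.last_sweep_ops = ops
    if update_spatial:
        state.spatial = estimate_spatial(state)
    state.iteration += 1
    return state


@dataclass
class TrainResult:
    """Final sampler state plus the recorded log-joint trace."""

    state: ModelState
    trace: list = field(default_factory=list)  # (iteration, log_joint) pairs


def train(
    corpus: Corpus,
    params: HyperParams,
    n_iter: int,
    log_every: int = 1,
    checkpoint_dir=None,
    initial_state: ModelState | None = None,
    anneal_sweeps: int = ANNEAL_SWEEPS,
) -> TrainResult:
    """Run the sampler for ``n_iter`` sweeps from a fresh (or given) state.

    During the first ``anneal_sweeps`` sweeps the estimated spatial
    variances are floored at a value that decays geometrically from the
    per-axis variance of all peaks down to the prior variance roi_sigma**2.
    Early on, the flat spatial term lets assignments organize on the word
    and correspondence structure; as the floor tightens the Gaussians lock
    onto their clusters.  Without this schedule the sampler frequently
    freezes in modes where one component spans two activation clusters
    while another duplicates a cluster.  The log-joint is recorded every
    ``log_every`` sweeps.  If a ``checkpoint_dir`` is given, an interrupted
    run leaves a loadable checkpoint there.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    state = initial_state if initial_state is not None else initialize(corpus, params)
    start_var = state.x_coord.var(axis=0) if state.n_peaks else np.zeros(3)
    end_var = params.roi_sigma**2
    trace = []
    try:
        for it in range(n_iter):
            gibbs_sweep(state)
            if state.iteration <= anneal_sweeps and start_var.mean() > end_var:
                frac = (state.iteration - 1) / anneal_sweeps
                floor = start_var * (end_var / start_var.mean()) ** frac
                state.spatial.sigma[:] = np.maximum(state.spatial.sigma, floor)
            if (it + 1) % log_every == 0:
                lj = log_joint(state, check=False)
                trace.append((state.iteration, lj))
                logger.info("sweep %d: log joint %.2f", state.iteration, lj)
    except KeyboardInterrupt:
        if checkpoint_dir is not None:
            state.save(checkpoint_dir)
            logger.warning("interrupted; checkpoint saved to %s", checkpoint_dir)
        raise
    if checkpoint_dir is not None:
        state.save(checkpoint_dir)
    return TrainResult(state=state, trace=trace)
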