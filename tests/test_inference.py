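"""Sampler correctness: conditionals, sweeps, training, determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from braintopics import (
    Corpus,
    Document,
    HyperParams,
    ModelState,
    gibbs_sweep,
    initialize,
    log_joint,
    peak_conditional,
    train,
    word_conditional,
)
from braintopics.model import build_state


def retally(state):
    (
        state.nwt,
        state.nt_w,
        state.nxd,
        state.nzd,
        state.ntr,
        state.nt_x,
    ) = state.tally_counts()


class TestInitialize:
    def test_same_seed_bit_identical(self, tiny_corpus):
        params = HyperParams(n_topics=3, n_regions=2, symmetric=True, seed=42)
        s1 = initialize(tiny_corpus, params)
        s2 = initialize(tiny_corpus, params)
        assert np.array_equal(s1.z, s2.z)
        assert np.array_equal(s1.y, s2.y)
        assert np.array_equal(s1.c, s2.c)
        assert np.array_equal(s1.spatial.mu, s2.spatial.mu)

    def test_single_topic_trivial(self, tiny_corpus):
        params = HyperParams(n_topics=1, n_regions=1, symmetric=False, seed=0)
        state = initialize(tiny_corpus, params)
        assert (state.z == 0).all() and (state.y == 0).all()
        state.check_counts()

    def test_counts_are_exact_tallies(self, tiny_corpus):
        params = HyperParams(n_topics=3, n_regions=2, symmetric=True, seed=1)
        state = initialize(tiny_corpus, params)
        state.check_counts()

    def test_symmetric_init_assigns_subregion_by_hemisphere(self, tiny_corpus):
        params = HyperParams(n_topics=2, n_regions=2, symmetric=True, seed=5)
        state = initialize(tiny_corpus, params)
        xs = state.x_coord[:, 0]
        assert np.array_equal(state.c[xs < 0], np.zeros((xs < 0).sum(), dtype=int))
        assert np.array_equal(state.c[xs > 0], np.ones((xs > 0).sum(), dtype=int))

    def test_empty_corpus_rejected(self, toy_grid):
        corpus = Corpus([], [], toy_grid)
        with pytest.raises(ValueError, match="empty"):
            initialize(corpus, HyperParams(n_topics=2, symmetric=False, n_regions=1))


class TestWordConditional:
    def test_peak_dominated_topic(self, toy_grid):
        # doc 0: word counts for w0 are (1,0) and topic totals (2,1) once
        # token 0 is removed; peak-topic counts (2,0); gamma=0.1, beta=0.01
        docs = [
            Document("d0", [0, 0], [[-5.0, 0.0, 0.0], [5.0, 0.0, 0.0]]),
            Document("d1", [1, 2], [[0.0, 5.0, 0.0]]),
        ]
        corpus = Corpus(docs, ["w0", "w1", "w2"], toy_grid)
        params = HyperParams(
            n_topics=2, n_regions=1, symmetric=False, beta=0.01, gamma=0.1, seed=0
        )
        state = build_state(
            corpus, params, z=[0, 0, 0, 1], y=[0, 0, 1], c=[0, 0, 0],
            rng=np.random.default_rng(0),
        )
        probs = word_conditional(state, 0, 0)
        p1 = 2.1 * (1 + 0.01) / (2 + 0.03)
        p2 = 0.1 * 0.01 / (1 + 0.03)
        assert probs[0] == pytest.approx(p1 / (p1 + p2), abs=1e-12)
        assert probs[0] > 0.999

    def test_symmetric_counts_give_uniform(self, toy_grid):
        docs = [Document("d", [0], [[-5.0, 0.0, 0.0], [5.0, 0.0, 0.0]])]
        corpus = Corpus(docs, ["w0", "w1"], toy_grid)
        params = HyperParams(n_topics=2, n_regions=1, symmetric=False, seed=0)
        # one peak per topic and no other word token: with the current token
        # removed, every count is symmetric under topic exchange
        state = build_state(
            corpus, params, z=[0], y=[0, 1], c=[0, 0], rng=np.random.default_rng(0)
        )
        probs = word_conditional(state, 0, 0)
        assert np.allclose(probs, 0.5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_normalized_for_random_states(self, seed):
        import braintopics

        grid = braintopics.BrainGrid.toy()
        rng = np.random.default_rng(seed)
        docs = [
            Document(f"d{i}", rng.integers(4, size=rng.integers(1, 5)),
                     rng.normal(scale=10, size=(rng.integers(1, 4), 3)))
            for i in range(3)
        ]
        corpus = Corpus(docs, ["a", "b", "c", "d"], grid)
        params = HyperParams(n_topics=3, n_regions=2, symmetric=False, seed=seed)
        state = initialize(corpus, params)
        for d in range(3):
            for i in range(state.w_offsets[d + 1] - state.w_offsets[d]):
                assert word_conditional(state, d, i).sum() == pytest.approx(1.0, abs=1e-12)
            for j in range(state.x_offsets[d + 1] - state.x_offsets[d]):
                assert peak_conditional(state, d, j).sum() == pytest.approx(1.0, abs=1e-12)


class TestPeakConditional:
    def test_wordless_document_reduces_to_prior_times_density(self, toy_grid):
        # a document with zero word tokens has an empty correspondence
        # product: the conditional is prior x subregion weight x density
        docs = [
            Document("d0", [], [[-5.0, 0.0, 0.0], [6.0, 1.0, 0.0]]),
            Document("d1", [0], [[0.0, 5.0, 0.0]]),
        ]
        corpus = Corpus(docs, ["w0"], toy_grid)
        params = HyperParams(
            n_topics=2, n_regions=1, symmetric=False, alpha=0.5, delta=1.0, seed=0
        )
        state = build_state(
            corpus, params, z=[0], y=[0, 1, 0], c=[0, 0, 0],
            rng=np.random.default_rng(0),
        )
        probs = peak_conditional(state, 0, 0)
        # independent scripted evaluation of the stated formula
        x = state.x_coord[0]
        expected = np.zeros(2)
        for t in range(2):
            nxd = state.nxd[0].astype(float).copy()
            nxd[state.y[0]] -= 1
            ntr = state.ntr.astype(float).copy()
            ntr[state.y[0], 0] -= 1
            mu, var = state.spatial.mu[t, 0], state.spatial.sigma[t, 0]
            dens = math.exp(
                sum(
                    -0.5 * ((x[i] - mu[i]) ** 2 / var[i] + math.log(2 * math.pi * var[i]))
                    for i in range(3)
                )
            )
            expected[t] = (
                (nxd[t] + 0.5) * (ntr[t, 0] + 1.0) / (ntr[t].sum() + 1.0) * dens
            )
        expected /= expected.sum()
        assert np.allclose(probs.ravel(), expected, atol=1e-12)

    def test_exchangeable_topics_give_uniform(self, toy_grid):
        docs = [Document("d", [], [[0.0, 0.0, 0.0]])]
        corpus = Corpus(docs, [], toy_grid)
        params = HyperParams(n_topics=2, n_regions=2, symmetric=False, seed=0)
        state = build_state(
            corpus, params, z=[], y=[0], c=[0], rng=np.random.default_rng(0)
        )
        # identical spatial parameters for every component
        state.spatial.mu[:] = 0.0
        state.spatial.sigma[:] = 30.0
        retally(state)
        probs = peak_conditional(state, 0, 0)
        assert np.allclose(probs, 0.25)


class TestOracleEquivalence:
    """The conditionals are exact ratios of the joint — no free parameters."""

    @pytest.mark.parametrize("n_regions,symmetric", [(1, False), (2, False), (2, True)])
    def test_conditionals_match_log_joint_ratios(self, tiny_corpus, n_regions, symmetric):
        params = HyperParams(
            n_topics=2, n_regions=n_regions, symmetric=symmetric,
            alpha=0.7, beta=0.4, gamma=0.3, delta=0.9, seed=7,
        )
        state = initialize(tiny_corpus, params)
        for d in range(len(tiny_corpus)):
            for i in range(state.w_offsets[d + 1] - state.w_offsets[d]):
                cond = word_conditional(state, d, i)
                g = state.w_offsets[d] + i
                orig = state.z[g]
                ljs = []
                for t in range(2):
                    state.z[g] = t
                    retally(state)
                    ljs.append(log_joint(state))
                state.z[g] = orig
                retally(state)
                ref = np.exp(np.array(ljs) - max(ljs))
                assert np.allclose(cond, ref / ref.sum(), atol=1e-10)
            for j in range(state.x_offsets[d + 1] - state.x_offsets[d]):
                cond = peak_conditional(state, d, j)
                g = state.x_offsets[d] + j
                oy, oc = state.y[g], state.c[g]
                ljs = np.zeros((2, n_regions))
                for t in range(2):
                    for r in range(n_regions):
                        state.y[g], state.c[g] = t, r
                        retally(state)
                        ljs[t, r] = log_joint(state)
                state.y[g], state.c[g] = oy, oc
                retally(state)
                ref = np.exp(ljs - ljs.max())
                assert np.allclose(cond, ref / ref.sum(), atol=1e-10)


class TestGibbsSweep:
    def test_counts_conserved_after_every_sweep(self, tiny_corpus):
        params = HyperParams(n_topics=3, n_regions=2, symmetric=True, seed=2)
        state = initialize(tiny_corpus, params)
        for _ in range(10):
            gibbs_sweep(state)
            state.check_counts()
            assert state.nwt.sum() == tiny_corpus.n_word_tokens
            assert state.ntr.sum() == tiny_corpus.n_peaks

    def test_operation_count_linear_in_tokens_and_peaks(self, toy_grid):
        def corpus_with(n_words, n_peaks):
            rng = np.random.default_rng(0)
            docs = [
                Document(
                    "d",
                    rng.integers(3, size=n_words),
                    rng.normal(scale=8, size=(n_peaks, 3)),
                )
            ]
            return Corpus(docs, ["a", "b", "c"], toy_grid)

        params = HyperParams(n_topics=3, n_regions=2, symmetric=False, seed=0)
        base = initialize(corpus_with(10, 6), params)
        gibbs_sweep(base)
        assert base.last_sweep_ops == 3 * 10 + 3 * 2 * 6
        double_peaks = initialize(corpus_with(10, 12), params)
        gibbs_sweep(double_peaks)
        # doubling N_X doubles the peak-sweep operation count exactly
        assert double_peaks.last_sweep_ops - 3 * 10 == 2 * (base.last_sweep_ops - 3 * 10)

    def test_symmetric_mirror_invariant_after_every_sweep(self, tiny_corpus):
        params = HyperParams(n_topics=2, n_regions=2, symmetric=True, seed=9)
        state = initialize(tiny_corpus, params)
        for _ in range(5):
            gibbs_sweep(state)
            assert np.array_equal(
                state.spatial.mu[:, 0] * np.array([-1.0, 1.0, 1.0]),
                state.spatial.mu[:, 1],
            )
            assert np.array_equal(state.spatial.sigma[:, 0], state.spatial.sigma[:, 1])


class TestTrain:
    def test_trace_length(self, tiny_corpus):
        params = HyperParams(n_topics=2, n_regions=1, symmetric=False, seed=0)
        result = train(tiny_corpus, params, n_iter=20, log_every=5)
        assert len(result.trace) == 4

    def test_log_joint_improves_on_synthetic_data(self):
        from braintopics import default_recovery_truth, generate_corpus, recovery_grid

        truth = default_recovery_truth(seed=3)
        corpus = generate_corpus(truth, n_docs=60, grid=recovery_grid(), seed=3)
        result = train(corpus, truth.params, n_iter=60, log_every=1)
        vals = np.array([lj for _, lj in result.trace])
        n = len(vals) // 5
        assert vals[-n:].mean() > vals[:n].mean()

    def test_checkpoint_resume_continues_identically(self, tiny_corpus, tmp_path):
        params = HyperParams(n_topics=2, n_regions=2, symmetric=True, seed=4)
        full = train(tiny_corpus, params, n_iter=8, log_every=8)
        part = train(tiny_corpus, params, n_iter=5, log_every=5,
                     checkpoint_dir=tmp_path / "ckpt")
        resumed = ModelState.load(tmp_path / "ckpt")
        assert resumed.iteration == 5
        res = train(tiny_corpus, params, n_iter=3, log_every=3, initial_state=resumed)
        assert np.array_equal(res.state.z, full.state.z)
        assert np.array_equal(res.state.y, full.state.y)
        assert np.array_equal(res.state.c, full.state.c)
        assert np.allclose(res.state.spatial.mu, full.state.spatial.mu)

    def test_zero_iterations_rejected(self, tiny_corpus):
        params = HyperParams(n_topics=2, n_regions=1, symmetric=False, seed=0)
        with pytest.raises(ValueError):
            train(tiny_corpus, params, n_iter=0)
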