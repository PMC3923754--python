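"""Gibbs samplers: conditionals vs naive oracles, counts, determinism."""

import numpy as np
import pytest

from rednotes.models import (
    HyperParams,
    RedLDA,
    VanillaLDA,
    fit_red_lda,
    fit_vanilla_lda,
    gibbs_conditional_copied,
    gibbs_conditional_copied_fallback,
    gibbs_conditional_vanilla,
    infer_theta,
)
from rednotes.redundancy import RedundancyAnnotation
from rednotes.synthetic import GeneratorConfig, generate_corpus

from conftest import corpus_from_token_lists


def naive_conditional_from_z(state, d, w, alpha, beta):
    """Recompute the standard conditional from raw z (independent oracle)."""
    lay = state.layout
    K, V = state.K, state.V
    n_dk = np.zeros(K)
    n_kw_w = np.zeros(K)
    n_k = np.zeros(K)
    for t in range(len(state.z)):
        k = int(state.z[t])
        if int(lay.doc_of[t]) == d:
            n_dk[k] += 1
        if lay.counted[t]:
            n_k[k] += 1
            if int(lay.word[t]) == w:
                n_kw_w[k] += 1
    p = (n_dk + alpha) * (n_kw_w + beta) / (n_k + V * beta)
    return p / p.sum()


def naive_copied_conditional_from_z(state, record_id, w, delta):
    """Recompute the source-sampling conditional from raw z."""
    lo, hi = state.layout.source_range[record_id]
    counts = np.zeros(state.K)
    for t in range(lo, hi):
        if int(state.layout.word[t]) == w and int(state.z[t]) >= 0:
            counts[int(state.z[t])] += 1
    p = counts + delta
    return p / p.sum()


def fitted_state(corpus, annotation, n_iterations, seed, K=3, red=True):
    cls = RedLDA if red else VanillaLDA
    est = cls(
        n_topics=K, alpha=0.5, beta=0.05, delta=0.3,
        n_iterations=n_iterations, random_state=seed,
    )
    est.fit(corpus, annotation=annotation)
    return est.state_


class TestConditionals:
    def test_k1_returns_one(self):
        corpus, ann, _ = generate_corpus(GeneratorConfig(n_records=2, seed=0))
        est = RedLDA(n_topics=1, n_iterations=1, random_state=0).fit(
            corpus, annotation=ann
        )
        p = gibbs_conditional_vanilla(est.state_, 0, 0, alpha=0.5, beta=0.1)
        assert p == pytest.approx([1.0])

    def test_symmetric_when_counts_zero(self):
        corpus = corpus_from_token_lists({"r": {"a": [0, 1]}}, V=5)
        est = VanillaLDA(n_topics=2, n_iterations=0, random_state=0).fit(corpus)
        st = est.state_
        # zero out counts to emulate the all-empty state
        st.n_dk[:] = 0
        st.n_kw[:] = 0
        st.n_k[:] = 0
        p = gibbs_conditional_vanilla(st, 0, 0, alpha=1.0, beta=0.1)
        assert p == pytest.approx([0.5, 0.5])

    def test_hand_computed_example(self):
        corpus = corpus_from_token_lists({"r": {"a": list(range(10))}}, V=10)
        est = VanillaLDA(n_topics=2, n_iterations=0, random_state=0).fit(corpus)
        st = est.state_
        st.n_dk[0] = [3, 1]
        st.n_kw[:] = 0
        w = 4
        st.n_kw[0, w], st.n_kw[1, w] = 2, 0
        st.n_k[:] = [10, 5]
        p = gibbs_conditional_vanilla(st, 0, w, alpha=1.0, beta=0.1)
        expected = np.array([4 * 2.1 / 11, 2 * 0.1 / 6])
        expected /= expected.sum()
        assert p == pytest.approx(expected)

    def test_copied_conditional_direct_normalization(self):
        # source has w twice in topic 0, never in topic 1; delta=0.5
        src = [7, 7, 3, 4, 5]
        copy = [7] * 12 + [3, 4, 5]
        corpus = corpus_from_token_lists({"r": {"a": src + [8] * 20, "b": copy}}, V=10)
        ann = RedundancyAnnotation.empty(corpus)
        est = RedLDA(n_topics=2, n_iterations=0, random_state=0).fit(
            corpus, annotation=ann
        )
        st = est.state_
        lo, hi = st.layout.source_range["r"]
        # force source assignments for word 7: both occurrences to topic 0
        for t in range(lo, hi):
            if st.layout.word[t] == 7:
                st.z[t] = 0
        p = gibbs_conditional_copied(st, "r", 7, delta=0.5)
        assert p == pytest.approx([2.5 / 3.0, 0.5 / 3.0])

    def test_copied_conditional_three_occurrences(self):
        src = [7, 7, 7, 4, 5]
        corpus = corpus_from_token_lists({"r": {"a": src + [8] * 10, "b": [4, 5]}}, V=10)
        ann = RedundancyAnnotation.empty(corpus)
        est = RedLDA(n_topics=2, n_iterations=0, random_state=0).fit(
            corpus, annotation=ann
        )
        st = est.state_
        lo, hi = st.layout.source_range["r"]
        zs = iter([1, 1, 0])
        for t in range(lo, hi):
            if st.layout.word[t] == 7:
                st.z[t] = next(zs)
        p = gibbs_conditional_copied(st, "r", 7, delta=0.5)
        assert p == pytest.approx([1.5 / 4.0, 2.5 / 4.0])

    def test_copied_conditional_rejects_absent_word(self):
        corpus = corpus_from_token_lists({"r": {"a": [1, 2, 3] * 5, "b": [4, 5]}}, V=10)
        ann = RedundancyAnnotation.empty(corpus)
        est = RedLDA(n_topics=2, n_iterations=0, random_state=0).fit(
            corpus, annotation=ann
        )
        with pytest.raises(ValueError, match="fallback"):
            gibbs_conditional_copied(est.state_, "r", 9, delta=0.5)

    def test_fallback_equals_vanilla_without_copies(self):
        corpus, _, _ = generate_corpus(GeneratorConfig(n_records=3, seed=1))
        ann = RedundancyAnnotation.empty(corpus)
        st = fitted_state(corpus, ann, n_iterations=3, seed=5)
        pa = gibbs_conditional_copied_fallback(st, 2, 7, alpha=0.5, beta=0.05)
        pb = gibbs_conditional_vanilla(st, 2, 7, alpha=0.5, beta=0.05)
        assert pa == pytest.approx(pb)

    def test_all_zero_counts_uniform_k3(self):
        corpus = corpus_from_token_lists({"r": {"a": [0, 1, 2]}}, V=5)
        est = VanillaLDA(n_topics=3, n_iterations=0, random_state=0).fit(corpus)
        st = est.state_
        st.n_dk[:] = 0
        st.n_kw[:] = 0
        st.n_k[:] = 0
        p = gibbs_conditional_copied_fallback(st, 0, 1, alpha=1.0, beta=0.1)
        assert p == pytest.approx([1 / 3] * 3)

    def test_conditionals_match_naive_oracle_many_random_states(self):
        """All three conditional forms vs from-scratch recomputation."""
        rng = np.random.default_rng(99)
        checks = 0
        for trial in range(25):
            cfg = GeneratorConfig(
                K=3, V=30, n_records=3, notes_per_record=(2, 3),
                source_length=(20, 30), other_length=(10, 18),
                copy_fraction=(0.3, 0.6), span_length=(8, 10),
                seed=int(rng.integers(2**31)),
            )
            corpus, ann, _ = generate_corpus(cfg)
            st = fitted_state(corpus, ann, n_iterations=int(rng.integers(1, 4)),
                              seed=int(rng.integers(2**31)))
            lay = st.layout
            for _ in range(45):
                t = int(rng.integers(len(st.z)))
                d, w = int(lay.doc_of[t]), int(lay.word[t])
                rid = lay.doc_ids[d][0]
                p = gibbs_conditional_vanilla(st, d, w, 0.5, 0.05)
                q = naive_conditional_from_z(st, d, w, 0.5, 0.05)
                np.testing.assert_allclose(p, q, rtol=1e-12)
                p = gibbs_conditional_copied_fallback(st, d, w, 0.5, 0.05)
                np.testing.assert_allclose(p, q, rtol=1e-12)
                if st.source_word_topic_counts(rid, w).sum() > 0:
                    p = gibbs_conditional_copied(st, rid, w, 0.3)
                    q2 = naive_copied_conditional_from_z(st, rid, w, 0.3)
                    np.testing.assert_allclose(p, q2, rtol=1e-12)
                    checks += 1
                checks += 2
        assert checks >= 1000


class TestCountConsistency:
    @pytest.mark.parametrize("n_iterations", [1, 3, 10])
    def test_incremental_counts_match_recomputation(self, n_iterations):
        corpus, ann, _ = generate_corpus(GeneratorConfig(n_records=8, seed=2))
        st = fitted_state(corpus, ann, n_iterations=n_iterations, seed=3)
        n_dk, n_kw, n_k = st.recompute_counts()
        assert np.array_equal(n_dk, st.n_dk)
        assert np.array_equal(n_kw, st.n_kw)
        assert np.array_equal(n_k, st.n_k)

    def test_topic_word_total_excludes_copied(self):
        corpus, ann, _ = generate_corpus(GeneratorConfig(n_records=8, seed=2))
        st = fitted_state(corpus, ann, n_iterations=5, seed=3)
        n_counted = int(st.layout.counted.sum())
        assert int(st.n_kw.sum()) == n_counted
        assert int(st.n_k.sum()) == n_counted
        assert np.array_equal(st.n_kw.sum(axis=1), st.n_k)

    def test_doc_topic_rows_sum_to_note_lengths(self):
        corpus, ann, _ = generate_corpus(GeneratorConfig(n_records=5, seed=6))
        st = fitted_state(corpus, ann, n_iterations=4, seed=1)
        lengths = np.diff(st.layout.doc_start)
        assert np.array_equal(st.n_dk.sum(axis=1), lengths)

    def test_fully_copied_note_contributes_nothing_to_topic_words(self):
        src = list(range(100, 160))
        corpus = corpus_from_token_lists(
            {"r": {"a": src, "b": src[10:40]}}, V=200
        )
        from rednotes.redundancy import annotate_redundancy

        ann = annotate_redundancy(corpus.clusters[0])
        assert all(ann.copied[("r", "b")])
        st = fitted_state(corpus, ann, n_iterations=5, seed=0)
        assert int(st.n_kw.sum()) == 60  # only the source note's tokens


class TestFitting:
    def test_same_seed_identical_trajectory(self):
        corpus, ann, _ = generate_corpus(GeneratorConfig(n_records=5, seed=8))
        h = HyperParams(K=4, alpha=0.5, beta=0.05, n_iterations=15, seed=21)
        _, s1 = fit_vanilla_lda(corpus, h)
        _, s2 = fit_vanilla_lda(corpus, h)
        assert np.array_equal(s1.z, s2.z)

    def test_zero_redundancy_reduction_bit_exact(self):
        corpus, _, _ = generate_corpus(GeneratorConfig(n_records=6, seed=9))
        empty = RedundancyAnnotation.empty(corpus)
        h = HyperParams(K=4, alpha=0.5, beta=0.05, n_iterations=25, seed=13)
        mv, sv = fit_vanilla_lda(corpus, h)
        mr, sr = fit_red_lda(corpus, empty, h)
        assert np.array_equal(sv.z, sr.z)
        np.testing.assert_array_equal(mv.phi, mr.phi)
        np.testing.assert_array_equal(mv.theta, mr.theta)

    def test_python_and_numba_kernels_agree_bitwise(self):
        corpus, ann, _ = generate_corpus(
            GeneratorConfig(n_records=3, source_length=(30, 40),
                            other_length=(15, 25), seed=10)
        )
        kw = dict(n_topics=3, alpha=0.5, beta=0.05, delta=0.3,
                  n_iterations=8, random_state=17)
        fast = RedLDA(**kw).fit(corpus, annotation=ann)
        slow = RedLDA(**kw).fit(corpus, annotation=ann, use_python_kernel=True)
        assert np.array_equal(fast.state_.z, slow.state_.z)
        np.testing.assert_array_equal(fast.components_, slow.components_)

    def test_k1_phi_is_smoothed_unigram_distribution(self):
        corpus = corpus_from_token_lists({"r": {"a": [0, 0, 1, 2]}}, V=4)
        h = HyperParams(K=1, alpha=1.0, beta=0.5, n_iterations=3, seed=0)
        model, _ = fit_vanilla_lda(corpus, h)
        expected = (np.array([2, 1, 1, 0]) + 0.5) / (4 + 4 * 0.5)
        np.testing.assert_allclose(model.phi[0], expected)

    def test_rows_normalized(self):
        corpus, ann, _ = generate_corpus(GeneratorConfig(n_records=5, seed=11))
        h = HyperParams(K=3, alpha=0.5, beta=0.05, n_iterations=10, seed=2)
        model, _ = fit_red_lda(corpus, ann, h)
        np.testing.assert_allclose(model.phi.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(model.theta.sum(axis=1), 1.0, atol=1e-8)

    def test_empty_corpus_fatal(self):
        corpus = corpus_from_token_lists({"r": {"a": []}}, V=3)
        with pytest.raises(ValueError):
            VanillaLDA(n_topics=2, n_iterations=1).fit(corpus)

    def test_annotation_missing_note_fatal(self):
        corpus, ann, _ = generate_corpus(GeneratorConfig(n_records=2, seed=0))
        del ann.copied[("r0001", "n01")]
        with pytest.raises(ValueError, match="missing"):
            RedLDA(n_topics=2, n_iterations=1).fit(corpus, annotation=ann)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_disjoint_vocabulary_blocks_separate(self, seed):
        rng = np.random.default_rng(seed)
        records = {}
        for d in range(16):
            block = d % 2
            toks = rng.integers(block * 20, block * 20 + 20, size=60).tolist()
            records[f"r{d:02d}"] = {"n": toks}
        corpus = corpus_from_token_lists(records, V=40)
        h = HyperParams(K=2, alpha=0.5, beta=0.05, n_iterations=200, seed=seed)
        model, _ = fit_vanilla_lda(corpus, h)
        for k in range(2):
            block_mass = model.phi[k, :20].sum()
            assert max(block_mass, 1 - block_mass) >= 0.9


class TestInferTheta:
    def test_k1_returns_unit(self):
        corpus = corpus_from_token_lists({"r": {"a": [0, 1, 2]}}, V=3)
        model, _ = fit_vanilla_lda(
            corpus, HyperParams(K=1, alpha=1.0, beta=0.1, n_iterations=2, seed=0)
        )
        theta = infer_theta(model, [0, 1])
        assert theta == pytest.approx([1.0])

    def test_all_oov_uniform_with_warning(self):
        corpus = corpus_from_token_lists({"r": {"a": [0, 1, 2]}}, V=3)
        model, _ = fit_vanilla_lda(
            corpus, HyperParams(K=2, alpha=1.0, beta=0.1, n_iterations=2, seed=0)
        )
        with pytest.warns(UserWarning, match="out of vocabulary"):
            theta = infer_theta(model, [99, 100])
        assert theta == pytest.approx([0.5, 0.5])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_peaked_phi_note_recovers_its_topic(self, seed):
        corpus, _, truth = generate_corpus(GeneratorConfig(n_records=4, seed=seed))
        K, V = 3, 30
        phi = np.full((K, V), 1e-4)
        for k in range(K):
            phi[k, k * 10 : (k + 1) * 10] = 0.1
        phi /= phi.sum(axis=1, keepdims=True)
        from rednotes.models import TopicModel

        model = TopicModel(phi=phi, theta=np.ones((1, K)) / K, doc_ids=[],
                           alpha=0.5, beta=0.01)
        rng = np.random.default_rng(seed)
        for j in range(K):
            note = rng.choice(np.arange(j * 10, (j + 1) * 10), size=40).tolist()
            theta = infer_theta(model, note, n_iterations=30, seed=seed)
            assert int(np.argmax(theta)) == j
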