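"""Dynamic topic model: softmax mapping, chain updates, EM behavior."""

import numpy as np
import pytest

from dtmtox import (DTMSimSpec, DynamicTopicModel, generate_dtm_corpus,
                    match_topics, softmax_probs)
from dtmtox.dtm import _build_chain, lda_init, update_topic_chain
from dtmtox.kalman import chain_geometry


class TestSoftmaxProbs:
    def test_uniform_for_constant_means(self):
        np.testing.assert_allclose(softmax_probs(np.zeros(4), np.zeros(4)), 0.25)

    def test_shift_invariance(self, rng):
        m = rng.normal(size=10)
        v = rng.uniform(0, 1, size=10)
        np.testing.assert_allclose(softmax_probs(m, v), softmax_probs(m + 7.3, v),
                                   atol=1e-12)

    def test_log_ratio_closed_form(self):
        p = softmax_probs(np.log([1.0, 2.0, 3.0]), np.zeros(3))
        np.testing.assert_allclose(p, [1 / 6, 2 / 6, 3 / 6])

    def test_variance_tilts_mass(self):
        # equal means: larger marginal variance means larger expected exp
        p = softmax_probs(np.zeros(2), np.array([0.0, 2.0]))
        assert p[1] > p[0]

    def test_no_overflow_for_large_means(self):
        p = softmax_probs(np.array([1e4, 1e4 - 1.0]))
        assert np.isfinite(p).all() and p.sum() == pytest.approx(1.0)


class TestChainUpdate:
    def geom(self, T=3, W=12):
        return chain_geometry(T, 0.01, 0.05, 1.0), T, W

    def test_zero_counts_revert_to_prior_mean(self, rng):
        geom, T, W = self.geom()
        chain = _build_chain(rng.normal(0, 2, size=(T, W)), geom)
        for _ in range(8):
            chain = update_topic_chain(chain, np.zeros((T, W)), np.zeros(T),
                                       geom, max_iter=50)
        assert np.abs(chain.mean).max() < 0.05

    def test_single_slice_matches_multinomial_mle(self, rng):
        # abundant counts, wide prior: fitted distribution ~ empirical
        geom = chain_geometry(1, 1e-3, 0.005, 50.0)
        counts = rng.integers(200, 2000, size=(1, 20)).astype(float)
        chain = _build_chain(np.zeros((1, 20)), geom)
        for _ in range(12):
            chain = update_topic_chain(chain, counts, counts.sum(axis=1),
                                       geom, max_iter=100)
        mle = counts[0] / counts.sum()
        tv = 0.5 * np.abs(chain.pi[0] - mle).sum()
        assert tv < 1e-3

    def test_ascent_contract(self, rng):
        from dtmtox.dtm import _chain_objective
        geom, T, W = self.geom()
        counts = rng.uniform(0, 50, size=(T, W))
        totals = counts.sum(axis=1)
        chain = _build_chain(rng.normal(0, 1, size=(T, W)), geom)
        before = _chain_objective(chain.mean, geom, counts, totals)
        chain2 = update_topic_chain(chain, counts, totals, geom)
        after = _chain_objective(chain2.mean, geom, counts, totals)
        assert after >= before - 1e-6 * abs(before)

    def test_negative_counts_rejected(self, rng):
        geom, T, W = self.geom()
        chain = _build_chain(np.zeros((T, W)), geom)
        with pytest.raises(ValueError):
            update_topic_chain(chain, -np.ones((T, W)), np.zeros(T), geom)


class TestLdaInit:
    def test_single_topic_is_pooled_frequency(self, tiny_corpus):
        corpus, _ = tiny_corpus
        geom = chain_geometry(corpus.n_slices, 0.005, 0.005, 5.0)
        chains = lda_init(corpus, 1, 0.01, geom, random_state=0)
        totals = np.zeros(corpus.n_words)
        for d in corpus.documents:
            totals[d.word_ids] += d.counts
        expected = totals / totals.sum()
        # chain smoothing shrinks slightly; compare on total variation
        tv = 0.5 * np.abs(chains[0].pi[0] - expected).sum()
        assert tv < 0.01

    def test_deterministic_given_seed(self, tiny_corpus):
        corpus, _ = tiny_corpus
        geom = chain_geometry(corpus.n_slices, 0.005, 0.005, 5.0)
        a = lda_init(corpus, 2, 0.01, geom, random_state=3)
        b = lda_init(corpus, 2, 0.01, geom, random_state=3)
        np.testing.assert_array_equal(a[0].mean, b[0].mean)
        np.testing.assert_array_equal(a[1].beta_hat, b[1].beta_hat)

    def test_no_zero_initial_probability(self, tiny_corpus):
        corpus, _ = tiny_corpus
        geom = chain_geometry(corpus.n_slices, 0.005, 0.005, 5.0)
        chains = lda_init(corpus, 3, 0.01, geom, random_state=0)
        for c in chains:
            assert c.pi.min() > 0


class TestFit:
    def test_normalization_invariants(self, tiny_fit):
        _, m = tiny_fit
        np.testing.assert_allclose(m.doc_topic_.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(m.topic_word_.sum(axis=2), 1.0, atol=1e-9)

    def test_elbo_nondecreasing(self, tiny_fit):
        _, m = tiny_fit
        t = m.elbo_trace_
        assert np.all(np.diff(t) >= -1e-6 * np.abs(t[:-1]))

    def test_seeded_determinism(self, tiny_corpus):
        corpus, _ = tiny_corpus
        a = DynamicTopicModel(n_topics=2, em_max_iter=5, random_state=9).fit(corpus)
        b = DynamicTopicModel(n_topics=2, em_max_iter=5, random_state=9).fit(corpus)
        np.testing.assert_array_equal(a.doc_topic_, b.doc_topic_)
        np.testing.assert_array_equal(a.topic_word_, b.topic_word_)
        np.testing.assert_array_equal(a.elbo_trace_, b.elbo_trace_)

    def test_transform_close_to_training_posteriors(self, tiny_fit):
        corpus, m = tiny_fit
        again = m.transform(corpus)
        # transform re-runs the E step from a cold start; ambiguous documents
        # may settle in a different basin, but almost all assignments agree
        same_argmax = (again.argmax(axis=1) == m.doc_topic_.argmax(axis=1))
        assert same_argmax.mean() >= 0.95

    def test_small_chain_variance_gives_smoother_topics(self, tiny_corpus):
        corpus, _ = tiny_corpus
        big = DynamicTopicModel(n_topics=2, alpha=0.05, chain_variance=0.05,
                                em_max_iter=20, random_state=0).fit(corpus)
        small = DynamicTopicModel(n_topics=2, alpha=0.05, chain_variance=0.005,
                                  em_max_iter=20, random_state=0).fit(corpus)

        def mean_tv(model):
            pi = model.topic_word_
            return 0.5 * np.abs(np.diff(pi, axis=0)).sum(axis=2).mean()

        assert mean_tv(small) < mean_tv(big)

    def test_time_sensitivity_vs_exchangeable_lda(self):
        # drifting topics: fitting the slices in reversed order must change
        # the per-slice word distributions, while pooled static LDA cannot
        # see the order at all
        from dtmtox import StaticLDA
        from dtmtox.corpus import Corpus, Document
        spec = DTMSimSpec(n_topics=2, n_words=40, n_slices=4, docs_per_slice=25,
                          tokens_per_doc=60, chain_variance=0.3, seed=13)
        corpus, _ = generate_dtm_corpus(spec)
        T = corpus.n_slices
        rev_docs = []
        for d in sorted(corpus.documents, key=lambda d: T - 1 - d.slice_index):
            rev_docs.append(Document(
                doc_id=d.doc_id, compound_id=d.compound_id,
                time_point=d.time_point, slice_index=T - 1 - d.slice_index,
                word_ids=d.word_ids, counts=d.counts))
        rev = Corpus(vocabulary=corpus.vocabulary, documents=rev_docs,
                     time_labels=list(range(T)))
        kw = dict(n_topics=2, alpha=0.05, chain_variance=0.3,
                  em_max_iter=20, random_state=0)
        fwd_fit = DynamicTopicModel(**kw).fit(corpus)
        rev_fit = DynamicTopicModel(**kw).fit(rev)
        # same slice index, reordered data: the dynamic model's slice-0
        # estimate now reflects the other end of the drift
        matching, _, _ = match_topics(fwd_fit.topic_word_, rev_fit.topic_word_)
        drift = max(
            0.5 * np.abs(fwd_fit.topic_word_[0, k]
                         - rev_fit.topic_word_[0, matching[k]]).sum()
            for k in range(2))
        assert drift > 0.05  # time order matters to the dynamic model

        pooled_fwd = StaticLDA(n_topics=2, random_state=0).fit(
            [(d.word_ids, d.counts) for d in corpus.documents])
        pooled_rev = StaticLDA(n_topics=2, random_state=0).fit(
            [(d.word_ids, d.counts) for d in rev_docs])
        assert np.abs(pooled_fwd.components_ - pooled_rev.components_).max() < 1e-6

    def test_empty_corpus_rejected(self, tiny_corpus):
        corpus, _ = tiny_corpus
        from dtmtox.corpus import Corpus
        empty = Corpus(vocabulary=corpus.vocabulary, documents=[], time_labels=[0])
        with pytest.raises(ValueError):
            DynamicTopicModel(n_topics=2).fit(empty)

    def test_bad_hyperparameters_rejected(self, tiny_corpus):
        corpus, _ = tiny_corpus
        with pytest.raises(ValueError):
            DynamicTopicModel(n_topics=0).fit(corpus)
        with pytest.raises(ValueError):
            DynamicTopicModel(alpha=0.0).fit(corpus)
        with pytest.raises(ValueError):
            DynamicTopicModel(chain_variance=-1.0).fit(corpus)

    def test_sklearn_param_interface(self):
        m = DynamicTopicModel(n_topics=7)
        assert m.get_params()["n_topics"] == 7
        m.set_params(alpha=0.5)
        assert m.alpha == 0.5
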