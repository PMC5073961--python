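"""Static latent Dirichlet allocation by variational EM.

Serves two roles: pooled-over-slices initialization of the dynamic model's
topic chains, and the degenerate single-slice model the dynamic model must
reduce to.  Topics are point estimates (multinomial rows); documents carry
a symmetric Dirichlet(alpha) prior over topic proportions, and inference is
the standard mean-field fixed point on (gamma, phi).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.special import gammaln, logsumexp, psi
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted, check_random_state

from .corpus import Corpus

logger = logging.getLogger(__name__)

__all__ = ["StaticLDA", "doc_e_step"]


def doc_e_step(counts, elog_doc, alpha, gamma0=None, max_iter=100, tol=1e-3):
    """Mean-field update for one document, given expected log topic-word terms.

    Parameters
    ----------
    counts : int array, shape (n,)
        Token counts of the document's distinct words.
    elog_doc : array, shape (K, n)
        E[log p(word | topic)] restricted to the document's words, taken at
        the document's time slice.
    alpha : float
        Symmetric Dirichlet concentration of the document-topic prior.
    gamma0 : array shape (K,), optional
        Warm start for the variational Dirichlet parameters.

    Returns
    -------
    gamma : (K,) variational Dirichlet parameters; satisfies
        ``sum(gamma) = K * alpha + counts.sum()`` exactly.
    phi : (K, n) per-word topic responsibilities (columns sum to 1).
    bound : float, this document's contribution to the ELBO.

    Iteration stops when mean ``|delta gamma|`` falls below ``tol``; the
    update order (phi from gamma, then gamma from phi) makes each sweep a
    pair of exact coordinate maximizations, so the bound cannot decrease
    from a warm start.
    """
    counts = np.asarray(counts, dtype=float)
    K = elog_doc.shape[0]
    N = counts.sum()
    if counts.size == 0:
        gamma = np.full(K, alpha)
        logger.debug("document with zero tokens: posterior equals prior")
        return gamma, np.zeros((K, 0)), 0.0

    gamma = np.full(K, alpha + N / K) if gamma0 is None else np.asarray(gamma0, float).copy()
    lphi = None
    for _ in range(max_iter):
        elog_theta = psi(gamma) - psi(gamma.sum())
        lphi = elog_theta[:, None] + elog_doc
        lphi -= logsumexp(lphi, axis=0, keepdims=True)
        phi = np.exp(lphi)
        new_gamma = alpha + phi @ counts
        delta = np.abs(new_gamma - gamma).mean()
        gamma = new_gamma
        if delta < tol:
            break
    phi = np.exp(lphi)
    elog_theta = psi(gamma) - psi(gamma.sum())
    token_term = float(
        np.sum(counts * np.sum(phi * (elog_doc + elog_theta[:, None] - lphi), axis=0))
    )
    theta_term = float(
        gammaln(K * alpha)
        - K * gammaln(alpha)
        + np.sum((alpha - gamma) * elog_theta)
        + np.sum(gammaln(gamma))
        - gammaln(gamma.sum())
    )
    return gamma, phi, token_term + theta_term


class StaticLDA(BaseEstimator):
    """Exchangeable (time-blind) LDA fitted by batch variational EM.

    Parameters
    ----------
    n_topics : int, default 20
    alpha : float, default 0.01
        Symmetric Dirichlet document-topic prior.
    em_max_iter, em_rel_tol : EM loop controls (relative bound change).
    doc_max_iter, doc_tol : per-document fixed-point controls.
    eps : probability floor applied to topic rows before taking logs.
    init : "random" (seeded gamma noise) or "docs" (each topic seeded from a
        maximally dissimilar document, k-means++ style — more reliable when
        documents are near-pure mixtures).
    init_components : optional (n_topics, n_words) matrix of initial topic
        probabilities; overrides the seeded random initialization.
    random_state : seed for the topic initialization.

    Attributes
    ----------
    components_ : (n_topics, n_words) topic-word probabilities.
    doc_topic_ : (n_docs, n_topics) normalized posterior topic mixtures.
    gamma_ : raw variational Dirichlet parameters.
    bound_trace_ : ELBO after each E sweep.
    converged_ : bool
    """

    def __init__(self, n_topics=20, alpha=0.01, em_max_iter=50, em_rel_tol=1e-4,
                 doc_max_iter=100, doc_tol=1e-3, eps=1e-12, init="random",
                 init_components=None, random_state=None):
        self.n_topics = n_topics
        self.alpha = alpha
        self.em_max_iter = em_max_iter
        self.em_rel_tol = em_rel_tol
        self.doc_max_iter = doc_max_iter
        self.doc_tol = doc_tol
        self.eps = eps
        self.init = init
        self.init_components = init_components
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _extract(corpus):
        if isinstance(corpus, Corpus):
            docs = [(d.word_ids, d.counts) for d in corpus.documents]
            n_words = corpus.n_words
        else:
            docs = [(np.asarray(i, dtype=np.int64), np.asarray(c, dtype=np.int64))
                    for i, c in corpus]
            n_words = 1 + max((int(i.max()) for i, _ in docs if i.size), default=0)
        if not docs:
            raise ValueError("corpus is empty")
        return docs, n_words

    def _floor_normalize(self, mat):
        mat = np.maximum(mat, self.eps)
        return mat / mat.sum(axis=1, keepdims=True)

    @staticmethod
    def _doc_seeded_topics(docs, W, K, rng):
        """Seed each topic from a document, greedily picking documents that
        are maximally dissimilar (cosine) to those already picked."""
        freqs = np.zeros((len(docs), W))
        for d, (ids, cts) in enumerate(docs):
            if ids.size:
                freqs[d, ids] = cts
        norms = np.linalg.norm(freqs, axis=1)
        norms[norms == 0] = 1.0
        unit = freqs / norms[:, None]
        picks = [int(rng.randint(len(docs)))]
        max_sim = unit @ unit[picks[0]]
        while len(picks) < min(K, len(docs)):
            nxt = int(np.argmin(max_sim))
            picks.append(nxt)
            max_sim = np.maximum(max_sim, unit @ unit[nxt])
        topics = np.full((K, W), 1.0 / W)
        for k, d in enumerate(picks):
            total = freqs[d].sum()
            if total > 0:
                topics[k] += freqs[d] / total
        # tiny seeded jitter so duplicate picks cannot make topics identical
        topics *= rng.uniform(0.98, 1.02, size=topics.shape)
        return topics / topics.sum(axis=1, keepdims=True)

    # -- estimator API -----------------------------------------------------
    def fit(self, corpus, y=None):
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        docs, W = self._extract(corpus)
        if self.n_topics > len(docs):
            warnings.warn(f"n_topics={self.n_topics} exceeds number of documents ({len(docs)})")
        K = self.n_topics
        if self.init_components is not None:
            topics = self._floor_normalize(np.asarray(self.init_components, float))
            if topics.shape != (K, W):
                raise ValueError(f"init_components must have shape {(K, W)}")
        else:
            rng = check_random_state(self.random_state)
            if self.init == "docs":
                topics = self._floor_normalize(
                    self._doc_seeded_topics(docs, W, K, rng))
            elif self.init == "random":
                topics = self._floor_normalize(rng.gamma(100.0, 0.01, size=(K, W)))
            else:
                raise ValueError(f"unknown init {self.init!r}")
        elog = np.log(topics)

        gammas = [None] * len(docs)
        trace = []
        self.converged_ = False
        for it in range(self.em_max_iter):
            ewc = np.zeros((K, W))
            bound = 0.0
            new_gammas = []
            for d, (ids, cts) in enumerate(docs):
                g, phi, b = doc_e_step(cts, elog[:, ids], self.alpha, gammas[d],
                                       self.doc_max_iter, self.doc_tol)
                new_gammas.append(g)
                bound += b
                if ids.size:
                    np.add.at(ewc, (slice(None), ids), phi * cts)
            gammas = new_gammas
            trace.append(bound)
            if it > 0 and abs(trace[-1] - trace[-2]) <= self.em_rel_tol * abs(trace[-2]):
                self.converged_ = True
                break
            topics = self._floor_normalize(ewc)
            elog = np.log(topics)

        self.components_ = topics
        self.gamma_ = np.vstack(gammas)
        self.doc_topic_ = self.gamma_ / self.gamma_.sum(axis=1, keepdims=True)
        self.bound_trace_ = np.array(trace)
        self.bound_ = trace[-1]
        self.n_iter_ = len(trace)
        return self

    def transform(self, corpus):
        """Posterior topic mixtures for (possibly new) documents, topics fixed."""
        check_is_fitted(self, "components_")
        docs, _ = self._extract(corpus)
        elog = np.log(self.components_)
        out = np.empty((len(docs), self.n_topics))
        for d, (ids, cts) in enumerate(docs):
            g, _, _ = doc_e_step(cts, elog[:, ids], self.alpha, None,
                                 self.doc_max_iter, self.doc_tol)
            out[d] = g / g.sum()
        return out

    def fit_transform(self, corpus, y=None):
        return self.fit(corpus).doc_topic_
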