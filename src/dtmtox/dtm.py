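"""Dynamic topic model with variational Kalman inference.

Topics are chains of natural-parameter vectors beta_{t,k,.} following a
Gaussian random walk across time slices (transition variance
``chain_variance``); documents within a slice follow standard LDA with a
symmetric Dirichlet(alpha) prior over topic proportions.  Inference is
variational EM: the E step runs the mean-field (gamma, phi) fixed point per
document against E[log p(w | topic, slice)]; the M step updates each
topic's pseudo-observations beta_hat by maximizing the chain's contribution
to the ELBO, with the chain posterior recovered by Kalman smoothing and the
softmax normalizer handled through the zeta bound
``E[log sum_w exp beta_w] <= log sum_w exp(m~_w + V~_w / 2)``.

Both steps are exact coordinate ascents on one ELBO, so the recorded trace
is non-decreasing up to floating-point noise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted, check_random_state

from .corpus import Corpus
from .kalman import ChainGeometry, chain_geometry, kalman_smooth
from .lda import StaticLDA, doc_e_step

logger = logging.getLogger(__name__)

__all__ = ["DynamicTopicModel", "TopicChain", "softmax_probs", "lda_init",
           "update_topic_chain"]


def softmax_probs(mean, variance=None):
    """Map Gaussian natural-parameter marginals to a probability vector.

    ``pi_w`` is proportional to ``exp(mean_w + variance_w / 2)`` — the
    expected-exponential form of the zeta bound — computed in log space.
    A constant shift of the means leaves the result unchanged.
    """
    x = np.asarray(mean, dtype=float)
    if variance is not None:
        x = x + 0.5 * np.asarray(variance, dtype=float)
    return np.exp(x - logsumexp(x, axis=-1, keepdims=True))


@dataclass
class TopicChain:
    """Variational state of one topic's chain over time slices."""

    beta_hat: np.ndarray  # pseudo-observations, (T, W)
    mean: np.ndarray  # smoothed means m~, (T, W)
    variance: np.ndarray  # smoothed variances V~, (T,) (shared across words)
    filtered_mean: np.ndarray
    filtered_variance: np.ndarray
    log_zeta: np.ndarray  # (T,)
    kl: float  # KL(q || p) of this chain

    @property
    def elog(self) -> np.ndarray:
        """E[log p(word | topic)] lower-bound terms, (T, W)."""
        return self.mean - self.log_zeta[:, None]

    @property
    def pi(self) -> np.ndarray:
        """Per-slice topic-word probabilities, (T, W)."""
        return softmax_probs(self.mean, self.variance[:, None])


def _build_chain(beta_hat, geom: ChainGeometry) -> TopicChain:
    sm = kalman_smooth(beta_hat, geom.nu, geom.chain_variance, geom.init_variance)
    log_zeta = 0.5 * sm.variance + logsumexp(sm.mean, axis=1)
    return TopicChain(
        beta_hat=np.asarray(beta_hat, dtype=float),
        mean=sm.mean,
        variance=sm.variance,
        filtered_mean=sm.filtered_mean,
        filtered_variance=sm.filtered_variance,
        log_zeta=log_zeta,
        kl=geom.kl(sm.mean),
    )


def _chain_objective(mean, geom: ChainGeometry, counts, totals):
    """Per-topic ELBO contribution as a function of the smoothed means."""
    lse = logsumexp(mean, axis=1)
    log_zeta = 0.5 * geom.smoothed_variance + lse
    ll = float(np.sum(counts * mean) - totals @ log_zeta)
    return ll - geom.kl(mean)


def update_topic_chain(chain: TopicChain, expected_counts, totals,
                       geom: ChainGeometry, max_iter: int = 15) -> TopicChain:
    """M-step for one topic: ascend the chain bound in the pseudo-observations.

    ``expected_counts[t, w]`` is ``sum_d c_{d,w} phi_{d,w,k}`` over documents
    of slice t and ``totals`` its row sums.  The objective (token term minus
    chain KL) is concave in ``beta_hat`` because the smoothed means are a
    fixed linear map of the observations; L-BFGS with analytic gradient is
    run for ``max_iter`` iterations and the update is accepted only if the
    bound did not decrease, so the ascent contract holds by construction.
    """
    counts = np.asarray(expected_counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if np.any(counts < 0):
        raise ValueError("expected counts must be non-negative")
    S = geom.smoother
    Lp = geom.prior_precision
    Vt = geom.smoothed_variance
    T, W = counts.shape

    def neg_f(beta_flat):
        B = beta_flat.reshape(T, W)
        m = S @ B
        lse = logsumexp(m, axis=1)
        sm = np.exp(m - lse[:, None])
        log_zeta = 0.5 * Vt + lse
        Lm = Lp @ m
        f = (np.sum(counts * m) - totals @ log_zeta
             - W * geom.kl_const - 0.5 * np.sum(m * Lm))
        grad_m = counts - totals[:, None] * sm - Lm
        if not np.isfinite(f):
            raise FloatingPointError("non-finite topic bound during M step")
        return -f, -(S.T @ grad_m).ravel()

    f0 = -neg_f(chain.beta_hat.ravel())[0]
    res = minimize(neg_f, chain.beta_hat.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter})
    if -res.fun >= f0:
        new = _build_chain(res.x.reshape(T, W), geom)
    else:  # line search failed to improve; keep the current chain
        new = replace(chain)
    return new


def lda_init(corpus, n_topics, alpha, geom: ChainGeometry, eps=1e-12,
             lda_iters=20, random_state=None):
    """Initialize topic chains from a pooled (time-blind) static LDA fit.

    Every slice of chain k starts at the centered log of the epsilon-floored
    static topic k; smoothing then yields the initial variational state.
    Deterministic given ``random_state``.
    """
    lda = StaticLDA(n_topics=n_topics, alpha=alpha, em_max_iter=lda_iters,
                    eps=eps, init="docs", random_state=random_state).fit(corpus)
    chains = []
    for k in range(n_topics):
        logp = np.log(np.maximum(lda.components_[k], eps))
        logp = logp - logp.mean()
        beta_hat = np.tile(logp, (geom.T, 1))
        chains.append(_build_chain(beta_hat, geom))
    return chains


class DynamicTopicModel(BaseEstimator):
    """Dynamic topic model estimator (scikit-learn style).

    Parameters
    ----------
    n_topics : int, default 20
        Number of topics K.
    alpha : float, default 0.01
        Symmetric Dirichlet prior on document topic proportions; smaller
        values concentrate each document on fewer topics.
    chain_variance : float, default 0.005
        Transition variance sigma^2 of the topic chains; smaller values give
        more similar word distributions across consecutive time points.
    init_variance : float or None
        Variance of the pre-first-slice state; defaults to
        ``1000 * chain_variance`` (a wide, near-uninformative start).
    obs_variance : float, default 0.005
        Variance of the variational pseudo-observations, fixed (not
        optimized).  Small values reflect the high-information per-slice
        counts of fold-change-scaled corpora.
    em_max_iter, em_rel_tol : EM loop controls.
    doc_max_iter, doc_tol : per-document fixed-point controls.
    m_step_iter : int, inner L-BFGS iterations per topic per M step.
    eps : probability floor before any log.
    n_init : int, default 1
        Number of seeded restarts; the run with the highest final ELBO wins.
    random_state : seed driving the (static LDA) initialization.

    Attributes
    ----------
    doc_topic_ : (n_docs, n_topics) posterior P(T|D), rows sum to 1.
    topic_word_ : (n_slices, n_topics, n_words) per-slice P(W|T)_t,
        rows sum to 1.
    elbo_trace_ : ELBO after each E sweep (non-decreasing within tolerance).
    doc_bound_ : document-side (data likelihood) part of the final ELBO.
    chain_kl_ : summed topic-chain KL part of the final ELBO.
    chains_ : list of :class:`TopicChain`.
    converged_, n_iter_, gamma_, slice_sizes_, time_labels_
    """

    def __init__(self, n_topics=20, alpha=0.01, chain_variance=0.005,
                 init_variance=None, obs_variance=0.005,
                 em_max_iter=50, em_rel_tol=1e-4,
                 doc_max_iter=100, doc_tol=1e-3, m_step_iter=15,
                 init_lda_iter=20, eps=1e-12, n_init=1, random_state=None):
        self.n_topics = n_topics
        self.alpha = alpha
        self.chain_variance = chain_variance
        self.init_variance = init_variance
        self.obs_variance = obs_variance
        self.em_max_iter = em_max_iter
        self.em_rel_tol = em_rel_tol
        self.doc_max_iter = doc_max_iter
        self.doc_tol = doc_tol
        self.m_step_iter = m_step_iter
        self.init_lda_iter = init_lda_iter
        self.eps = eps
        self.n_init = n_init
        self.random_state = random_state

    def _validate(self):
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.chain_variance <= 0 or self.obs_variance <= 0:
            raise ValueError("variances must be > 0")
        if self.em_rel_tol <= 0 or self.doc_tol <= 0:
            raise ValueError("tolerances must be > 0")

    @staticmethod
    def _extract(corpus: Corpus):
        if not isinstance(corpus, Corpus):
            raise TypeError("fit expects a Corpus")
        if len(corpus) == 0:
            raise ValueError("corpus is empty")
        docs = [(d.slice_index, d.word_ids, d.counts) for d in corpus.documents]
        return docs, corpus.n_slices, corpus.n_words

    def fit(self, corpus: Corpus, y=None):
        """Fit by variational EM; with ``n_init > 1`` the fit is restarted
        from different seeded initializations and the run with the highest
        final ELBO is kept."""
        self._validate()
        rng = check_random_state(self.random_state)
        seeds = [rng.randint(np.iinfo(np.int32).max)
                 for _ in range(max(1, self.n_init))]
        best = None
        for init_seed in seeds:
            state = self._fit_once(corpus, init_seed)
            if best is None or state["elbo_trace_"][-1] > best["elbo_trace_"][-1]:
                best = state
        for key, value in best.items():
            setattr(self, key, value)
        return self

    def _fit_once(self, corpus: Corpus, init_seed: int) -> dict:
        docs, T, W = self._extract(corpus)
        K = self.n_topics
        if K > len(docs):
            warnings.warn(f"n_topics={K} exceeds number of documents ({len(docs)})")
        sigma0 = (1000.0 * self.chain_variance if self.init_variance is None
                  else self.init_variance)
        geom = chain_geometry(T, self.obs_variance, self.chain_variance, sigma0)
        chains = lda_init(corpus, K, self.alpha, geom, eps=self.eps,
                          lda_iters=self.init_lda_iter, random_state=init_seed)

        elog = np.stack([c.elog for c in chains], axis=1)  # (T, K, W)
        gammas = [None] * len(docs)
        trace = []
        doc_bound = np.nan
        converged = False
        for it in range(self.em_max_iter):
            ewc = np.zeros((K, T, W))
            doc_bound = 0.0
            new_gammas = []
            for d, (s, ids, cts) in enumerate(docs):
                g, phi, b = doc_e_step(cts, elog[s][:, ids], self.alpha, gammas[d],
                                       self.doc_max_iter, self.doc_tol)
                new_gammas.append(g)
                doc_bound += b
                if ids.size:
                    np.add.at(ewc[:, s, :], (slice(None), ids), phi * cts)
            gammas = new_gammas
            kl = sum(c.kl for c in chains)
            trace.append(doc_bound - kl)
            logger.debug("EM iter %d: ELBO %.4f (doc %.4f, chain KL %.4f)",
                         it, trace[-1], doc_bound, kl)
            if it > 0 and abs(trace[-1] - trace[-2]) <= self.em_rel_tol * abs(trace[-2]):
                converged = True
                break
            totals = ewc.sum(axis=2)  # (K, T)
            chains = [
                update_topic_chain(chains[k], ewc[k], totals[k], geom,
                                   self.m_step_iter)
                for k in range(K)
            ]
            elog = np.stack([c.elog for c in chains], axis=1)
        if not converged:
            warnings.warn(f"EM did not converge in {self.em_max_iter} iterations")

        gamma = np.vstack(gammas)
        return {
            "converged_": converged,
            "geometry_": geom,
            "chains_": chains,
            "gamma_": gamma,
            "doc_topic_": gamma / gamma.sum(axis=1, keepdims=True),
            "topic_word_": np.stack([c.pi for c in chains], axis=1),  # (T,K,W)
            "elbo_trace_": np.array(trace),
            "doc_bound_": doc_bound,
            "chain_kl_": float(sum(c.kl for c in chains)),
            "n_iter_": len(trace),
            "doc_ids_": [getattr(d, "doc_id", str(i))
                         for i, d in enumerate(corpus.documents)],
            "time_labels_": list(corpus.time_labels),
            "slice_sizes_": corpus.slice_sizes,
            "vocabulary_": corpus.vocabulary,
        }

    def transform(self, corpus: Corpus):
        """Posterior P(T|D) for documents under the fitted topic chains."""
        check_is_fitted(self, "chains_")
        docs, T, W = self._extract(corpus)
        if T > len(self.time_labels_) or W != self.topic_word_.shape[2]:
            raise ValueError("corpus is not aligned with the fitted model")
        elog = np.stack([c.elog for c in self.chains_], axis=1)
        out = np.empty((len(docs), self.n_topics))
        for d, (s, ids, cts) in enumerate(docs):
            g, _, _ = doc_e_step(cts, elog[s][:, ids], self.alpha, None,
                                 self.doc_max_iter, self.doc_tol)
            out[d] = g / g.sum()
        return out

    def fit_transform(self, corpus: Corpus, y=None):
        return self.fit(corpus).doc_topic_
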