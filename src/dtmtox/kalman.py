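"""Variational Kalman smoothing for topic chains.

Each topic's natural parameters follow a Gaussian random walk over time
slices: beta_1 ~ N(0, sigma0^2 + sigma^2) and beta_t | beta_{t-1} ~
N(beta_{t-1}, sigma^2), independently per word.  The variational family
treats per-slice pseudo-observations beta_hat_t with variance nu_t as noisy
readings of the chain; the posterior is obtained by a forward filter and
backward (RTS) smoother.  Because nu is shared across words, the posterior
variances depend only on the slice, not the word.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["kalman_smooth", "ChainGeometry", "chain_geometry", "SmoothResult"]


@dataclass
class SmoothResult:
    mean: np.ndarray  # smoothed means m~, shape (T,) or (T, W)
    variance: np.ndarray  # smoothed variances V~, shape (T,)
    filtered_mean: np.ndarray  # forward means m, same shape as mean
    filtered_variance: np.ndarray  # forward variances V, shape (T,)


def _as_nu(nu, T):
    nu = np.broadcast_to(np.asarray(nu, dtype=float), (T,)).copy()
    if np.any(nu <= 0):
        raise ValueError("observation variances must be > 0")
    return nu


def kalman_smooth(beta_hat, nu, chain_variance, init_variance) -> SmoothResult:
    """Forward-filter / backward-smooth a chain of pseudo-observations.

    Parameters
    ----------
    beta_hat : array, shape (T,) or (T, W)
        Variational observations per slice (optionally per word).
    nu : scalar or array shape (T,)
        Observation variances.
    chain_variance : float
        Transition variance sigma^2 of the random walk.
    init_variance : float
        Variance sigma0^2 of the pre-first-slice state (the slice-1 prior
        variance is ``init_variance + chain_variance``).
    """
    beta_hat = np.atleast_1d(np.asarray(beta_hat, dtype=float))
    squeeze = beta_hat.ndim == 1
    if squeeze:
        beta_hat = beta_hat[:, None]
    T = beta_hat.shape[0]
    if T < 1:
        raise ValueError("need at least one slice")
    if chain_variance <= 0 or init_variance <= 0:
        raise ValueError("chain and initial variances must be > 0")
    nu = _as_nu(nu, T)

    m = np.zeros_like(beta_hat)
    V = np.zeros(T)
    m_prev = np.zeros(beta_hat.shape[1])
    V_prev = init_variance
    for t in range(T):
        P = V_prev + chain_variance
        denom = P + nu[t]
        m[t] = (nu[t] * m_prev + P * beta_hat[t]) / denom
        V[t] = nu[t] * P / denom
        m_prev, V_prev = m[t], V[t]

    ms = np.empty_like(m)
    Vs = np.empty(T)
    ms[-1] = m[-1]
    Vs[-1] = V[-1]
    for t in range(T - 2, -1, -1):
        g = chain_variance / (V[t] + chain_variance)  # 1 - smoother gain
        ms[t] = g * m[t] + (1.0 - g) * ms[t + 1]
        J = V[t] / (V[t] + chain_variance)
        Vs[t] = V[t] + J * J * (Vs[t + 1] - (V[t] + chain_variance))

    if squeeze:
        m, ms = m[:, 0], ms[:, 0]
    return SmoothResult(mean=ms, variance=Vs, filtered_mean=m, filtered_variance=V)


@dataclass
class ChainGeometry:
    """Slice-level matrices shared by every word of a chain.

    ``prior_precision`` is the tridiagonal precision of the random-walk
    prior; ``posterior_cov`` the (dense, T x T) posterior covariance under
    the pseudo-observation model; ``smoother`` the linear map from
    observations to smoothed means (``m~ = smoother @ beta_hat``); and
    ``kl_const`` the per-word, mean-independent part of KL(q || p):
    0.5 * (tr(Lambda_p Sigma_q) - T + log det Sigma_p - log det Sigma_q).
    """

    T: int
    nu: np.ndarray
    chain_variance: float
    init_variance: float
    prior_precision: np.ndarray
    posterior_cov: np.ndarray
    smoother: np.ndarray
    smoothed_variance: np.ndarray
    kl_const: float

    def kl(self, smoothed_mean) -> float:
        """KL(q || p) for a chain, summed over words.

        ``smoothed_mean`` has shape (T,) or (T, W); the mean-dependent part
        is 0.5 * m~' Lambda_p m~ per word.
        """
        m = np.atleast_2d(np.asarray(smoothed_mean, dtype=float).T).T  # (T, W)
        quad = 0.5 * float(np.sum(m * (self.prior_precision @ m)))
        W = m.shape[1]
        return W * self.kl_const + quad


def chain_geometry(T, nu, chain_variance, init_variance) -> ChainGeometry:
    nu = _as_nu(nu, T)
    s1 = init_variance + chain_variance
    Lp = np.zeros((T, T))
    Lp[0, 0] = 1.0 / s1
    for t in range(T - 1):
        Lp[t, t] += 1.0 / chain_variance
        Lp[t + 1, t + 1] += 1.0 / chain_variance
        Lp[t, t + 1] -= 1.0 / chain_variance
        Lp[t + 1, t] -= 1.0 / chain_variance
    Lq = Lp + np.diag(1.0 / nu)
    Sq = np.linalg.inv(Lq)
    smoother = Sq @ np.diag(1.0 / nu)
    sign_p, logdet_Lp = np.linalg.slogdet(Lp)
    sign_q, logdet_Lq = np.linalg.slogdet(Lq)
    if sign_p <= 0 or sign_q <= 0:
        raise ValueError("prior/posterior precision not positive definite")
    # log det Sigma_p - log det Sigma_q = logdet(Lq) - logdet(Lp)
    kl_const = 0.5 * (np.trace(Lp @ Sq) - T + logdet_Lq - logdet_Lp)
    return ChainGeometry(
        T=T,
        nu=nu,
        chain_variance=chain_variance,
        init_variance=init_variance,
        prior_precision=Lp,
        posterior_cov=Sq,
        smoother=smoother,
        smoothed_variance=np.diag(Sq).copy(),
        kl_const=float(kl_const),
    )
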