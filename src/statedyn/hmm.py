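"""Exact discrete-state inference for hidden Markov chains.

Scaled forward-backward smoothing and Viterbi decoding over log emission
scores. These are the inner discrete-inference primitives of the switching
linear dynamical system: the continuous latent subspace supplies per-state
expected log emissions, and the chain posterior (gamma, xi) comes from here.

All routines operate on a leading batch axis so that a cohort of subjects
with equal run length can be smoothed in one pass.
"""

from __future__ import annotations

import numpy as np

from ._utils import check_prob_vector, check_stochastic_matrix


def forward_backward(log_emissions: np.ndarray, transition: np.ndarray,
                     initial: np.ndarray):
    """HMM smoothing for a single sequence.

    Parameters
    ----------
    log_emissions : (T, K) array
        Log emission score of each state at each time point. Need not be
        normalized densities; any finite scores are accepted.
    transition : (K, K) row-stochastic matrix.
    initial : (K,) initial state distribution.

    Returns
    -------
    gamma : (T, K) posterior state probabilities (rows sum to 1).
    xi : (T-1, K, K) pairwise posteriors; ``xi[t].sum()`` is 1 and
        ``xi[t].sum(axis=1) == gamma[t]`` up to numerical tolerance.
    log_evidence : float, log of the total emission-weighted chain probability.
    """
    logb = np.asarray(log_emissions, dtype=float)
    if not np.all(np.isfinite(logb)):
        raise ValueError("log emissions must be finite")
    pi = check_stochastic_matrix(transition)
    p0 = check_prob_vector(initial)
    gamma, xi, logz = _forward_backward_batch(logb[None], pi, p0)
    return gamma[0], xi[0], float(logz[0])


def _forward_backward_batch(logb: np.ndarray, pi: np.ndarray, p0: np.ndarray):
    """Scaled forward-backward over a batch: logb (S, T, K) -> (gamma, xi, logz)."""
    s, t_len, k = logb.shape
    # per-timepoint max-shift keeps exp() in range regardless of emission scale
    shift = logb.max(axis=2, keepdims=True)
    b = np.exp(logb - shift)

    alpha = np.empty((s, t_len, k))
    c = np.empty((s, t_len))
    a0 = p0[None, :] * b[:, 0]
    c[:, 0] = a0.sum(axis=1)
    alpha[:, 0] = a0 / c[:, 0, None]
    for t in range(1, t_len):
        a = (alpha[:, t - 1] @ pi) * b[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]

    beta = np.empty((s, t_len, k))
    beta[:, -1] = 1.0
    xi = np.empty((s, t_len - 1, k, k))
    for t in range(t_len - 2, -1, -1):
        bb = b[:, t + 1] * beta[:, t + 1]
        # joint over (s_t, s_{t+1}) before normalization
        j = alpha[:, t, :, None] * pi[None] * bb[:, None, :]
        xi[:, t] = j / j.sum(axis=(1, 2))[:, None, None]
        beta[:, t] = (bb @ pi.T) / c[:, t + 1, None]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    logz = np.log(c).sum(axis=1) + shift[:, :, 0].sum(axis=1)
    return gamma, xi, logz


def viterbi(log_emissions: np.ndarray, transition: np.ndarray,
            initial: np.ndarray) -> np.ndarray:
    """Most probable state path (max-product decoding), 0-based labels."""
    logb = np.asarray(log_emissions, dtype=float)
    pi = check_stochastic_matrix(transition)
    p0 = check_prob_vector(initial)
    t_len, k = logb.shape
    with np.errstate(divide="ignore"):
        logpi = np.log(pi)
        delta = np.log(p0) + logb[0]
    back = np.zeros((t_len, k), dtype=int)
    for t in range(1, t_len):
        cand = delta[:, None] + logpi
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(k)] + logb[t]
    path = np.empty(t_len, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(t_len - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of an ergodic chain (left Perron eigenvector)."""
    pi = check_stochastic_matrix(transition)
    w, v = np.linalg.eig(pi.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    p = np.real(v[:, i])
    p = np.abs(p)
    return p / p.sum()
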