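"""Linear-Gaussian latent-chain inference.

Two complementary solvers:

* :func:`kalman_smoother` — classical Kalman filter + RTS smoother for a
  single-regime linear dynamical system, with the exact marginal
  log-likelihood from the prediction-error decomposition.
* :func:`solve_gaussian_chain` — batched information-form solver for a
  block-tridiagonal Gaussian (a Markov chain of d-dimensional Gaussians with
  arbitrary pairwise quadratic couplings). This is the inner continuous
  E-step of the switching model, where responsibilities mix the per-state
  dynamics into time-varying precision blocks.
"""

from __future__ import annotations

import numpy as np

from ._utils import check_psd


def kalman_smoother(y: np.ndarray, A: np.ndarray, Q: np.ndarray, C: np.ndarray,
                    R: np.ndarray, mu0: np.ndarray | None = None,
                    S0: np.ndarray | None = None):
    """RTS smoothing for ``x_t = A x_{t-1} + w_t``, ``y_t = C x_t + v_t``.

    ``R`` may be a full (R, R) covariance or a length-R vector of diagonal
    observation variances. Returns ``(means, covs, crosscovs, loglik)`` where
    ``crosscovs[t] = Cov(x_{t+1}, x_t | y_{1:T})`` has shape (T-1, d, d).
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    t_len, r = y.shape
    A = np.asarray(A, dtype=float)
    d = A.shape[0]
    C = np.asarray(C, dtype=float).reshape(r, d)
    Q = check_psd(np.asarray(Q, dtype=float), "Q")
    R = np.asarray(R, dtype=float)
    R_full = np.diag(R) if R.ndim == 1 else check_psd(R, "R")
    mu0 = np.zeros(d) if mu0 is None else np.asarray(mu0, dtype=float)
    S0 = np.eye(d) if S0 is None else check_psd(np.asarray(S0, dtype=float), "S0")

    mu_f = np.empty((t_len, d))
    V_f = np.empty((t_len, d, d))
    mu_p = np.empty((t_len, d))
    V_p = np.empty((t_len, d, d))
    loglik = 0.0
    m_pred, v_pred = mu0, S0
    for t in range(t_len):
        mu_p[t], V_p[t] = m_pred, v_pred
        s = C @ v_pred @ C.T + R_full
        s = 0.5 * (s + s.T)
        innov = y[t] - C @ m_pred
        sol = np.linalg.solve(s, innov)
        sign, logdet = np.linalg.slogdet(s)
        loglik += -0.5 * (r * np.log(2 * np.pi) + logdet + innov @ sol)
        gain = v_pred @ C.T @ np.linalg.inv(s)
        mu_f[t] = m_pred + gain @ innov
        V_f[t] = v_pred - gain @ s @ gain.T
        V_f[t] = 0.5 * (V_f[t] + V_f[t].T)
        m_pred = A @ mu_f[t]
        v_pred = A @ V_f[t] @ A.T + Q

    means = np.empty((t_len, d))
    covs = np.empty((t_len, d, d))
    cross = np.empty((max(t_len - 1, 0), d, d))
    means[-1], covs[-1] = mu_f[-1], V_f[-1]
    for t in range(t_len - 2, -1, -1):
        j = V_f[t] @ A.T @ np.linalg.inv(V_p[t + 1])
        means[t] = mu_f[t] + j @ (means[t + 1] - mu_p[t + 1])
        covs[t] = V_f[t] + j @ (covs[t + 1] - V_p[t + 1]) @ j.T
        covs[t] = 0.5 * (covs[t] + covs[t].T)
        cross[t] = covs[t + 1] @ j.T  # Cov(x_{t+1}, x_t)
    return means, covs, cross, float(loglik)


def solve_gaussian_chain(j_diag: np.ndarray, j_off: np.ndarray, h: np.ndarray):
    """Posterior moments of a batch of block-tridiagonal Gaussians.

    The density is ``exp(-0.5 x' J x + h' x)`` with ``J`` block-tridiagonal:
    diagonal blocks ``j_diag[:, t]`` and upper off-diagonal blocks
    ``j_off[:, t] = J[t, t+1]``.

    Parameters
    ----------
    j_diag : (S, T, d, d), j_off : (S, T-1, d, d), h : (S, T, d)

    Returns
    -------
    means : (S, T, d)
    covs : (S, T, d, d) marginal covariances
    cross : (S, T-1, d, d) ``Cov(x_t, x_{t+1})``
    logdet : (S,) log-determinant of J (for Gaussian entropy/normalizer).
    """
    s, t_len, d, _ = j_diag.shape
    jt = np.empty_like(j_diag)   # forward-eliminated diagonal blocks
    ht = np.empty_like(h)
    jt[:, 0] = j_diag[:, 0]
    ht[:, 0] = h[:, 0]
    # cache M_t = jt[t]^{-1} @ [j_off[t] | ht[t]] to reuse in the back pass
    sol_off = np.empty((s, t_len - 1, d, d))
    sol_h = np.empty((s, t_len, d))
    for t in range(1, t_len):
        rhs = np.concatenate([j_off[:, t - 1], ht[:, t - 1, :, None]], axis=2)
        sol = np.linalg.solve(jt[:, t - 1], rhs)
        sol_off[:, t - 1] = sol[:, :, :d]
        sol_h[:, t - 1] = sol[:, :, d]
        jt[:, t] = j_diag[:, t] - np.swapaxes(j_off[:, t - 1], 1, 2) @ sol_off[:, t - 1]
        ht[:, t] = h[:, t] - np.einsum("sij,si->sj", j_off[:, t - 1], sol_h[:, t - 1])

    means = np.empty((s, t_len, d))
    covs = np.empty((s, t_len, d, d))
    cross = np.empty((s, t_len - 1, d, d))
    sign, logdet_last = np.linalg.slogdet(jt[:, -1])
    covs[:, -1] = np.linalg.inv(jt[:, -1])
    means[:, -1] = np.einsum("sij,sj->si", covs[:, -1], ht[:, -1])
    logdet = logdet_last
    for t in range(t_len - 2, -1, -1):
        inv_jt = np.linalg.inv(jt[:, t])
        sgn, ld = np.linalg.slogdet(jt[:, t])
        logdet = logdet + ld
        g = inv_jt @ j_off[:, t]
        means[:, t] = sol_h[:, t] - np.einsum("sij,sj->si", g, means[:, t + 1])
        covs[:, t] = inv_jt + g @ covs[:, t + 1] @ np.swapaxes(g, 1, 2)
        covs[:, t] = 0.5 * (covs[:, t] + np.swapaxes(covs[:, t], 1, 2))
        cross[:, t] = -g @ covs[:, t + 1]  # Cov(x_t, x_{t+1})
    return means, covs, cross, logdet
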