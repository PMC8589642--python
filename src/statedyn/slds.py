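"""Switching linear dynamical system with Markov switching (the latent
brain-state model).

Generative model, shared across subjects: a hidden Markov chain s_t with
transition matrix Pi selects among K linear-Gaussian regimes in a
d-dimensional latent subspace,

    x_t = A_{s_t} x_{t-1} + w_t,   w_t ~ N(0, Q_{s_t}),   x_1 ~ N(0, I),
    y_t = C x_t + v_t,             v_t ~ N(0, diag(r)),

with loading C shared across states so that each state is "a unique
dynamical process in a common latent subspace". Subjects contribute
independent chains (no transition across subject boundaries; the initial
distribution re-applies per subject) under shared parameters, so state
labels are comparable across the cohort.

Inference is structured variational EM: q(s) q(x) coordinate ascent with
exact HMM forward-backward over states given expected per-state dynamics
scores, exact block-tridiagonal Gaussian smoothing of the latent
trajectory given responsibilities, and closed-form M-steps for point
estimates of the parameters. The evidence lower bound (ELBO) is monotone
across iterations up to the tiny ridge used to regularize covariance
M-steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from ._utils import derive_seed, spectral_radius
from .hmm import _forward_backward_batch, viterbi
from .kalman import solve_gaussian_chain

RIDGE = 1e-6
PRUNE_THRESHOLD = 1e-3
LOG2PI = np.log(2.0 * np.pi)


@dataclass
class SwitchingLDSModel:
    """Fitted group-level parameters of the switching LDS."""
    K: int
    d: int
    C: np.ndarray                 # (R, d) shared loading
    A: np.ndarray                 # (K, d, d) per-state dynamics
    Q: np.ndarray                 # (K, d, d) per-state process covariance
    r_obs: np.ndarray             # (R,) diagonal observation variances
    Pi: np.ndarray                # (K, K) transition matrix
    pi0: np.ndarray               # (K,) initial state distribution
    elbo_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = False
    seed: int | None = None
    restart: int | None = None
    pruned_states: list = field(default_factory=list)

    @property
    def elbo(self) -> float:
        return float(self.elbo_trace[-1]) if self.elbo_trace.size else np.nan

    @property
    def n_rois(self) -> int:
        return self.C.shape[0]

    def n_params(self) -> int:
        k, d, r = self.K, self.d, self.n_rois
        return (r * d + r + k * (d * d + d * (d + 1) // 2)
                + k * (k - 1) + (k - 1))

    def to_json(self, path=None) -> str:
        obj = {
            "K": self.K, "d": self.d, "n_rois": self.n_rois,
            "C": self.C.tolist(), "A": self.A.tolist(), "Q": self.Q.tolist(),
            "r_obs": self.r_obs.tolist(), "Pi": self.Pi.tolist(),
            "pi0": self.pi0.tolist(), "elbo_trace": self.elbo_trace.tolist(),
            "converged": self.converged, "seed": self.seed,
            "restart": self.restart, "pruned_states": self.pruned_states,
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SwitchingLDSModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(K=obj["K"], d=obj["d"], C=np.array(obj["C"]),
                   A=np.array(obj["A"]), Q=np.array(obj["Q"]),
                   r_obs=np.array(obj["r_obs"]), Pi=np.array(obj["Pi"]),
                   pi0=np.array(obj["pi0"]),
                   elbo_trace=np.array(obj["elbo_trace"]),
                   converged=obj["converged"], seed=obj["seed"],
                   restart=obj["restart"],
                   pruned_states=list(obj["pruned_states"]))


@dataclass
class StatePosterior:
    """Per-subject posterior over the latent state chain."""
    gamma: np.ndarray             # (T, K) state probabilities
    xi: np.ndarray                # (T-1, K, K) pairwise posteriors
    log_emissions: np.ndarray     # (T, K) expected dynamics scores
    latent_means: np.ndarray      # (T, d)
    latent_covs: np.ndarray       # (T, d, d)
    transition: np.ndarray        # (K, K), for Viterbi decoding
    initial: np.ndarray           # (K,)

    @property
    def hard_sequence(self) -> np.ndarray:
        return np.argmax(self.gamma, axis=1)


def decode_states(posterior: StatePosterior, mode: str = "argmax") -> np.ndarray:
    """Hard state sequence: per-timepoint argmax or max-probability path."""
    if mode == "argmax":
        return posterior.hard_sequence
    if mode == "viterbi":
        return viterbi(posterior.log_emissions, posterior.transition,
                       posterior.initial)
    raise ValueError("mode must be 'argmax' or 'viterbi'")


# ---------------------------------------------------------------------------
# E-step pieces (batched over subjects with equal run length)
# ---------------------------------------------------------------------------

def _chain_potentials(y, gamma, C, A, Qinv, r_obs):
    """Block-tridiagonal precision/potential of q(x) given responsibilities."""
    s, t_len, _ = y.shape
    d = A.shape[1]
    at_qinv = np.swapaxes(A, 1, 2) @ Qinv          # (K, d, d) A' Qinv
    at_qinv_a = at_qinv @ A                        # (K, d, d)
    g = gamma[:, 1:, :]                            # (S, T-1, K)
    j_diag = np.zeros((s, t_len, d, d))
    j_diag[:, 1:] += np.einsum("stk,kij->stij", g, Qinv)
    j_diag[:, :-1] += np.einsum("stk,kij->stij", g, at_qinv_a)
    j_off = -np.einsum("stk,kij->stij", g, at_qinv)  # J[t, t+1] = -A' Qinv
    rinv_c = C / r_obs[:, None]                    # (R, d)
    j_diag += (C.T @ rinv_c)[None, None]
    j_diag[:, 0] += np.eye(d)                      # x_1 ~ N(0, I)
    h = y @ rinv_c                                 # (S, T, d)
    return j_diag, j_off, h


def _expected_emissions(means, covs, cross, A, Q):
    """Expected per-state dynamics log-scores E_q(x)[log N(x_t; A_k x_{t-1}, Q_k)].

    Time 0 carries a zero score for every state (the x_1 prior is
    state-independent).
    """
    d = A.shape[1]
    e_cur = covs + means[..., :, None] * means[..., None, :]
    e_cross = cross + means[:, :-1, :, None] * means[:, 1:, None, :]
    qinv = np.linalg.inv(Q)
    _, logdet_q = np.linalg.slogdet(Q)
    qinv_a = qinv @ A
    at_qinv_a = np.swapaxes(A, 1, 2) @ qinv_a
    quad = (np.einsum("kij,stji->stk", qinv, e_cur[:, 1:])
            - 2.0 * np.einsum("kij,stji->stk", qinv_a, e_cross)
            + np.einsum("kij,stji->stk", at_qinv_a, e_cur[:, :-1]))
    logf = np.zeros((means.shape[0], means.shape[1], A.shape[0]))
    logf[:, 1:] = -0.5 * (d * LOG2PI + logdet_q[None, None] + quad)
    return logf, e_cur, e_cross


def _obs_loglik(y, means, covs, C, r_obs):
    s, t_len, r = y.shape
    cm = means @ C.T
    resid2 = ((y - cm) ** 2).sum(axis=(0, 1))
    cvc = np.einsum("stij,ri,rj->r", covs, C, C)
    return -0.5 * (s * t_len * (r * LOG2PI + np.log(r_obs).sum())
                   + ((resid2 + cvc) / r_obs).sum())


class _Batches:
    """Subjects grouped by run length so the chain solver can vectorize."""

    def __init__(self, dataset):
        arrays = [np.atleast_2d(np.asarray(y, dtype=float)) for y in dataset]
        r = arrays[0].shape[1]
        for y in arrays:
            if y.shape[1] != r:
                raise ValueError("all series must share the number of regions")
            if np.any(~np.isfinite(y)):
                raise ValueError("series contain non-finite values")
        self.n_rois = r
        self.n_subjects = len(arrays)
        by_t = {}
        for i, y in enumerate(arrays):
            by_t.setdefault(y.shape[0], []).append(i)
        self.groups = []
        for t_len in sorted(by_t):
            idx = by_t[t_len]
            self.groups.append((idx, np.stack([arrays[i] for i in idx])))
        self.total_timepoints = sum(y.shape[0] for y in arrays)


def _vem(batches: _Batches, params: dict, gammas: list, max_iter: int,
         tol: float, update_params: bool = True):
    """Coordinate-ascent variational EM. ``gammas`` holds one (S, T, K)
    responsibility array per batch (the initialization)."""
    C, A, Q = params["C"], params["A"], params["Q"]
    r_obs, Pi, pi0 = params["r_obs"], params["Pi"], params["pi0"]
    k, d = A.shape[0], A.shape[1]
    r = C.shape[0]
    elbo_trace = []
    converged = False
    posteriors_out = [None] * len(batches.groups)

    for it in range(max_iter):
        qinv = np.linalg.inv(Q)
        elbo = 0.0
        # global M-step accumulators
        w_k = np.zeros(k)
        s_prev = np.zeros((k, d, d))
        s_cur = np.zeros((k, d, d))
        s_cross = np.zeros((k, d, d))
        syx = np.zeros((r, d))
        sxx_all = np.zeros((d, d))
        syy = np.zeros(r)
        xi_sum = np.zeros((k, k))
        g1_sum = np.zeros(k)

        for bi, (idx, y) in enumerate(batches.groups):
            s, t_len, _ = y.shape
            gamma = gammas[bi]
            j_diag, j_off, h = _chain_potentials(y, gamma, C, A, qinv, r_obs)
            means, covs, cross, logdet = solve_gaussian_chain(j_diag, j_off, h)
            logf, e_cur, e_cross = _expected_emissions(means, covs, cross, A, Q)
            gamma, xi, logz = _forward_backward_batch(logf, Pi, pi0)
            gammas[bi] = gamma
            posteriors_out[bi] = (gamma, xi, logf, means, covs)

            elbo += logz.sum()
            elbo += _obs_loglik(y, means, covs, C, r_obs)
            elbo += -0.5 * (d * LOG2PI * s
                            + np.einsum("sii->", e_cur[:, 0]))   # x_1 prior
            elbo += 0.5 * s * t_len * d * (1.0 + LOG2PI) - 0.5 * logdet.sum()

            if update_params:
                g = gamma[:, 1:, :]
                w_k += g.sum(axis=(0, 1))
                s_prev += np.einsum("stk,stij->kij", g, e_cur[:, :-1])
                s_cur += np.einsum("stk,stij->kij", g, e_cur[:, 1:])
                s_cross += np.einsum("stk,stij->kij", g, e_cross)
                syx += np.einsum("str,std->rd", y, means)
                sxx_all += e_cur.sum(axis=(0, 1))
                syy += (y ** 2).sum(axis=(0, 1))
                xi_sum += xi.sum(axis=(0, 1))
                g1_sum += gamma[:, 0, :].sum(axis=0)

        elbo_trace.append(elbo)
        if it > 0 and abs(elbo - elbo_trace[-2]) <= tol * abs(elbo_trace[-2]):
            converged = True
            break

        if update_params:
            eye = np.eye(d)
            for j in range(k):
                if w_k[j] < 1e-8:
                    continue   # empty state: keep previous dynamics
                a_j = np.linalg.solve(
                    (s_prev[j] + RIDGE * eye).T, s_cross[j]).T
                q_j = (s_cur[j] - a_j @ s_cross[j] - s_cross[j].T @ a_j.T
                       + a_j @ s_prev[j] @ a_j.T) / w_k[j]
                A[j] = a_j
                Q[j] = 0.5 * (q_j + q_j.T) + RIDGE * eye
            C = np.linalg.solve((sxx_all + RIDGE * eye).T, syx.T).T
            r_obs = np.maximum(
                (syy - 2.0 * (C * syx).sum(axis=1)
                 + np.einsum("ri,ij,rj->r", C, sxx_all, C))
                / batches.total_timepoints, 1e-6)
            Pi = xi_sum + 1e-10
            Pi = Pi / Pi.sum(axis=1, keepdims=True)
            pi0 = (g1_sum + 1e-10) / (g1_sum + 1e-10).sum()

    params = {"C": C, "A": A, "Q": Q, "r_obs": r_obs, "Pi": Pi, "pi0": pi0}
    return params, posteriors_out, np.array(elbo_trace), converged


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def initialize_states(dataset, K: int, d: int, seed: int = 0,
                      window: int = 15, stride: int = 1):
    """Initial soft responsibilities from k-means on short-window covariance
    descriptors (upper-triangle vectorized, z-scored across windows).

    Window labels map to their center timepoint; edge timepoints take the
    nearest window's label. The winning state gets responsibility 0.9, the
    rest share 0.1. Clustering is invariant to subject ordering (features
    are canonically sorted before fitting).
    """
    from sklearn.cluster import KMeans

    batches = dataset if isinstance(dataset, _Batches) else _Batches(dataset)
    feats, owners = [], []
    for bi, (idx, y) in enumerate(batches.groups):
        s, t_len, r = y.shape
        n_win = t_len - window + 1
        if n_win < 1:
            raise ValueError("series shorter than the descriptor window")
        for si in range(s):
            ys = y[si]
            # sliding-window covariance descriptors
            for start in range(0, n_win, stride):
                seg = ys[start:start + window]
                cov = np.cov(seg.T, bias=True)
                iu = np.triu_indices(r)
                feats.append(cov[iu])
            owners.append((bi, si, t_len, n_win))
    feats = np.asarray(feats)
    if K > feats.shape[0]:
        raise ValueError(f"K={K} exceeds the number of windows {feats.shape[0]}")
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (feats - mu) / sd
    km = KMeans(n_clusters=K, n_init=5, random_state=int(seed) % (2**31 - 1))
    order = np.lexsort(z.T[::-1])
    km.fit(z[order])
    labels = km.predict(z)

    gammas = [np.empty((len(idx), t, K))
              for (idx, y), t in zip(batches.groups,
                                     [y.shape[1] for _, y in batches.groups])]
    pos = 0
    half = window // 2
    for bi, si, t_len, n_win in owners:
        lab_w = labels[pos:pos + n_win]
        pos += n_win
        lab_t = np.empty(t_len, dtype=int)
        centers = np.arange(n_win) + half
        for t in range(t_len):
            lab_t[t] = lab_w[np.clip(t - half, 0, n_win - 1)]
        _ = centers
        g = np.full((t_len, K), 0.1 / max(K - 1, 1))
        g[np.arange(t_len), lab_t] = 0.9 if K > 1 else 1.0
        g /= g.sum(axis=1, keepdims=True)
        gammas[bi][si] = g
    return gammas


def _marginal_hmm_refine(batches: _Batches, gammas, K: int,
                         n_iter: int = 10):
    """Refine initial responsibilities with a few EM iterations of a
    marginal Gaussian-emission HMM on the observations (full per-state
    covariances, no temporal latent structure). Cheap, deterministic, and
    moves the window-based k-means labels much closer to the state
    boundaries before the variational EM starts."""
    r = batches.n_rois
    pi = np.full((K, K), 0.05 / max(K - 1, 1))
    np.fill_diagonal(pi, 0.95 if K > 1 else 1.0)
    p0 = np.full(K, 1.0 / K)
    for _ in range(n_iter):
        w_k = np.zeros(K)
        mus = np.zeros((K, r))
        for bi, (_, y) in enumerate(batches.groups):
            g = gammas[bi]
            w_k += g.sum(axis=(0, 1))
            mus += np.einsum("stk,str->kr", g, y)
        mus /= np.maximum(w_k, 1e-12)[:, None]
        covs = np.zeros((K, r, r))
        for bi, (_, y) in enumerate(batches.groups):
            g = gammas[bi]
            for j in range(K):
                yc = y - mus[j]
                covs[j] += np.einsum("st,str,stq->rq", g[:, :, j], yc, yc)
        covs = covs / np.maximum(w_k, 1e-12)[:, None, None] + 1e-6 * np.eye(r)
        cinv = np.linalg.inv(covs)
        _, logdet = np.linalg.slogdet(covs)
        xi_sum = np.zeros((K, K))
        for bi, (_, y) in enumerate(batches.groups):
            yc = y[:, :, None, :] - mus[None, None]
            quad = np.einsum("stkr,krq,stkq->stk", yc, cinv, yc)
            logb = -0.5 * (r * LOG2PI + logdet[None, None] + quad)
            g, xi, _ = _forward_backward_batch(logb, pi, p0)
            gammas[bi] = g
            xi_sum += xi.sum(axis=(0, 1))
        if K > 1:
            pi = xi_sum + 1e-8
            pi /= pi.sum(axis=1, keepdims=True)
    return gammas


def _init_params(batches: _Batches, gammas, K: int, d: int):
    """Initial parameters: PCA factor loading + per-state weighted least
    squares on projected latent proxies."""
    r = batches.n_rois
    cov = np.zeros((r, r))
    for _, y in batches.groups:
        yc = y - y.mean(axis=1, keepdims=True)
        cov += np.einsum("str,stq->rq", yc, yc)
    cov /= batches.total_timepoints
    w, v = np.linalg.eigh(cov)
    w, v = w[::-1], v[:, ::-1]
    noise = max(float(w[d:].mean()) if r > d else 1e-3, 1e-6)
    C = v[:, :d] * np.sqrt(np.maximum(w[:d] - noise, 1e-3))
    r_obs = np.maximum(np.diag(cov) - np.einsum("rd,rd->r", C, C), 1e-3)

    pinv = np.linalg.pinv(C)
    A = np.zeros((K, d, d))
    Q = np.zeros((K, d, d))
    eye = np.eye(d)
    s_prev = np.zeros((K, d, d))
    s_cross = np.zeros((K, d, d))
    s_cur = np.zeros((K, d, d))
    w_k = np.zeros(K)
    trans = np.ones((K, K))
    for bi, (_, y) in enumerate(batches.groups):
        x = y @ pinv.T
        g = gammas[bi][:, 1:, :]
        xp, xc = x[:, :-1], x[:, 1:]
        s_prev += np.einsum("stk,sti,stj->kij", g, xp, xp)
        s_cross += np.einsum("stk,sti,stj->kij", g, xp, xc)
        s_cur += np.einsum("stk,sti,stj->kij", g, xc, xc)
        w_k += g.sum(axis=(0, 1))
        hard = np.argmax(gammas[bi], axis=2)
        for si in range(hard.shape[0]):
            np.add.at(trans, (hard[si, :-1], hard[si, 1:]), 1.0)
    for j in range(K):
        if w_k[j] < d + 1:
            A[j] = 0.5 * eye
            Q[j] = eye
            continue
        A[j] = np.linalg.solve((s_prev[j] + RIDGE * eye).T, s_cross[j]).T
        q_j = (s_cur[j] - A[j] @ s_cross[j] - s_cross[j].T @ A[j].T
               + A[j] @ s_prev[j] @ A[j].T) / w_k[j]
        Q[j] = 0.5 * (q_j + q_j.T) + 1e-3 * eye
        rho = spectral_radius(A[j])
        if rho >= 0.99:
            A[j] *= 0.95 / rho
    Pi = trans / trans.sum(axis=1, keepdims=True)
    pi0 = np.full(K, 1.0 / K)
    return {"C": C, "A": A, "Q": Q, "r_obs": r_obs, "Pi": Pi, "pi0": pi0}


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_switching_lds(dataset, K: int, d: int, n_restarts: int = 10,
                      seed: int = 0, tol: float = 1e-6, max_iter: int = 500,
                      window: int = 15):
    """Fit the switching LDS to a list of (T, R) series.

    Runs ``n_restarts`` seeded initializations and keeps the model with the
    highest final ELBO (ties broken by lowest restart index). Returns
    ``(model, posteriors)`` with one :class:`StatePosterior` per subject in
    dataset order. Deterministic given ``seed``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    batches = _Batches(dataset)
    if d > batches.n_rois:
        raise ValueError("latent dimension cannot exceed the number of regions")
    best = None
    for rst in range(max(n_restarts, 1)):
        rseed = derive_seed(seed, "restart", rst)
        gammas = initialize_states(batches, K, d, seed=rseed, window=window)
        gammas = _marginal_hmm_refine(batches, gammas, K)
        params = _init_params(batches, gammas, K, d)
        params, post, trace, conv = _vem(batches, params, gammas,
                                         max_iter=max_iter, tol=tol)
        if best is None or trace[-1] > best[2][-1] + 1e-12:
            best = (params, post, trace, conv, rst)
    params, post, trace, conv, rst = best

    pruned = []
    for j in range(K):
        m = max(float(post_b[0][:, :, j].max()) for post_b in post)
        if m < PRUNE_THRESHOLD:
            pruned.append(j)

    model = SwitchingLDSModel(
        K=K, d=d, C=params["C"], A=params["A"], Q=params["Q"],
        r_obs=params["r_obs"], Pi=params["Pi"], pi0=params["pi0"],
        elbo_trace=trace, converged=conv, seed=seed, restart=rst,
        pruned_states=pruned)

    posteriors = [None] * batches.n_subjects
    for bi, (idx, _) in enumerate(batches.groups):
        gamma, xi, logf, means, covs = post[bi]
        for pos, i in enumerate(idx):
            posteriors[i] = StatePosterior(
                gamma=gamma[pos], xi=xi[pos], log_emissions=logf[pos],
                latent_means=means[pos], latent_covs=covs[pos],
                transition=model.Pi, initial=model.pi0)
    return model, posteriors


def evaluate_elbo(model: SwitchingLDSModel, dataset, n_iter: int = 100,
                  tol: float = 1e-10):
    """E-step-only coordinate ascent at fixed parameters; returns the
    converged ELBO and posteriors (the variational bound on the data
    log-likelihood under ``model``)."""
    batches = _Batches(dataset)
    gammas = [np.tile(model.pi0, (len(idx), y.shape[1], 1))
              for idx, y in batches.groups]
    params = {"C": model.C, "A": model.A.copy(), "Q": model.Q.copy(),
              "r_obs": model.r_obs, "Pi": model.Pi, "pi0": model.pi0}
    params, post, trace, conv = _vem(batches, params, gammas, max_iter=n_iter,
                                     tol=tol, update_params=False)
    posteriors = [None] * batches.n_subjects
    for bi, (idx, _) in enumerate(batches.groups):
        gamma, xi, logf, means, covs = post[bi]
        for pos, i in enumerate(idx):
            posteriors[i] = StatePosterior(
                gamma=gamma[pos], xi=xi[pos], log_emissions=logf[pos],
                latent_means=means[pos], latent_covs=covs[pos],
                transition=model.Pi, initial=model.pi0)
    return float(trace[-1]), posteriors


def select_num_states(dataset, K_range, d: int, seed: int = 0,
                      n_restarts: int = 3, criterion: str = "bic",
                      max_iter: int = 200):
    """One fit per K; returns (table, selected_K).

    BIC = -2 ELBO + n_params log(total timepoints). The default selection
    criterion is BIC (the ELBO itself is non-decreasing in K up to restart
    noise, so it cannot select a finite K).
    """
    import pandas as pd

    rows = []
    fits = {}
    n_obs = sum(np.atleast_2d(y).shape[0] for y in dataset)
    for K in K_range:
        if not 1 <= K <= 10:
            raise ValueError("K_range must lie within [1, 10]")
        model, _ = fit_switching_lds(dataset, K=K, d=d,
                                     n_restarts=n_restarts,
                                     seed=derive_seed(seed, "selectK", K),
                                     max_iter=max_iter)
        bic = -2.0 * model.elbo + model.n_params() * np.log(n_obs)
        rows.append({"K": K, "elbo": model.elbo, "bic": bic,
                     "n_params": model.n_params(),
                     "converged": model.converged})
        fits[K] = model
    table = pd.DataFrame(rows)
    if criterion == "bic":
        selected = int(table.loc[table["bic"].idxmin(), "K"])
    elif criterion == "elbo":
        selected = int(table.loc[table["elbo"].idxmax(), "K"])
    else:
        raise ValueError("criterion must be 'bic' or 'elbo'")
    return table, selected


def align_states(model_labels, reference_labels, K: int | None = None):
    """Hungarian alignment of two labelings of the same timepoints.

    Returns ``(perm, accuracy)`` where ``perm[model_label] ->
    reference_label`` maximizes timepoint overlap.
    """
    def _flat(x):
        if isinstance(x, (list, tuple)):
            return np.concatenate([np.asarray(v, dtype=int).ravel() for v in x])
        return np.asarray(x, dtype=int).ravel()

    a, b = _flat(model_labels), _flat(reference_labels)
    if a.size != b.size:
        raise ValueError("labelings must cover the same timepoints")
    k = int(K) if K is not None else int(max(a.max(), b.max())) + 1
    conf = np.zeros((k, k))
    np.add.at(conf, (a, b), 1.0)
    rows, cols = linear_sum_assignment(-conf)
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    accuracy = conf[rows, cols].sum() / a.size
    return perm, float(accuracy)


def state_covariance(model: SwitchingLDSModel, posteriors=None, dataset=None,
                     method: str = "model", per_subject: bool = False,
                     min_weight: float = 2.0):
    """Per-state observed-space covariance and correlation matrices.

    ``method='model'``: stationary model-implied C Sigma_k C' + diag(r)
    with Sigma_k solving the state-k discrete Lyapunov equation (errors if
    a state's dynamics are unstable).
    ``method='empirical'``: responsibility-weighted sample covariance of the
    observations (pooled, or per subject with ``per_subject=True``; states
    with total weight below ``min_weight`` yield NaN matrices).

    Returns ``(cov, corr)`` arrays of shape (K, R, R), or dicts
    subject-index -> arrays when ``per_subject`` is set.
    """
    if method == "model":
        from scipy.linalg import solve_discrete_lyapunov
        covs = []
        for j in range(model.K):
            rho = spectral_radius(model.A[j])
            if rho >= 1.0:
                raise ValueError(f"state {j+1} dynamics unstable "
                                 f"(spectral radius {rho:.3f})")
            sig = solve_discrete_lyapunov(model.A[j], model.Q[j])
            covs.append(model.C @ sig @ model.C.T + np.diag(model.r_obs))
        cov = np.stack(covs)
        return cov, _to_corr(cov)
    if method != "empirical":
        raise ValueError("method must be 'model' or 'empirical'")
    if posteriors is None or dataset is None:
        raise ValueError("empirical method needs posteriors and dataset")

    def weighted_cov(ys, gs):
        r = ys[0].shape[1]
        cov = np.full((model.K, r, r), np.nan)
        for j in range(model.K):
            w = np.concatenate([g[:, j] for g in gs])
            y = np.vstack(ys)
            tot = w.sum()
            if tot < min_weight:
                continue
            mu = (w[:, None] * y).sum(axis=0) / tot
            yc = y - mu
            cov[j] = (w[:, None] * yc).T @ yc / tot
        return cov

    if per_subject:
        out_cov, out_corr = {}, {}
        for i, (p, y) in enumerate(zip(posteriors, dataset)):
            c = weighted_cov([np.atleast_2d(np.asarray(y, dtype=float))],
                             [p.gamma])
            out_cov[i] = c
            out_corr[i] = _to_corr(c)
        return out_cov, out_corr
    ys = [np.atleast_2d(np.asarray(y, dtype=float)) for y in dataset]
    cov = weighted_cov(ys, [p.gamma for p in posteriors])
    return cov, _to_corr(cov)


def _to_corr(cov: np.ndarray) -> np.ndarray:
    corr = np.full_like(cov, np.nan)
    for j in range(cov.shape[0]):
        c = cov[j]
        if not np.all(np.isfinite(c)):
            continue
        s = np.sqrt(np.diag(c))
        corr[j] = c / np.outer(s, s)
        np.fill_diagonal(corr[j], 1.0)
    return corr
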