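"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the analysis assumes: per-subject
multi-ROI fMRI time series generated from K latent brain states with
Markov dwell structure, each state a distinct stable linear-Gaussian
dynamical regime in a low-dimensional factor subspace; trial-level
two-choice behavior produced by a drift-diffusion process whose drift rate
is coupled to the occupancy of a designated "task-optimal" state; and
symptom scores coupled to a "non-optimal" state. Defaults mirror the study
conditions: 11 ROIs spanning salience (SN), frontoparietal (FPN) and
default-mode (DMN) networks, TR = 0.49 s, K = 4 states, 96 task trials
with jittered 1-4 s inter-trial intervals, and an ADHD subgroup whose
transition matrix favors the non-optimal state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior as bh
from ._utils import (as_rng, check_prob_vector, check_stochastic_matrix,
                     derive_seed, spectral_radius)
from .hmm import stationary_distribution

ROI_NAMES = ["lAI", "rAI", "dMPFC",                     # salience network
             "lMFG", "rMFG", "lFEF", "rFEF", "lIPS", "rIPS",  # frontoparietal
             "VMPFC", "PCC"]                            # default mode


def _dynamics_from_stationary(sigma: np.ndarray, rhos) -> tuple:
    """(A, Q) with A = U diag(rho) U' sharing the eigenvectors of the target
    stationary covariance ``sigma``, and Q = sigma - A sigma A' (PSD by
    construction): each state decays at distinct rates along its own
    covariance modes while its latent trajectory keeps exactly the requested
    stationary structure."""
    lam, u = np.linalg.eigh(np.asarray(sigma, dtype=float))
    rho = np.asarray(rhos, dtype=float)
    a = u @ np.diag(rho) @ u.T
    q = u @ np.diag(lam * (1.0 - rho**2)) @ u.T
    return a, 0.5 * (q + q.T)


def default_state_dynamics(n_states: int = 4, latent_dim: int = 3):
    """Per-state (A_k, Q_k) whose stationary latent covariances have clearly
    distinct orientations (different signs/strengths of network coupling),
    mirroring latent states with distinct functional-connectivity patterns:

    S1  task-optimal: strong positive SN-FPN coupling, DMN suppressed;
    S2  non-optimal: DMN-dominated with negative SN-DMN coupling;
    S3  SN-FPN anticoupled;
    S4  positive SN-DMN coupling (failure to disengage the DMN).
    """
    if (n_states, latent_dim) == (4, 3):
        sigmas = [
            np.array([[4.5, 3.9, 0.0], [3.9, 4.5, 0.0], [0.0, 0.0, 0.2]]),
            np.array([[0.4, 0.0, -1.1], [0.0, 0.25, 0.0], [-1.1, 0.0, 4.5]]),
            np.array([[4.0, -3.4, 0.0], [-3.4, 4.0, 0.0], [0.0, 0.0, 0.4]]),
            np.array([[2.5, 0.0, 2.1], [0.0, 0.4, 0.0], [2.1, 0.0, 2.5]]),
        ]
        rhos = [(0.90, 0.60, 0.50), (0.85, 0.55, 0.50),
                (0.80, 0.60, 0.45), (0.70, 0.55, 0.50)]
    else:
        # generic fallback: rotate an anisotropic spectrum through distinct
        # orientations (fixed generator: defaults must not vary by call)
        rng = np.random.default_rng(12345)
        lam = np.linspace(2.5, 0.4, latent_dim)
        sigmas, rhos = [], []
        for k in range(n_states):
            m = rng.standard_normal((latent_dim, latent_dim))
            u, _ = np.linalg.qr(m)
            sigmas.append(u @ np.diag(np.roll(lam, k)) @ u.T)
            rhos.append(tuple(0.5 + 0.4 * rng.random(latent_dim)))
    pairs = [_dynamics_from_stationary(s, r) for s, r in zip(sigmas, rhos)]
    return (np.stack([a for a, _ in pairs]), np.stack([q for _, q in pairs]))


def default_loading(n_rois: int = 11, latent_dim: int = 3) -> np.ndarray:
    """Network-structured loading: SN nodes on dim 0, FPN on dim 1, DMN on
    dim 2, with small cross-loadings."""
    if (n_rois, latent_dim) == (11, 3):
        membership = [0, 0, 0, 1, 1, 1, 1, 1, 1, 2, 2]
        c = np.full((11, 3), 0.2)
        for r, m in enumerate(membership):
            c[r, m] = 1.0
        return c
    rng = np.random.default_rng(54321)
    c = 0.2 + 0.8 * (rng.random((n_rois, latent_dim)) < 0.4)
    c[np.arange(n_rois), np.arange(n_rois) % latent_dim] = 1.0
    return c


def default_transition_matrix(n_states: int = 4, stay: float = 0.95) -> np.ndarray:
    pi = np.full((n_states, n_states), (1 - stay) / max(n_states - 1, 1))
    np.fill_diagonal(pi, stay if n_states > 1 else 1.0)
    return pi


def adhd_transition_matrix(base: np.ndarray, optimal_state: int = 0,
                           nonoptimal_state: int = 1) -> np.ndarray:
    """Shift dwell structure away from the optimal state and toward the
    non-optimal state (shorter S1 dwell, longer S2 dwell)."""
    pi = np.array(base, dtype=float)
    k = pi.shape[0]
    if k > 1:
        for row, stay in ((optimal_state, 0.92), (nonoptimal_state, 0.96)):
            off = 1.0 - pi[row, row]
            pi[row] *= (1.0 - stay) / off
            pi[row, row] = stay
    return check_stochastic_matrix(pi)


@dataclass
class Coupling:
    """Subject-level coupling: occupancy of ``state`` shifts a behavioral or
    symptom parameter. Either an explicit ``slope`` (units of the parameter
    per unit occupancy) or a ``target_r`` (population correlation induced
    given the empirical occupancy spread) must be given."""
    state: int
    param: str          # "v", "a", "t", "inattention", "hyperactivity"
    noise_sd: float
    slope: float | None = None
    target_r: float | None = None

    def resolve_slope(self, occ_sd: float) -> float:
        if self.slope is not None:
            return self.slope
        if self.target_r is None:
            raise ValueError("coupling needs slope or target_r")
        r = self.target_r
        if not (-1 < r < 1):
            raise ValueError("target_r must be in (-1, 1)")
        if occ_sd <= 0:
            raise ValueError("zero occupancy spread; cannot induce coupling")
        return r * self.noise_sd / (occ_sd * np.sqrt(1 - r**2))


def default_couplings():
    return [Coupling(state=0, param="v", noise_sd=0.55, target_r=0.5),
            Coupling(state=1, param="inattention", noise_sd=5.0, target_r=0.4)]


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort."""
    n_subjects: int = 20
    n_timepoints: int = 700
    tr: float = 0.49
    n_rois: int = 11
    n_states: int = 4
    latent_dim: int = 3
    transition_matrix: np.ndarray | None = None
    state_dynamics: tuple | None = None     # (A: K x d x d, Q: K x d x d)
    loading: np.ndarray | None = None       # R x d
    obs_noise: np.ndarray | None = None     # diagonal variances (R,)
    snr: float = 1.0
    coupling: list = field(default_factory=default_couplings)
    n_trials: int = 96
    seed: int = 0
    adhd_fraction: float = 0.5
    adhd_effect: bool = True                # ADHD subgroup gets shifted dwell
    iti_range: tuple = (1.0, 4.0)
    stim_duration: float = 0.5
    response_window: float = 1.5
    contaminant_prob: float = 0.02
    roi_names: list = field(default_factory=lambda: list(ROI_NAMES))

    def __post_init__(self):
        if self.transition_matrix is None:
            self.transition_matrix = default_transition_matrix(self.n_states)
        self.transition_matrix = check_stochastic_matrix(
            np.asarray(self.transition_matrix, dtype=float))
        if self.state_dynamics is None:
            self.state_dynamics = default_state_dynamics(self.n_states,
                                                         self.latent_dim)
        a, q = (np.asarray(m, dtype=float) for m in self.state_dynamics)
        self.state_dynamics = (a, q)
        if self.loading is None:
            self.loading = default_loading(self.n_rois, self.latent_dim)
        self.loading = np.asarray(self.loading, dtype=float)
        if len(self.roi_names) != self.n_rois:
            self.roi_names = [f"ROI{i+1:02d}" for i in range(self.n_rois)]
        self.validate()

    def validate(self):
        k, d = self.n_states, self.latent_dim
        if self.transition_matrix.shape != (k, k):
            raise ValueError("transition_matrix shape mismatch")
        a, q = self.state_dynamics
        if a.shape != (k, d, d) or q.shape != (k, d, d):
            raise ValueError("state_dynamics shape mismatch")
        for j in range(k):
            if spectral_radius(a[j]) >= 1.0:
                raise ValueError(f"A_{j+1} is unstable (spectral radius >= 1)")
            w = np.linalg.eigvalsh(0.5 * (q[j] + q[j].T))
            if w.min() < -1e-10:
                raise ValueError(f"Q_{j+1} is not PSD")
        if self.loading.shape != (self.n_rois, d):
            raise ValueError("loading shape mismatch")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.obs_noise is not None:
            on = np.asarray(self.obs_noise, dtype=float).ravel()
            if on.size != self.n_rois or np.any(on < 0):
                raise ValueError("obs_noise must be R nonnegative variances")
            self.obs_noise = on

    # -- model-implied quantities -----------------------------------------
    def stationary_latent_cov(self, k: int) -> np.ndarray:
        from scipy.linalg import solve_discrete_lyapunov
        a, q = self.state_dynamics
        return solve_discrete_lyapunov(a[k], q[k])

    def obs_noise_variances(self) -> np.ndarray:
        """Diagonal observation-noise variances; derived from ``snr`` (ratio
        of state-signal variance to noise variance, in trace) when
        ``obs_noise`` is not given explicitly."""
        if self.obs_noise is not None:
            return self.obs_noise
        p = stationary_distribution(self.transition_matrix)
        c = self.loading
        sig_tr = sum(p[k] * np.trace(c @ self.stationary_latent_cov(k) @ c.T)
                     for k in range(self.n_states))
        return np.full(self.n_rois, sig_tr / (self.snr * self.n_rois))

    def state_observed_cov(self, k: int) -> np.ndarray:
        """Model-implied stationary observed covariance in state k."""
        c = self.loading
        return c @ self.stationary_latent_cov(k) @ c.T + np.diag(
            self.obs_noise_variances())


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_state_sequence(transition_matrix, initial_dist, n_timepoints: int,
                            seed=0) -> np.ndarray:
    """Sample a Markov state sequence (0-based labels)."""
    pi = check_stochastic_matrix(np.asarray(transition_matrix, dtype=float))
    p0 = check_prob_vector(np.asarray(initial_dist, dtype=float))
    rng = as_rng(seed)
    k = pi.shape[0]
    cum = np.cumsum(pi, axis=1)
    cum0 = np.cumsum(p0)
    u = rng.random(n_timepoints)
    seq = np.empty(n_timepoints, dtype=int)
    seq[0] = int(np.searchsorted(cum0, u[0]))
    for t in range(1, n_timepoints):
        seq[t] = int(np.searchsorted(cum[seq[t - 1]], u[t]))
    return np.minimum(seq, k - 1)


def simulate_roi_timeseries(config: SimulationConfig, state_sequence,
                            seed=0):
    """Generate one subject's T x R ROI series and its latent trajectory.

    x_t = A_{s_t} x_{t-1} + w_t, w_t ~ N(0, Q_{s_t});
    y_t = C x_t + v_t, v_t ~ N(0, R_obs), with R_obs set by ``config.snr``.
    """
    seq = np.asarray(state_sequence, dtype=int)
    t_len = seq.size
    a, q = config.state_dynamics
    c = config.loading
    d = config.latent_dim
    rng = as_rng(seed)
    chol = np.stack([np.linalg.cholesky(q[k] + 1e-12 * np.eye(d))
                     for k in range(config.n_states)])
    x = np.empty((t_len, d))
    s0 = config.stationary_latent_cov(seq[0])
    x[0] = np.linalg.cholesky(s0 + 1e-12 * np.eye(d)) @ rng.standard_normal(d)
    z = rng.standard_normal((t_len, d))
    for t in range(1, t_len):
        k = seq[t]
        x[t] = a[k] @ x[t - 1] + chol[k] @ z[t]
    noise_sd = np.sqrt(config.obs_noise_variances())
    y = x @ c.T + rng.standard_normal((t_len, config.n_rois)) * noise_sd
    return y, x


def simulate_motion_regressors(n_timepoints: int, seed=0,
                               step_sd: float = 1.0) -> np.ndarray:
    """Six smooth low-frequency nuisance traces (3 translations, 3 rotations)
    as column-standardized Gaussian random walks."""
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    rng = as_rng(seed)
    walk = np.cumsum(rng.standard_normal((n_timepoints, 6)) * step_sd, axis=0)
    walk -= walk.mean(axis=0)
    sd = walk.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return walk / sd


def simulate_behavior(config: SimulationConfig, occupancy_per_subject,
                      seed=0, groups=None, simulate_trials: bool = True):
    """Per-subject behavioral truth and simulated trials.

    DDM parameters (a, v, t) are drawn from cohort distributions shifted by
    the configured occupancy couplings; symptom scores likewise. Trials come
    from the Euler-Maruyama DDM simulator (1 ms step, optional uniform
    contaminants); RTs beyond the response window become omissions.
    ex-Gaussian truth (mu, sigma, tau) is the moment-matched ex-Gaussian of
    each subject's DDM RT distribution, so tau and v are internally coupled.

    Returns ``(params: DataFrame, trials: dict subject -> DataFrame)``.
    """
    occ = np.asarray(occupancy_per_subject, dtype=float)
    if occ.ndim != 2:
        raise ValueError("occupancy must be (n_subjects, K)")
    if np.any(occ < -1e-9) or np.any(occ > 1 + 1e-9) or \
            not np.allclose(occ.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("occupancies must lie in [0,1] and sum to 1")
    n = occ.shape[0]
    rng = as_rng(seed)
    if groups is None:
        groups = np.array(["TD"] * n)
    groups = np.asarray(groups)

    base = {
        "a": np.clip(rng.normal(1.4, 0.15, n), 0.8, 2.5),
        "v": np.full(n, 2.5),
        "t": np.clip(rng.normal(0.25, 0.03, n), 0.15, 0.4),
        "inattention": np.where(groups == "ADHD", 18.0, 7.0),
        "hyperactivity": np.where(groups == "ADHD", 14.0, 7.0)
        + rng.normal(0, 4.0, n),
    }
    coupled = {c.param for c in config.coupling}
    if "v" not in coupled:
        base["v"] = rng.normal(2.5, 0.55, n)
    if "inattention" not in coupled:
        base["inattention"] = base["inattention"] + rng.normal(0, 5.0, n)
    for c in config.coupling:
        if c.param not in base:
            raise ValueError(f"unknown coupled parameter {c.param!r}")
        if c.state >= occ.shape[1]:
            raise ValueError("coupling state index out of range")
        o = occ[:, c.state]
        slope = c.resolve_slope(float(o.std(ddof=1))) if n > 1 else 0.0
        base[c.param] = (base[c.param] + slope * (o - o.mean())
                         + rng.normal(0, c.noise_sd, n))

    a = np.clip(base["a"], 0.5, 3.5)
    v = np.clip(base["v"], 0.2, 7.0)
    t0 = np.clip(base["t"], 0.1, 0.45)
    inatt = np.clip(base["inattention"], 0.0, 27.0)
    hyper = np.clip(base["hyperactivity"], 0.0, 27.0)
    mu, sigma, tau = bh.exgauss_from_ddm(a, v, t0)

    params = pd.DataFrame({
        "subject": [f"s{i+1:03d}" for i in range(n)],
        "group": groups, "a": a, "v": v, "t": t0,
        "mu": mu, "sigma": sigma, "tau": tau,
        "inattention": inatt, "hyperactivity": hyper,
    })

    trials = {}
    if not simulate_trials:
        return params, trials
    nt = config.n_trials
    for i, sub in enumerate(params["subject"]):
        sub_seed = derive_seed(seed if isinstance(seed, int) else 0,
                               "trials", i)
        rng_s = np.random.default_rng(sub_seed)
        rt, correct = bh.simulate_ddm_trials(
            a[i], v[i], t0[i], n_trials=nt, seed=rng_s,
            contaminant_prob=config.contaminant_prob,
            response_window=config.response_window)
        iti = rng_s.uniform(*config.iti_range, size=nt)
        onsets = np.concatenate(
            [[2.0], 2.0 + np.cumsum(config.stim_duration + iti)[:-1]])
        stim = rng_s.integers(0, 2, size=nt)  # 0 = left, 1 = right
        choice = np.where(np.isnan(rt), "",
                          np.where(correct == 1,
                                   np.where(stim == 1, "right", "left"),
                                   np.where(stim == 1, "left", "right")))
        trials[sub] = pd.DataFrame({
            "trial": np.arange(1, nt + 1), "onset_s": onsets,
            "rt_s": rt, "correct": correct, "choice": choice,
        })
    return params, trials


@dataclass
class Cohort:
    """A generated cohort plus its ground truth."""
    config: SimulationConfig
    subjects: list
    timeseries: list          # per subject (T, R)
    latents: list             # per subject (T, d)
    motion: list              # per subject (T, 6)
    trials: dict              # subject -> trials DataFrame
    participants: pd.DataFrame
    ground_truth: dict        # state_sequences, occupancy, lifetimes, params


def generate_cohort(config: SimulationConfig, seed: int | None = None) -> Cohort:
    """Full synthetic cohort: state sequences, ROI series, motion, behavior,
    subject table and ground truth."""
    from .metrics import mean_lifetime, occupancy_rate

    seed = config.seed if seed is None else seed
    n, k = config.n_subjects, config.n_states
    n_adhd = int(round(config.adhd_fraction * n))
    groups = np.array(["ADHD"] * n_adhd + ["TD"] * (n - n_adhd))
    rng = as_rng(derive_seed(seed, "cohort"))
    rng.shuffle(groups)

    pi_td = config.transition_matrix
    pi_adhd = adhd_transition_matrix(pi_td) if config.adhd_effect else pi_td
    subjects = [f"s{i+1:03d}" for i in range(n)]
    seqs, ys, xs, motions = [], [], [], []
    for i in range(n):
        pi_i = pi_adhd if groups[i] == "ADHD" else pi_td
        p0 = stationary_distribution(pi_i)
        seq = simulate_state_sequence(pi_i, p0, config.n_timepoints,
                                      derive_seed(seed, "seq", i))
        y, x = simulate_roi_timeseries(config, seq, derive_seed(seed, "ts", i))
        seqs.append(seq)
        ys.append(y)
        xs.append(x)
        motions.append(simulate_motion_regressors(
            config.n_timepoints, derive_seed(seed, "motion", i)))

    occ = np.stack([occupancy_rate(s, n_states=k) for s in seqs])
    life = np.stack([mean_lifetime(s, tr=config.tr, n_states=k)["lifetime_trs"]
                     for s in seqs])
    params, trials = simulate_behavior(config, occ, derive_seed(seed, "behav"),
                                       groups=groups)

    rng_p = as_rng(derive_seed(seed, "participants"))
    participants = pd.DataFrame({
        "subject": subjects,
        "group": groups,
        "inattention": params["inattention"].round(1),
        "hyperactivity": params["hyperactivity"].round(1),
        "age": rng_p.uniform(9, 12, n).round(1),
        "gender": rng_p.integers(0, 2, n),
        "iq": np.clip(rng_p.normal(110, 12, n), 81, 150).round(0),
        "mean_fd": np.abs(rng_p.normal(0.12, 0.05, n)).round(4) + 0.01,
    })

    ground_truth = {
        "state_sequences": seqs,
        "occupancy": occ,
        "lifetime_trs": life,
        "params": params,
        "transition_matrix_td": pi_td,
        "transition_matrix_adhd": pi_adhd,
    }
    return Cohort(config=config, subjects=subjects, timeseries=ys, latents=xs,
                  motion=motions, trials=trials, participants=participants,
                  ground_truth=ground_truth)


def easy_preset(n_subjects: int = 20, seed: int = 0, **kw) -> SimulationConfig:
    """snr = 1.0 recovery regime."""
    return SimulationConfig(n_subjects=n_subjects, snr=1.0, seed=seed, **kw)


def hard_preset(n_subjects: int = 20, seed: int = 0, **kw) -> SimulationConfig:
    """snr = 0.3 stress regime."""
    return SimulationConfig(n_subjects=n_subjects, snr=0.3, seed=seed, **kw)
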