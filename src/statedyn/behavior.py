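"""Trial-level behavioral models: ex-Gaussian RT distributions and the
drift-diffusion model (DDM).

The ex-Gaussian (Normal(mu, sigma) convolved with Exponential(tau)) describes
the positively skewed shape of reaction-time distributions; tau indexes the
slow-response tail linked to attentional lapses. The DDM describes two-choice
decisions as noisy evidence accumulation between two boundaries: boundary
separation ``a`` (response caution), drift rate ``v`` (accumulation speed) and
non-decision time ``t`` (encoding/motor latency). Both are fit per subject by
maximum likelihood; the DDM likelihood is the Wiener first-passage-time
density evaluated by the small-time/large-time series expansions with an
automatic switch. EZ-diffusion closed forms provide an independent
moment-based route to (a, v, t).

Conventions: all RTs in seconds; diffusion coefficient s = 1; unbiased start
z = a/2; upper boundary = correct response (accuracy coding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from ._utils import as_rng

RT_CONTAMINANT_FLOOR = 0.15  # s; faster responses are treated as contaminants


# ---------------------------------------------------------------------------
# ex-Gaussian
# ---------------------------------------------------------------------------

@dataclass
class ExGaussianParams:
    """Maximum-likelihood ex-Gaussian fit for one subject."""
    mu: float
    sigma: float
    tau: float
    loglik: float = np.nan
    n: int = 0
    converged: bool = True
    flags: list = field(default_factory=list)

    @property
    def implied_mean(self) -> float:
        return self.mu + self.tau

    @property
    def implied_var(self) -> float:
        return self.sigma**2 + self.tau**2


def exgauss_logpdf(x, mu: float, sigma: float, tau: float):
    """Stable log-density of the exponentially modified Gaussian.

    Uses the scaled complementary error function (erfcx) when the naive
    exponent would overflow, so small tau/sigma ratios stay finite.
    """
    if sigma <= 0 or tau <= 0:
        raise ValueError("sigma and tau must be positive")
    x = np.asarray(x, dtype=float)
    z = (x - mu) / sigma
    w = sigma / tau
    y = (w - z) / np.sqrt(2.0)
    out = np.empty_like(z)
    pos = y >= 0
    # y >= 0: erfc(y) underflows; fold its Gaussian factor into the exponent
    out[pos] = (-np.log(2 * tau) + np.log(special.erfcx(y[pos]))
                - 0.5 * z[pos] ** 2)
    # y < 0: erfc(y) in (1, 2), the direct form is safe
    out[~pos] = (-np.log(2 * tau) + w * w / 2 - w * z[~pos]
                 + np.log(special.erfc(y[~pos])))
    return out if out.ndim else float(out)


def exgauss_loglik(rts, mu: float, sigma: float, tau: float) -> float:
    """Summed log-likelihood of RTs under the ex-Gaussian model."""
    ll = float(np.sum(exgauss_logpdf(np.asarray(rts, dtype=float), mu, sigma, tau)))
    if not np.isfinite(ll):
        raise ValueError("non-finite ex-Gaussian log-likelihood")
    return ll


def _exgauss_moment_start(rts: np.ndarray):
    m, s = rts.mean(), rts.std(ddof=1)
    g1 = float(stats.skew(rts, bias=False))
    g1 = min(max(g1, 0.01), 4.0)
    tau0 = s * (g1 / 2.0) ** (1.0 / 3.0)
    sigma0 = np.sqrt(max(s**2 - tau0**2, (0.1 * s) ** 2))
    return m - tau0, sigma0, tau0


def fit_exgauss(rts, min_trials: int = 20) -> ExGaussianParams:
    """Maximum-likelihood ex-Gaussian fit (bounded quasi-Newton from a
    moment-based start: tau0 = sd*(skew/2)^(1/3), mu0 = mean - tau0)."""
    rts = np.asarray(rts, dtype=float)
    rts = rts[np.isfinite(rts)]
    if rts.size < min_trials:
        raise ValueError(f"need >= {min_trials} responded trials, got {rts.size}")
    mu0, sigma0, tau0 = _exgauss_moment_start(rts)
    s = rts.std(ddof=1)
    bounds = [(rts.min() - 5 * s, rts.max()), (1e-4, 10 * s), (1e-4, 10 * s)]

    def nll(theta):
        mu, sigma, tau = theta
        return -np.sum(exgauss_logpdf(rts, mu, sigma, tau))

    res = optimize.minimize(nll, x0=[mu0, sigma0, tau0], method="L-BFGS-B",
                            bounds=bounds)
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"ex-Gaussian fit failed: {res.message}")
    mu, sigma, tau = res.x
    flags = []
    if tau <= 2e-4:
        flags.append("tau_at_lower_bound")
    return ExGaussianParams(mu=float(mu), sigma=float(sigma), tau=float(tau),
                            loglik=float(-res.fun), n=int(rts.size),
                            converged=bool(res.success), flags=flags)


# ---------------------------------------------------------------------------
# Wiener first-passage-time density
# ---------------------------------------------------------------------------

def _wfpt_f1(u: np.ndarray, w: float, err: float) -> np.ndarray:
    """Standardized (a=1, v=0) lower-boundary FPT density at scaled time u.

    Chooses per element between the small-time and large-time series, each
    truncated so the approximation error is below ``err``.
    """
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    ok = u > 0
    if not np.any(ok):
        return out
    uu = u[ok]

    with np.errstate(divide="ignore", invalid="ignore"):
        # required number of terms, per Navarro & Fuss (2009)
        kl = np.where(np.pi * uu * err < 1,
                      np.sqrt(np.maximum(-2 * np.log(np.pi * uu * err), 0)
                              / (np.pi**2 * uu)),
                      0.0)
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(uu)))
        arg = 2 * np.sqrt(2 * np.pi * uu) * err
        ks = np.where(arg < 1,
                      2 + np.sqrt(np.maximum(-2 * uu * np.log(arg), 0)),
                      2.0)
        ks = np.maximum(ks, np.sqrt(uu) + 1)

    val = np.empty_like(uu)
    small = ks < kl
    if np.any(small):
        us = uu[small]
        kmax = int(np.ceil(ks[small].max()))
        lo = -((kmax - 1) // 2)
        hi = (kmax - 1 + 1) // 2 + 1
        j = np.arange(lo, hi)
        wj = w + 2 * j[None, :]
        terms = wj * np.exp(-wj**2 / (2 * us[:, None]))
        val[small] = terms.sum(axis=1) / np.sqrt(2 * np.pi * us**3)
    large = ~small
    if np.any(large):
        ul = uu[large]
        kmax = int(np.ceil(kl[large].max()))
        j = np.arange(1, kmax + 1)
        terms = (j[None, :] * np.exp(-j[None, :] ** 2 * np.pi**2 * ul[:, None] / 2)
                 * np.sin(j[None, :] * np.pi * w))
        val[large] = np.pi * terms.sum(axis=1)
    out[ok] = np.maximum(val, 0.0)
    return out


def wfpt_density(rt_decision, a: float, v: float, boundary: str = "lower",
                 w: float = 0.5, err: float = 1e-10):
    """Wiener first-passage-time density at the given boundary.

    ``rt_decision`` is decision time (RT minus non-decision time), seconds.
    ``w`` is the relative start point (0.5 = unbiased). Densities at
    non-positive times are 0. Vectorized over ``rt_decision``.
    """
    if a <= 0:
        raise ValueError("boundary separation a must be positive")
    if boundary not in ("lower", "upper"):
        raise ValueError("boundary must be 'lower' or 'upper'")
    t = np.asarray(rt_decision, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if boundary == "upper":
        v, w = -v, 1.0 - w
    u = t / a**2
    f1 = _wfpt_f1(u, w, err)
    with np.errstate(over="ignore"):
        dens = f1 / a**2 * np.exp(-v * a * w - v**2 * t / 2)
    dens = np.where(t > 0, dens, 0.0)
    return float(dens[0]) if scalar else dens


def wfpt_boundary_prob(a: float, v: float, boundary: str = "lower",
                       w: float = 0.5) -> float:
    """Probability of absorption at the given boundary (closed form)."""
    if boundary == "upper":
        v, w = -v, 1.0 - w
    if abs(v) < 1e-12:
        return 1.0 - w
    return float((np.exp(-2 * v * a * w) - np.exp(-2 * v * a))
                 / (1.0 - np.exp(-2 * v * a))) if abs(v * a) < 350 else (
                     1.0 if v < 0 else 0.0)


@lru_cache(maxsize=1)
def _fpt_moment_funcs():
    """Closed-form raw moments of the symmetric-start first-passage time.

    Derived from the Laplace transform E[exp(-s T)] = cosh(v b)/cosh(b g),
    g = sqrt(v^2 + 2 s), with half-separation b = a/2. Moments are even in v.
    """
    import sympy as sp

    v, b, s = sp.symbols("v b s", positive=True)
    g = sp.sqrt(v**2 + 2 * s)
    phi = sp.cosh(v * b) / sp.cosh(b * g)
    m = []
    expr = phi
    for k in range(1, 4):
        expr_d = sp.diff(phi, s, k)
        mk = sp.simplify(((-1) ** k) * expr_d.subs(s, 0))
        m.append(sp.lambdify((v, b), mk, modules="numpy"))
    _ = expr
    return tuple(m)


def ddm_decision_moments(a, v):
    """Mean, variance and third central moment of DDM decision time.

    Unbiased start, diffusion s = 1. With z = a/2 the decision-time
    distribution is identical at both boundaries, so these are also the
    moments of the full RT distribution shifted by non-decision time.
    Vectorized over (a, v); drift magnitudes below 1e-3 are clamped.
    """
    m1f, m2f, m3f = _fpt_moment_funcs()
    a = np.asarray(a, dtype=float)
    vv = np.maximum(np.abs(np.asarray(v, dtype=float)), 1e-3)
    b = a / 2.0
    m1 = m1f(vv, b)
    m2 = m2f(vv, b)
    m3 = m3f(vv, b)
    var = m2 - m1**2
    m3c = m3 - 3 * m1 * m2 + 2 * m1**3
    return m1, var, m3c


def ddm_accuracy(a, v):
    """P(correct) = P(hit upper boundary) for unbiased start: logistic(a v)."""
    return 1.0 / (1.0 + np.exp(-np.asarray(a, dtype=float) * np.asarray(v, dtype=float)))


def exgauss_from_ddm(a, v, t0):
    """Moment-matched ex-Gaussian parameters implied by a DDM subject.

    Matches mean, variance and third central moment of the DDM RT
    distribution (decision time + non-decision time): tau^3 = m3c/2,
    sigma^2 = var - tau^2, mu = mean - tau. When the DDM skew exceeds the
    ex-Gaussian maximum, sigma is floored at 5% of the RT sd.
    """
    m1, var, m3c = ddm_decision_moments(a, v)
    sd = np.sqrt(var)
    tau = np.cbrt(np.maximum(m3c, 1e-12) / 2.0)
    tau = np.minimum(tau, 0.995 * sd)
    sigma = np.sqrt(np.maximum(var - tau**2, (0.05 * sd) ** 2))
    mu = np.asarray(t0, dtype=float) + m1 - tau
    return mu, sigma, tau


# ---------------------------------------------------------------------------
# DDM simulation (Euler-Maruyama)
# ---------------------------------------------------------------------------

def simulate_ddm_trials(a, v, t0, n_trials: int | None = None, dt: float = 0.001,
                        seed=0, max_time: float = 10.0,
                        contaminant_prob: float = 0.0,
                        response_window: float | None = None):
    """Simulate DDM trials by Euler-Maruyama with step ``dt`` (default 1 ms).

    ``a``, ``v``, ``t0`` may be scalars (with ``n_trials`` trials) or
    per-trial arrays. Optional uniform contaminant trials replace the
    diffusion RT with a uniform draw on (0.2 s, 1.5 s) and a coin-flip
    outcome. If ``response_window`` is set, slower RTs become omissions
    (rt = NaN, correct = 0).

    Returns ``(rt, correct)`` arrays; ``correct`` is 1 when the upper
    boundary is hit.
    """
    rng = as_rng(seed)
    a = np.asarray(a, dtype=float)
    if a.ndim == 0:
        if n_trials is None:
            raise ValueError("n_trials required with scalar parameters")
        a = np.full(n_trials, float(a))
        v = np.full(n_trials, float(v))
        t0 = np.full(n_trials, float(t0))
    else:
        n_trials = a.size
        v = np.broadcast_to(np.asarray(v, dtype=float), a.shape).copy()
        t0 = np.broadcast_to(np.asarray(t0, dtype=float), a.shape).copy()
    if np.any(a <= 0) or np.any(t0 < 0):
        raise ValueError("require a > 0 and t0 >= 0")

    x = a / 2.0
    rt = np.full(n_trials, np.nan)
    correct = np.zeros(n_trials, dtype=int)
    active = np.ones(n_trials, dtype=bool)
    sqdt = np.sqrt(dt)
    n_steps = int(np.ceil(max_time / dt))
    for step in range(1, n_steps + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        x_prev = x[idx].copy()
        x[idx] += v[idx] * dt + sqdt * rng.standard_normal(idx.size)
        hit_up = x[idx] >= a[idx]
        hit_lo = x[idx] <= 0.0
        # Brownian-bridge correction: paths with interior endpoints may still
        # have crossed within the step; absorb with the bridge probability.
        interior = ~(hit_up | hit_lo)
        if np.any(interior):
            ii = idx[interior]
            xp, xn = x_prev[interior], x[ii]
            p_up = np.exp(-2.0 * (a[ii] - xp) * (a[ii] - xn) / dt)
            p_lo = np.exp(-2.0 * xp * xn / dt)
            u = rng.random(ii.size)
            bu = u < p_up
            bl = (u >= p_up) & (u < p_up + p_lo)
            hit_up[interior] |= bu
            hit_lo[interior] |= bl
        done = hit_up | hit_lo
        if np.any(done):
            j = idx[done]
            rt[j] = step * dt + t0[j]
            correct[j] = hit_up[done].astype(int)
            active[j] = False

    if contaminant_prob > 0:
        is_cont = rng.random(n_trials) < contaminant_prob
        k = int(is_cont.sum())
        if k:
            rt[is_cont] = rng.uniform(0.2, 1.5, size=k)
            correct[is_cont] = rng.integers(0, 2, size=k)
    if response_window is not None:
        late = ~np.isnan(rt) & (rt > response_window)
        rt[late] = np.nan
        correct[late] = 0
    return rt, correct


# ---------------------------------------------------------------------------
# EZ-diffusion (closed-form inversion; independent of the MLE route)
# ---------------------------------------------------------------------------

def ez_diffusion(accuracy: float, rt_mean: float, rt_var: float,
                 n_trials: int | None = None):
    """EZ-diffusion closed-form (a, v, t) from accuracy, RT mean and variance.

    Standard closed forms with s = 1. Edge cases (accuracy exactly 0, 0.5 or
    1) use the 1/(2n) correction and are flagged. Returns
    ``(a, v, t, flags)``.
    """
    flags = []
    pc = float(accuracy)
    if not (0.0 <= pc <= 1.0):
        raise ValueError("accuracy must be in [0, 1]")
    if rt_var <= 0:
        raise ValueError("rt_var must be positive")
    if pc in (0.0, 1.0) or pc == 0.5:
        if n_trials is None:
            raise ValueError("n_trials required for edge-corrected accuracy")
        if pc == 1.0:
            pc = 1.0 - 1.0 / (2 * n_trials)
            flags.append("accuracy_edge_corrected")
        elif pc == 0.0:
            pc = 1.0 / (2 * n_trials)
            flags.append("accuracy_edge_corrected")
        else:
            pc = 0.5 + 1.0 / (2 * n_trials)
            flags.append("accuracy_at_chance_corrected")
    ll = np.log(pc / (1 - pc))
    x = ll * (ll * pc**2 - ll * pc + pc - 0.5) / rt_var
    vv = np.sign(pc - 0.5) * x**0.25
    aa = ll / vv
    y = -vv * aa
    mdt = (aa / (2 * vv)) * (1 - np.exp(y)) / (1 + np.exp(y))
    t0 = rt_mean - mdt
    return float(aa), float(vv), float(t0), flags


# ---------------------------------------------------------------------------
# DDM maximum-likelihood fit
# ---------------------------------------------------------------------------

@dataclass
class DDMParams:
    """Per-subject drift-diffusion parameters (s = 1, unbiased start)."""
    a: float
    v: float
    t: float
    loglik: float = np.nan
    n: int = 0
    converged: bool = True
    flags: list = field(default_factory=list)


def _ddm_nll(theta, rt_correct, rt_error, err=1e-8):
    a, v, t0 = theta
    ll = 0.0
    if rt_correct.size:
        d = wfpt_density(rt_correct - t0, a, v, boundary="upper", err=err)
        if np.any(d <= 0):
            return 1e12
        ll += np.log(d).sum()
    if rt_error.size:
        d = wfpt_density(rt_error - t0, a, v, boundary="lower", err=err)
        if np.any(d <= 0):
            return 1e12
        ll += np.log(d).sum()
    return -ll if np.isfinite(ll) else 1e12


def fit_ddm(trials: pd.DataFrame, min_trials: int = 40,
            penalty: tuple | None = None) -> DDMParams:
    """Per-subject Wiener maximum-likelihood fit of (a, v, t).

    ``trials`` needs columns ``rt_s`` and ``correct``. Correct responses load
    the upper boundary. Responded trials faster than 0.15 s are excluded as
    contaminants; omissions (NaN RT) are excluded from the likelihood.
    ``penalty`` optionally supplies ``(means, scales, weight)`` for ridge
    shrinkage toward cohort means (used by :func:`fit_ddm_cohort`).
    """
    rt = trials["rt_s"].to_numpy(dtype=float)
    correct = trials["correct"].to_numpy(dtype=int)
    responded = np.isfinite(rt)
    flags = []
    contam = responded & (rt < RT_CONTAMINANT_FLOOR)
    if contam.any():
        flags.append(f"excluded_{int(contam.sum())}_fast_contaminants")
    keep = responded & ~contam
    rt_c = rt[keep & (correct == 1)]
    rt_e = rt[keep & (correct == 0)]
    n_used = rt_c.size + rt_e.size
    if n_used < min_trials:
        raise ValueError(f"need >= {min_trials} responded trials, got {n_used}")
    if rt_e.size == 0:
        flags.append("all_correct_v_weakly_identified")

    rts_all = np.concatenate([rt_c, rt_e])
    acc = rt_c.size / n_used
    try:
        a0, v0, t00, _ = ez_diffusion(acc, rts_all.mean(), rts_all.var(ddof=1),
                                      n_trials=n_used)
    except (ValueError, FloatingPointError):
        a0, v0, t00 = 1.2, 1.0, 0.5 * rts_all.min()
    min_rt = rts_all.min()
    t00 = min(max(t00, 0.03), min_rt - 5e-3)
    a0 = min(max(a0, 0.35), 3.8)
    v0 = min(max(v0, -7.5), 7.5)
    bounds = [(0.3, 4.0), (-8.0, 8.0), (0.02, min_rt - 1e-3)]

    def objective(theta):
        val = _ddm_nll(theta, rt_c, rt_e)
        if penalty is not None:
            means, scales, weight = penalty
            val += weight * np.sum(((theta - means) / scales) ** 2)
        return val

    best = None
    for x0 in ([a0, v0, t00], [1.4, 2.0, t00], [1.0, 0.5, 0.6 * min_rt]):
        res = optimize.minimize(objective, x0=x0, method="L-BFGS-B",
                                bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError("DDM fit failed to find a finite-likelihood optimum")
    a, v, t0 = best.x
    return DDMParams(a=float(a), v=float(v), t=float(t0),
                     loglik=float(-_ddm_nll(best.x, rt_c, rt_e)), n=int(n_used),
                     converged=bool(best.success), flags=flags)


def fit_ddm_cohort(trials_by_subject: dict, hierarchical: str = "off",
                   shrink_weight: float = 2.0) -> dict:
    """Fit every subject; ``hierarchical='shrinkage'`` refits each subject
    with a ridge penalty toward the cohort means (scaled by cohort sds)."""
    if hierarchical not in ("off", "shrinkage"):
        raise ValueError("hierarchical must be 'off' or 'shrinkage'")
    fits = {s: fit_ddm(df) for s, df in trials_by_subject.items()}
    if hierarchical == "shrinkage" and len(fits) >= 3:
        theta = np.array([[f.a, f.v, f.t] for f in fits.values()])
        means = theta.mean(axis=0)
        scales = np.maximum(theta.std(axis=0, ddof=1), [0.05, 0.1, 0.01])
        fits = {s: fit_ddm(df, penalty=(means, scales, shrink_weight))
                for s, df in trials_by_subject.items()}
    return fits


# ---------------------------------------------------------------------------
# Summaries and cohort-level QC
# ---------------------------------------------------------------------------

def rt_summaries(trials: pd.DataFrame) -> dict:
    """Accuracy (omission = error, over all trials) and mean/sd of RT over
    correct responded trials (sample sd, n-1)."""
    if len(trials) == 0:
        raise ValueError("no trials")
    rt = trials["rt_s"].to_numpy(dtype=float)
    correct = trials["correct"].to_numpy(dtype=int)
    responded = np.isfinite(rt)
    accuracy = float((correct[responded] == 1).sum()) / len(trials)
    rt_ok = rt[responded & (correct == 1)]
    if rt_ok.size == 0:
        raise ValueError("no correct responded trials")
    return {
        "accuracy": accuracy,
        "rt_mean": float(rt_ok.mean()),
        "rt_std": float(rt_ok.std(ddof=1)) if rt_ok.size > 1 else 0.0,
        "n_trials": int(len(trials)),
        "n_omissions": int((~responded).sum()),
    }


def flag_outliers(table: pd.DataFrame, columns=("accuracy", "rt_mean"),
                  z: float = 2.5) -> pd.Series:
    """Cohort outlier flags: |x - mean| > z * sd on any listed column."""
    flags = pd.Series(False, index=table.index)
    for col in columns:
        x = table[col].astype(float)
        sd = x.std(ddof=1)
        if sd > 0:
            flags |= (x - x.mean()).abs() > z * sd
    return flags
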