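"""Shared helpers: deterministic seed derivation, validation, small linalg checks."""

from __future__ import annotations

import numpy as np

_MASK64 = (1 << 64) - 1


def splitmix64(x: int) -> int:
    """One step of the splitmix64 sequence (used to derive independent seeds)."""
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64


def derive_seed(seed: int, *tokens) -> int:
    """Derive a sub-seed (< 2**31) from a master seed and a sequence of tokens.

    Tokens may be ints or strings; strings are hashed bytewise so the derivation
    is stable across processes (unlike the builtin ``hash``).
    """
    x = int(seed) & _MASK64
    for tok in tokens:
        if isinstance(tok, str):
            for b in tok.encode():
                x = splitmix64(x ^ b)
        else:
            x = splitmix64(x ^ (int(tok) & _MASK64))
    return splitmix64(x) % (2**31 - 1)


def check_stochastic_matrix(pi: np.ndarray, name: str = "transition_matrix",
                            atol: float = 1e-12) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.ndim != 2 or pi.shape[0] != pi.shape[1]:
        raise ValueError(f"{name} must be square, got shape {pi.shape}")
    if np.any(pi < -atol):
        raise ValueError(f"{name} has negative entries")
    rows = pi.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-8):
        raise ValueError(f"{name} rows must sum to 1, got {rows}")
    return pi / rows[:, None]


def check_prob_vector(p: np.ndarray, name: str = "initial_dist") -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or np.any(p < -1e-12) or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError(f"{name} must be a probability vector")
    return p / p.sum()


def spectral_radius(a: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(a))))


def check_psd(m: np.ndarray, name: str = "matrix", tol: float = 1e-10) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(m)
    if w.min() < -tol * max(1.0, w.max()):
        raise ValueError(f"{name} is not positive semidefinite (min eig {w.min():.3g})")
    return m


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
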