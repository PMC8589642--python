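"""Analysis-ready ROI time series: eigenvariate extraction, nuisance
regression, high-pass filtering, standardization.

The pipeline order is fixed: eigenvariate -> nuisance regression ->
high-pass (discrete-cosine detrending, the SPM convention) -> z-scoring.
High-pass is implemented as regression on a DCT basis spanning frequencies
below the cutoff rather than an IIR filter: deterministic, no edge
transients, and exactly idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_CUTOFF_HZ = 0.008


def first_eigenvariate(voxel_matrix: np.ndarray) -> np.ndarray:
    """First principal time course of a T x V voxel matrix.

    Columns are demeaned internally; the output is the first left singular
    vector scaled to the standard deviation of the mean voxel series, with
    sign chosen so its correlation with the mean voxel series is
    non-negative.
    """
    y = np.atleast_2d(np.asarray(voxel_matrix, dtype=float))
    if y.ndim != 2 or y.shape[0] < 2:
        raise ValueError("voxel matrix must be T x V with T >= 2")
    yc = y - y.mean(axis=0)
    if not np.any(yc):
        raise ValueError("degenerate ROI: all voxel series are constant")
    u, s, _ = np.linalg.svd(yc, full_matrices=False)
    ev = u[:, 0]
    mean_series = yc.mean(axis=1)
    if ev @ mean_series < 0:
        ev = -ev
    scale = mean_series.std(ddof=0)
    if scale == 0:
        scale = (s[0] / np.sqrt(y.shape[0]))
    return ev / ev.std(ddof=0) * scale


def regress_nuisance(series: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """OLS residuals of each column of ``series`` on ``confounds`` + intercept."""
    y = np.atleast_2d(np.asarray(series, dtype=float))
    x = np.atleast_2d(np.asarray(confounds, dtype=float))
    if x.shape[0] != y.shape[0]:
        raise ValueError("series and confounds must share T")
    t_len, c = x.shape
    if t_len <= c + 1:
        raise ValueError(f"need T > C + 1 (T={t_len}, C={c})")
    design = np.column_stack([np.ones(t_len), x])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the offending columns for the error message
        bad = []
        for j in range(1, design.shape[1]):
            sub = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(j - 1)
        raise ValueError(f"confounds are rank-deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def dct_basis(n_timepoints: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine drift basis spanning frequencies below ``cutoff_hz``.

    Component k has frequency k / (2 T tr); the basis holds all k >= 1 below
    the cutoff (the constant k = 0 term is handled by the intercept).
    """
    if cutoff_hz >= 1.0 / (2.0 * tr):
        raise ValueError(f"cutoff {cutoff_hz} Hz is at or above Nyquist "
                         f"{1.0 / (2 * tr):.4g} Hz")
    n_comp = int(np.floor(2.0 * n_timepoints * tr * cutoff_hz))
    t = np.arange(n_timepoints)
    ks = np.arange(1, n_comp + 1)
    basis = np.sqrt(2.0 / n_timepoints) * np.cos(
        np.pi * np.outer(2 * t + 1, ks) / (2.0 * n_timepoints))
    return basis


def highpass_filter(series: np.ndarray, tr: float,
                    cutoff_hz: float = DEFAULT_CUTOFF_HZ) -> np.ndarray:
    """Remove slow drifts by regressing out the DCT basis below the cutoff."""
    y = np.atleast_2d(np.asarray(series, dtype=float))
    basis = dct_basis(y.shape[0], tr, cutoff_hz)
    y = y - y.mean(axis=0)
    if basis.shape[1] == 0:
        return y
    beta, *_ = np.linalg.lstsq(basis, y, rcond=None)
    return y - basis @ beta


def standardize(series: np.ndarray) -> np.ndarray:
    """Column z-scoring (population sd); errors on constant columns."""
    y = np.atleast_2d(np.asarray(series, dtype=float))
    sd = y.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = list(np.flatnonzero(sd == 0))
        raise ValueError(f"zero-variance columns: {bad}")
    return (y - y.mean(axis=0)) / sd


@dataclass
class PrepResult:
    series: np.ndarray
    provenance: dict = field(default_factory=dict)


def prepare_timeseries(series: np.ndarray, tr: float,
                       confounds: np.ndarray | None = None,
                       cutoff_hz: float = DEFAULT_CUTOFF_HZ) -> PrepResult:
    """Fixed-order prep: nuisance regression -> high-pass -> z-score.

    (Eigenvariate extraction happens upstream when voxel-level data exist;
    ROI-level inputs enter here directly.)
    """
    y = np.atleast_2d(np.asarray(series, dtype=float))
    if y.shape[1] < 2 or y.shape[0] < 50:
        raise ValueError("need T >= 50 timepoints and R >= 2 regions")
    if np.any(~np.isfinite(y)):
        raise ValueError("series contains missing values")
    steps = []
    if confounds is not None:
        y = regress_nuisance(y, confounds)
        steps.append("nuisance_regression_6param")
    y = highpass_filter(y, tr, cutoff_hz)
    steps.append(f"dct_highpass_{cutoff_hz}Hz")
    y = standardize(y)
    steps.append("zscore")
    return PrepResult(series=y, provenance={"steps": steps, "tr": tr})


def motion_qc(motion_mm: np.ndarray, max_displacement: float = 5.0,
              max_mean_fd: float = 0.5) -> dict:
    """Head-motion QC flags (flags, not silent drops).

    ``motion_mm`` is the T x 6 realignment-parameter table in mm / radians
    (rotations are converted to mm on a 50 mm sphere before displacement).
    """
    m = np.asarray(motion_mm, dtype=float)
    mm = m.copy()
    if mm.shape[1] == 6:
        mm[:, 3:] *= 50.0
    disp = np.abs(mm - mm[0]).max()
    fd = np.abs(np.diff(mm, axis=0)).sum(axis=1)
    mean_fd = float(fd.mean()) if fd.size else 0.0
    return {
        "max_displacement_mm": float(disp),
        "mean_scan_to_scan_mm": mean_fd,
        "exclude_max_displacement": bool(disp > max_displacement),
        "exclude_mean_fd": bool(mean_fd > max_mean_fd),
    }
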