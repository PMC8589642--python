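"""State-dynamics summary statistics and their group/edge-wise comparisons.

Occupancy rate is the fraction of timepoints a latent state is occupied;
mean lifetime is the average dwell duration of a state before switching
(for a Markov chain with self-transition p, its expectation is 1/(1-p)
TRs). Group contrasts use Welch two-sample t-tests with Benjamini-Hochberg
FDR across states; link-wise functional-connectivity contrasts between two
states use paired t-tests across subjects on the upper-triangle edges with
BH-FDR, returning the significant-link mask used downstream for feature
selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def occupancy_rate(sequence_or_gamma, mode: str = "hard",
                   n_states: int | None = None) -> np.ndarray:
    """Per-state occupancy fractions.

    ``mode='hard'``: count fractions of a 0-based hard state sequence.
    ``mode='soft'``: column means of a (T, K) posterior-probability matrix.
    """
    x = np.asarray(sequence_or_gamma)
    if x.size == 0:
        raise ValueError("empty sequence")
    if mode == "soft":
        if x.ndim != 2:
            raise ValueError("soft mode needs a (T, K) posterior matrix")
        return x.mean(axis=0)
    if mode != "hard":
        raise ValueError("mode must be 'hard' or 'soft'")
    seq = x.astype(int).ravel()
    k = int(n_states) if n_states is not None else int(seq.max()) + 1
    return np.bincount(seq, minlength=k).astype(float) / seq.size


def mean_lifetime(sequence, tr: float = 1.0,
                  n_states: int | None = None) -> dict:
    """Mean dwell duration per state over maximal runs.

    Boundary-truncated runs are included (simple average of maximal run
    lengths). States never visited get NaN lifetime and ``visited=False``.
    Returns lifetimes in TRs and in seconds (TRs * tr).
    """
    seq = np.asarray(sequence, dtype=int).ravel()
    if seq.size == 0:
        raise ValueError("empty sequence")
    k = int(n_states) if n_states is not None else int(seq.max()) + 1
    change = np.flatnonzero(np.diff(seq) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [seq.size]])
    run_states = seq[starts]
    run_lens = (ends - starts).astype(float)
    life = np.full(k, np.nan)
    visited = np.zeros(k, dtype=bool)
    for s in range(k):
        m = run_states == s
        if m.any():
            life[s] = run_lens[m].mean()
            visited[s] = True
    return {"lifetime_trs": life, "lifetime_s": life * tr, "visited": visited}


def metrics_table(hard_sequences: dict, tr: float,
                  n_states: int | None = None,
                  gammas: dict | None = None) -> pd.DataFrame:
    """Subject x metric table: occupancy and mean lifetime per state."""
    rows = []
    for sub, seq in hard_sequences.items():
        k = n_states if n_states is not None else int(np.max(seq)) + 1
        occ = occupancy_rate(seq, n_states=k)
        life = mean_lifetime(seq, tr=tr, n_states=k)
        row = {"subject": sub}
        for s in range(k):
            row[f"occupancy_S{s+1}"] = occ[s]
            row[f"lifetime_trs_S{s+1}"] = life["lifetime_trs"][s]
            row[f"lifetime_s_S{s+1}"] = life["lifetime_s"][s]
            if gammas is not None:
                row[f"occupancy_soft_S{s+1}"] = occupancy_rate(
                    gammas[sub], mode="soft")[s]
        rows.append(row)
    return pd.DataFrame(rows)


def fdr_bh(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection mask)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def compare_groups(metric_table: pd.DataFrame, group_labels,
                   columns=None, q: float = 0.05) -> pd.DataFrame:
    """Welch two-sample t-tests per metric column, BH-FDR across columns.

    ``group_labels`` must contain exactly two groups; the t statistic is
    signed as (first group mean - second group mean) with groups in sorted
    label order.
    """
    g = np.asarray(group_labels)
    levels = sorted(pd.unique(g))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    i1, i2 = g == levels[0], g == levels[1]
    if i1.sum() < 2 or i2.sum() < 2:
        raise ValueError("each group needs n >= 2")
    if columns is None:
        columns = [c for c in metric_table.columns
                   if metric_table[c].dtype.kind in "fc" or
                   metric_table[c].dtype.kind in "iu"]
    rows = []
    for col in columns:
        x = metric_table.loc[i1, col].astype(float).to_numpy()
        y = metric_table.loc[i2, col].astype(float).to_numpy()
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        if x.size < 2 or y.size < 2:
            t, p = np.nan, np.nan   # e.g. lifetime of a never-visited state
        elif np.array_equal(x, y):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(x, y, equal_var=False)
        rows.append({"metric": col,
                     f"mean_{levels[0]}": x.mean() if x.size else np.nan,
                     f"mean_{levels[1]}": y.mean() if y.size else np.nan,
                     "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    out["significant"] = False
    valid = np.isfinite(out["p"].to_numpy())
    if valid.any():
        q_adj, rej = fdr_bh(out.loc[valid, "p"].to_numpy(), q=q)
        out.loc[valid, "q"] = q_adj
        out.loc[valid, "significant"] = rej
    return out


def fc_state_contrast(fc_by_subject: dict, state_pair=(0, 1),
                      q: float = 0.001, roi_names=None):
    """Link-wise paired t-test between the FC matrices of two states.

    ``fc_by_subject`` maps subject -> (K, R, R) per-state connectivity
    matrices (NaN matrices mark unvisited states; those subjects are dropped
    with a report). Returns ``(edge_table, mask)`` where ``mask`` is the
    boolean upper-triangle significant-link selection at BH-FDR level ``q``.
    """
    s1, s2 = state_pair
    kept, dropped = [], []
    for sub, fc in fc_by_subject.items():
        fc = np.asarray(fc, dtype=float)
        if np.all(np.isfinite(fc[s1])) and np.all(np.isfinite(fc[s2])):
            kept.append((sub, fc))
        else:
            dropped.append(sub)
    if len(kept) < 3:
        raise ValueError(f"need >= 3 subjects with both states visited, "
                         f"got {len(kept)}")
    r = kept[0][1].shape[1]
    iu, ju = np.triu_indices(r, k=1)
    x1 = np.stack([fc[s1][iu, ju] for _, fc in kept])
    x2 = np.stack([fc[s2][iu, ju] for _, fc in kept])
    diff = x1 - x2
    sd = diff.std(axis=0, ddof=1)
    t = np.zeros(diff.shape[1])
    p = np.ones(diff.shape[1])
    nz = sd > 0
    tt = stats.ttest_rel(x1[:, nz], x2[:, nz])
    t[nz], p[nz] = tt.statistic, tt.pvalue
    p_adj, mask = fdr_bh(p, q=q)
    names = roi_names if roi_names is not None else [f"ROI{i+1:02d}"
                                                     for i in range(r)]
    table = pd.DataFrame({
        "roi_i": [names[i] for i in iu], "roi_j": [names[j] for j in ju],
        "t": t, "p": p, "q": p_adj, "selected": mask,
    })
    table.attrs["n_subjects"] = len(kept)
    table.attrs["dropped_subjects"] = dropped
    return table, mask
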