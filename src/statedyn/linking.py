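"""Brain-behavior linking: correlations, covariate regressions, and
cross-validated multivariate prediction with permutation inference.

All cross-validation is leave-one-out (LOOCV): every subject is predicted
exactly once by a model that never saw them; feature scaling is estimated
on the training fold only. Permutation p-values follow the
(1 + #{null >= observed}) / (1 + n_perm) convention, with the full LOOCV
re-run for every permuted target, so p can never be 0 and the test is
exact under exchangeability.

The elastic-net connectivity predictor supports two feature-selection
modes: "pooled" computes the significant-link mask once on all subjects
before LOOCV (the convention of selecting features on the full sample
before cross-validating, retained for comparability), and "nested"
recomputes the mask inside each training fold (strictly out-of-sample,
recommended).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.svm import SVC, SVR

from ._utils import as_rng


@dataclass
class PredictionResult:
    """Out-of-fold predictions plus permutation inference."""
    predictions: np.ndarray       # one held-out prediction per subject
    observed: np.ndarray
    score: float                  # Pearson r (regression) or accuracy
    score_name: str
    p_value: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    features: list = field(default_factory=list)
    null_scores: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def pearson_with_p(x, y):
    """Sample Pearson correlation with two-sided p (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def covariate_regression(outcome, predictors, covariates=None,
                         predictor_names=None, covariate_names=None):
    """OLS of outcome on predictors plus nuisance covariates.

    Returns a table with raw coefficients, standardized betas
    (coef * sd(x)/sd(y)) and partial two-sided p-values for each predictor
    and covariate. Collinear columns raise with their names.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    xp = np.atleast_2d(np.asarray(predictors, dtype=float))
    if xp.shape[0] != y.size:
        xp = xp.T
    names = list(predictor_names or [f"x{i+1}" for i in range(xp.shape[1])])
    if covariates is not None:
        xc = np.atleast_2d(np.asarray(covariates, dtype=float))
        if xc.shape[0] != y.size:
            xc = xc.T
        cnames = list(covariate_names or
                      [f"cov{i+1}" for i in range(xc.shape[1])])
        x = np.column_stack([xp, xc])
        names += cnames
    else:
        x = xp
    n, p = x.shape
    if n <= p + 1:
        raise ValueError(f"need n > #predictors + 1 (n={n}, p={p})")
    design = sm.add_constant(x)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        rank = np.linalg.matrix_rank(design)
        bad = [names[j - 1] for j in range(1, design.shape[1])
               if np.linalg.matrix_rank(np.delete(design, j, axis=1)) == rank]
        raise ValueError(f"collinear design columns: {bad}")
    fit = sm.OLS(y, design).fit()
    sd_y = y.std(ddof=1)
    rows = []
    for j, name in enumerate(names, start=1):
        sd_x = x[:, j - 1].std(ddof=1)
        rows.append({
            "term": name, "coef": fit.params[j],
            "beta_std": fit.params[j] * sd_x / sd_y if sd_y > 0 else np.nan,
            "se": fit.bse[j], "t": fit.tvalues[j], "p": fit.pvalues[j],
        })
    table = pd.DataFrame(rows)
    table.attrs["r_squared"] = float(fit.rsquared)
    table.attrs["n"] = int(n)
    return table


# ---------------------------------------------------------------------------
# LOOCV engines
# ---------------------------------------------------------------------------

def _fold_scalers(x):
    """Per-fold training means/sds for leave-one-out standardization."""
    n = x.shape[0]
    out = []
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        mu = x[tr].mean(axis=0)
        sd = x[tr].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        out.append((tr, mu, sd))
    return out


def _rbf_gram(a, b, gamma):
    d2 = (np.sum(a**2, axis=1)[:, None] + np.sum(b**2, axis=1)[None]
          - 2.0 * a @ b.T)
    return np.exp(-gamma * np.maximum(d2, 0.0))


def _loocv_svr(x, y, c, epsilon):
    """LOOCV RBF-SVR predictions; per-fold kernels are precomputed once so
    permutation re-runs only refit the (cheap) dual problem."""
    n, p = x.shape
    gamma = 1.0 / p
    folds = []
    for tr, mu, sd in _fold_scalers(x):
        xtr = (x[tr] - mu) / sd
        xte = (x[~tr] - mu) / sd
        ktr = _rbf_gram(xtr, xtr, gamma)
        kte = _rbf_gram(xte, xtr, gamma)
        folds.append((tr, ktr, kte))

    def run(target):
        pred = np.empty(n)
        for i, (tr, ktr, kte) in enumerate(folds):
            m = SVR(kernel="precomputed", C=c, epsilon=epsilon)
            m.fit(ktr, target[tr])
            pred[i] = m.predict(kte)[0]
        return pred

    return run


def svr_predict_loocv(features, target, n_perm: int = 1000, seed: int = 0,
                      C: float = 1.0, epsilon: float = 0.1,
                      feature_names=None,
                      alpha_stop: float | None = None) -> PredictionResult:
    """Nonlinear (RBF) support vector regression under LOOCV.

    Fixed hyperparameters (C=1, epsilon=0.1, kernel scale 1/#features after
    training-fold standardization); score is Pearson r between held-out
    predictions and observed values; inference by target permutation with
    the full LOOCV re-run per permutation.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(target, dtype=float).ravel()
    if x.shape[0] != y.size:
        raise ValueError("features and target length mismatch")
    if y.size < 10:
        raise ValueError("need n >= 10 subjects")
    if y.std() == 0:
        raise ValueError("constant target")
    run = _loocv_svr(x, y, C, epsilon)
    pred = run(y)
    r_obs = _safe_r(pred, y)
    p, null = _permutation_p(run, y, r_obs, n_perm, seed, _safe_r,
                             alpha_stop=alpha_stop)
    return PredictionResult(predictions=pred, observed=y, score=r_obs,
                            score_name="pearson_r", p_value=p,
                            n_permutations=n_perm, seed=seed,
                            features=list(feature_names or []),
                            null_scores=null)


def svm_classify_loocv(features, labels, n_perm: int = 1000, seed: int = 0,
                       C: float = 1.0, feature_names=None,
                       alpha_stop: float | None = None) -> PredictionResult:
    """Linear SVM classification under LOOCV; score is CV accuracy,
    inference by label permutation."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    lab = np.asarray(labels)
    classes = np.unique(lab)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.size}")
    if min((lab == c).sum() for c in classes) < 5:
        raise ValueError("each class needs n >= 5")
    y = (lab == classes[1]).astype(int)
    n = y.size
    folds = []
    for tr, mu, sd in _fold_scalers(x):
        xtr = (x[tr] - mu) / sd
        xte = (x[~tr] - mu) / sd
        folds.append((tr, xtr @ xtr.T, xte @ xtr.T))

    def run(target):
        pred = np.empty(n, dtype=int)
        for i, (tr, ktr, kte) in enumerate(folds):
            t = target[tr]
            if np.unique(t).size < 2:
                pred[i] = int(t[0])
                continue
            m = SVC(kernel="precomputed", C=C)
            m.fit(ktr, t)
            pred[i] = int(m.predict(kte)[0])
        return pred

    def acc(pred, obs):
        return float((pred == obs).mean())

    pred = run(y)
    a_obs = acc(pred, y)
    p, null = _permutation_p(run, y, a_obs, n_perm, seed, acc,
                             alpha_stop=alpha_stop)
    return PredictionResult(predictions=pred, observed=y, score=a_obs,
                            score_name="cv_accuracy", p_value=p,
                            n_permutations=n_perm, seed=seed,
                            features=list(feature_names or []),
                            null_scores=null,
                            extras={"classes": classes.tolist()})


def _safe_r(pred, obs):
    if np.std(pred) == 0 or np.std(obs) == 0:
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1])


def _permutation_p(run, y, observed, n_perm, seed, score_fn,
                   alpha_stop: float | None = None):
    """Permutation p with optional curtailment: when ``alpha_stop`` is set,
    permutations stop as soon as rejection at that level is impossible
    (the count of null >= observed already exceeds the critical count).
    The accept/reject decision at ``alpha_stop`` is identical to the full
    test; the returned p is then a conservative upper bound."""
    if n_perm <= 0:
        return None, None
    rng = as_rng(seed)
    crit = (np.floor(alpha_stop * (1 + n_perm)) - 1
            if alpha_stop is not None else np.inf)
    null = []
    exceed = 0
    for b in range(n_perm):
        yp = rng.permutation(y)
        s = score_fn(run(yp), yp)
        null.append(s)
        if s >= observed - 1e-12:
            exceed += 1
            if exceed > crit:
                break
    done = len(null)
    if done == n_perm:
        p = (1.0 + exceed) / (1.0 + n_perm)
    else:
        p = (1.0 + exceed) / (1.0 + done)   # already above alpha_stop
    return float(p), np.asarray(null)


# ---------------------------------------------------------------------------
# Elastic-net connectivity prediction
# ---------------------------------------------------------------------------

def _select_links(fc_a, fc_b, q, top_k):
    """Paired-t feature selection between two states' link features; falls
    back to the ``top_k`` smallest-p links when the FDR mask is empty."""
    from .metrics import fdr_bh

    diff = fc_a - fc_b
    sd = diff.std(axis=0, ddof=1)
    t = np.zeros(diff.shape[1])
    p = np.ones(diff.shape[1])
    nz = sd > 0
    if nz.any():
        res = stats.ttest_rel(fc_a[:, nz], fc_b[:, nz])
        t[nz], p[nz] = res.statistic, res.pvalue
    _, mask = fdr_bh(p, q=q)
    if not mask.any():
        mask = np.zeros_like(mask)
        mask[np.argsort(p)[:min(top_k, p.size)]] = True
    return mask


def _enet_cv_predict(xtr, ytr, xte, l1_ratio, inner_cv, n_lambdas,
                     lambda_eps=1e-2):
    """Elastic-net prediction with the penalty chosen by inner k-fold CV
    over a geometric lambda grid (sklearn path convention:
    lambda_max = max|X'y_c| / (n l1_ratio))."""
    n = ytr.size
    yc_all = ytr - ytr.mean()
    lam_max = np.abs(xtr.T @ yc_all).max() / (n * l1_ratio)
    lam_max = max(lam_max, 1e-8)
    grid = np.geomspace(lam_max, lambda_eps * lam_max, n_lambdas)
    idx = np.arange(n)
    folds = np.array_split(idx, inner_cv)

    def _path(xa, ya):
        # the path solver fits no intercept: center, fit, restore intercept
        mx, my = xa.mean(axis=0), ya.mean()
        xc = np.asfortranarray(xa - mx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, coefs, _ = enet_path(xc, ya - my, l1_ratio=l1_ratio,
                                    alphas=grid, check_input=False)
        return coefs, my - mx @ coefs

    err = np.zeros(n_lambdas)
    for va in folds:
        tr = np.setdiff1d(idx, va)
        coefs, icept = _path(xtr[tr], ytr[tr])
        pred = xtr[va] @ coefs + icept
        err += ((pred - ytr[va][:, None]) ** 2).sum(axis=0)
    best = int(np.argmin(err))
    coefs, icept = _path(xtr, ytr)
    return (float((xte @ coefs + icept)[0, best]), float(grid[best]),
            coefs[:, best])


def elasticnet_predict_loocv(fc_features, target, feature_mask=None,
                             mode: str = "nested", fc_contrast_features=None,
                             n_perm: int = 1000, seed: int = 0,
                             l1_ratio: float = 0.5, q: float = 0.001,
                             top_k: int = 10, inner_cv: int = 5,
                             n_lambdas: int = 10,
                             alpha_stop: float | None = None) -> PredictionResult:
    """Elastic-net prediction from functional-connectivity link features.

    ``mode='pooled'`` uses a fixed ``feature_mask`` (computed once on all
    subjects, as in the original analysis); ``mode='nested'`` recomputes the
    paired-t selection inside each training fold from
    ``fc_contrast_features`` = (links_state_a, links_state_b), the per-subject
    link features of the two contrasted states. The regularization path
    (alpha = l1_ratio fixed, lambda by inner k-fold CV) is fit on the
    training fold in both modes.
    """
    x = np.atleast_2d(np.asarray(fc_features, dtype=float))
    y = np.asarray(target, dtype=float).ravel()
    n = y.size
    if x.shape[0] != n:
        raise ValueError("features and target length mismatch")
    if n < 10:
        raise ValueError("need n >= 10 subjects")
    if mode == "pooled":
        if feature_mask is None:
            raise ValueError("pooled mode requires a precomputed feature_mask")
        mask_all = np.asarray(feature_mask, dtype=bool)
        if not mask_all.any():
            raise ValueError("no features selected")
    elif mode == "nested":
        if fc_contrast_features is None:
            raise ValueError("nested mode requires fc_contrast_features "
                             "(per-subject link features of both states)")
        fca, fcb = (np.atleast_2d(np.asarray(m, dtype=float))
                    for m in fc_contrast_features)
        mask_all = None
    else:
        raise ValueError("mode must be 'pooled' or 'nested'")

    scalers = _fold_scalers(x)
    fold_masks = None
    if mask_all is None:
        fold_masks = [_select_links(fca[tr], fcb[tr], q, top_k)
                      for tr, _, _ in scalers]

    coef_support = np.zeros(x.shape[1])

    def run(target_vec, record=False):
        pred = np.empty(n)
        for i, (tr, mu, sd) in enumerate(scalers):
            mask = mask_all if mask_all is not None else fold_masks[i]
            xtr = ((x[tr] - mu) / sd)[:, mask]
            xte = ((x[i] - mu) / sd)[None, mask]
            pred[i], _, coefs = _enet_cv_predict(xtr, target_vec[tr], xte,
                                                 l1_ratio, inner_cv, n_lambdas)
            if record:
                coef_support[np.flatnonzero(mask)[coefs != 0]] += 1
        return pred

    pred = run(y, record=True)
    r_obs = _safe_r(pred, y)
    p, null = _permutation_p(run, y, r_obs, n_perm, seed, _safe_r,
                             alpha_stop=alpha_stop)
    return PredictionResult(predictions=pred, observed=y, score=r_obs,
                            score_name="pearson_r", p_value=p,
                            n_permutations=n_perm, seed=seed,
                            null_scores=null,
                            extras={"mode": mode,
                                    "coef_support_frac": coef_support / n})


def elastic_net_path_fit(x, y, lam: float, l1_ratio: float = 0.5,
                         max_iter: int = 10000, tol: float = 1e-8):
    """Single elastic-net fit at a fixed penalty (sklearn objective
    1/(2n)||y - Xb||^2 + lam * (l1 |b|_1 + (1-l1)/2 |b|_2^2)); exposed so
    the unregularized limit and oracle checks can target one solver call."""
    en = ElasticNet(alpha=lam, l1_ratio=l1_ratio, max_iter=max_iter, tol=tol)
    en.fit(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return en.coef_.copy(), float(en.intercept_)
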