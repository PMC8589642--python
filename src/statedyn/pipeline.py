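"""End-to-end orchestration: simulate -> prep -> fit -> metrics -> behavior
-> link -> report, with provenance, resumability and a markdown summary.

Every stage reads only the previous stage's plain-text outputs, records its
effective parameters in ``manifest.json`` (with content hashes), and can be
re-run independently: a stage whose outputs exist under a matching manifest
entry is skipped unless ``force`` is set. Per-stage seeds derive
deterministically from the global seed, so identical config + seed gives
identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bh
from . import io as sio
from . import linking as lk
from . import metrics as sm
from . import prep as sprep
from . import slds as sslds
from . import synth as ssynth
from ._utils import derive_seed

STAGES = ["simulate", "prep", "fit", "metrics", "behavior", "link", "report"]


@dataclass
class RunConfig:
    out_dir: str = "run"
    data_dir: str | None = None      # external input dir (None -> simulate)
    tr: float = 0.49
    n_subjects: int = 20
    n_timepoints: int = 700
    K: int = 4
    d: int = 3
    n_restarts: int = 10
    max_iter: int = 300
    cutoff_hz: float = 0.008
    snr: float = 1.0
    n_trials: int = 96
    ddm_shrinkage: bool = False
    n_perm: int = 200
    enet_mode: str = "nested"
    fdr_q_states: float = 0.05
    fdr_q_links: float = 0.001
    seed: int = 0
    version: str = "0.1.0"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        known = {k: v for k, v in obj.items() if k in cls.__dataclass_fields__}
        unknown = set(obj) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class Manifest:
    def __init__(self, run_dir: Path):
        self.path = run_dir / "manifest.json"
        self.data = {"stages": {}}
        if self.path.exists():
            with open(self.path) as fh:
                self.data = json.load(fh)

    def stage_done(self, stage: str, params_key: str) -> bool:
        entry = self.data["stages"].get(stage)
        if entry is None or entry.get("params_key") != params_key:
            return False
        return all(Path(f).exists() and _hash_file(Path(f)) == h
                   for f, h in entry["files"].items())

    def record(self, stage: str, params_key: str, files):
        self.data["stages"][stage] = {
            "params_key": params_key,
            "files": {str(f): _hash_file(Path(f)) for f in files},
        }
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=1)


def _params_key(config: RunConfig, stage: str) -> str:
    payload = json.dumps({"stage": stage, **asdict(config)}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, run_dir: Path) -> Path:
    data = run_dir / "data"
    sim = ssynth.SimulationConfig(
        n_subjects=config.n_subjects, n_timepoints=config.n_timepoints,
        tr=config.tr, n_states=config.K, latent_dim=config.d,
        snr=config.snr, n_trials=config.n_trials,
        seed=derive_seed(config.seed, "simulate"))
    cohort = ssynth.generate_cohort(sim)
    sio.write_cohort(cohort, data)
    return data


def stage_prep(config: RunConfig, run_dir: Path, data_dir: Path) -> Path:
    out = run_dir / "prep"
    out.mkdir(parents=True, exist_ok=True)
    qc = {}
    for sub in sio.list_subjects(data_dir):
        y, roi_names = sio.read_roi_timeseries(data_dir, sub)
        motion = sio.read_motion(data_dir, sub)
        res = sprep.prepare_timeseries(y, tr=config.tr, confounds=motion,
                                       cutoff_hz=config.cutoff_hz)
        pd.DataFrame(res.series, columns=roi_names).to_csv(
            out / f"sub-{sub}_roits.tsv", sep="\t", index=False,
            float_format="%.6f")
        entry = dict(res.provenance)
        if motion is not None:
            entry.update(sprep.motion_qc(motion))
        qc[sub] = entry
    with open(out / "qc_report.json", "w") as fh:
        json.dump(qc, fh, indent=1)
    return out


def stage_fit(config: RunConfig, run_dir: Path, prep_dir: Path) -> Path:
    out = run_dir / "fit"
    out.mkdir(parents=True, exist_ok=True)
    subs = sio.list_subjects(prep_dir)
    dataset = [sio.read_roi_timeseries(prep_dir, s)[0] for s in subs]
    model, posteriors = sslds.fit_switching_lds(
        dataset, K=config.K, d=config.d, n_restarts=config.n_restarts,
        seed=derive_seed(config.seed, "fit"), max_iter=config.max_iter)
    model.to_json(out / "model.json")
    for sub, post in zip(subs, posteriors):
        sio.write_posteriors(out, sub, post.gamma)
    return out


def stage_metrics(config: RunConfig, run_dir: Path, prep_dir: Path,
                  fit_dir: Path) -> Path:
    out = run_dir / "metrics"
    out.mkdir(parents=True, exist_ok=True)
    model = sslds.SwitchingLDSModel.from_json(fit_dir / "model.json")
    subs = sio.list_subjects(prep_dir)
    gammas = {s: pd.read_csv(fit_dir / f"sub-{s}_posterior.tsv",
                             sep="\t").to_numpy() for s in subs}
    hard = {s: np.argmax(g, axis=1) for s, g in gammas.items()}
    table = sm.metrics_table(hard, tr=config.tr, n_states=config.K,
                             gammas=gammas)
    table.to_csv(out / "state_metrics.tsv", sep="\t", index=False,
                 float_format="%.6f")

    dataset = [sio.read_roi_timeseries(prep_dir, s)[0] for s in subs]
    roi_names = sio.read_roi_timeseries(prep_dir, subs[0])[1]
    posts = [sslds.StatePosterior(
        gamma=gammas[s], xi=np.zeros((0, config.K, config.K)),
        log_emissions=np.zeros_like(gammas[s]),
        latent_means=np.zeros((1, config.d)),
        latent_covs=np.zeros((1, config.d, config.d)),
        transition=model.Pi, initial=model.pi0) for s in subs]
    fc_cov, _ = sslds.state_covariance(model, posts, dataset,
                                       method="empirical", per_subject=True)
    iu, ju = np.triu_indices(len(roi_names), k=1)
    rows = []
    for i, s in enumerate(subs):
        for k in range(config.K):
            c = fc_cov[i][k]
            for a, b in zip(iu, ju):
                rows.append({"subject": s, "state": f"S{k+1}",
                             "roi_i": roi_names[a], "roi_j": roi_names[b],
                             "cov": c[a, b]})
    pd.DataFrame(rows).to_csv(out / "fc_links.tsv", sep="\t", index=False,
                              float_format="%.6f")
    return out


def stage_behavior(config: RunConfig, run_dir: Path, data_dir: Path) -> Path:
    out = run_dir / "behavior"
    out.mkdir(parents=True, exist_ok=True)
    subs = sio.list_subjects(data_dir)
    rows = []
    trials_by_sub = {s: sio.read_trials(data_dir, s) for s in subs}
    ddm = bh.fit_ddm_cohort(
        trials_by_sub,
        hierarchical="shrinkage" if config.ddm_shrinkage else "off")
    for s in subs:
        tr = trials_by_sub[s]
        summ = bh.rt_summaries(tr)
        rts = tr["rt_s"].to_numpy(dtype=float)
        ok = np.isfinite(rts) & (tr["correct"].to_numpy() == 1) & \
            (rts >= bh.RT_CONTAMINANT_FLOOR)
        exg = bh.fit_exgauss(rts[ok])
        d = ddm[s]
        rows.append({"subject": s, **summ, "mu": exg.mu, "sigma": exg.sigma,
                     "tau": exg.tau, "a": d.a, "v": d.v, "t": d.t,
                     "flags": ";".join(exg.flags + d.flags)})
    table = pd.DataFrame(rows)
    table["outlier"] = bh.flag_outliers(table)
    table.to_csv(out / "behavior_fits.tsv", sep="\t", index=False,
                 float_format="%.6f")
    return out


def stage_link(config: RunConfig, run_dir: Path, metrics_dir: Path,
               behavior_dir: Path, data_dir: Path) -> Path:
    out = run_dir / "link"
    out.mkdir(parents=True, exist_ok=True)
    metrics = pd.read_csv(metrics_dir / "state_metrics.tsv", sep="\t")
    behav = pd.read_csv(behavior_dir / "behavior_fits.tsv", sep="\t")
    participants = sio.read_participants(data_dir)
    table = metrics.merge(behav, on="subject").merge(participants,
                                                     on="subject")
    table.to_csv(out / "subject_table.tsv", sep="\t", index=False)
    seed = derive_seed(config.seed, "link")
    k = config.K

    # dimensional correlations: state dynamics vs behavior/symptoms
    rows = []
    metric_cols = ([f"occupancy_S{j+1}" for j in range(k)]
                   + [f"lifetime_trs_S{j+1}" for j in range(k)])
    target_cols = ["rt_std", "tau", "v", "inattention", "hyperactivity"]
    for m in metric_cols:
        for t in target_cols:
            sub = table[[m, t]].dropna()
            if len(sub) < 4 or sub[m].std() == 0 or sub[t].std() == 0:
                continue
            r, p = lk.pearson_with_p(sub[m], sub[t])
            rows.append({"metric": m, "target": t, "n": len(sub),
                         "r": r, "p": p})
    corr = pd.DataFrame(rows)
    corr["q"], _ = sm.fdr_bh(corr["p"].to_numpy(), q=config.fdr_q_states)
    corr.to_csv(out / "correlations.tsv", sep="\t", index=False,
                float_format="%.6f")

    # group contrasts on occupancy/lifetime
    groups = table["group"].to_numpy()
    contrast = sm.compare_groups(table, groups, columns=metric_cols,
                                 q=config.fdr_q_states)
    contrast.to_csv(out / "group_contrasts.tsv", sep="\t", index=False,
                    float_format="%.6f")

    # SVR: per-state dynamics features -> inattention
    feats = table[[f"occupancy_S{j+1}" for j in range(k)]
                  + [f"lifetime_trs_S{j+1}" for j in range(k)]].fillna(0.0)
    svr = lk.svr_predict_loocv(feats.to_numpy(), table["inattention"],
                               n_perm=config.n_perm, seed=seed,
                               feature_names=list(feats.columns))
    pd.DataFrame({"subject": table["subject"],
                  "observed": svr.observed,
                  "predicted": svr.predictions}).to_csv(
        out / "predictions.tsv", sep="\t", index=False, float_format="%.6f")

    # SVM: group classification from the same features
    svm = lk.svm_classify_loocv(feats.to_numpy(), groups,
                                n_perm=config.n_perm,
                                seed=derive_seed(config.seed, "link-svm"))

    # elastic net: S1 FC links -> drift rate, S1-vs-S2 contrast selection
    fc = pd.read_csv(metrics_dir / "fc_links.tsv", sep="\t")
    wide = fc.pivot_table(index="subject", columns=["state", "roi_i", "roi_j"],
                          values="cov")
    s1 = wide["S1"].reindex(table["subject"]).to_numpy()
    s2 = wide["S2"].reindex(table["subject"]).to_numpy()
    en_res = None
    ok = np.all(np.isfinite(s1), axis=1) & np.all(np.isfinite(s2), axis=1)
    if ok.sum() >= 10:
        en_res = lk.elasticnet_predict_loocv(
            s1[ok], table.loc[ok, "v"].to_numpy(), mode=config.enet_mode,
            fc_contrast_features=(s1[ok], s2[ok]), n_perm=config.n_perm,
            seed=derive_seed(config.seed, "link-enet"),
            q=config.fdr_q_links)

    results = {
        "svr_inattention": {"r": svr.score, "p": svr.p_value,
                            "n_perm": svr.n_permutations},
        "svm_group": {"cv_accuracy": svm.score, "p": svm.p_value,
                      "classes": svm.extras["classes"],
                      "n_perm": svm.n_permutations},
    }
    if en_res is not None:
        results["enet_fc_drift"] = {"r": en_res.score, "p": en_res.p_value,
                                    "mode": config.enet_mode,
                                    "n": int(ok.sum())}
    with open(out / "classification.json", "w") as fh:
        json.dump(results, fh, indent=1)
    return out


def stage_report(config: RunConfig, run_dir: Path, data_dir: Path) -> Path:
    out = run_dir / "report.md"
    lines = [f"# statedyn run report", "",
             f"seed: {config.seed}; K={config.K}, d={config.d}, "
             f"TR={config.tr}s, n_restarts={config.n_restarts}", ""]
    fit_dir, metrics_dir, link_dir = (run_dir / s for s in
                                      ("fit", "metrics", "link"))
    model = sslds.SwitchingLDSModel.from_json(fit_dir / "model.json")
    lines += [f"## Model", f"- final ELBO: {model.elbo:.1f} "
              f"(converged: {model.converged}, restart {model.restart})",
              f"- transition-matrix diagonal: "
              f"{np.round(np.diag(model.Pi), 3).tolist()}",
              f"- pruned states: {model.pruned_states or 'none'}", ""]
    table = pd.read_csv(metrics_dir / "state_metrics.tsv", sep="\t")
    occ_cols = [c for c in table.columns if c.startswith("occupancy_S")
                and "soft" not in c]
    lines += ["## State dynamics (cohort means)", "",
              "| state | occupancy | lifetime (TRs) |", "|---|---|---|"]
    for j, c in enumerate(occ_cols):
        lt = table[f"lifetime_trs_S{j+1}"].mean()
        lines.append(f"| S{j+1} | {table[c].mean():.3f} | {lt:.1f} |")
    lines.append("")

    gt = sio.read_ground_truth(data_dir)
    if gt is not None:
        subs = sio.list_subjects(data_dir)
        hard, true = [], []
        for s in subs:
            g = pd.read_csv(fit_dir / f"sub-{s}_posterior.tsv",
                            sep="\t").to_numpy()
            hard.append(np.argmax(g, axis=1))
            true.append(gt["state_sequences"][s])
        perm, acc = sslds.align_states(hard, true, K=config.K)
        occ_fit = np.stack([np.bincount(perm[h], minlength=config.K)
                            / h.size for h in hard])
        occ_true = np.stack([gt["occupancy"][s] for s in subs])
        mae = float(np.abs(occ_fit - occ_true).mean())
        lines += ["## Ground-truth recovery", "",
                  f"- aligned state accuracy: {acc:.3f}",
                  f"- occupancy MAE: {mae:.4f}",
                  f"- state permutation (model -> truth): {perm.tolist()}", ""]

    cls = json.loads((link_dir / "classification.json").read_text())
    lines += ["## Brain-behavior linking", "",
              "```json", json.dumps(cls, indent=1), "```", ""]
    out.write_text("\n".join(lines))
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, stages=None, force: bool = False) -> Path:
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(run_dir)
    stages = list(stages or STAGES)
    data_dir = Path(config.data_dir) if config.data_dir else run_dir / "data"

    def wrap(stage, fn, outputs):
        key = _params_key(config, stage)
        if not force and manifest.stage_done(stage, key):
            return
        try:
            fn()
        except Exception as exc:     # halt with stage-scoped error
            raise StageError(stage, exc) from exc
        manifest.record(stage, key, outputs())

    if "simulate" in stages and config.data_dir is None:
        wrap("simulate", lambda: stage_simulate(config, run_dir),
             lambda: sorted((run_dir / "data").glob("*.tsv"))[:3]
             + [run_dir / "data" / "ground_truth.json"])
    if "prep" in stages:
        wrap("prep", lambda: stage_prep(config, run_dir, data_dir),
             lambda: [run_dir / "prep" / "qc_report.json"])
    if "fit" in stages:
        wrap("fit", lambda: stage_fit(config, run_dir, run_dir / "prep"),
             lambda: [run_dir / "fit" / "model.json"])
    if "metrics" in stages:
        wrap("metrics", lambda: stage_metrics(config, run_dir,
                                              run_dir / "prep",
                                              run_dir / "fit"),
             lambda: [run_dir / "metrics" / "state_metrics.tsv",
                      run_dir / "metrics" / "fc_links.tsv"])
    if "behavior" in stages:
        wrap("behavior", lambda: stage_behavior(config, run_dir, data_dir),
             lambda: [run_dir / "behavior" / "behavior_fits.tsv"])
    if "link" in stages:
        wrap("link", lambda: stage_link(config, run_dir, run_dir / "metrics",
                                        run_dir / "behavior", data_dir),
             lambda: [run_dir / "link" / "classification.json",
                      run_dir / "link" / "correlations.tsv"])
    if "report" in stages:
        wrap("report", lambda: stage_report(config, run_dir, data_dir),
             lambda: [run_dir / "report.md"])
    return run_dir


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

def validate_inputs(indir) -> dict:
    """Schema/unit/consistency checks on a dataset directory. Returns a
    report dict; never raises on content problems."""
    indir = Path(indir)
    errors, warnings = [], []
    subs = sio.list_subjects(indir)
    if not subs:
        errors.append("no sub-*_roits.tsv files found")
    participants = None
    ppath = indir / "participants.tsv"
    if ppath.exists():
        participants = sio.read_participants(indir)
        required = {"subject", "group"}
        missing = required - set(participants.columns)
        if missing:
            errors.append(f"participants.tsv missing columns {sorted(missing)}")
    else:
        errors.append("participants.tsv not found")

    shapes = {}
    for s in subs:
        try:
            y, names = sio.read_roi_timeseries(indir, s)
        except Exception as exc:
            errors.append(f"sub-{s}: unreadable ROI series ({exc})")
            continue
        shapes[s] = y.shape
        if np.any(~np.isfinite(y)):
            errors.append(f"sub-{s}: non-finite ROI values")
        if y.shape[1] < 2 or y.shape[0] < 50:
            errors.append(f"sub-{s}: series too small {y.shape}")
        tpath = indir / f"sub-{s}_trials.csv"
        if tpath.exists():
            tr = sio.read_trials(indir, s)
            if "rt_s" in tr.columns:
                rt = tr["rt_s"].dropna()
                if len(rt) and rt.max() > 10:
                    errors.append(f"sub-{s}: rt_s values exceed 10 s "
                                  "(milliseconds in a seconds column?)")
            elif "rt_ms" not in tr.columns:
                errors.append(f"sub-{s}: trials need rt_s or rt_ms")
        else:
            warnings.append(f"sub-{s}: no trials file")
        if participants is not None and \
                s not in set(participants["subject"].astype(str)):
            errors.append(f"sub-{s}: present on disk but absent from "
                          "participants.tsv")
    if participants is not None:
        extra = set(participants["subject"].astype(str)) - set(subs)
        for s in sorted(extra):
            warnings.append(f"{s}: in participants.tsv but no ROI series")
    return {"n_subjects": len(subs), "errors": errors, "warnings": warnings,
            "ok": not errors}
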