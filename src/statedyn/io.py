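"""Plain-text dataset layout shared by the generator and the pipeline.

Per subject: ``sub-<id>_roits.tsv`` (header = ROI names, one row per TR),
``sub-<id>_motion.tsv`` (6 realignment parameters), ``sub-<id>_trials.csv``
(trial, onset_s, rt_s, correct, choice); cohort-level ``participants.tsv``
and ``ground_truth.json``. All numeric tables are TSV/CSV with headers —
no binaries, so outputs stay diffable and cross-language readable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

MOTION_COLS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def write_cohort(cohort, outdir) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    roi_names = cohort.config.roi_names
    for i, sub in enumerate(cohort.subjects):
        pd.DataFrame(cohort.timeseries[i], columns=roi_names).to_csv(
            out / f"sub-{sub}_roits.tsv", sep="\t", index=False,
            float_format="%.6f")
        pd.DataFrame(cohort.motion[i], columns=MOTION_COLS).to_csv(
            out / f"sub-{sub}_motion.tsv", sep="\t", index=False,
            float_format="%.6f")
        cohort.trials[sub].to_csv(out / f"sub-{sub}_trials.csv", index=False,
                                  float_format="%.4f")
    cohort.participants.to_csv(out / "participants.tsv", sep="\t", index=False)
    gt = cohort.ground_truth
    json_gt = {
        "tr": cohort.config.tr,
        "n_states": cohort.config.n_states,
        "state_sequences": {s: seq.tolist() for s, seq in
                            zip(cohort.subjects, gt["state_sequences"])},
        "occupancy": {s: occ.tolist() for s, occ in
                      zip(cohort.subjects, gt["occupancy"])},
        "lifetime_trs": {s: np.where(np.isfinite(l), l, -1.0).tolist()
                         for s, l in zip(cohort.subjects, gt["lifetime_trs"])},
        "params": gt["params"].to_dict(orient="list"),
        "transition_matrix_td": gt["transition_matrix_td"].tolist(),
        "transition_matrix_adhd": gt["transition_matrix_adhd"].tolist(),
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(json_gt, fh)
    return out


def list_subjects(indir) -> list:
    indir = Path(indir)
    subs = sorted(p.name[len("sub-"):-len("_roits.tsv")]
                  for p in indir.glob("sub-*_roits.tsv"))
    return subs


def read_roi_timeseries(indir, subject) -> tuple:
    df = pd.read_csv(Path(indir) / f"sub-{subject}_roits.tsv", sep="\t")
    return df.to_numpy(dtype=float), list(df.columns)


def read_motion(indir, subject) -> np.ndarray:
    path = Path(indir) / f"sub-{subject}_motion.tsv"
    if not path.exists():
        return None
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def read_trials(indir, subject) -> pd.DataFrame:
    """Trial table; RTs in milliseconds (an explicit ``rt_ms`` column) are
    converted to the internal seconds convention."""
    df = pd.read_csv(Path(indir) / f"sub-{subject}_trials.csv")
    if "rt_s" not in df.columns and "rt_ms" in df.columns:
        df["rt_s"] = df["rt_ms"].astype(float) / 1000.0
    return df


def read_participants(indir) -> pd.DataFrame:
    return pd.read_csv(Path(indir) / "participants.tsv", sep="\t")


def read_ground_truth(indir) -> dict | None:
    path = Path(indir) / "ground_truth.json"
    if not path.exists():
        return None
    with open(path) as fh:
        gt = json.load(fh)
    gt["state_sequences"] = {s: np.asarray(v, dtype=int)
                             for s, v in gt["state_sequences"].items()}
    gt["occupancy"] = {s: np.asarray(v, dtype=float)
                       for s, v in gt["occupancy"].items()}
    return gt


def write_posteriors(outdir, subject, gamma) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    k = gamma.shape[1]
    path = out / f"sub-{subject}_posterior.tsv"
    pd.DataFrame(gamma, columns=[f"S{j+1}" for j in range(k)]).to_csv(
        path, sep="\t", index=False, float_format="%.6f")
    return path
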