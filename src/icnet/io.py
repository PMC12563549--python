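"""Readers and writers for the on-disk study and stage outputs.

All formats are plain text: BIDS-style events TSVs, per-ROI voxel
matrices as tab-separated files with JSON sidecars, FD/motion TSVs,
long-format RSM tables, square ICM matrices with ROI-id headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import Icm
from .glm import TrialPatternSet
from .synthetic import SESSIONS, RunData

__all__ = [
    "read_roster", "iter_sessions", "load_run", "load_session_runs",
    "write_patterns", "read_patterns", "write_rsm", "read_rsm_vectors",
    "write_icm", "read_icm", "load_config",
]


def read_roster(study_dir) -> pd.DataFrame:
    return pd.read_csv(Path(study_dir) / "roster.tsv", sep="\t")


def iter_sessions(study_dir):
    """Yield (subject_id, group, session, func_dir) for every session."""
    roster = read_roster(study_dir)
    for _, row in roster.iterrows():
        for session in SESSIONS:
            func = Path(study_dir) / row["subject_id"] / f"ses-{session}" / "func"
            if func.is_dir():
                yield row["subject_id"], row["group"], session, func


def load_run(func_dir, phase: str, run: int) -> RunData | None:
    """Load one run (events, FD, motion, all ROI matrices) from disk."""
    func_dir = Path(func_dir)
    stem = f"task-{phase}_run-{run:02d}"
    ev_path = func_dir / f"{stem}_events.tsv"
    if not ev_path.exists():
        return None
    events = pd.read_csv(ev_path, sep="\t")
    events["context"] = events["context"].fillna("")
    fd = np.loadtxt(func_dir / f"{stem}_fd.tsv", ndmin=1)
    motion = np.loadtxt(func_dir / f"{stem}_motion.tsv", ndmin=2)
    rois = sorted(func_dir.glob(f"{stem}_roi-*.tsv"))
    mats, tr = [], None
    for rp in rois:
        mats.append(np.loadtxt(rp, ndmin=2))
        side = json.loads(rp.with_suffix(".json").read_text())
        tr = side["tr"]
    data = np.hstack(mats)
    V = mats[0].shape[1]
    sid = func_dir.parent.parent.name
    session = func_dir.parent.name.replace("ses-", "")
    abs_motion = float(np.abs(motion[:, :3]).max())
    return RunData(run, phase, session, sid, events, data, fd, motion,
                   abs_motion, tr, len(mats), V,
                   truth_fidelity=np.empty((0, 0)),
                   truth_amplitude=np.empty((0, 0)),
                   trial_ids=np.array([], dtype=int))


def load_session_runs(func_dir, phase: str, max_runs: int = 16) -> list:
    runs = []
    for k in range(max_runs):
        rd = load_run(func_dir, phase, k)
        if rd is not None:
            runs.append(rd)
    return runs


# --- stage outputs -------------------------------------------------------

def write_patterns(out_dir, subject_id, session, phase, patterns: dict,
                   meta: pd.DataFrame) -> None:
    d = Path(out_dir) / subject_id / f"ses-{session}" / phase
    d.mkdir(parents=True, exist_ok=True)
    meta.to_csv(d / "trials.tsv", sep="\t", index=False)
    for r, pat in patterns.items():
        np.savetxt(d / f"tmap_roi-{r:03d}.tsv", pat.tmaps, fmt="%.6f",
                   delimiter="\t")


def read_patterns(patterns_dir, subject_id, session, phase) -> tuple:
    d = Path(patterns_dir) / subject_id / f"ses-{session}" / phase
    meta = pd.read_csv(d / "trials.tsv", sep="\t")
    patterns = {}
    for f in sorted(d.glob("tmap_roi-*.tsv")):
        r = int(f.stem.split("-")[-1])
        t = np.loadtxt(f, ndmin=2)
        patterns[r] = TrialPatternSet(t, t, meta.copy(), roi_id=r)
    return patterns, meta


def write_rsm(out_dir, subject_id, session, phase, context, roi_id,
              entries: pd.DataFrame) -> None:
    d = Path(out_dir) / subject_id / f"ses-{session}" / phase / context
    d.mkdir(parents=True, exist_ok=True)
    entries.to_csv(d / f"rsm_roi-{roi_id:03d}.tsv", sep="\t", index=False)


def read_rsm_vectors(rsm_dir, subject_id, session, phase, context) -> dict:
    """Read per-ROI RSM tables back as cell-aligned vectors."""
    d = Path(rsm_dir) / subject_id / f"ses-{session}" / phase / context
    vectors = {}
    for f in sorted(d.glob("rsm_roi-*.tsv")):
        r = int(f.stem.split("-")[-1])
        tab = pd.read_csv(f, sep="\t").sort_values(["trial_i", "trial_j"])
        vectors[r] = tab["z"].to_numpy()
    return vectors


def write_icm(out_dir, icm: Icm, phase: str) -> None:
    d = Path(out_dir) / icm.subject_id / f"ses-{icm.session}" / phase
    d.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(icm.matrix, columns=[f"roi_{r}" for r in icm.roi_ids])
    df.to_csv(d / f"icm_{icm.context}.tsv", sep="\t", index=False,
              float_format="%.6f")


def read_icm(icm_dir, subject_id, session, phase, context) -> Icm:
    f = (Path(icm_dir) / subject_id / f"ses-{session}" / phase
         / f"icm_{context}.tsv")
    df = pd.read_csv(f, sep="\t")
    roi_ids = np.array([int(c.split("_")[1]) for c in df.columns])
    return Icm(subject_id, session, context, df.to_numpy(), roi_ids)


# --- configuration -------------------------------------------------------

def load_config(path) -> dict:
    """Parse a YAML pipeline configuration into config objects.

    Recognized top-level keys: ``study`` (StudyConfig fields),
    ``planted`` (PlantedEffect fields) and pipeline settings (phases,
    contexts, targets, n_perm, q_threshold, seed, ...).
    """
    import yaml

    from .pipeline import PipelineConfig
    from .synthetic import PlantedEffect, StudyConfig

    raw = yaml.safe_load(Path(path).read_text()) or {}
    study_kw = raw.pop("study", {})
    for key in ("group_sizes", "iti_range", "fidelity_range"):
        if key in study_kw:
            study_kw[key] = tuple(study_kw[key])
    planted_kw = raw.pop("planted", {})
    if "edge_list" in planted_kw:
        planted_kw["edge_list"] = tuple(map(tuple, planted_kw["edge_list"]))
    for key in ("phases", "contexts", "targets", "distance_methods"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(study=StudyConfig(**study_kw),
                          planted=PlantedEffect(**planted_kw), **raw)
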