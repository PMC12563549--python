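"""End-to-end pipeline: simulate -> LS-S -> RSM -> ICM -> inference.

Chains the stage modules over a (synthetic or on-disk) study: per
subject and session, motion censoring, LS-S single-trial t-maps per
ROI, within-context RSMs, informational connectivity matrices; then
group-level edge contrasts with permutation + FDR inference,
connectivity-profile distance tests, and the behavioral learning-rate
statistics. A JSON manifest records configuration, seed and per-stage
counts so a rerun with the same config is reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from .connectivity import compute_icm, icm_change
from .distance import distance_prepost_test, profile_distance
from .glm import build_lss_designs, censor, fit_lss, TrialPatternSet
from .inference import edge_contrast, permutation_pvalues, significant_edges
from .similarity import canonical_pairs
from .stats import fisher_z, paired_t
from .synthetic import (GROUPS, SESSIONS, PlantedEffect, StudyConfig,
                        generate_behavior, generate_cohort,
                        generate_subject_session, roi_table)

__all__ = ["PipelineConfig", "run_pipeline", "report",
           "subject_session_icms", "subject_session_patterns"]


@dataclass
class PipelineConfig:
    """Everything one pipeline invocation needs.

    Thresholds default to the analysis conventions used throughout the
    package: FD censoring at 0.9 mm, 20% run-exclusion fraction,
    1.25 mm absolute-motion limit, 10,000 permutations, FDR q < 0.05.
    """

    study: StudyConfig = field(default_factory=StudyConfig)
    planted: PlantedEffect = field(default_factory=PlantedEffect)
    phases: tuple = ("encoding", "retrieval")
    contexts: tuple = ("all", "spatial", "temporal")
    targets: tuple = ("navigation", "verbal")
    n_perm: int = 10_000
    q_threshold: float = 0.05
    fd_threshold: float = 0.9
    run_fraction: float = 0.20
    abs_threshold: float = 1.25
    distance_methods: tuple = ("pearson", "spearman")
    use_tmaps: bool = True
    seed: int = 0


# ---------------------------------------------------------------------------
# Per-subject stages
# ---------------------------------------------------------------------------

def subject_session_patterns(cfg: PipelineConfig, runs: list) -> tuple:
    """Censor + LS-S over one subject-session's runs of one phase.

    Returns (patterns_by_roi, meta, n_excluded_runs). All ROIs of a run
    are fit in one pass (the design is shared); excluded runs contribute
    no trials.
    """
    study = cfg.study
    V = study.voxels_per_roi
    per_roi_t = {r: [] for r in range(study.n_rois)}
    per_roi_b = {r: [] for r in range(study.n_rois)}
    meta_rows = []
    excluded_runs = 0
    for rd in runs:
        rep = censor(rd.fd, rd.events, rd.tr, cfg.fd_threshold,
                     cfg.run_fraction, rd.abs_motion, cfg.abs_threshold)
        if not rep.usable:
            excluded_runs += 1
            continue
        n_vols = rd.data.shape[0]
        designs = build_lss_designs(rd.events, rd.phase, n_vols, rd.tr,
                                    censor_report=rep, motion=rd.motion)
        fit = fit_lss(rd.data, designs, check_rank=False)
        interest = rd.events[rd.events["trial_type"].isin(
            ["encoding", "source_retrieval"])].sort_values("trial")
        assert [d.trial for d in designs] == interest["trial"].tolist()
        meta_rows.append(pd.DataFrame({
            "trial": interest["trial"].to_numpy(),
            "run": rd.run,
            "context": interest["context"].to_numpy(),
            "excluded": interest["trial"].isin(rep.excluded_trials).to_numpy(),
            "correct": interest["correct"].to_numpy(dtype=bool),
        }))
        for r in range(study.n_rois):
            per_roi_t[r].append(fit.tmaps[:, r * V:(r + 1) * V])
            per_roi_b[r].append(fit.betas[:, r * V:(r + 1) * V])
    if not meta_rows:
        return None, None, excluded_runs
    meta = pd.concat(meta_rows, ignore_index=True)
    patterns = {
        r: TrialPatternSet(np.vstack(per_roi_b[r]), np.vstack(per_roi_t[r]),
                           meta.copy(), roi_id=r)
        for r in range(study.n_rois)
    }
    return patterns, meta, excluded_runs


def rsm_vectors_fast(cfg: PipelineConfig, patterns: dict, meta: pd.DataFrame,
                     context: str, phase: str) -> dict:
    """Vectorized equivalent of compute_rsm + rsm_vector over all ROIs.

    Produces, for each ROI, the Fisher-z similarities of the canonical
    cross-run same-context trial pairs in ascending order — numerically
    identical to the per-ROI :func:`icnet.similarity.compute_rsm` /
    :func:`icnet.similarity.rsm_vector` route (asserted in tests), but
    computing the trial-pair bookkeeping once instead of per ROI.
    """
    keep = ~meta["excluded"].to_numpy(dtype=bool)
    if phase == "retrieval":
        keep &= meta["correct"].to_numpy(dtype=bool)
    if context != "all":
        keep &= (meta["context"] == context).to_numpy()
    else:
        keep &= meta["context"].isin(["spatial", "temporal"]).to_numpy()
    sub = meta[keep]
    pairs = canonical_pairs(sub, context)
    if len(pairs) < 2:
        raise ValueError(f"<2 usable cross-run {context} trial pairs at {phase}")
    order = np.argsort(sub["trial"].to_numpy(), kind="stable")
    rows = sub.index.to_numpy()[order]
    trials_sorted = sub["trial"].to_numpy()[order]
    zi = np.searchsorted(trials_sorted, pairs[:, 0])
    zj = np.searchsorted(trials_sorted, pairs[:, 1])
    vectors = {}
    for r, pat in patterns.items():
        X = pat.tmaps if cfg.use_tmaps else pat.betas
        corr = np.corrcoef(X[rows])
        vectors[r] = fisher_z(corr[zi, zj])
    return vectors


def subject_session_icms(cfg: PipelineConfig, patterns: dict,
                         meta: pd.DataFrame, phase: str, subject_id: str,
                         session: str) -> dict:
    """Within-context RSMs and the per-context ICMs for one subject-session."""
    icms = {}
    for context in cfg.contexts:
        vectors = rsm_vectors_fast(cfg, patterns, meta, context, phase)
        icms[context] = compute_icm(vectors, subject_id, session, context)
    return icms


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def _behavior_stats(cfg: PipelineConfig, cohort: pd.DataFrame) -> pd.DataFrame:
    """Learning rates per subject/session plus group-level pre/post tests."""
    rows = []
    for _, s in cohort.iterrows():
        for session in SESSIONS:
            tabs = generate_behavior(cfg.study, int(s["subject_index"]),
                                     session, s["group"], cfg.planted)
            nav_err = [beh.normalized_error(a, o) for a, o in
                       zip(tabs["nav"]["actual"], tabs["nav"]["optimal"])]
            rows.append({
                "subject_id": s["subject_id"], "group": s["group"],
                "session": session,
                "nav_learning_rate": beh.navigation_learning_rate(nav_err),
                "verbal_learning_rate": beh.verbal_learning_rate(
                    tabs["recall"]["recalled"].to_numpy()),
                "training_slope_early": beh.daily_max_slope(
                    tabs["training"]["max_words"][:5],
                    tabs["training"]["day"][:5]),
                "training_slope_late": beh.daily_max_slope(
                    tabs["training"]["max_words"][5:],
                    tabs["training"]["day"][5:]),
            })
    return pd.DataFrame(rows)


def _behavior_group_tests(per_subject: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for group, g in per_subject.groupby("group"):
        wide = g.pivot(index="subject_id", columns="session")
        for measure in ("nav_learning_rate", "verbal_learning_rate"):
            res = paired_t(wide[(measure, "pre")], wide[(measure, "post")])
            rows.append({"group": group, "measure": measure, "t": res.t,
                         "dof": res.dof, "p": res.p,
                         "mean_change": res.mean_diff})
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig, out_dir=None, progress: bool = False
                 ) -> dict:
    """Run the full analysis chain on a generated study.

    Returns a dict with keys ``edges`` (significant-edge table over all
    requested phase/context/target contrasts), ``edge_scan`` (per-edge t
    and permutation p for every contrast), ``distance`` (per-ROI pre/post
    profile-distance tests per group and method), ``behavior`` tables,
    and ``manifest``. With ``out_dir`` the tables and manifest are also
    written as TSV/JSON.
    """
    t0 = time.time()
    study = cfg.study
    cohort = generate_cohort(study)
    deltas = {}     # (phase, context) -> {subject_id: edge delta vector}
    dist_rows = []
    skipped = []
    for _, s in cohort.iterrows():
        si, sid, group = int(s["subject_index"]), s["subject_id"], s["group"]
        icms_by_session = {}
        for session in SESSIONS:
            data = generate_subject_session(study, si, session, group,
                                            cfg.planted, phases=cfg.phases)
            icms_by_session[session] = {}
            for phase in cfg.phases:
                patterns, meta, n_skip = subject_session_patterns(
                    cfg, data[phase])
                if patterns is None:
                    skipped.append((sid, session, phase, "all runs excluded"))
                    continue
                try:
                    icms = subject_session_icms(cfg, patterns, meta, phase,
                                                sid, session)
                except ValueError as e:
                    skipped.append((sid, session, phase, str(e)))
                    continue
                icms_by_session[session][phase] = icms
                if {"spatial", "temporal"}.issubset(icms):
                    for method in cfg.distance_methods:
                        for roi in range(study.n_rois):
                            d = profile_distance(icms["spatial"],
                                                 icms["temporal"], roi, method)
                            dist_rows.append({
                                "subject_id": sid, "group": group,
                                "phase": phase, "roi": roi, "method": method,
                                "session": session, "distance": d})
        for phase in cfg.phases:
            pre = icms_by_session["pre"].get(phase)
            post = icms_by_session["post"].get(phase)
            if pre is None or post is None:
                continue
            for context in cfg.contexts:
                dz = icm_change(pre[context], post[context])
                ii, jj = np.triu_indices(study.n_rois, k=1)
                deltas.setdefault((phase, context), {})[sid] = dz[ii, jj]
        if progress:
            print(f"  processed {sid} ({group})", flush=True)

    # --- group-level edge inference ---
    roster = cohort.set_index("subject_id")["group"]
    edge_tables, scan_rows = [], []
    rng_seed = cfg.seed
    for (phase, context), subj_map in sorted(deltas.items()):
        sids = sorted(subj_map)
        mat = np.vstack([subj_map[x] for x in sids])
        groups = roster.loc[sids].to_numpy()
        for target in cfg.targets:
            t_obs = edge_contrast(mat, groups, target)
            p = permutation_pvalues(mat, groups, target, cfg.n_perm,
                                    seed=rng_seed)
            roi_ids = np.arange(study.n_rois)
            edge_tables.append(significant_edges(
                p, t_obs, roi_ids, cfg.q_threshold, context, phase, target))
            ii, jj = np.triu_indices(study.n_rois, k=1)
            scan_rows.append(pd.DataFrame({
                "phase": phase, "context": context, "target_group": target,
                "roi_i": ii, "roi_j": jj, "t": t_obs, "p_perm": p}))
    edges = (pd.concat(edge_tables, ignore_index=True) if edge_tables
             else pd.DataFrame())
    if len(edges):
        rois = roi_table(study).set_index("roi_id")
        for side in ("i", "j"):
            edges[f"roi_{side}_name"] = rois.loc[edges[f"roi_{side}"],
                                                 "roi_name"].to_numpy()
            edges[f"network_{side}"] = rois.loc[edges[f"roi_{side}"],
                                                "network"].to_numpy()
    edge_scan = (pd.concat(scan_rows, ignore_index=True) if scan_rows
                 else pd.DataFrame())

    # --- distance tests ---
    dist_df = pd.DataFrame(dist_rows)
    dist_tests = []
    if len(dist_df):
        for (phase, method), block in dist_df.groupby(["phase", "method"]):
            for group in GROUPS:
                if not (block["group"] == group).any():
                    continue
                try:
                    res = distance_prepost_test(block, group, method,
                                                cfg.q_threshold)
                except ValueError as e:
                    skipped.append(("distance", phase, f"{group}/{method}",
                                    str(e)))
                    continue
                res.insert(0, "phase", phase)
                dist_tests.append(res)
    distance = (pd.concat(dist_tests, ignore_index=True) if dist_tests
                else pd.DataFrame())

    # --- behavior ---
    behavior_subjects = _behavior_stats(cfg, cohort)
    behavior_tests = _behavior_group_tests(behavior_subjects)

    manifest = {
        "config": {
            "study": asdict(cfg.study),
            "planted": {k: (list(map(list, v)) if k == "edge_list" else v)
                        for k, v in asdict(cfg.planted).items()},
            "phases": list(cfg.phases), "contexts": list(cfg.contexts),
            "targets": list(cfg.targets), "n_perm": cfg.n_perm,
            "q_threshold": cfg.q_threshold, "seed": cfg.seed,
        },
        "n_subjects": int(len(cohort)),
        "skipped": [list(x) for x in skipped],
        "n_significant_edges": int(len(edges)),
        "n_distance_hits": int(distance["significant"].sum())
        if len(distance) else 0,
        "runtime_s": round(time.time() - t0, 2),
    }
    results = {"edges": edges, "edge_scan": edge_scan, "distance": distance,
               "distance_raw": dist_df, "behavior": behavior_subjects,
               "behavior_tests": behavior_tests, "manifest": manifest}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("edges", "edge_scan", "distance", "distance_raw",
                     "behavior", "behavior_tests"):
            results[name].to_csv(out / f"{name}.tsv", sep="\t", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return results


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def report(results) -> str:
    """Human-readable summary of a pipeline result dict or directory."""
    if isinstance(results, (str, Path)):
        d = Path(results)
        results = {}
        warn = []
        for name in ("edges", "distance", "behavior_tests"):
            f = d / f"{name}.tsv"
            if f.exists():
                try:
                    results[name] = pd.read_csv(f, sep="\t")
                except pd.errors.EmptyDataError:
                    results[name] = pd.DataFrame()
            else:
                warn.append(name)
        mf = d / "manifest.json"
        results["manifest"] = (json.loads(mf.read_text()) if mf.exists()
                               else {})
        if warn:
            results["_warnings"] = warn

    lines = ["Informational-connectivity pipeline report",
             "=" * 44]
    for name in results.get("_warnings", []):
        lines.append(f"WARNING: missing output table {name!r}")
    edges = results.get("edges")
    if edges is None or not len(edges):
        lines.append("Significant edges: none")
    else:
        lines.append(f"Significant edges: {len(edges)}")
        for (phase, context, target), block in edges.groupby(
                ["phase", "context", "target_group"]):
            lines.append(f"  {phase}/{context}: {target} vs rest — "
                         f"{len(block)} edge(s)")
            for _, e in block.head(10).iterrows():
                lines.append(
                    f"    ROI {e.roi_i:>3} – ROI {e.roi_j:>3}  "
                    f"t={e.t:+.2f}  q={e.q:.4f}  {e.direction}")
    dist = results.get("distance")
    if dist is not None and len(dist):
        hits = dist[dist["significant"]]
        lines.append(f"Profile-distance hits: {len(hits)}")
        for _, h in hits.head(10).iterrows():
            lines.append(f"    ROI {h.roi:>3} [{h.group}/{h.method}] "
                         f"t={h.t:+.2f} q={h.q:.4f} "
                         f"{'post>pre' if h.post_greater else 'post<pre'}")
    else:
        lines.append("Profile-distance hits: none")
    bt = results.get("behavior_tests")
    if bt is not None and len(bt):
        lines.append("Behavior (pre->post learning-rate change, paired t):")
        for _, b in bt.iterrows():
            lines.append(f"    {b['group']:<11} {b['measure']:<21} "
                         f"t({b.dof})={b.t:+.2f} p={b.p:.4f}")
    mf = results.get("manifest", {})
    if mf:
        lines.append(f"Subjects: {mf.get('n_subjects')}; "
                     f"skipped: {len(mf.get('skipped', []))}; "
                     f"runtime: {mf.get('runtime_s')}s")
    return "\n".join(lines)
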