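"""Study-level validation experiments on synthetic data.

Each runner builds a full synthetic study, pushes it through the
pipeline stages, and scores the outcome against the generator's ground
truth: permutation-test calibration under the null, planted-edge
recovery power, LS-S amplitude fidelity, and profile-distance recovery.
These are the package's own correctness experiments; they run at
desk scale (reduced ROI/trial counts, documented in the methods note)
so a full replicate set completes in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .inference import permutation_pvalues
from .pipeline import (PipelineConfig, subject_session_icms,
                       subject_session_patterns)
from .stats import bh_fdr
from .synthetic import (PlantedEffect, StudyConfig, generate_cohort,
                        generate_distance_cohort, generate_subject_session)

__all__ = [
    "study_edge_deltas", "null_calibration", "planted_recovery",
    "lss_fidelity", "distance_recovery",
]

#: Coupling schedule used for planted-edge recovery runs: base 0.2
#: rising to 0.7 post-training in the target group, which yields a mean
#: planted-edge change of about +0.5 Fisher-z units.
RECOVERY_BASE_COUPLING = 0.2
RECOVERY_DELTA_COUPLING = 0.5


def study_edge_deltas(study: StudyConfig, planted: PlantedEffect,
                      phase: str = "encoding", context: str = "all"):
    """Run simulate -> censor -> LS-S -> RSM -> ICM -> post-pre deltas.

    Returns (groups, deltas) with one row per subject that yielded both
    sessions, columns = unique edges.
    """
    cfg = PipelineConfig(study=study, planted=planted, phases=(phase,),
                         contexts=(context,))
    cohort = generate_cohort(study)
    groups, rows = [], []
    ii, jj = np.triu_indices(study.n_rois, k=1)
    for _, s in cohort.iterrows():
        si, group = int(s["subject_index"]), s["group"]
        mats = {}
        for session in ("pre", "post"):
            data = generate_subject_session(study, si, session, group,
                                            planted, phases=(phase,))
            pats, meta, _ = subject_session_patterns(cfg, data[phase])
            if pats is None:
                break
            try:
                icms = subject_session_icms(cfg, pats, meta, phase,
                                            s["subject_id"], session)
            except ValueError:
                break
            mats[session] = icms[context].matrix
        if len(mats) == 2:
            dz = mats["post"] - mats["pre"]
            rows.append(dz[ii, jj])
            groups.append(group)
    return np.array(groups), np.vstack(rows)


def null_calibration(seed: int = 0, n_replicates: int = 100,
                     n_perm: int = 1000, q: float = 0.05,
                     n_trials: int = 24, target: str = "verbal",
                     progress: bool = False) -> dict:
    """Permutation + FDR calibration on null studies (no planted effects).

    24 ROIs, 12 subjects per group, no coupling difference between
    groups. Pools per-edge permutation p-values over replicates
    (uniform under the null) and scores the empirical false-discovery
    proportion of the BH-corrected edge family per replicate.
    """
    pooled, fdp = [], []
    for rep in range(n_replicates):
        study = StudyConfig(group_sizes=(12, 12, 12), n_rois=24,
                            voxels_per_roi=30, n_encoding_trials=n_trials,
                            seed=seed + 7919 * rep)
        planted = PlantedEffect()   # delta_coupling = 0: global null
        groups, deltas = study_edge_deltas(study, planted)
        p = permutation_pvalues(deltas, groups, target, n_perm,
                                seed=seed + rep)
        pooled.append(p)
        rej = bh_fdr(p, q).n_rejected
        fdp.append(1.0 if rej > 0 else 0.0)   # every rejection is false
        if progress and (rep + 1) % 10 == 0:
            print(f"  null replicate {rep + 1}/{n_replicates}", flush=True)
    pooled = np.concatenate(pooled)
    ks = sps.kstest(pooled, "uniform")
    mc_se = np.sqrt(q * (1 - q) / n_replicates)
    return {
        "ks_p": float(ks.pvalue),
        "ks_stat": float(ks.statistic),
        "empirical_fdr": float(np.mean(fdp)),
        "fdr_bound": q + 3 * mc_se,
        "n_pvalues": int(pooled.size),
        "p_values": pooled,
    }


def planted_recovery(seed: int = 0, n_replicates: int = 50,
                     n_perm: int = 1000, q: float = 0.05,
                     progress: bool = False) -> dict:
    """Planted-edge recovery at the published contrast's group sizes.

    Group sizes 26/25/20 (navigation/verbal/control) with two coupled
    ROI pairs whose coupling rises post-training in the verbal group
    only; scores the fraction of replicates in which every planted edge
    survives FDR and the false-discovery proportion among non-planted
    edges.
    """
    edge_list = ((0, 1), (2, 3))
    n_rois = 12
    ii, jj = np.triu_indices(n_rois, k=1)
    edge_pos = {tuple(e): int(np.flatnonzero((ii == e[0]) & (jj == e[1]))[0])
                for e in edge_list}
    hits, fdps, mean_dzs = [], [], []
    for rep in range(n_replicates):
        study = StudyConfig(group_sizes=(26, 25, 20), n_rois=n_rois,
                            voxels_per_roi=30, n_encoding_trials=40,
                            seed=seed + 104729 * rep + 1)
        planted = PlantedEffect(edge_list=edge_list, target_group="verbal",
                                base_coupling=RECOVERY_BASE_COUPLING,
                                delta_coupling=RECOVERY_DELTA_COUPLING)
        groups, deltas = study_edge_deltas(study, planted)
        mean_dzs.append(deltas[groups == "verbal"][:,
                        list(edge_pos.values())].mean())
        p = permutation_pvalues(deltas, groups, "verbal", n_perm,
                                seed=seed + rep)
        fdr = bh_fdr(p, q)
        planted_idx = np.array(list(edge_pos.values()))
        hits.append(bool(fdr.rejected[planted_idx].all()))
        n_rej = fdr.n_rejected
        n_false = int(fdr.rejected.sum() - fdr.rejected[planted_idx].sum())
        fdps.append(n_false / n_rej if n_rej else 0.0)
        if progress and (rep + 1) % 10 == 0:
            print(f"  recovery replicate {rep + 1}/{n_replicates}", flush=True)
    mc_se = np.sqrt(q * (1 - q) / n_replicates)
    return {
        "recovery_rate": float(np.mean(hits)),
        "empirical_fdr": float(np.mean(fdps)),
        "fdr_bound": q + 3 * mc_se,
        "mean_planted_dz": float(np.mean(mean_dzs)),
        "n_replicates": n_replicates,
    }


def lss_fidelity(seed: int = 0) -> dict:
    """Amplitude recovery of the LS-S stage against generator truth.

    At the default contrast-to-noise ratio, the correlation between
    planted per-trial voxel amplitudes and estimated betas is computed
    per ROI; with noise switched off and one trial per run (isolated,
    fully modeled responses), recovery is exact.
    """
    study = StudyConfig(group_sizes=(2, 2, 2), n_rois=4, voxels_per_roi=50,
                        n_encoding_trials=40, seed=seed)
    cfg = PipelineConfig(study=study, phases=("encoding",))
    data = generate_subject_session(study, 0, "pre", "control",
                                    phases=("encoding",))
    pats, meta, _ = subject_session_patterns(cfg, data["encoding"])
    keep = ~meta["excluded"].to_numpy()
    corrs = []
    for r in range(study.n_rois):
        truth = np.vstack([rd.roi_truth_amplitude(r)
                           for rd in data["encoding"]])
        corrs.append(np.corrcoef(truth[keep].ravel(),
                                 pats[r].betas[keep].ravel())[0, 1])

    study0 = StudyConfig(group_sizes=(2, 2, 2), n_rois=2, voxels_per_roi=40,
                         n_encoding_trials=4, n_encoding_runs=4,
                         noise_sd=0.0, spike_prob=0.0, seed=seed)
    cfg0 = PipelineConfig(study=study0, phases=("encoding",))
    data0 = generate_subject_session(study0, 0, "pre", "control",
                                     phases=("encoding",))
    pats0, _, _ = subject_session_patterns(cfg0, data0["encoding"])
    errs = []
    for r in range(study0.n_rois):
        truth = np.vstack([rd.roi_truth_amplitude(r)
                           for rd in data0["encoding"]])
        errs.append(np.abs(pats0[r].betas - truth).max())
    return {
        "min_roi_recovery_corr": float(np.min(corrs)),
        "mean_roi_recovery_corr": float(np.mean(corrs)),
        "noiseless_max_abs_error": float(np.max(errs)),
    }


def distance_recovery(seed: int = 0, n_replicates: int = 50,
                      n_subjects: int = 24, n_rois: int = 24,
                      shift: float = 0.3, sd: float = 0.1,
                      q: float = 0.05) -> dict:
    """Detection of a planted profile-distance divergence in one ROI.

    Each replicate draws per-subject spatial/temporal profile distances
    with a +``shift`` post-training change (subject sd ``sd``) in one
    ROI and none elsewhere, then runs the paired-t + FDR test across
    ROIs.
    """
    from .distance import distance_prepost_test

    planted_roi = 5
    hits, fdps = [], []
    for rep in range(n_replicates):
        tab = generate_distance_cohort(n_subjects, n_rois, planted_roi,
                                       shift=shift, sd=sd,
                                       seed=seed + 3571 * rep)
        res = distance_prepost_test(tab, "verbal", "pearson", q)
        sig = res[res["significant"]]
        hits.append(bool((sig["roi"] == planted_roi).any()))
        n_rej = len(sig)
        n_false = int((sig["roi"] != planted_roi).sum())
        fdps.append(n_false / n_rej if n_rej else 0.0)
    mc_se = np.sqrt(q * (1 - q) / n_replicates)
    return {
        "recovery_rate": float(np.mean(hits)),
        "empirical_fdr": float(np.mean(fdps)),
        "fdr_bound": q + 3 * mc_se,
        "n_replicates": n_replicates,
    }
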