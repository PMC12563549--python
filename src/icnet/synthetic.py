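"""Synthetic cognitive-training study generator with planted effects.

Emulates a three-arm training study (navigation / verbal memory / video
control; default 27/27/21 subjects) scanned pre and post training: per
subject and session, 4 encoding runs (context-pure, spatial or
temporal) and 4 retrieval runs of a source-memory task, per-ROI
voxel x time BOLD matrices, framewise-displacement traces with motion
spikes, and behavioral tables for the navigation and verbal-memory
transfer tasks plus the 10-day training course.

The fMRI generative mechanism plants *informational* coupling, i.e.
correlated representational-similarity structure, via shared latent
trial fidelities:

* each ROI holds a fixed, unit-RMS "context pattern" per context
  (spatial/temporal), stable across sessions;
* each trial t has a latent fidelity f_t in [0, 1]; the trial's voxel
  pattern is f_t * P_context + sqrt(1 - f_t^2) * residual, so trial-pair
  similarity tracks f_t * f_t';
* a coupled ROI pair draws its fidelity latents with correlation equal
  to the coupling strength (base, plus ``delta_coupling`` at the post
  session for the target group only); uncoupled ROIs draw
  independently. Shared fidelity is the minimal generative cause of
  informational connectivity, which is by definition correlated
  trial-pair similarity structure.
* the voxel pattern time course is convolved with the same double-gamma
  HRF the GLM uses, scaled to a configurable contrast-to-noise ratio,
  and summed with task-nuisance responses, low-frequency drift, white
  noise, and motion-spike artifacts at high-FD volumes.

Residual pattern directions are (where voxel count allows) mutually
orthogonal, zero-mean and equal-norm, so that in the noiseless limit
trial-pair similarity equals f_t * f_t' exactly and two perfectly
coupled ROIs have identical similarity matrices.

Ground truth (fidelities, voxel amplitudes, coupling schedule,
behavioral parameters) is carried alongside the data so recovery tests
can score every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .glm import hrf_regressor, hrf_regressor_matrix

__all__ = [
    "GROUPS",
    "StudyConfig",
    "PlantedEffect",
    "RunData",
    "generate_cohort",
    "generate_events",
    "generate_motion",
    "generate_subject_session",
    "generate_behavior",
    "generate_distance_cohort",
    "write_study",
]

GROUPS = ("navigation", "verbal", "control")
SESSIONS = ("pre", "post")
PHASES = ("encoding", "retrieval")

#: network labels cycled over ROIs (Yeo-style functional systems)
NETWORKS = ("Visual", "SomMot", "DorsAttn", "SalVentAttn",
            "Limbic", "Cont", "Default")

# internal stage codes for seed derivation
_STAGE_COHORT = 1
_STAGE_EVENTS = 2
_STAGE_MOTION = 3
_STAGE_LATENT = 4
_STAGE_NOISE = 5
_STAGE_PATTERN = 6
_STAGE_BEHAVIOR = 7


@dataclass(frozen=True)
class StudyConfig:
    """Study-level parameters; defaults mirror the emulated study design.

    TR 1.56 s; 4 encoding runs (context-pure, two spatial + two
    temporal) with 80 trials total; 4 retrieval runs with 100 trials;
    groups of 27/27/21. ``cnr`` is the per-voxel peak signal amplitude
    in units of the white-noise standard deviation.
    """

    group_sizes: tuple = (27, 27, 21)       # navigation, verbal, control
    n_rois: int = 24
    voxels_per_roi: int = 50
    tr: float = 1.56
    n_encoding_runs: int = 4
    n_retrieval_runs: int = 4
    n_encoding_trials: int = 80             # half spatial, half temporal
    n_retrieval_trials: int = 100
    trial_duration: float = 6.0             # encoding stimulus, seconds
    iti_range: tuple = (2.0, 6.0)           # jittered fixation
    cnr: float = 1.0
    noise_sd: float = 1.0
    drift_amplitude: float = 0.5            # in noise-sd units
    spike_prob: float = 0.02                # per-volume FD-spike probability
    retrieval_accuracy: float = 0.85
    fidelity_range: tuple = (0.15, 0.9)
    background_coupling: float = 0.0    # optional global fidelity factor
    seed: int = 0

    def __post_init__(self):
        if len(self.group_sizes) != len(GROUPS):
            raise ValueError(f"need {len(GROUPS)} group sizes")
        if min(self.group_sizes) < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.voxels_per_roi < 30:
            raise ValueError("ROIs must contain a minimum of 30 voxels")
        if self.n_rois < 2 or self.n_rois > 242:
            raise ValueError("n_rois must be in [2, 242]")
        if self.n_encoding_runs % 2:
            raise ValueError("encoding runs must split evenly across contexts")
        if self.n_encoding_trials % self.n_encoding_runs:
            raise ValueError("encoding trials must divide evenly across runs")
        if self.n_retrieval_trials % self.n_retrieval_runs:
            raise ValueError("retrieval trials must divide evenly across runs")

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes)


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth effects injected into the synthetic study.

    ``edge_list`` ROI pairs share fidelity latents with correlation
    ``base_coupling`` everywhere, raised by ``delta_coupling`` at the
    post session in ``target_group`` only. ``distance_roi`` (optional)
    gets a post-session spatial/temporal profile divergence: the ROI is
    decoupled from the study's global background fidelity factor on
    temporal-context trials only, so its temporal connectivity profile
    flattens while the spatial one is preserved. ``behavior_gain``
    shifts the trained group's post-session learning curve (navigation
    initial-error reduction / recall slope increase).
    """

    edge_list: tuple = ()
    target_group: str = "verbal"
    base_coupling: float = 0.2
    delta_coupling: float = 0.0
    distance_roi: int | None = None
    behavior_gain: float = 0.0

    def __post_init__(self):
        if self.target_group not in GROUPS:
            raise ValueError(f"unknown group {self.target_group!r}")
        for c in (self.base_coupling, self.base_coupling + self.delta_coupling):
            if not 0.0 <= c <= 1.0:
                raise ValueError("coupling must stay in [0, 1]")
        seen = set()
        for i, j in self.edge_list:
            if i == j:
                raise ValueError("self-edges are not valid couplings")
            if i in seen or j in seen:
                raise ValueError("each ROI may appear in at most one planted edge")
            seen.update((i, j))

    def coupling(self, group: str, session: str) -> float:
        c = self.base_coupling
        if group == self.target_group and session == "post":
            c += self.delta_coupling
        return c


def _rng(config: StudyConfig, *key) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *key])


def roi_table(config: StudyConfig) -> pd.DataFrame:
    """ROI roster: id, name, network label, voxel count."""
    ids = np.arange(config.n_rois)
    return pd.DataFrame({
        "roi_id": ids,
        "roi_name": [f"ROI_{i:03d}" for i in ids],
        "network": [NETWORKS[i % len(NETWORKS)] for i in ids],
        "n_voxels": config.voxels_per_roi,
    })


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: StudyConfig) -> pd.DataFrame:
    """Subject roster: id, group, sex, site; both sessions implied.

    Sexes and sites are balanced within group up to rounding, with a
    seed-determined interleaving so the two factors are not confounded.
    """
    rows = []
    idx = 0
    for group, size in zip(GROUPS, config.group_sizes):
        rng = _rng(config, _STAGE_COHORT, GROUPS.index(group))
        idx_in = np.arange(size)
        sexes = np.array(["M", "F"])[idx_in % 2]
        sites = np.array(["A", "B"])[((idx_in + 1) // 2) % 2]
        perm = rng.permutation(size)
        for k in range(size):
            rows.append({
                "subject_id": f"sub-{idx:03d}",
                "subject_index": idx,
                "group": group,
                "sex": sexes[perm[k]],
                "site": sites[perm[k]],
            })
            idx += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

def _session_code(session: str) -> int:
    if session not in SESSIONS:
        raise ValueError(f"session must be one of {SESSIONS}")
    return SESSIONS.index(session)


def _encoding_run_events(rng, config: StudyConfig, run: int, context: str,
                         trial_ids) -> pd.DataFrame:
    rows = []
    t = 0.0
    rows.append(dict(onset=t, duration=4.0, trial_type="instruction", trial=-1,
                     context="", response_time=np.nan, correct=True))
    t += 4.0
    lo, hi = config.iti_range
    for k, trial in enumerate(trial_ids):
        rows.append(dict(onset=t, duration=config.trial_duration,
                         trial_type="encoding", trial=trial, context=context,
                         response_time=np.nan, correct=True))
        t += config.trial_duration
        rt = rng.uniform(0.8, 3.0)
        rows.append(dict(onset=t, duration=rt, trial_type="rating", trial=trial,
                         context=context, response_time=rt, correct=True))
        rows.append(dict(onset=t + rt, duration=6.0 - rt, trial_type="post_rating",
                         trial=trial, context=context, response_time=np.nan,
                         correct=True))
        t += 6.0
        rows.append(dict(onset=t, duration=rng.uniform(lo, hi), trial_type="iti",
                         trial=-1, context="", response_time=np.nan, correct=True))
        t = rows[-1]["onset"] + rows[-1]["duration"]
        if (k + 1) % 5 == 0 and k + 1 < len(trial_ids):
            # unmodeled control-judgment block: the implicit baseline
            rows.append(dict(onset=t, duration=8.0, trial_type="baseline",
                             trial=-1, context="", response_time=np.nan,
                             correct=True))
            t += 8.0
    df = pd.DataFrame(rows)
    df["run"] = run
    df["phase"] = "encoding"
    return df


def _retrieval_run_events(rng, config: StudyConfig, run: int, trial_ids,
                          contexts, correct_flags) -> pd.DataFrame:
    rows = []
    t = 0.0
    rows.append(dict(onset=t, duration=4.0, trial_type="instruction", trial=-1,
                     context="", response_time=np.nan, correct=True))
    t += 4.0
    lo, hi = config.iti_range
    for trial, context, ok in zip(trial_ids, contexts, correct_flags):
        rt_item = rng.uniform(0.8, 3.0)
        rows.append(dict(onset=t, duration=rt_item, trial_type="item_retrieval",
                         trial=trial, context=context, response_time=rt_item,
                         correct=ok))
        rows.append(dict(onset=t + rt_item, duration=6.0 - rt_item,
                         trial_type="post_item", trial=trial, context=context,
                         response_time=np.nan, correct=ok))
        t += 6.0
        rt_src = rng.uniform(1.0, 4.0)
        rows.append(dict(onset=t, duration=rt_src, trial_type="source_retrieval",
                         trial=trial, context=context, response_time=rt_src,
                         correct=ok))
        rows.append(dict(onset=t + rt_src, duration=6.0 - rt_src,
                         trial_type="post_source", trial=trial, context=context,
                         response_time=np.nan, correct=ok))
        t += 6.0
        # ITI fixation: unmodeled implicit baseline at retrieval
        rows.append(dict(onset=t, duration=rng.uniform(lo, hi), trial_type="iti",
                         trial=-1, context="", response_time=np.nan, correct=True))
        t = rows[-1]["onset"] + rows[-1]["duration"]
    df = pd.DataFrame(rows)
    df["run"] = run
    df["phase"] = "retrieval"
    return df


def generate_events(config: StudyConfig, subject_index: int, session: str
                    ) -> dict:
    """Event tables per phase, one BIDS-style table per run.

    Encoding runs are context-pure (spatial/temporal alternating, equal
    split); retrieval runs mix contexts, with per-trial source-judgment
    correctness drawn at ``retrieval_accuracy``. Onsets are strictly
    increasing; ITIs are jittered uniformly over ``iti_range``.
    """
    sess = _session_code(session)
    out = {"encoding": [], "retrieval": []}
    per_run = config.n_encoding_trials // config.n_encoding_runs
    for run in range(config.n_encoding_runs):
        rng = _rng(config, _STAGE_EVENTS, subject_index, sess, 0, run)
        context = "spatial" if run % 2 == 0 else "temporal"
        trial_ids = np.arange(run * per_run, (run + 1) * per_run)
        out["encoding"].append(
            _encoding_run_events(rng, config, run, context, trial_ids))
    per_run_r = config.n_retrieval_trials // config.n_retrieval_runs
    for run in range(config.n_retrieval_runs):
        rng = _rng(config, _STAGE_EVENTS, subject_index, sess, 1, run)
        trial_ids = np.arange(run * per_run_r, (run + 1) * per_run_r)
        contexts = np.array(["spatial", "temporal"])[np.arange(per_run_r) % 2]
        rng.shuffle(contexts)
        correct = rng.random(per_run_r) < config.retrieval_accuracy
        out["retrieval"].append(
            _retrieval_run_events(rng, config, run, trial_ids, contexts, correct))
    return out


def run_length_vols(events: pd.DataFrame, tr: float, pad: float = 16.0) -> int:
    """Number of volumes covering all events plus a settle-down pad."""
    end = (events["onset"] + events["duration"]).max() + pad
    return int(np.ceil(end / tr))


# ---------------------------------------------------------------------------
# Motion
# ---------------------------------------------------------------------------

def generate_motion(config: StudyConfig, subject_index: int, session: str,
                    phase: str, run: int, n_vols: int):
    """FD trace, six motion-parameter columns, and absolute displacement.

    FD is generated directly as the spike-magnitude series (baseline
    ~0.1 mm jitter, spikes above 0.9 mm with probability
    ``spike_prob``); the six nuisance columns are slow random walks.
    """
    sess = _session_code(session)
    rng = _rng(config, _STAGE_MOTION, subject_index, sess,
               PHASES.index(phase), run)
    fd = np.abs(rng.normal(0.08, 0.04, n_vols))
    fd[0] = 0.0
    spikes = rng.random(n_vols) < config.spike_prob
    spikes[0] = False
    fd[spikes] = rng.uniform(1.0, 2.5, spikes.sum())
    motion = np.cumsum(rng.normal(0.0, 0.02, (n_vols, 6)), axis=0)
    abs_motion = float(np.abs(motion[:, :3]).max())
    return fd, motion, abs_motion


# ---------------------------------------------------------------------------
# Patterns and latent fidelities
# ---------------------------------------------------------------------------

def _orthogonal_basis(rng, V: int, n: int, against: np.ndarray) -> np.ndarray:
    """n random columns, zero-mean, orthogonal to ``against`` columns and
    (while dimension allows) to each other; each scaled to unit RMS."""
    R = rng.standard_normal((V, n))
    A = np.column_stack([np.ones(V), against]) if against.size else np.ones((V, 1))
    Q_a, _ = np.linalg.qr(A)
    R -= Q_a @ (Q_a.T @ R)
    n_ortho = min(n, V - A.shape[1])
    if n_ortho > 0:
        Q, _ = np.linalg.qr(R[:, :n_ortho])
        R[:, :n_ortho] = Q
    # any overflow columns stay merely projected; normalize all to RMS 1
    R /= np.sqrt((R**2).mean(axis=0, keepdims=True))
    return R


def context_patterns(config: StudyConfig, subject_index: int) -> np.ndarray:
    """Session-stable unit-RMS context pattern per (ROI, context).

    Shape (n_rois, 2, V); index 0 = spatial, 1 = temporal. Zero-mean
    across voxels so similarity equals the fidelity product exactly in
    the noiseless, orthogonal-residual limit.
    """
    V = config.voxels_per_roi
    rng = _rng(config, _STAGE_PATTERN, subject_index)
    P = np.empty((config.n_rois, 2, V))
    for r in range(config.n_rois):
        B = _orthogonal_basis(rng, V, 2, against=np.empty((V, 0)))
        P[r, 0], P[r, 1] = B[:, 0], B[:, 1]
    return P


def _fidelities(config: StudyConfig, subject_index: int, session: str,
                phase: str, n_trials: int, group: str,
                planted: PlantedEffect, temporal_trials=None) -> np.ndarray:
    """Latent fidelity per (ROI, trial).

    All ROIs share a weak global factor (``background_coupling``),
    which gives every ROI correlated spatial and temporal connectivity
    profiles; planted edges add pairwise coupling on top; a planted
    ``distance_roi`` loses the background factor on temporal trials at
    the post session (target group only).
    """
    sess = _session_code(session)
    rng = _rng(config, _STAGE_LATENT, subject_index, sess, PHASES.index(phase))
    e = rng.standard_normal((config.n_rois, n_trials))
    g0 = rng.standard_normal(n_trials)         # global background factor
    b = config.background_coupling
    x = np.sqrt(b) * g0[None, :] + np.sqrt(1 - b) * e
    s = planted.coupling(group, session)
    for i, j in planted.edge_list:
        g = rng.standard_normal(n_trials)
        x[i] = np.sqrt(s) * g + np.sqrt(1 - s) * x[i]
        x[j] = np.sqrt(s) * g + np.sqrt(1 - s) * x[j]
    if (planted.distance_roi is not None and session == "post"
            and group == planted.target_group and temporal_trials is not None
            and len(temporal_trials)):
        d = planted.distance_roi
        x[d, temporal_trials] = e[d, temporal_trials]  # background removed
    lo, hi = config.fidelity_range
    return lo + (hi - lo) * norm.cdf(x)


# ---------------------------------------------------------------------------
# BOLD synthesis
# ---------------------------------------------------------------------------

@dataclass
class RunData:
    """Generated data for one run: signal, motion, and ground truth."""

    run: int
    phase: str
    session: str
    subject_id: str
    events: pd.DataFrame
    data: np.ndarray              # (n_vols, n_rois * V)
    fd: np.ndarray
    motion: np.ndarray
    abs_motion: float
    tr: float
    n_rois: int
    voxels_per_roi: int
    truth_fidelity: np.ndarray    # (n_rois, n_trials_run)
    truth_amplitude: np.ndarray   # (n_trials_run, n_rois * V)
    trial_ids: np.ndarray

    def roi_data(self, roi: int) -> np.ndarray:
        V = self.voxels_per_roi
        return self.data[:, roi * V:(roi + 1) * V]

    def roi_truth_amplitude(self, roi: int) -> np.ndarray:
        V = self.voxels_per_roi
        return self.truth_amplitude[:, roi * V:(roi + 1) * V]


_NUISANCE_SIGNAL = {
    # relative response amplitude of non-trial events (fraction of cnr)
    "encoding": {"rating": 0.6, "post_rating": 0.3, "iti": 0.2,
                 "instruction": 0.5},
    "retrieval": {"item_retrieval": 0.6, "post_item": 0.3,
                  "post_source": 0.3, "instruction": 0.5},
}
_INTEREST_TYPE = {"encoding": "encoding", "retrieval": "source_retrieval"}


def generate_subject_session(config: StudyConfig, subject_index: int,
                             session: str, group: str,
                             planted: PlantedEffect | None = None,
                             phases=PHASES) -> dict:
    """Generate all runs for one subject and session.

    Returns ``{phase: [RunData, ...]}``. Trial voxel patterns are
    f * P_context + sqrt(1 - f^2) * residual (unit-RMS components),
    scaled by ``cnr * noise_sd``; the pattern's time course is the
    trial's HRF-convolved boxcar. Nuisance events evoke spatially
    uniform responses; low-frequency drift, white noise and spike
    artifacts at high-FD volumes are added on top.
    """
    planted = planted or PlantedEffect()
    sess = _session_code(session)
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    V = config.voxels_per_roi
    amp = config.cnr * (config.noise_sd if config.noise_sd > 0 else 1.0)
    events_all = generate_events(config, subject_index, session)
    P = context_patterns(config, subject_index)
    out = {}
    for phase in phases:
        runs = events_all[phase]
        n_trials = (config.n_encoding_trials if phase == "encoding"
                    else config.n_retrieval_trials)
        all_ev = pd.concat(runs, ignore_index=True)
        interest = all_ev[all_ev["trial_type"] == _INTEREST_TYPE[phase]]
        ctx_of_trial = dict(zip(interest["trial"], interest["context"]))
        temporal_trials = sorted(
            t for t, c in ctx_of_trial.items() if c == "temporal")
        fid = _fidelities(config, subject_index, session, phase, n_trials,
                          group, planted, temporal_trials=temporal_trials)
        basis_rng = _rng(config, _STAGE_PATTERN, subject_index, sess,
                         PHASES.index(phase), 7)
        residual = np.empty((config.n_rois, n_trials, V))
        for c_idx, ctx in enumerate(("spatial", "temporal")):
            trials_c = sorted(t for t, c in ctx_of_trial.items() if c == ctx)
            for r in range(config.n_rois):
                B = _orthogonal_basis(basis_rng, V, len(trials_c),
                                      against=P[r, c_idx:c_idx + 1].T)
                residual[r, trials_c] = B.T
        out[phase] = []
        for run_events in runs:
            out[phase].append(_generate_run(
                config, subject_index, session, group, phase, run_events,
                fid, residual, P, ctx_of_trial, amp))
    return out


def _generate_run(config, subject_index, session, group, phase, events,
                  fid, residual, P, ctx_of_trial, amp):
    sess = _session_code(session)
    V = config.voxels_per_roi
    run = int(events["run"].iloc[0])
    n_vols = run_length_vols(events, config.tr)
    types = events["trial_type"].to_numpy()
    ev_onsets = events["onset"].to_numpy(dtype=float)
    ev_durations = events["duration"].to_numpy(dtype=float)
    im = types == _INTEREST_TYPE[phase]
    trial_ids = events["trial"].to_numpy(dtype=int)[im]
    C = hrf_regressor_matrix(ev_onsets[im], ev_durations[im], n_vols, config.tr)

    # trial pattern amplitudes: (n_trials_run, n_rois * V)
    ctx_idx = np.array([0 if ctx_of_trial[t] == "spatial" else 1
                        for t in trial_ids])
    W = np.empty((trial_ids.size, config.n_rois * V))
    truth_f = np.empty((config.n_rois, trial_ids.size))
    for r in range(config.n_rois):
        f = fid[r, trial_ids]                               # (n_trials,)
        pats = P[r, ctx_idx]                                # (n_trials, V)
        res = residual[r, trial_ids]                        # (n_trials, V)
        W[:, r * V:(r + 1) * V] = amp * (
            f[:, None] * pats + np.sqrt(1 - f**2)[:, None] * res)
        truth_f[r] = f
    signal = C @ W

    nuis = np.zeros(n_vols)
    for tt, rel in _NUISANCE_SIGNAL[phase].items():
        nm = (types == tt) & (ev_durations > 0)
        if nm.any():
            nuis += rel * amp * hrf_regressor(
                ev_onsets[nm], ev_durations[nm], n_vols, config.tr)
    signal += nuis[:, None]

    fd, motion, abs_motion = generate_motion(
        config, subject_index, session, phase, run, n_vols)
    rng = _rng(config, _STAGE_NOISE, subject_index, sess,
               PHASES.index(phase), run)
    if config.noise_sd > 0:
        t = np.arange(n_vols) / n_vols
        n_cos = 3
        drift_basis = np.column_stack(
            [np.cos(np.pi * (k + 1) * t) for k in range(n_cos)])
        drift_coef = rng.normal(0.0, config.drift_amplitude * config.noise_sd,
                                (n_cos, signal.shape[1]))
        signal += drift_basis @ drift_coef
        signal += rng.normal(0.0, config.noise_sd, signal.shape)
        spikes = fd > 0.9
        if spikes.any():
            signal[spikes] += rng.normal(0.0, 6.0 * config.noise_sd,
                                         (int(spikes.sum()), signal.shape[1]))
    return RunData(run, phase, session, f"sub-{subject_index:03d}", events,
                   signal, fd, motion, abs_motion, config.tr, config.n_rois,
                   V, truth_f, W, trial_ids)


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

# navigation transfer: normalized error a * exp(-k (t-1)) + b
_NAV_A, _NAV_B, _NAV_K, _NAV_NOISE = 0.8, 0.15, 0.10, 0.05
#: post-session fractional reduction of the initial-error amplitude
#: common to all groups (practice effect); a smaller early-late error
#: gap raises the learning rate toward 0
_NAV_COMMON_GAIN = 0.15
# verbal transfer: recall ~ c0 + rate * trial, capped at 12 words
_REC_C0, _REC_RATE, _REC_NOISE = 3.5, 1.2, 0.8
# training daily maxima: intercept and day slopes (first 5 / last 5 days)
_TRAIN_PARAMS = {
    "verbal": (7.0, 2.5, 1.5),
    "navigation": (7.0, 0.8, 0.5),
    "control": (7.0, 0.5, 0.3),
}
N_NAV_TRIALS = 20
N_RECALL_TRIALS = 5
N_TRAINING_DAYS = 10


def generate_behavior(config: StudyConfig, subject_index: int, session: str,
                      group: str, planted: PlantedEffect | None = None) -> dict:
    """Behavioral tables for one subject/session.

    ``nav``: 20 transfer-task trials with actual and optimal path
    lengths, normalized error decaying exponentially over trials; the
    initial-error amplitude shrinks post-training (most for the
    navigation group when ``behavior_gain`` > 0), which narrows the
    early-late error gap and raises the learning rate.
    ``recall``: words recalled per transfer
    trial (<= 12 words, 5 trials), growing linearly with a rate raised
    post-training for the verbal group. ``training``: daily maximum
    recalled words over the 10 training days (subject-stable; linear
    growth with group-dependent slopes for days 1-5 and 6-10).
    """
    planted = planted or PlantedEffect()
    sess = _session_code(session)
    rng = _rng(config, _STAGE_BEHAVIOR, subject_index, sess)

    a = _NAV_A
    if session == "post":
        shrink = _NAV_COMMON_GAIN
        if group == "navigation":
            shrink += planted.behavior_gain
        a *= max(1.0 - shrink, 0.1)
    trials = np.arange(1, N_NAV_TRIALS + 1)
    err = a * np.exp(-_NAV_K * (trials - 1)) + _NAV_B
    err = np.maximum(err + rng.normal(0, _NAV_NOISE, N_NAV_TRIALS), 0.0)
    optimal = rng.uniform(80.0, 120.0, N_NAV_TRIALS)
    nav = pd.DataFrame({
        "trial": trials,
        "optimal": optimal,
        "actual": optimal * (1.0 + err),
    })

    rate = _REC_RATE
    if session == "post" and group == "verbal":
        rate += planted.behavior_gain
    t_rec = np.arange(1, N_RECALL_TRIALS + 1)
    recalled = _REC_C0 + rate * t_rec + rng.normal(0, _REC_NOISE,
                                                   N_RECALL_TRIALS)
    recalled = np.clip(np.round(recalled), 0, 12).astype(int)
    recall = pd.DataFrame({"trial": t_rec, "recalled": recalled})

    # training course: one per subject, identical across sessions
    t_rng = _rng(config, _STAGE_BEHAVIOR, subject_index, 9)
    m0, s1, s2 = _TRAIN_PARAMS[group]
    days = np.arange(1, N_TRAINING_DAYS + 1)
    base = np.where(days <= 5, m0 + s1 * days,
                    m0 + 5 * s1 + s2 * (days - 5))
    daily = np.maximum(np.round(base + t_rng.normal(0, 1.0, days.size)), 0)
    training = pd.DataFrame({"day": days, "max_words": daily.astype(int)})
    return {"nav": nav, "recall": recall, "training": training}


# ---------------------------------------------------------------------------
# Distance-level cohort (lightweight synthetic; no BOLD)
# ---------------------------------------------------------------------------

def generate_distance_cohort(n_subjects: int, n_rois: int, planted_roi: int,
                             shift: float = 0.3, sd: float = 0.1,
                             baseline: float = 1.0, baseline_sd: float = 0.15,
                             seed: int = 0, group: str = "verbal"
                             ) -> pd.DataFrame:
    """Synthetic per-subject profile-distance tables with one planted ROI.

    A lightweight stand-in for the full BOLD chain when only the
    ROI-level distance test is under study: every ROI's pre and post
    distances are drawn around ``baseline``; the planted ROI's post
    distance is shifted by ``shift`` with subject noise ``sd``. Output
    is long-format (subject_id, group, roi, session, distance) ready
    for :func:`icnet.distance.distance_prepost_test`.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 31])
    rows = []
    for s in range(n_subjects):
        pre = np.clip(rng.normal(baseline, baseline_sd, n_rois), 0.0, 2.0)
        post = np.clip(pre + rng.normal(0.0, sd, n_rois), 0.0, 2.0)
        post[planted_roi] = np.clip(
            pre[planted_roi] + rng.normal(shift, sd), 0.0, 2.0)
        for roi in range(n_rois):
            rows.append((f"sub-{s:03d}", group, roi, "pre", pre[roi]))
            rows.append((f"sub-{s:03d}", group, roi, "post", post[roi]))
    return pd.DataFrame(rows, columns=["subject_id", "group", "roi",
                                       "session", "distance"])


# ---------------------------------------------------------------------------
# On-disk study
# ---------------------------------------------------------------------------

def write_study(config: StudyConfig, planted: PlantedEffect, out_dir,
                phases=PHASES, subjects=None) -> dict:
    """Write a full synthetic study to ``out_dir`` as plain-text files.

    Layout: ``roster.tsv``, ``rois.tsv``; per subject/session/run BIDS
    style ``*_events.tsv``, per-ROI voxel matrices ``*_roi-XXX.tsv``
    with JSON sidecars, ``*_fd.tsv`` and ``*_motion.tsv``; behavioral
    tables under ``beh/``; ground truth (fidelities, coupling schedule,
    behavior parameters) under ``ground_truth/``. Identical
    (config, seed) yield byte-identical files. Returns a manifest dict.
    """
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    cohort.to_csv(out / "roster.tsv", sep="\t", index=False)
    rois = roi_table(config)
    rois.to_csv(out / "rois.tsv", sep="\t", index=False)
    gt_dir = out / "ground_truth"
    gt_dir.mkdir(exist_ok=True)
    sched = [{"roi_i": int(i), "roi_j": int(j),
              "base": planted.base_coupling,
              "post_target": planted.base_coupling + planted.delta_coupling,
              "target_group": planted.target_group}
             for i, j in planted.edge_list]
    (gt_dir / "coupling_schedule.json").write_text(json.dumps(sched, indent=1))
    (gt_dir / "planted_effect.json").write_text(
        json.dumps(asdict(planted), indent=1, default=list))

    count = 0
    if subjects is None:
        subjects = cohort["subject_index"].tolist()
    for _, row in cohort[cohort["subject_index"].isin(subjects)].iterrows():
        si, sid, group = int(row["subject_index"]), row["subject_id"], row["group"]
        for session in SESSIONS:
            sdir = out / sid / f"ses-{session}"
            (sdir / "func").mkdir(parents=True, exist_ok=True)
            (sdir / "beh").mkdir(parents=True, exist_ok=True)
            data = generate_subject_session(config, si, session, group,
                                            planted, phases=phases)
            for phase, runs in data.items():
                for rd in runs:
                    stem = f"task-{phase}_run-{rd.run:02d}"
                    fdir = sdir / "func"
                    rd.events.to_csv(fdir / f"{stem}_events.tsv", sep="\t",
                                     index=False)
                    np.savetxt(fdir / f"{stem}_fd.tsv", rd.fd, fmt="%.6f")
                    np.savetxt(fdir / f"{stem}_motion.tsv", rd.motion,
                               fmt="%.6f", delimiter="\t")
                    fids = pd.DataFrame(rd.truth_fidelity.T,
                                        columns=[f"roi_{r:03d}" for r in
                                                 range(config.n_rois)])
                    fids.insert(0, "trial", rd.trial_ids)
                    fids.to_csv(gt_dir / f"{sid}_ses-{session}_{stem}_fidelity.tsv",
                                sep="\t", index=False, float_format="%.6f")
                    for r in range(config.n_rois):
                        rstem = fdir / f"{stem}_roi-{r:03d}"
                        np.savetxt(f"{rstem}.tsv", rd.roi_data(r), fmt="%.5f",
                                   delimiter="\t")
                        meta = {"tr": config.tr, "roi_id": r,
                                "roi_name": rois["roi_name"][r],
                                "network": rois["network"][r],
                                "n_voxels": config.voxels_per_roi}
                        Path(f"{rstem}.json").write_text(json.dumps(meta))
                    count += 1
            beh = generate_behavior(config, si, session, group, planted)
            for name, df in beh.items():
                df.to_csv(sdir / "beh" / f"{name}.tsv", sep="\t", index=False)
    manifest = {"n_subjects": len(subjects), "runs_written": count,
                "seed": config.seed, "phases": list(phases)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
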