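"""Least-Squares-Separate (LS-S) single-trial estimation.

One GLM is fit per trial: the trial of interest gets its own regressor
and every other trial of the same kind is collapsed into a second
regressor, alongside the task nuisance regressors, head-motion columns
and one spike regressor per high-motion volume. The per-trial voxel
pattern handed downstream is the t-map (beta / SE), which normalizes
each voxel's estimate by its noise level.

Motion handling follows scrubbing conventions: volumes with framewise
displacement (FD) above 0.9 mm are censored via spike regressors; a run
is dropped entirely when more than 20% of its volumes are censored or
absolute motion exceeds 1.25 mm (half a voxel); trials whose modeled
response window contains any censored volume are flagged for exclusion
from similarity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "double_gamma_hrf",
    "hrf_regressor",
    "hrf_regressor_matrix",
    "censor",
    "build_lss_designs",
    "fit_lss",
    "CensorReport",
    "DesignMatrix",
    "TrialPatternSet",
]

# Canonical double-gamma HRF parameters (SPM-style): response peak 6 s,
# undershoot peak 16 s, both dispersions 1 s, undershoot ratio 1/6.
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_PEAK_DISP = 1.0
HRF_UNDERSHOOT_DISP = 1.0
HRF_RATIO = 1.0 / 6.0

#: Designs are built on a grid of TR/OVERSAMPLE so jittered onsets that do
#: not align with volume acquisition times are represented correctly.
OVERSAMPLE = 10

#: Seconds added after event offset when deciding whether a censored
#: volume contaminates a trial's modeled response (covers the HRF rise).
RESPONSE_WINDOW = 6.0


def double_gamma_hrf(dt: float, length: float = 32.0) -> np.ndarray:
    """Sample the canonical double-gamma HRF at spacing ``dt``.

    Difference of two gamma densities (peak at ~5 s, undershoot at
    ~15 s), truncated at ``length`` seconds and normalized to unit peak.
    """
    from scipy.stats import gamma

    if dt <= 0:
        raise ValueError("dt must be positive")
    if length < 20:
        raise ValueError("HRF length must cover the undershoot (>= 20 s)")
    if dt >= length:
        raise ValueError("dt must be smaller than the kernel length")
    t = np.arange(0, length, dt)
    peak = gamma.pdf(t, HRF_PEAK_DELAY / HRF_PEAK_DISP, scale=HRF_PEAK_DISP)
    under = gamma.pdf(
        t, HRF_UNDERSHOOT_DELAY / HRF_UNDERSHOOT_DISP, scale=HRF_UNDERSHOOT_DISP
    )
    h = peak - HRF_RATIO * under
    return h / h.max()


def _hrf_kernel(dt: float) -> np.ndarray:
    # tiny cache: designs and synthesis hit the same dt thousands of times
    key = round(dt, 9)
    if key not in _hrf_kernel._cache:
        _hrf_kernel._cache[key] = double_gamma_hrf(dt)
    return _hrf_kernel._cache[key]


_hrf_kernel._cache = {}


def hrf_regressor_matrix(onsets, durations, n_vols: int, tr: float,
                         oversample: int = OVERSAMPLE) -> np.ndarray:
    """One HRF-convolved boxcar column per event, sampled at volume times.

    Boxcars are laid out on a fine grid of ``tr / oversample`` seconds,
    convolved with the canonical HRF, then sampled at t = i * TR.
    Returns an (n_vols, n_events) array.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    if onsets.size != durations.size:
        raise ValueError("onsets and durations must have equal length")
    dt = tr / oversample
    fine_n = n_vols * oversample
    h = _hrf_kernel(dt)
    out = np.empty((n_vols, onsets.size))
    box = np.empty(fine_n)
    for k, (on, du) in enumerate(zip(onsets, durations)):
        box[:] = 0.0
        i0 = int(round(on / dt))
        i1 = int(round((on + du) / dt))
        if i0 < fine_n:
            box[i0:min(i1, fine_n)] = 1.0
        out[:, k] = np.convolve(box, h)[:fine_n:oversample]
    return out


def hrf_regressor(onsets, durations, n_vols: int, tr: float,
                  oversample: int = OVERSAMPLE) -> np.ndarray:
    """Single HRF-convolved regressor pooling all given events."""
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    if onsets.size != durations.size:
        raise ValueError("onsets and durations must have equal length")
    dt = tr / oversample
    fine_n = n_vols * oversample
    box = np.zeros(fine_n)
    for on, du in zip(onsets, durations):
        i0 = int(round(on / dt))
        i1 = int(round((on + du) / dt))
        if i0 < fine_n:
            box[i0:min(i1, fine_n)] += 1.0
    return np.convolve(box, _hrf_kernel(dt))[:fine_n:oversample].copy()


# ---------------------------------------------------------------------------
# Motion censoring
# ---------------------------------------------------------------------------

@dataclass
class CensorReport:
    """Censoring decisions for one run."""

    censored_volumes: np.ndarray        # indices with FD > threshold
    fraction_censored: float
    run_excluded: bool
    abs_motion_excluded: bool
    excluded_trials: dict = field(default_factory=dict)  # trial -> reason

    @property
    def usable(self) -> bool:
        return not (self.run_excluded or self.abs_motion_excluded)


def censor(fd_trace, events: pd.DataFrame, tr: float,
           fd_threshold: float = 0.9, run_fraction: float = 0.20,
           abs_motion: float = 0.0, abs_threshold: float = 1.25,
           response_window: float = RESPONSE_WINDOW) -> CensorReport:
    """Apply FD-based volume censoring and run/trial exclusion rules.

    Volumes with FD > ``fd_threshold`` (mm) are censored. The run is
    excluded when the censored fraction exceeds ``run_fraction`` or when
    ``abs_motion`` (maximum absolute displacement, mm) exceeds
    ``abs_threshold``. A trial is excluded when any censored volume falls
    inside [onset, onset + duration + response_window].

    ``events`` must carry ``onset``, ``duration``, ``trial`` columns;
    rows with trial < 0 (nuisance events) are ignored for trial
    exclusion.
    """
    fd = np.asarray(fd_trace, dtype=float)
    if np.any(fd < 0):
        raise ValueError("negative framewise displacement")
    bad = np.flatnonzero(fd > fd_threshold)
    frac = bad.size / fd.size if fd.size else 0.0
    run_excluded = frac > run_fraction
    abs_excluded = abs_motion > abs_threshold

    excluded: dict = {}
    if bad.size:
        bad_times = bad * tr  # volume acquisition onset times
        trials = events[events["trial"] >= 0]
        for trial, grp in trials.groupby("trial"):
            lo = grp["onset"].min()
            hi = (grp["onset"] + grp["duration"]).max() + response_window
            if np.any((bad_times >= lo) & (bad_times < hi)):
                excluded[int(trial)] = "censored frame in response window"
    return CensorReport(bad, frac, run_excluded, abs_excluded, excluded)


# ---------------------------------------------------------------------------
# LS-S design construction
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Design for one single-trial GLM."""

    matrix: np.ndarray
    names: list
    trial: int
    tr: float
    run: int = 0
    flags: list = field(default_factory=list)

    @property
    def n_vols(self) -> int:
        return self.matrix.shape[0]


# nuisance task regressors per phase, in the order they enter the design
_ENCODING_NUISANCE = ["rating", "post_rating", "iti", "instruction"]
_RETRIEVAL_NUISANCE = ["post_source", "item_retrieval", "post_item", "instruction"]
_INTEREST = {"encoding": "encoding", "retrieval": "source_retrieval"}


def build_lss_designs(events: pd.DataFrame, phase: str, n_vols: int, tr: float,
                      censor_report: CensorReport | None = None,
                      motion: np.ndarray | None = None) -> list:
    """Build one LS-S design matrix per trial of interest.

    At encoding the trial of interest is the 6 s encoding event; the
    remaining columns model all other encoding trials, rating periods,
    post-rating remainders, ITI fixations and instructions (the control
    judgment period stays unmodeled as implicit baseline). At retrieval
    the trial of interest is the source-judgment period; other source
    trials, post-judgment remainders, item-retrieval periods, post-item
    remainders and instructions are modeled, with ITI unmodeled. Spike
    regressors (one column per censored volume), six motion columns and
    an intercept complete each design. A trial with a missing response
    time is modeled at its nominal full duration and flagged.
    """
    if phase not in _INTEREST:
        raise ValueError(f"phase must be 'encoding' or 'retrieval', got {phase!r}")
    interest_type = _INTEREST[phase]
    nuisance_types = _ENCODING_NUISANCE if phase == "encoding" else _RETRIEVAL_NUISANCE

    types = events["trial_type"].to_numpy()
    onsets = events["onset"].to_numpy(dtype=float)
    durations = events["duration"].to_numpy(dtype=float).copy()
    trial_ids = events["trial"].to_numpy(dtype=int)

    im = types == interest_type
    if not im.any():
        raise ValueError(f"no {interest_type!r} events in table")
    missing = im & np.isnan(durations)
    flags_missing_rt = set(trial_ids[missing].tolist())
    # nominal full duration for missing RTs (6 s trial window)
    durations[missing] = 6.0

    per_trial = hrf_regressor_matrix(onsets[im], durations[im], n_vols, tr)
    all_interest = per_trial.sum(axis=1)
    trial_cols = {
        int(t): per_trial[:, k] for k, t in enumerate(trial_ids[im])
    }
    nuisance_cols, nuisance_names = [], []
    for tt in nuisance_types:
        nm = (types == tt) & (durations > 0)
        if nm.any():
            nuisance_cols.append(
                hrf_regressor(onsets[nm], durations[nm], n_vols, tr))
            nuisance_names.append(tt)

    extra_cols, extra_names = [], []
    if censor_report is not None and censor_report.censored_volumes.size:
        for v in censor_report.censored_volumes:
            col = np.zeros(n_vols)
            col[v] = 1.0
            extra_cols.append(col)
            extra_names.append(f"spike_{v}")
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n_vols:
            raise ValueError("motion columns must match run length")
        for j in range(motion.shape[1]):
            extra_cols.append(motion[:, j])
            extra_names.append(f"motion_{j}")

    run_id = int(events["run"].iloc[0]) if "run" in events else 0
    designs = []
    for trial in sorted(trial_cols):
        c = trial_cols[trial]
        if len(trial_cols) > 1:
            cols = [c, all_interest - c]
            names = ["trial_of_interest", "other_trials"]
        else:  # lone trial in run: no "other trials" regressor exists
            cols = [c]
            names = ["trial_of_interest"]
        cols = cols + nuisance_cols + extra_cols + [np.ones(n_vols)]
        names = names + nuisance_names + extra_names + ["intercept"]
        X = np.column_stack(cols)
        if np.any(np.all(X == 0, axis=0)):
            dead = [names[j] for j in np.flatnonzero(np.all(X == 0, axis=0))]
            raise ValueError(f"all-zero design column(s): {dead}")
        flags = ["missing_rt"] if trial in flags_missing_rt else []
        designs.append(DesignMatrix(X, names, trial, tr, run_id, flags))
    return designs


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class TrialPatternSet:
    """Per-trial voxel patterns for one ROI (or a stack of ROIs).

    ``betas`` and ``tmaps`` are (n_trials, n_voxels); ``meta`` has one
    row per trial (trial, run, context, excluded, correct).
    """

    betas: np.ndarray
    tmaps: np.ndarray
    meta: pd.DataFrame
    roi_id: int = -1

    def usable(self) -> pd.DataFrame:
        return self.meta[~self.meta["excluded"]]


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # walk columns to name the first that adds no rank
        for j in range(1, X.shape[1] + 1):
            if np.linalg.matrix_rank(X[:, :j]) < j:
                raise np.linalg.LinAlgError(
                    f"rank-deficient design: column {names[j - 1]!r} is collinear"
                )


def _fit_one(X: np.ndarray, Y: np.ndarray) -> tuple:
    """Generic OLS t-map for the first design column."""
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ (X.T @ Y)
    resid = Y - X @ coef
    dof = X.shape[0] - X.shape[1]
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se = np.sqrt(sigma2 * XtX_inv[0, 0])
    return coef[0], se


def _shared_nuisance(designs: list) -> bool:
    """True when every design differs only in its first trial column(s)."""
    if len(designs) < 2:
        return False
    head = designs[0].names
    if head[:2] != ["trial_of_interest", "other_trials"]:
        return False
    return all(d.names == head for d in designs)


def fit_lss(data: np.ndarray, designs: list, meta: pd.DataFrame | None = None,
            check_rank: bool = True) -> TrialPatternSet:
    """Fit each single-trial design by OLS and return beta- and t-maps.

    ``data`` is (n_vols, n_voxels). For each design the coefficient of
    the trial-of-interest column and its standard error are computed;
    t = beta / SE with residual dof = n_vols - n_columns. No temporal
    prewhitening is applied (plain OLS). Trials flagged as excluded in
    ``meta`` are still estimated but carry their exclusion flag.

    When the designs share all columns beyond the two trial columns
    (the LS-S construction), the shared nuisance block is residualized
    once via QR (Frisch–Waugh) and each trial needs only a 2-column
    solve; the result is identical to fitting each full design.
    """
    Y = np.asarray(data, dtype=float)
    n_trials = len(designs)
    if n_trials == 0:
        raise ValueError("no designs to fit")
    if Y.shape[0] != designs[0].n_vols:
        raise ValueError("data rows must equal design rows")
    V = Y.shape[1]
    betas = np.empty((n_trials, V))
    tmaps = np.empty((n_trials, V))
    if check_rank:
        for d in designs:
            _check_rank(d.matrix, d.names)
    if _shared_nuisance(designs):
        Z = designs[0].matrix[:, 2:]
        Qz, _ = np.linalg.qr(Z)
        Yt = Y - Qz @ (Qz.T @ Y)
        ssq = np.einsum("ij,ij->j", Yt, Yt)
        dof = Y.shape[0] - (Z.shape[1] + 2)
        if dof <= 0:
            raise ValueError("no residual degrees of freedom")
        for k, d in enumerate(designs):
            U = d.matrix[:, :2]
            Ut = U - Qz @ (Qz.T @ U)
            G = Ut.T @ Ut
            G_inv = np.linalg.inv(G)
            UtY = Ut.T @ Yt
            b = G_inv @ UtY
            rss = ssq - np.einsum("ij,ij->j", UtY, b)
            sigma2 = np.maximum(rss, 0.0) / dof
            se = np.sqrt(sigma2 * G_inv[0, 0])
            betas[k] = b[0]
            with np.errstate(divide="ignore", invalid="ignore"):
                tmaps[k] = np.where(se > 0, b[0] / se, 0.0)
    else:
        for k, d in enumerate(designs):
            beta, se = _fit_one(d.matrix, Y)
            betas[k] = beta
            with np.errstate(divide="ignore", invalid="ignore"):
                tmaps[k] = np.where(se > 0, beta / se, 0.0)
    if meta is None:
        meta = pd.DataFrame({
            "trial": [d.trial for d in designs],
            "run": [d.run for d in designs],
            "context": "",
            "excluded": False,
            "correct": True,
        })
    return TrialPatternSet(betas, tmaps, meta.reset_index(drop=True))
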