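"""Behavioral learning-rate statistics for the two training regimens.

Navigation: per-trial distance error is the navigated path length minus
the shortest possible path, normalized either by the optimal path
itself (transfer task) or by 120% of it (the training criterion
threshold). The transfer-task learning rate contrasts the first and
last halves of the 20-trial session:

    LR = -(E_first - E_last) / (E_first + E_last)

with E_* the summed normalized errors of each half — bounded in [-1, 1]
and invariant to rescaling all errors.

Verbal memory: the transfer-task learning rate is the recall gain per
trial, (last - first) / n_trials, on a 12-word list with at most five
attempts; the training measure is the OLS slope of each day's maximum
recalled words, fit separately over training days 1-5 and 6-10.
"""

from __future__ import annotations

import numpy as np

from .stats import PairedTResult

__all__ = [
    "normalized_error",
    "training_error",
    "route_success",
    "navigation_learning_rate",
    "verbal_learning_rate",
    "count_recalled",
    "daily_max_slope",
    "slope_cohort_test",
]

#: Training criterion: a route counts as learned when its length does
#: not exceed 120% of the shortest possible path.
TRAINING_THRESHOLD = 1.2

MAX_WORDS = 12
MAX_ATTEMPTS = 5


def _check_trial(actual: float, optimal: float) -> None:
    if optimal <= 0:
        raise ValueError("optimal distance must be positive")
    if actual < optimal:
        raise ValueError(
            f"actual distance {actual} shorter than optimal {optimal}: impossible path"
        )


def normalized_error(actual: float, optimal: float) -> float:
    """(actual - optimal) / optimal: distance error in optimal-path units."""
    _check_trial(actual, optimal)
    return (actual - optimal) / optimal


def training_error(actual: float, optimal: float, percent: bool = False) -> float:
    """Distance error normalized by the 120% training threshold."""
    _check_trial(actual, optimal)
    e = (actual - optimal) / (TRAINING_THRESHOLD * optimal)
    return 100.0 * e if percent else e


def route_success(actual: float, optimal: float) -> bool:
    """Criterion check: path no longer than 120% of the optimum (inclusive)."""
    _check_trial(actual, optimal)
    return actual <= TRAINING_THRESHOLD * optimal


def navigation_learning_rate(errors) -> float:
    """First-half vs last-half contrast of normalized distance errors.

    ``errors`` is an even-length sequence (20 trials in the transfer
    task) of per-trial normalized errors. Returns
    -(E_first - E_last)/(E_first + E_last) with E the half sums; NaN
    (flagged undefined) when every error is zero.
    """
    e = np.asarray(errors, dtype=float)
    if e.ndim != 1 or e.size < 2 or e.size % 2:
        raise ValueError("need an even number (>= 2) of trials")
    if np.any(e < 0):
        raise ValueError("normalized errors must be non-negative")
    half = e.size // 2
    first, last = e[:half].sum(), e[half:].sum()
    if first + last == 0:
        return float("nan")
    return -(first - last) / (first + last)


def verbal_learning_rate(recalled) -> float:
    """Recall gain per trial: (last - first) / number of trials."""
    counts = np.asarray(recalled, dtype=float)
    if counts.size == 0:
        raise ValueError("empty recall series")
    if np.any(counts < 0):
        raise ValueError("recall counts must be non-negative")
    return (counts[-1] - counts[0]) / counts.size


def count_recalled(response_words, list_words) -> int:
    """Number of list words recovered in a typed free-recall response.

    Case-insensitive exact match after whitespace trimming; order-free;
    a word recalled twice counts once.
    """
    target = {w.strip().lower() for w in list_words}
    hits = {w.strip().lower() for w in response_words} & target
    return len(hits)


def daily_max_slope(daily_max, days=None) -> float:
    """OLS slope of the daily maximum recalled words on day index.

    ``days`` defaults to 1..len(daily_max); pass explicit day numbers to
    fit a sub-range (e.g. training days 1-5 or 6-10).
    """
    y = np.asarray(daily_max, dtype=float)
    if days is None:
        days = np.arange(1, y.size + 1, dtype=float)
    x = np.asarray(days, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 days with matching day indices")
    if np.ptp(x) == 0:
        raise ValueError("day indices are constant")
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def slope_cohort_test(slopes) -> PairedTResult:
    """One-sample t of per-subject slopes against zero."""
    from .stats import paired_t

    slopes = np.asarray(slopes, dtype=float)
    return paired_t(np.zeros_like(slopes), slopes)
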