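"""Trajectory post-processing: steady states, peak ordering, scenario ranks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryStat",
    "detect_steady_state",
    "peak_order",
    "compare_scenarios",
    "trajectory_stat",
    "InsufficientDataError",
    "ComparisonError",
]

DEFAULT_WINDOW = 50
DEFAULT_REL_TOL = 0.02
DEFAULT_SMOOTHING = 11

_EPS = 1e-12


class InsufficientDataError(ValueError):
    pass


class ComparisonError(ValueError):
    pass


@dataclass
class TrajectoryStat:
    name: str
    mean: np.ndarray
    sd: np.ndarray
    n_replicates: int
    peak_step: int
    peak_value: float
    steady_state_step: int | None


def moving_average(series, window: int) -> np.ndarray:
    """Trailing moving average: out[t] = mean(series[t : t + window])."""
    x = np.asarray(series, dtype=float)
    c = np.concatenate([[0.0], np.cumsum(x)])
    return (c[window:] - c[:-window]) / window


def detect_steady_state(series, window: int = DEFAULT_WINDOW,
                        rel_tol: float = DEFAULT_REL_TOL) -> int | None:
    """First step after which the moving average stops drifting.

    Returns the smallest step ``s`` such that for every window starting at or
    after ``s`` the relative change of the ``window``-step moving average over
    the following ``window`` steps stays below ``rel_tol``; ``None`` if the
    criterion never holds.  Relative change is measured against
    ``max(moving average, eps)``, so the detector is invariant to uniform
    scaling of the series.
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    if not (0.0 < rel_tol < 1.0):
        raise ValueError(f"rel_tol must be in (0, 1), got {rel_tol}")
    x = np.asarray(series, dtype=float)
    if len(x) < 2 * window:
        raise InsufficientDataError(
            f"series of length {len(x)} is shorter than 2 x window "
            f"({2 * window})")
    ma = moving_average(x, window)
    # change of the moving average across one window length
    change = np.abs(ma[window:] - ma[:-window])
    denom = np.maximum(np.abs(ma[:-window]), _EPS)
    ok = (change / denom) < rel_tol
    if not ok[-1]:
        return None
    bad = np.flatnonzero(~ok)
    return int(bad[-1] + 1) if len(bad) else 0


def smooth(series, window: int = DEFAULT_SMOOTHING) -> np.ndarray:
    """Centered moving average with shrinking edge windows."""
    s = pd.Series(np.asarray(series, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def peak_order(series_a, series_b,
               smoothing_window: int = DEFAULT_SMOOTHING) -> str:
    """Compare the smoothed argmax steps: ``a_first``, ``b_first`` or ``tie``."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both series must be non-empty")
    pa = int(np.argmax(smooth(a, smoothing_window)))
    pb = int(np.argmax(smooth(b, smoothing_window)))
    if pa < pb:
        return "a_first"
    if pb < pa:
        return "b_first"
    return "tie"


def trajectory_stat(result, column: str,
                    window: int = DEFAULT_WINDOW,
                    rel_tol: float = DEFAULT_REL_TOL,
                    smoothing_window: int = DEFAULT_SMOOTHING) -> TrajectoryStat:
    """Summarize one census column of a :class:`~lobulesim.engine.ScenarioResult`."""
    mean = result.mean[column].to_numpy()
    sd = result.sd[column].to_numpy()
    sm = smooth(mean, smoothing_window)
    peak = int(np.argmax(sm))
    try:
        ss = detect_steady_state(mean, window, rel_tol)
    except InsufficientDataError:
        ss = None
    return TrajectoryStat(column, mean, sd, result.n_replicates, peak,
                          float(sm[peak]), ss)


def compare_scenarios(results: dict, metric: str, at_step: int) -> dict:
    """Rank scenarios by the mean of ``metric`` at ``at_step``.

    Returns ``{"ranking": [...ascending...], "means": {...}, "sds": {...},
    "pairwise": {(a, b): sign(mean_a - mean_b)}}``.  All scenarios must share
    the same run length and replicate count.
    """
    if not results:
        raise ComparisonError("no scenarios to compare")
    lengths = {name: r.n_steps for name, r in results.items()}
    reps = {name: r.n_replicates for name, r in results.items()}
    if len(set(lengths.values())) != 1 or len(set(reps.values())) != 1:
        raise ComparisonError(
            f"mismatched run lengths {lengths} or replicate counts {reps}")
    means = {}
    sds = {}
    for name, r in results.items():
        row = r.mean[r.mean["step"] == at_step]
        if row.empty:
            raise ComparisonError(f"scenario {name!r} has no step {at_step}")
        means[name] = float(row[metric].iloc[0])
        sds[name] = float(r.sd[r.sd["step"] == at_step][metric].iloc[0])
    ranking = sorted(means, key=lambda k: means[k])
    names = list(results)
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairwise[(a, b)] = int(np.sign(means[a] - means[b]))
    return {"ranking": ranking, "means": means, "sds": sds,
            "pairwise": pairwise}
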