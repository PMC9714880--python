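"""Trajectory-to-behavior reduction and group statistics.

Reaction time follows the velocity criterion used for joystick reaches:
trajectories are smoothed with a cubic interpolating spline, speed is the
magnitude of the spline's analytic derivative, and RT is the first time
after stimulus onset at which speed exceeds 10% of its per-trial maximum.
Trials are excluded when RT < 100 ms (anticipation), RT > 1500 ms, |RT -
mean| > 3 SD (mean/SD per condition cell, computed after the absolute cuts,
one pass), or when the trajectory shows a change of mind (movement past 5%
of the maximum range toward one direction with a final response in the
other).  Stop-signal psychometrics bin stop trials on the staircase grid;
group statistics use a two-way (group x condition) type-II ANOVA for the
decision and flanker tasks and two-tailed t-tests for go-trial contrasts.

This module is independent of the simulator: it consumes trajectories and
tidy session tables, and ships a closed-form synthetic-trajectory generator
(minimum-jerk, change-of-mind, stationary) so it can be tested in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

from .errors import MetricError

__all__ = [
    "Trajectory", "BehaviorSummary", "compute_rt", "detect_change_of_mind",
    "filter_trials", "stop_probability_curve", "group_stats",
    "generate_synthetic_trajectory", "minimum_jerk_rt_offset",
]

EXCLUSION_RULES = ("no_response", "change_of_mind", "rt_below_100",
                   "rt_above_1500", "rt_outlier_3sd")


@dataclass(frozen=True)
class Trajectory:
    """A sampled 2-D reach: strictly increasing times (ms) and positions.

    The choice axis is x; left/right responses are negative/positive x.
    """

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        if self.times.ndim != 1 or self.positions.shape != (self.times.size, 2):
            raise MetricError("trajectory needs times (N,) and positions (N, 2)")
        if self.times.size < 4:
            raise MetricError("trajectory needs >= 4 samples for spline smoothing")
        if np.any(np.diff(self.times) <= 0):
            raise MetricError("trajectory times must be strictly increasing")


@dataclass
class BehaviorSummary:
    """Per-condition RT summaries, exclusion accounting, and test statistics."""

    rt_by_condition: pd.DataFrame
    exclusions: dict
    change_of_mind_rate: float
    stop_curve: pd.DataFrame | None = None
    tests: dict = field(default_factory=dict)


def compute_rt(traj: Trajectory, onset_ms: float = 0.0,
               fraction: float = 0.10) -> float | None:
    """Velocity-criterion reaction time, or ``None`` if the hand never moves.

    The spline is fit over the full trajectory (so pre-onset samples
    stabilize the fit); the threshold is ``fraction`` of the maximum speed
    observed from onset onward.
    """
    spl = CubicSpline(traj.times, traj.positions, axis=0)
    vel = spl.derivative()(traj.times)
    speed = np.hypot(vel[:, 0], vel[:, 1])
    after = traj.times >= onset_ms
    if not after.any():
        raise MetricError("no samples at or after stimulus onset")
    vmax = float(speed[after].max())
    if vmax <= 1e-12 * max(1.0, float(np.abs(traj.positions).max())):
        return None
    above = after & (speed > fraction * vmax)
    if not above.any():
        return None
    return float(traj.times[np.argmax(above)]) - onset_ms


def detect_change_of_mind(traj: Trajectory, range_extent: float,
                          final_direction: str | None = None,
                          criterion: float = 0.05) -> bool:
    """True iff the hand moved past ``criterion`` (5%) of the maximum range
    toward one direction and the final response went the opposite way."""
    if range_extent <= 0:
        raise MetricError("range_extent must be > 0")
    x = traj.positions[:, 0]
    if final_direction is None:
        final_direction = "right" if x[-1] > 0 else "left"
    thr = criterion * range_extent
    if final_direction == "right":
        return bool(np.min(x) < -thr)
    return bool(np.max(x) > thr)


def filter_trials(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the exclusion rules; return (analyzed table, per-rule counts).

    Rules in order: trials without an RT (successful stops / no response),
    change-of-mind trials, RT < 100 ms, RT > 1500 ms, then the 3-SD cut with
    mean/SD computed per (task, group, trial_type) cell after the absolute
    cuts (a single pass, not iterated).  Counts always reconcile:
    ``raw = analyzed + sum(counts)``.
    """
    report = {rule: 0 for rule in EXCLUSION_RULES}
    if records.empty:
        return records.copy(), report
    df = records.copy()
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")

    missing = rt.isna()
    report["no_response"] = int(missing.sum())
    df, rt = df[~missing], rt[~missing]

    if "change_of_mind" in df.columns:
        com = df["change_of_mind"].astype(bool)
        report["change_of_mind"] = int(com.sum())
        df, rt = df[~com], rt[~com]

    fast = rt < 100.0
    report["rt_below_100"] = int(fast.sum())
    df, rt = df[~fast], rt[~fast]
    slow = rt > 1500.0
    report["rt_above_1500"] = int(slow.sum())
    df, rt = df[~slow], rt[~slow]

    if not df.empty:
        cell_cols = [c for c in ("task", "group", "trial_type") if c in df.columns]
        if cell_cols:
            grp = rt.groupby([df[c] for c in cell_cols])
            mean = grp.transform("mean")
            sd = grp.transform("std").fillna(0.0)
        else:
            mean, sd = rt.mean(), rt.std() if len(rt) > 1 else 0.0
        outlier = (rt - mean).abs() > 3.0 * sd
        outlier &= sd > 0  # all-identical cells keep everything
        report["rt_outlier_3sd"] = int(outlier.sum())
        df = df[~outlier]

    assert len(records) == len(df) + sum(report.values())
    return df, report


def stop_probability_curve(records: pd.DataFrame, bin_width: float = 50.0) -> pd.DataFrame:
    """P(successful stop) per SSD bin, bins aligned to the staircase grid.

    Returns columns ``ssd_bin``, ``n``, ``p_stop`` sorted by bin.
    """
    stops = records[records["stop_outcome"].isin(["success", "fail"])]
    if stops.empty:
        raise MetricError("no stop trials in the table")
    bins = (np.round(stops["ssd"].astype(float) / bin_width) * bin_width)
    success = (stops["stop_outcome"] == "success").astype(float)
    out = (pd.DataFrame({"ssd_bin": bins, "success": success})
           .groupby("ssd_bin")["success"].agg(["size", "mean"]).reset_index())
    out.columns = ["ssd_bin", "n", "p_stop"]
    return out.sort_values("ssd_bin").reset_index(drop=True)


def isotonic_deviation(curve: pd.DataFrame, min_trials: int = 5) -> float:
    """Largest deviation of the stop-probability curve from the best
    non-increasing fit.

    Bins with at least ``min_trials`` stop trials are fit by count-weighted
    isotonic (non-increasing) regression; the return value is the maximum
    absolute residual, 0 for a perfectly monotone curve.  Binomial noise in
    sparse bins is thereby weighted by its evidence instead of being read as
    a monotonicity violation.
    """
    from scipy.optimize import isotonic_regression

    occ = curve[curve["n"] >= min_trials]
    if len(occ) < 2:
        return 0.0
    fit = isotonic_regression(occ["p_stop"].to_numpy(),
                              weights=occ["n"].to_numpy(), increasing=False)
    return float(np.max(np.abs(fit.x - occ["p_stop"].to_numpy())))


def group_stats(records: pd.DataFrame) -> dict:
    """Group statistics on analyzed RTs.

    Two-way type-II ANOVA (group x trial_type) per decision/flanker task and
    a two-tailed t-test on go-trial RTs between groups.  Returns a dict of
    result tables / (statistic, p) pairs with exact p-values.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    out: dict = {}
    df = records.dropna(subset=["rt_ms"]).copy()
    for task in ("decision", "flanker"):
        sub = df[df["task"] == task]
        if sub.empty or sub["group"].nunique() < 2:
            continue
        model = smf.ols("rt_ms ~ C(group) * C(trial_type)", data=sub).fit()
        out[f"anova_{task}"] = sm.stats.anova_lm(model, typ=2)
    go = df[(df["task"] == "stop_signal") & (df["trial_type"] == "go")]
    if go["group"].nunique() == 2:
        groups = [g["rt_ms"].to_numpy() for _, g in go.groupby("group")]
        t, p = stats.ttest_ind(*groups)
        out["ttest_go_groups"] = {"t": float(t), "p": float(p)}
    return out


def ttest_rt(a: pd.Series | np.ndarray, b: pd.Series | np.ndarray) -> tuple[float, float]:
    """Two-tailed independent-samples t-test on two RT samples."""
    a = pd.to_numeric(pd.Series(a), errors="coerce").dropna().to_numpy()
    b = pd.to_numeric(pd.Series(b), errors="coerce").dropna().to_numpy()
    if a.size < 2 or b.size < 2:
        raise MetricError("t-test needs >= 2 RTs per sample")
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# synthetic trajectories (closed-form fixtures with known ground truth)
# ---------------------------------------------------------------------------

def minimum_jerk_rt_offset(duration_ms: float, fraction: float = 0.10) -> float:
    """Analytic offset between movement onset and the 10%-of-peak-speed
    crossing of a minimum-jerk profile: ``s (1 - s) = sqrt(fraction) / 4``
    on normalized time, so the crossing sits at ``s * duration``."""
    s = (1.0 - np.sqrt(1.0 - np.sqrt(fraction))) / 2.0
    return float(s * duration_ms)


def _min_jerk_x(t, onset, duration, amplitude):
    s = np.clip((t - onset) / duration, 0.0, 1.0)
    return amplitude * (10 * s**3 - 15 * s**4 + 6 * s**5)


def generate_synthetic_trajectory(kind: str, params: dict | None = None,
                                  seed: int = 0) -> Trajectory:
    """Closed-form test trajectories with known ground truth.

    ``minimum_jerk``: straight reach along x with a minimum-jerk speed
    profile (params: onset_ms, duration_ms, amplitude, dt_ms, noise_sd).
    ``change_of_mind``: an excursion past +excursion_frac of the range
    followed by arrival at the opposite side.  ``stationary``: no movement.
    """
    p = dict(params or {})
    dt = p.get("dt_ms", 5.0)
    total = p.get("total_ms", 1200.0)
    t = np.arange(0.0, total + dt / 2, dt)
    rng = np.random.default_rng(seed)
    noise = p.get("noise_sd", 0.0)

    if kind == "minimum_jerk":
        onset = p.get("onset_ms", 300.0)
        duration = p.get("duration_ms", 600.0)
        amplitude = p.get("amplitude", 1.0)
        x = _min_jerk_x(t, onset, duration, amplitude)
    elif kind == "change_of_mind":
        onset = p.get("onset_ms", 200.0)
        range_extent = p.get("range_extent", 2.0)
        excursion = p.get("excursion_frac", 0.08) * range_extent
        final = -p.get("final_frac", 0.45) * range_extent
        t1, t2 = onset + 150.0, onset + 350.0
        x = np.zeros_like(t)
        rise = (t >= onset) & (t < t1)
        x[rise] = excursion * (t[rise] - onset) / (t1 - onset)
        swing = (t >= t1) & (t < t2)
        x[swing] = excursion + (final - excursion) * (t[swing] - t1) / (t2 - t1)
        x[t >= t2] = final
    elif kind == "stationary":
        x = np.zeros_like(t)
    else:
        raise MetricError(f"unknown synthetic trajectory kind '{kind}'")

    if noise > 0:
        x = x + noise * rng.standard_normal(t.size)
    pos = np.column_stack([x, np.zeros_like(x)])
    return Trajectory(times=t, positions=pos)
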