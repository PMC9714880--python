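"""The three task protocols — decision-making, arrow flanker, stop-signal —
as stimulus/context timelines, plus session orchestration.

Trial timelines are expressed relative to target onset (t = 0).  The long
pre-stimulus intervals of the human protocol (fixation etc.) are compressed
to a fixed settling period, during which the fields sit at rest; the
flanker precedes the target by ``flanker_lead_ms`` (100 ms), the stimulus
display lasts ``display_ms`` (1500 ms) which is also the response timeout,
and the stop cue arrives at the trial's SSD.  The SSD follows a 1-up/1-down
staircase: +50 ms after a successful stop, -50 ms after a failed one,
clamped to [floor, ceiling].

Conflict detection is routed from the protocol: the conflict-context field
is driven whenever flanker and target directions differ, from target onset.
The expected-outcome field is silent in the decision task (equally rewarded
options) and carries a bump at the correct target direction in the flanker
task.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics
from .architecture import (Architecture, GroupTaskParams, StimulusDrive,
                           build_architecture, encode_stimuli)
from .config import GROUPS, TASKS, SimConfig, substream
from .control import TrialResult, rhc_execute
from .errors import ConfigurationError

__all__ = [
    "TrialSpec", "StaircaseState", "TrialRecord", "TrialTimeline",
    "DIRECTION_ANGLE", "build_timeline", "make_session", "run_trial",
    "update_staircase", "run_session", "SESSION_COLUMNS",
]

DIRECTION_ANGLE = {"right": 0.0, "left": 180.0}
OPPOSITE = {"right": "left", "left": "right"}

TRIAL_TYPES = {
    "decision": ("instructed", "choice"),
    "flanker": ("congruent", "incongruent"),
    "stop_signal": ("go", "stop"),
}

# (n_per_type...) for each task under each preset; the "paper" preset is the
# simulation campaign (200 decision, 200 flanker, 100 go + 250 stop); "human"
# mirrors the participant protocol (2x52, 2x52, 3x60 with 40/20 go/stop).
PRESETS = {
    "paper": {"decision": (100, 100), "flanker": (100, 100), "stop_signal": (100, 250)},
    "human": {"decision": (52, 52), "flanker": (52, 52), "stop_signal": (120, 60)},
    # tiny sessions for end-to-end smoke runs; not a study condition
    "smoke": {"decision": (3, 3), "flanker": (3, 3), "stop_signal": (3, 6)},
}


@dataclass(frozen=True)
class TrialSpec:
    """One trial's protocol parameters."""

    task: str
    trial_type: str
    direction: str               # target direction: left | right
    flanker_direction: str | None = None
    ssd: float | None = None     # filled in at run time for stop trials
    timeout: float = 1500.0

    def __post_init__(self):
        if self.task not in TASKS:
            raise ConfigurationError(f"unknown task '{self.task}'")
        if self.trial_type not in TRIAL_TYPES[self.task]:
            raise ConfigurationError(
                f"trial type '{self.trial_type}' invalid for task '{self.task}'")
        if self.direction not in DIRECTION_ANGLE:
            raise ConfigurationError(f"unknown direction '{self.direction}'")


@dataclass(frozen=True)
class StaircaseState:
    """SSD staircase: current value, step size, bounds (all ms)."""

    current_ssd: float = 200.0
    step: float = 50.0
    floor: float = 0.0
    ceiling: float = 1500.0


def update_staircase(state: StaircaseState, outcome: str) -> StaircaseState:
    """Advance the staircase after a stop trial.

    Success makes the next stop harder (+step); failure easier (-step);
    the SSD is clamped to [floor, ceiling].
    """
    if outcome not in ("success", "fail"):
        raise ConfigurationError(f"staircase outcome must be success/fail, got '{outcome}'")
    delta = state.step if outcome == "success" else -state.step
    ssd = min(max(state.current_ssd + delta, state.floor), state.ceiling)
    return dataclasses.replace(state, current_ssd=ssd)


@dataclass
class TrialRecord:
    """Outcome of one simulated trial."""

    spec: TrialSpec
    rt: float | None
    rt_threshold: float | None
    chosen_direction: str | None
    stop_outcome: str            # success | fail | n/a
    change_of_mind: bool
    seed: int
    trial_index: int
    result: TrialResult | None = None

    def __post_init__(self):
        if self.stop_outcome == "success" and self.rt is not None:
            raise ConfigurationError("successful stop cannot carry an RT")


class TrialTimeline:
    """Per-trial external drives as functions of time (ms, 0 = target onset)."""

    def __init__(self, t_start, sensory, expected, conflict_window, stop_window,
                 context_amplitude, n_context=100):
        self.t_start = t_start
        self._sensory = sensory
        self._expected = expected
        self._conflict = conflict_window
        self._stop = stop_window
        self._amp = context_amplitude
        self._n_context = n_context
        self.stop_onset = None if stop_window is None else stop_window[0]

    def sensory_at(self, t):
        return self._sensory.at(t)

    def expected_at(self, t):
        return self._expected.at(t)

    def _window_drive(self, window, t):
        if window is not None and window[0] <= t < window[1]:
            return self._amp
        return 0.0

    def conflict_at(self, t):
        return self._window_drive(self._conflict, t)

    def stop_at(self, t):
        return self._window_drive(self._stop, t)


def build_timeline(spec: TrialSpec, cfg: SimConfig, ssd: float | None = None) -> TrialTimeline:
    """Assemble the stimulus/context timeline for one trial.

    Choice trials drive a bimodal sensory input; incongruent flanker trials
    drive the flanker direction first, the target 100 ms later, plus the
    conflict context from target onset; stop trials add the stop context at
    t = SSD.
    """
    labels = np.linspace(0.0, 180.0, 181)
    display = cfg.display_ms
    amp, width = cfg.stim_amplitude, cfg.stim_width_deg
    tgt = DIRECTION_ANGLE[spec.direction]
    sensory_drives = []
    expected_drives = []
    conflict_window = None
    stop_window = None
    t_start = -cfg.settle_ms

    if spec.task == "decision":
        if spec.trial_type == "choice":
            sensory_drives.append(StimulusDrive((0.0, 180.0), 0.0, display, amp, width))
        else:
            sensory_drives.append(StimulusDrive((tgt,), 0.0, display, amp, width))
    elif spec.task == "flanker":
        fl_dir = spec.flanker_direction or (
            spec.direction if spec.trial_type == "congruent" else OPPOSITE[spec.direction])
        fl = DIRECTION_ANGLE[fl_dir]
        t_start = -(cfg.settle_ms + cfg.flanker_lead_ms)
        sensory_drives.append(
            StimulusDrive((fl,), -cfg.flanker_lead_ms, display, amp, width))
        sensory_drives.append(StimulusDrive((tgt,), 0.0, display, amp, width))
        expected_drives.append(
            StimulusDrive((tgt,), 0.0, display, cfg.expected_amplitude, width))
        if fl_dir != spec.direction:
            conflict_window = (0.0, display)
    else:  # stop_signal
        sensory_drives.append(StimulusDrive((tgt,), 0.0, display, amp, width))
        if spec.trial_type == "stop":
            if ssd is None:
                raise ConfigurationError("stop trial requires an SSD")
            stop_window = (float(ssd), display)

    return TrialTimeline(
        t_start=t_start,
        sensory=encode_stimuli(sensory_drives, labels),
        expected=encode_stimuli(expected_drives, labels),
        conflict_window=conflict_window,
        stop_window=stop_window,
        context_amplitude=cfg.context_amplitude,
    )


def make_session(task: str, group: str, config: SimConfig | None = None,
                 seed: int = 0, preset: str = "paper") -> list[TrialSpec]:
    """Randomized trial list for one task/group session.

    The "paper" preset uses the simulation-campaign counts (200 decision
    trials half choice, 200 flanker trials half incongruent, 100 go + 250
    stop trials); the "human" preset mirrors the participant protocol.
    """
    if task not in TASKS:
        raise ConfigurationError(f"unknown task '{task}'")
    if group not in GROUPS:
        raise ConfigurationError(f"unknown group '{group}'")
    try:
        counts = PRESETS[preset][task]
    except KeyError:
        raise ConfigurationError(f"unknown preset '{preset}'") from None
    cfg = config or SimConfig()
    rng = substream(seed, 0, "session")
    type_a, type_b = TRIAL_TYPES[task]
    types = [type_a] * counts[0] + [type_b] * counts[1]
    rng.shuffle(types)
    specs = []
    for tt in types:
        direction = "left" if rng.random() < 0.5 else "right"
        fl = None
        if task == "flanker":
            fl = direction if tt == "congruent" else OPPOSITE[direction]
        specs.append(TrialSpec(task=task, trial_type=tt, direction=direction,
                               flanker_direction=fl, timeout=cfg.display_ms))
    return specs


def run_trial(
    spec: TrialSpec,
    model: Architecture,
    group_task: GroupTaskParams,
    staircase: StaircaseState | None = None,
    seed: int = 0,
    trial_index: int = 0,
    keep_result: bool = False,
    record_fields: bool = False,
    pause_clamp: bool = False,
) -> TrialRecord:
    """Simulate one trial and classify its outcome.

    The reaction time is read from the trajectory with the 10%-of-peak-
    velocity rule; the threshold-crossing RT (gamma crossing + motor
    latency) is logged alongside.  A stop trial succeeds iff no response
    registers before the timeout.
    """
    cfg = model.cfg
    ssd = None
    if spec.task == "stop_signal" and spec.trial_type == "stop":
        ssd = (staircase or StaircaseState(cfg.ssd_initial, cfg.ssd_step,
                                           cfg.ssd_floor, cfg.ssd_ceiling)).current_ssd
    timeline = build_timeline(spec, cfg, ssd=ssd)
    result = rhc_execute(model, timeline, group_task, cfg, master_seed=seed,
                         trial_index=trial_index, record_fields=record_fields,
                         pause_clamp=pause_clamp)
    ev = result.events
    responded = ev["t_response"] is not None

    traj = metrics.Trajectory(times=result.times, positions=result.positions)
    rt = metrics.compute_rt(traj, onset_ms=0.0) if responded else None
    com = False
    if responded:
        com = metrics.detect_change_of_mind(
            traj, range_extent=2.0 * cfg.target_distance,
            final_direction=ev["response_dir"])

    if spec.task == "stop_signal" and spec.trial_type == "stop":
        stop_outcome = "fail" if responded else "success"
    else:
        stop_outcome = "n/a"

    return TrialRecord(
        spec=dataclasses.replace(spec, ssd=ssd),
        rt=(rt if responded else None),
        rt_threshold=ev["rt_threshold_ms"] if responded else None,
        chosen_direction=ev["response_dir"],
        stop_outcome=stop_outcome,
        change_of_mind=com,
        seed=seed,
        trial_index=trial_index,
        result=result if keep_result else None,
    )


SESSION_COLUMNS = ["task", "group", "trial_type", "direction", "ssd", "rt_ms",
                   "rt_threshold_ms", "choice", "stop_outcome",
                   "change_of_mind", "trial_index", "seed"]


def run_session(
    session: list[TrialSpec],
    group: str,
    config: SimConfig | None = None,
    seed: int = 0,
    model: Architecture | None = None,
    keep_results: bool = False,
) -> pd.DataFrame:
    """Run a full session sequentially, threading the SSD staircase through
    stop trials, and return a tidy per-trial table (the SessionTable).

    Deterministic given the seed: each trial draws from named substreams
    keyed by (seed, trial index).
    """
    if not session:
        raise ConfigurationError("empty session")
    task = session[0].task
    if any(s.task != task for s in session):
        raise ConfigurationError("a session must contain a single task")
    cfg = config or SimConfig()
    arch = model or build_architecture(cfg)
    gt = GroupTaskParams.from_config(cfg, group, task)
    staircase = StaircaseState(cfg.ssd_initial, cfg.ssd_step,
                               cfg.ssd_floor, cfg.ssd_ceiling)
    rows = []
    records = []
    for idx, spec in enumerate(session):
        rec = run_trial(spec, arch, gt, staircase=staircase, seed=seed,
                        trial_index=idx, keep_result=keep_results)
        if rec.stop_outcome in ("success", "fail"):
            staircase = update_staircase(staircase, rec.stop_outcome)
        records.append(rec)
        rows.append({
            "task": task, "group": group, "trial_type": spec.trial_type,
            "direction": spec.direction, "ssd": rec.spec.ssd,
            "rt_ms": rec.rt, "rt_threshold_ms": rec.rt_threshold,
            "choice": rec.chosen_direction, "stop_outcome": rec.stop_outcome,
            "change_of_mind": rec.change_of_mind, "trial_index": idx,
            "seed": seed,
        })
    df = pd.DataFrame(rows, columns=SESSION_COLUMNS)
    if keep_results:
        df.attrs["records"] = records
    return df
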