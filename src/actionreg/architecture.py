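"""Wiring of the action-regulation model.

Six interconnected dynamic neural fields:

* ``spatial_sensory`` (181 direction-tuned neurons) — angular representation
  of the displayed targets;
* ``expected_outcome`` (181) — expected reward of reaching each direction;
* ``reach_planning`` (181) — the competition arena; its supra-threshold
  neurons drive the optimal controllers;
* ``stop_context`` / ``conflict_context`` (100 each) — task-context
  populations activated by a stop cue or by conflicting flanker information;
* ``pause`` (3 subpopulations x 75) — a basal-ganglia-style brake.  Each
  subpopulation serves one regulation function (selection between multiple
  options, conflict, outright stopping) and inhibits the reach-planning field
  one-to-all.

Sensory and expected-outcome outputs excite reach planning topologically
(one-to-one); the context fields excite their pause subpopulation one-to-all;
the sensory field excites the selection subpopulation one-to-all, gated on
the presence of two or more distinct supra-threshold bumps (no separate
context field is needed to signal a decision between options).  The drive to
the reach-planning field is

    S_action = eta_pos * v_pos + eta_reward * v_reward - eta_pau * v_pau + xi

with ``v_pau`` the summed pause output broadcast to all 181 reach neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .config import GROUPS, PAUSE_SUBPOPS, TASKS, SimConfig
from .errors import ConfigurationError, InvalidParameterError, WiringError
from .fields import FieldSpec, FieldState, KernelSpec, NoiseSpec, Projection, step_field

__all__ = [
    "Architecture", "GroupTaskParams", "StimulusDrive", "TimelineInput",
    "build_architecture", "encode_stimuli", "reach_drive", "pause_routing",
    "count_bumps", "PAUSE_SLICES",
]

N_DIRECTIONAL = 181
N_CONTEXT = 100
N_SUBPOP = 75
PAUSE_SLICES = {
    "selection": slice(0, 75),
    "conflict": slice(75, 150),
    "stop": slice(150, 225),
}


@dataclass(frozen=True)
class GroupTaskParams:
    """Group/task parameterization: per-subpopulation tonic pause drives.

    The disease mechanism is carried entirely here: PD has a higher tonic
    pause drive than neurotypical in the decision and flanker tasks, while in
    the stop-signal task the proactive (pre-cue) pause drive is higher for
    neurotypical than PD.
    """

    group: str
    task: str
    pause_tonic: dict

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ConfigurationError(f"unknown group '{self.group}'")
        if self.task not in TASKS:
            raise ConfigurationError(f"unknown task '{self.task}'")
        missing = set(PAUSE_SUBPOPS) - set(self.pause_tonic)
        if missing:
            raise ConfigurationError(f"pause_tonic missing subpopulations {sorted(missing)}")

    @classmethod
    def from_config(cls, cfg: SimConfig, group: str, task: str) -> "GroupTaskParams":
        return cls(group=group, task=task, pause_tonic=cfg.tonic_for(group, task))


@dataclass(frozen=True)
class StimulusDrive:
    """A Gaussian bump of drive at given directions within a time window.

    Multiple simultaneous directions (and overlapping drives) sum.
    """

    directions: tuple
    onset: float
    offset: float
    amplitude: float
    width: float

    def __post_init__(self):
        for d in self.directions:
            if not (0.0 <= d <= 180.0):
                raise InvalidParameterError(
                    f"stimulus direction {d} outside [0, 180] degrees")
        if self.amplitude < 0 or self.width <= 0:
            raise InvalidParameterError("stimulus amplitude >= 0 and width > 0 required")

    def bump(self, labels: np.ndarray) -> np.ndarray:
        out = np.zeros_like(labels, dtype=float)
        for d in self.directions:
            out += self.amplitude * np.exp(-((labels - d) ** 2) / (2 * self.width**2))
        return out


class TimelineInput:
    """Time-indexed external input assembled from stimulus drives."""

    def __init__(self, drives, labels: np.ndarray):
        self._windows = [(d.onset, d.offset, d.bump(labels)) for d in drives]
        self._zero = np.zeros(len(labels))

    def at(self, t: float) -> np.ndarray:
        out = None
        for onset, offset, bump in self._windows:
            if onset <= t < offset:
                out = bump if out is None else out + bump
        return self._zero if out is None else out


def encode_stimuli(drives, labels: np.ndarray) -> TimelineInput:
    """Map stimulus specifications to a time-indexed sensory-field input."""
    return TimelineInput(list(drives), np.asarray(labels, dtype=float))


def count_bumps(output: np.ndarray, threshold: float = 0.5) -> int:
    """Number of disjoint supra-threshold bumps in a field's rate output."""
    mask = np.asarray(output) > threshold
    if not mask.any():
        return 0
    # count rising edges of the boolean mask
    return int(mask[0]) + int(np.sum(~mask[:-1] & mask[1:]))


def pause_routing(
    sensory_output: np.ndarray,
    conflict_output: np.ndarray,
    stop_output: np.ndarray,
    group_task: GroupTaskParams,
    cfg: SimConfig,
) -> np.ndarray:
    """Assemble the input vector (225,) to the three pause subpopulations.

    Each subpopulation receives its one-to-all phasic drive — summed sensory
    output gated on multi-target detection for selection, summed context
    output for conflict and stop — plus its group/task tonic drive.
    """
    drive = np.zeros(3 * N_SUBPOP)
    tonic = group_task.pause_tonic
    sel = 0.0
    if count_bumps(sensory_output, cfg.multi_target_threshold) >= 2:
        sel = cfg.w_selection * float(np.sum(sensory_output))
    cap = cfg.pause_input_cap
    drive[PAUSE_SLICES["selection"]] = min(sel + tonic["selection"], cap)
    drive[PAUSE_SLICES["conflict"]] = min(
        cfg.w_conflict * float(np.sum(conflict_output)) + tonic["conflict"], cap)
    # the stop route must retain its full phasic strength to cancel a
    # committed action; only the delay routes saturate
    drive[PAUSE_SLICES["stop"]] = (
        cfg.w_stop * float(np.sum(stop_output)) + tonic["stop"])
    return drive


def reach_drive(
    v_pos: np.ndarray,
    v_reward: np.ndarray,
    v_pau: float | np.ndarray,
    gains: dict,
    noise: np.ndarray | None = None,
) -> np.ndarray:
    """Drive to the reach-planning field:
    ``eta_pos v_pos + eta_reward v_reward - eta_pau v_pau + xi``.

    ``v_pau`` is the pause field's summed one-to-all contribution (scalar,
    broadcast to all reach neurons)."""
    v_pos = np.asarray(v_pos, dtype=float)
    v_reward = np.asarray(v_reward, dtype=float)
    if v_pos.shape != v_reward.shape:
        raise WiringError(
            f"v_pos {v_pos.shape} and v_reward {v_reward.shape} sizes differ")
    s = gains["eta_pos"] * v_pos + gains["eta_reward"] * v_reward - gains["eta_pau"] * v_pau
    if noise is not None:
        if np.shape(noise) != v_pos.shape:
            raise WiringError("noise vector size mismatch in reach drive")
        s = s + noise
    return s


class Architecture:
    """The wired model: named field specs/states, projections, gains, threshold."""

    def __init__(self, specs: dict, projections: list, noise: dict,
                 gains: dict, gamma: float, cfg: SimConfig):
        self.specs = specs
        self.projections = projections
        self.noise = noise
        self.gains = gains
        self.gamma = gamma
        self.cfg = cfg
        self.states: dict[str, FieldState] = {}
        self.reset()
        self._validate()

    # -- lifecycle --------------------------------------------------------
    def reset(self) -> None:
        """Return every field to its resting state at t = 0."""
        self.states = {name: spec.rest_state() for name, spec in self.specs.items()}

    def _validate(self) -> None:
        sizes = {"spatial_sensory": N_DIRECTIONAL, "expected_outcome": N_DIRECTIONAL,
                 "reach_planning": N_DIRECTIONAL, "stop_context": N_CONTEXT,
                 "conflict_context": N_CONTEXT, "pause": 3 * N_SUBPOP}
        for name, n in sizes.items():
            if name not in self.specs:
                raise ConfigurationError(f"architecture is missing field '{name}'")
            if self.specs[name].n_neurons != n:
                raise ConfigurationError(
                    f"field '{name}' has {self.specs[name].n_neurons} neurons, "
                    f"expected {n}")
        for p in self.projections:
            src = self.specs[p.source].n_neurons
            tgt_name = p.target.split(".")[0]
            tgt = (N_SUBPOP if "." in p.target else self.specs[tgt_name].n_neurons)
            if p.topology == "one_to_one" and src != tgt:
                raise WiringError(
                    f"one_to_one projection {p.source}->{p.target} with "
                    f"sizes {src} != {tgt}")

    def validation_report(self) -> list[str]:
        """Human-readable listing of every field and projection."""
        lines = [f"field {name}: {spec.n_neurons} neurons, tau={spec.tau} ms, "
                 f"h={spec.h}, beta={spec.beta}"
                 for name, spec in self.specs.items()]
        lines += [f"projection {p.source} -> {p.target} [{p.topology}, {p.sign}, "
                  f"w={p.weight}]" for p in self.projections]
        return lines

    # -- runtime ----------------------------------------------------------
    def output(self, name: str) -> np.ndarray:
        return self.specs[name].output(self.states[name].u)

    def pause_output_sum(self) -> float:
        return float(self.output("pause").sum())

    def step(
        self,
        sensory_input: np.ndarray,
        expected_input: np.ndarray,
        stop_input: float,
        conflict_input: float,
        group_task: GroupTaskParams,
        dt: float,
        rngs: dict,
        pause_clamp: bool = False,
    ) -> None:
        """Advance every field by one synchronous Euler step.

        Outputs are computed from the pre-step states, routed per the wiring
        above, and all fields are updated together.  ``pause_clamp`` forces
        the pause contribution to zero (used by ablation analyses).
        """
        f_sens = self.output("spatial_sensory")
        f_exp = self.output("expected_outcome")
        f_stop = self.output("stop_context")
        f_conf = self.output("conflict_context")
        v_pau = 0.0 if pause_clamp else self.pause_output_sum()

        pause_in = pause_routing(f_sens, f_conf, f_stop, group_task, self.cfg)
        s_reach = reach_drive(f_sens, f_exp, v_pau, self.gains)

        ext = {
            "spatial_sensory": sensory_input,
            "expected_outcome": expected_input,
            "stop_context": stop_input,
            "conflict_context": conflict_input,
            "pause": pause_in,
            "reach_planning": s_reach,
        }
        for name, spec in self.specs.items():
            self.states[name] = step_field(
                self.states[name], spec, ext[name], 0.0, dt,
                noise=self.noise.get(name), rng=rngs.get(name))


def build_architecture(config: SimConfig | None = None) -> Architecture:
    """Construct the six-field model from a configuration (defaults shipped).

    All fields start at rest; projections follow the fixed wiring diagram.
    Raises :class:`ConfigurationError` / :class:`WiringError` naming the
    offending field or edge.
    """
    cfg = config or SimConfig()
    k = cfg.reach_kernel
    reach_kernel = KernelSpec(c_exc=k.c_exc, c_inh=k.c_inh,
                              sigma_exc=k.sigma_exc, sigma_inh=k.sigma_inh)

    def fc(name):
        return cfg.field_cfg(name)

    specs = {
        "spatial_sensory": FieldSpec.directional(
            "spatial_sensory", N_DIRECTIONAL, tau=fc("spatial_sensory").tau,
            h=fc("spatial_sensory").h, beta=fc("spatial_sensory").beta,
            u0=fc("spatial_sensory").u0, ceiling=cfg.ceiling),
        "expected_outcome": FieldSpec.directional(
            "expected_outcome", N_DIRECTIONAL, tau=fc("expected_outcome").tau,
            h=fc("expected_outcome").h, beta=fc("expected_outcome").beta,
            u0=fc("expected_outcome").u0, ceiling=cfg.ceiling),
        "reach_planning": FieldSpec.directional(
            "reach_planning", N_DIRECTIONAL, tau=fc("reach_planning").tau,
            h=fc("reach_planning").h, beta=fc("reach_planning").beta,
            u0=fc("reach_planning").u0, kernel=reach_kernel, ceiling=cfg.ceiling),
        "stop_context": FieldSpec.indexed(
            "stop_context", N_CONTEXT, tau=fc("stop_context").tau,
            h=fc("stop_context").h, beta=fc("stop_context").beta,
            u0=fc("stop_context").u0, ceiling=cfg.ceiling),
        "conflict_context": FieldSpec.indexed(
            "conflict_context", N_CONTEXT, tau=fc("conflict_context").tau,
            h=fc("conflict_context").h, beta=fc("conflict_context").beta,
            u0=fc("conflict_context").u0, ceiling=cfg.ceiling),
        "pause": FieldSpec.indexed(
            "pause", 3 * N_SUBPOP, tau=fc("pause").tau, h=fc("pause").h,
            beta=fc("pause").beta, u0=fc("pause").u0, ceiling=cfg.ceiling),
    }

    projections = [
        Projection("spatial_sensory", "reach_planning", "one_to_one",
                   cfg.eta_pos, "excitatory"),
        Projection("expected_outcome", "reach_planning", "one_to_one",
                   cfg.eta_reward, "excitatory"),
        Projection("pause", "reach_planning", "one_to_all",
                   cfg.eta_pau, "inhibitory"),
        Projection("spatial_sensory", "pause.selection", "one_to_all",
                   cfg.w_selection, "excitatory"),
        Projection("conflict_context", "pause.conflict", "one_to_all",
                   cfg.w_conflict, "excitatory"),
        Projection("stop_context", "pause.stop", "one_to_all",
                   cfg.w_stop, "excitatory"),
    ]

    noise = {name: NoiseSpec(sigma=fc(name).noise_sigma,
                             corr_len=fc(name).noise_corr, seed_stream=name)
             for name in specs}

    gains = {"eta_pos": cfg.eta_pos, "eta_reward": cfg.eta_reward,
             "eta_pau": cfg.eta_pau}
    return Architecture(specs, projections, noise, gains, cfg.gamma, cfg)
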