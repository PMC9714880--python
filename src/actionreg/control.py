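"""Stochastic optimal control of the reach: per-neuron finite-horizon LQ
policies, relative-desirability weighting, policy mixing, and
receding-horizon closed-loop execution.

The plant is a discrete-time planar point mass with viscous damping — state
``x = (px, py, vx, vy)``, control = acceleration — the minimal linear plant
consistent with the quadratic reach cost

    J_j = (x_T - g_j)' Q_T (x_T - g_j) + sum_t u_t' R u_t

whose minimizer is a time-indexed linear feedback law obtained by a backward
Riccati recursion.  For a goal state with zero velocity the plant leaves the
goal invariant, so the feedback gains depend only on steps-to-go and are
shared by every reach direction; they are computed once and cached.

During execution, each supra-threshold reach-planning neuron j contributes
its policy toward its preferred direction, weighted by relative desirability
(normalized sigmoided activity).  The executed command is the desirability
mixture of the active policies; the active policy set is refreshed every
``rhc_interval`` (9) plant steps — the receding-horizon re-plan — while the
mixture weights track the field state every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architecture import Architecture, GroupTaskParams
from .config import SimConfig, substream
from .errors import ActionRegError, InvalidParameterError

__all__ = [
    "Plant", "ControlPolicy", "DesirabilityWeights", "GainSchedule",
    "solve_policy", "relative_desirability", "mix_policies", "rhc_execute",
    "TrialResult",
]


@dataclass(frozen=True)
class Plant:
    """Discrete-time linear plant ``x+ = A x + B u``."""

    A: np.ndarray
    B: np.ndarray

    @classmethod
    def point_mass(cls, damping_per_s: float, dt_ms: float) -> "Plant":
        dt = dt_ms / 1000.0
        a = 1.0 - damping_per_s * dt
        A = np.array([[1, 0, dt, 0],
                      [0, 1, 0, dt],
                      [0, 0, a, 0],
                      [0, 0, 0, a]], dtype=float)
        B = np.array([[0, 0], [0, 0], [dt, 0], [0, dt]], dtype=float)
        return cls(A=A, B=B)

    def step(self, x: np.ndarray, u: np.ndarray) -> np.ndarray:
        return self.A @ x + self.B @ u


class GainSchedule:
    """Backward-Riccati feedback gains indexed by steps-to-go.

    ``K[j]`` is the gain applied when j steps remain; gains are goal-free
    because the recursion acts on the goal-relative error when the plant
    leaves the goal state invariant.  The schedule extends lazily.
    """

    def __init__(self, plant: Plant, Q_T: np.ndarray, R: np.ndarray, horizon: int):
        self.plant = plant
        self.Q_T = np.asarray(Q_T, dtype=float)
        self.R = np.asarray(R, dtype=float)
        n = plant.A.shape[0]
        m = plant.B.shape[1]
        self._K = np.zeros((1, m, n))
        self._P = self.Q_T.copy()
        self.extend(horizon)

    @property
    def horizon(self) -> int:
        return self._K.shape[0] - 1

    def extend(self, horizon: int) -> None:
        if horizon <= self.horizon:
            return
        A, B, R = self.plant.A, self.plant.B, self.R
        Ks = list(self._K)
        P = self._P
        for _ in range(self.horizon, horizon):
            BtP = B.T @ P
            M = R + BtP @ B
            try:
                K = np.linalg.solve(M, BtP @ A)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise ActionRegError(
                    f"Riccati recursion ill-conditioned: cond(R+B'PB)="
                    f"{np.linalg.cond(M):.3e}") from exc
            Ks.append(K)
            P = A.T @ P @ A - A.T @ P @ B @ K
        self._K = np.array(Ks)
        self._P = P

    def K(self, steps_to_go: int) -> np.ndarray:
        if steps_to_go > self.horizon:
            self.extend(steps_to_go)
        return self._K[steps_to_go]


_SCHEDULE_CACHE: dict = {}


def _shared_schedule(cfg: SimConfig, horizon: int = 1200) -> GainSchedule:
    key = (cfg.plant_damping, cfg.dt_ms, cfg.q_pos, cfg.q_vel, cfg.r_control)
    sched = _SCHEDULE_CACHE.get(key)
    if sched is None:
        plant = Plant.point_mass(cfg.plant_damping, cfg.dt_ms)
        Q_T = np.diag([cfg.q_pos, cfg.q_pos, cfg.q_vel, cfg.q_vel])
        R = cfg.r_control * np.eye(2)
        sched = GainSchedule(plant, Q_T, R, horizon)
        _SCHEDULE_CACHE[key] = sched
    return sched


@dataclass
class ControlPolicy:
    """Finite-horizon feedback law toward one goal position.

    ``control(x, steps_to_go)`` returns ``-K[stg] (x - g) - k[stg]`` where
    ``g`` is the goal state (goal position, zero velocity) and ``k`` is the
    affine feedforward, nonzero only for plants that do not leave the goal
    state invariant.
    """

    goal_state: np.ndarray
    horizon: int
    schedule: GainSchedule
    feedforward: np.ndarray | None = None  # (horizon+1, m), indexed by steps-to-go

    def control(self, x: np.ndarray, steps_to_go: int) -> np.ndarray:
        stg = max(1, int(steps_to_go))
        u = -self.schedule.K(stg) @ (np.asarray(x, dtype=float) - self.goal_state)
        if self.feedforward is not None and stg <= self.horizon:
            u = u - self.feedforward[stg]
        return u

    def simulate(self, x0: np.ndarray) -> np.ndarray:
        """Noise-free rollout over the full horizon; returns states (T+1, n)."""
        plant = self.schedule.plant
        xs = [np.asarray(x0, dtype=float)]
        for j in range(self.horizon, 0, -1):
            xs.append(plant.step(xs[-1], self.control(xs[-1], j)))
        return np.array(xs)


def solve_policy(
    plant: Plant,
    goal: np.ndarray,
    horizon: int,
    Q_T: np.ndarray,
    R: np.ndarray,
) -> ControlPolicy:
    """Solve the finite-horizon LQ reach problem toward ``goal`` (position).

    Handles general linear plants: when ``A g != g`` for the goal state an
    affine feedforward sequence is computed alongside the gains so the law
    remains exactly optimal.
    """
    if horizon < 1:
        raise InvalidParameterError("horizon must be >= 1")
    Q_T = np.asarray(Q_T, dtype=float)
    R = np.asarray(R, dtype=float)
    n = plant.A.shape[0]
    m = plant.B.shape[1]
    goal = np.asarray(goal, dtype=float)
    goal_state = np.zeros(n)
    goal_state[: goal.size] = goal
    sched = GainSchedule(plant, Q_T, R, horizon)
    d = plant.A @ goal_state - goal_state
    if np.allclose(d, 0.0):
        return ControlPolicy(goal_state=goal_state, horizon=horizon, schedule=sched)
    # affine recursion: V_{j}(z) = z'Pz + 2 s'z + c with drift d per step
    A, B = plant.A, plant.B
    ks = np.zeros((horizon + 1, m))
    s = np.zeros(n)
    P = Q_T.copy()
    for j in range(1, horizon + 1):
        BtP = B.T @ P
        M = R + BtP @ B
        K = np.linalg.solve(M, BtP @ A)
        k = np.linalg.solve(M, B.T @ (P @ d + s))
        ks[j] = k
        s = (A - B @ K).T @ (P @ (d - B @ k) + s) + K.T @ R @ k
        P = A.T @ P @ A - A.T @ P @ B @ K
    return ControlPolicy(goal_state=goal_state, horizon=horizon, schedule=sched,
                         feedforward=ks)


@dataclass(frozen=True)
class DesirabilityWeights:
    """Normalized supra-threshold reach activity: indices and weights.

    Weights are nonnegative and sum to 1 whenever any neuron exceeds the
    action-initiation threshold; empty otherwise.
    """

    indices: np.ndarray
    weights: np.ndarray

    @property
    def is_empty(self) -> bool:
        return self.indices.size == 0


def relative_desirability(
    u_reach: np.ndarray, gamma: float, beta: float = 1.0, u0: float = 0.0
) -> DesirabilityWeights:
    """Desirability d_j = f(u_j) / sum_k f(u_k) over neurons with u_j > gamma."""
    u_reach = np.asarray(u_reach, dtype=float)
    idx = np.flatnonzero(u_reach > gamma)
    if idx.size == 0:
        return DesirabilityWeights(indices=idx, weights=np.empty(0))
    z = np.clip(beta * (u_reach[idx] - u0), -500, 500)
    f = 1.0 / (1.0 + np.exp(-z))
    return DesirabilityWeights(indices=idx, weights=f / f.sum())


def mix_policies(
    policies: list[ControlPolicy],
    weights: DesirabilityWeights,
    x: np.ndarray,
    steps_to_go: int | None = None,
) -> np.ndarray | None:
    """Desirability-weighted mixture of the active policies at state x.

    Returns ``None`` (the no-command sentinel; the plant holds) when no
    neuron is supra-threshold.
    """
    if weights.is_empty:
        return None
    if len(policies) != weights.weights.size:
        raise InvalidParameterError("one policy per desirability weight required")
    u = np.zeros(policies[0].schedule.plant.B.shape[1])
    for w, pol in zip(weights.weights, policies):
        u += w * pol.control(x, steps_to_go if steps_to_go is not None else pol.horizon)
    return u


@dataclass
class TrialResult:
    """Closed-loop execution record of one trial."""

    times: np.ndarray            # ms, relative to target onset
    positions: np.ndarray        # (N, 2) workspace units
    velocities: np.ndarray       # (N, 2)
    events: dict
    traces: dict = field(default_factory=dict)


def rhc_execute(
    arch: Architecture,
    timeline,
    group_task: GroupTaskParams,
    cfg: SimConfig,
    master_seed: int,
    trial_index: int = 0,
    record_fields: bool = False,
    pause_clamp: bool = False,
) -> TrialResult:
    """Run the full closed loop for one trial.

    Fields are stepped each millisecond; once a reach neuron crosses the
    initiation threshold gamma, movement begins after the motor latency and
    the mixed policy is executed with re-planning every ``rhc_interval``
    steps.  The loop ends when a response registers (displacement along the
    choice axis beyond ``response_fraction`` of the target distance) or at
    the display timeout.  Logged events include threshold crossing,
    initiation, re-plan count, stop-cue onset, response time/direction, and
    the largest deviation of the desirability-weight sum from 1.
    """
    dt = cfg.dt_ms
    arch.reset()
    rngs = {name: substream(master_seed, trial_index, name)
            for name in arch.specs if arch.noise[name].sigma > 0}

    sched = _shared_schedule(cfg)
    labels = arch.specs["reach_planning"].labels
    phi = np.deg2rad(labels)
    r = cfg.target_distance
    goal_states = np.zeros((labels.size, 4))
    goal_states[:, 0] = r * np.cos(phi)
    goal_states[:, 1] = r * np.sin(phi)
    rcfg = arch.specs["reach_planning"]

    x = np.zeros(4)
    t = float(timeline.t_start)
    t_limit = float(cfg.display_ms)
    n_steps = int(round((t_limit - t) / dt)) + 1

    times = np.empty(n_steps)
    positions = np.empty((n_steps, 2))
    velocities = np.empty((n_steps, 2))
    traces: dict = {"reach_max": [], "pause_mean": [], "t": []} if record_fields else {}

    t_cross = None
    t_init = None
    replan_count = 0
    active = DesirabilityWeights(np.empty(0, dtype=int), np.empty(0))
    steps_since_replan = 0
    t_move_end = None
    response_t = None
    response_dir = None
    weight_dev_max = 0.0
    i = 0

    while i < n_steps:
        times[i] = t
        positions[i] = x[:2]
        velocities[i] = x[2:]

        if record_fields:
            traces["t"].append(t)
            traces["reach_max"].append(float(arch.states["reach_planning"].u.max()))
            pu = arch.states["pause"].u
            traces["pause_mean"].append(float(pu.mean()))

        # --- field dynamics -------------------------------------------------
        arch.step(
            sensory_input=timeline.sensory_at(t),
            expected_input=timeline.expected_at(t),
            stop_input=timeline.stop_at(t),
            conflict_input=timeline.conflict_at(t),
            group_task=group_task,
            dt=dt,
            rngs=rngs,
            pause_clamp=pause_clamp,
        )
        u_reach = arch.states["reach_planning"].u

        # --- action initiation ---------------------------------------------
        if t_cross is None and float(u_reach.max()) > arch.gamma:
            t_cross = t + dt
        if t_init is None and t_cross is not None and t + dt >= t_cross + cfg.motor_latency_ms:
            t_init = t + dt
            t_move_end = t_init + cfg.movement_duration_ms
            steps_since_replan = cfg.rhc_interval  # force an immediate plan

        # --- motor command ---------------------------------------------------
        u_cmd = np.zeros(2)
        if t_init is not None and response_t is None:
            if steps_since_replan >= cfg.rhc_interval:
                # receding-horizon re-plan: refresh the active policy set
                active = relative_desirability(u_reach, arch.gamma, rcfg.beta, rcfg.u0)
                replan_count += 1
                steps_since_replan = 0
                if not active.is_empty and (t_move_end - t) / dt < cfg.min_horizon:
                    t_move_end += cfg.horizon_extension_ms
            else:
                # weights track the field every step over the frozen set
                if not active.is_empty:
                    sub = u_reach[active.indices]
                    keep = sub > arch.gamma
                    if keep.any():
                        z = np.clip(rcfg.beta * (sub[keep] - rcfg.u0), -500, 500)
                        f = 1.0 / (1.0 + np.exp(-z))
                        active = DesirabilityWeights(active.indices[keep], f / f.sum())
                    else:
                        active = DesirabilityWeights(np.empty(0, dtype=int), np.empty(0))
            if not active.is_empty:
                wsum = float(active.weights.sum())
                weight_dev_max = max(weight_dev_max, abs(wsum - 1.0))
                stg = max(1, int(round((t_move_end - (t + dt)) / dt)))
                goal_mix = active.weights @ goal_states[active.indices]
                u_cmd = -sched.K(stg) @ (x - goal_mix)
            steps_since_replan += 1

        # --- plant ----------------------------------------------------------
        x = sched.plant.step(x, u_cmd)
        t += dt
        i += 1

        if response_t is None and abs(x[0]) >= cfg.response_fraction * r:
            response_t = t
            response_dir = "right" if x[0] > 0 else "left"
            times[i] = t
            positions[i] = x[:2]
            velocities[i] = x[2:]
            i += 1
            break

    events = {
        "t_cross": t_cross,
        "t_init": t_init,
        "rt_threshold_ms": (None if t_cross is None else t_cross + cfg.motor_latency_ms),
        "replan_count": replan_count,
        "t_response": response_t,
        "response_dir": response_dir,
        "stop_onset": getattr(timeline, "stop_onset", None),
        "weight_dev_max": weight_dev_max,
        "timed_out": response_t is None,
    }
    if record_fields:
        traces = {k: np.asarray(v) for k, v in traces.items()}
    return TrialResult(times=times[:i], positions=positions[:i],
                       velocities=velocities[:i], events=events, traces=traces)
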