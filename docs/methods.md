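# Methods

## Model overview

The simulator implements a systems-level theory of action regulation in
which reaching decisions emerge from competition between direction-tuned
neural populations, and a basal-ganglia-style **pause** mechanism delays or
cancels actions. Six dynamic neural fields (DNFs) are wired together:

| field | size | role |
|---|---|---|
| spatial_sensory | 181 | angular representation of displayed targets (0–180°) |
| expected_outcome | 181 | expected reward of reaching each direction |
| reach_planning | 181 | competition arena; drives the controllers |
| stop_context | 100 | activated by a stop cue |
| conflict_context | 100 | activated by conflicting flanker information |
| pause | 3 × 75 | selection / conflict / stop subpopulations; inhibits reach planning |

Sensory and expected-outcome outputs project one-to-one (topologically) onto
reach planning; context fields project one-to-all onto their pause
subpopulation; the sensory field projects one-to-all onto the *selection*
subpopulation, gated on the presence of ≥ 2 disjoint supra-threshold bumps
(two encoded targets need no separate context signal). The pause field
inhibits all reach neurons one-to-all with gain `eta_pau`.

Fields integrate by forward Euler at `dt = 1 ms` (guard `dt ≤ tau/5`), with
additive Gaussian noise scaled by `sqrt(dt)` (Euler–Maruyama) so that trial
statistics are invariant under step refinement. The 0–180° space is a
bounded line (left vs right reaches), so lateral interactions use
zero-padded (non-circular) distance-dependent weights.

## Dynamical regime and the participation threshold

The printed output nonlinearity is a plain logistic; the accompanying notion
that "neurons above a threshold participate" is implemented as a
configurable offset: `f(u) = 1/(1 + e^{-beta (u - u0)})`, default
`beta = 4, u0 = 2` for **all** fields. This choice does real work:

* At rest (`u = h = -3`) every field's output is ~`1e-9`, so the wired model
  sits at its fixed point to ≈ `1e-7` — no baseline leak, and the
  no-stimulus fixed-point test holds at `1e-6`.
* Winner-take-all requires the competition loop gain `c_inh · N · f'(u)` to
  exceed 1 while activity traverses the sensitive zone around `u0`. With a
  shallow sigmoid both populations saturate (`f' ≈ 0`) and mutual inhibition
  loses its differential — choice trials deadlock. The steep sigmoid
  concentrates `f'` near `u0 = 2`, below the initiation threshold
  `gamma = 2.3`, so selection resolves *before* movement starts; residual
  late resolutions produce occasional changes of mind.

The reach kernel (`C_exc = 0.35, σ_exc = 10°; C_inh = 0.30, σ_inh = 300°`)
gives local self-excitation plus near-global inhibition: two stimulus-driven
populations mutually suppress until noise breaks the symmetry, after which
the loser collapses below the participation threshold.

## Pause routing and the disease parameterization

Each pause subpopulation receives its phasic one-to-all drive plus a
group-and-task *tonic* drive — the only parameter that differs between
groups. PD carries a higher tonic on the selection (decision task) and
conflict (flanker task) subpopulations; in the stop-signal task the
proactive pre-cue drive is *higher for neurotypical* (the strategic brake
that produces the response-delay effect), lower for PD. Defaults (input
units): NT stop 4.983, PD stop 4.845, PD selection 4.710, PD conflict
4.632, all NT decision/flanker tonics 0. The pause gain `eta_pau = 0.05`
sets both the tonic braking (through the graded part of the pause sigmoid)
and the cancellation ceiling (`eta_pau x 75` per saturated subpopulation):
the stop cue must retain enough headroom above the proactive tonic level to
collapse a committed reach bump, which pins the ratio of phasic to tonic
inhibition.

The total afferent drive onto the selection and conflict subpopulations
saturates at `pause_input_cap = 5.025` — a synaptic-saturation assumption.
It makes the pause response during choice comparable across groups even
though PD starts from an elevated baseline (the tonically active
subpopulation is "not further activated" by the phasic input), which is
exactly the regime the theory needs for choice-trial RTs to be similar
across groups. The stop route is deliberately uncapped: a stop cue must
retain full cancellation strength on top of the proactive tonic.

## Motor periphery

The plant is a discrete-time planar point mass with viscous damping
(8 s⁻¹); control is acceleration. The reach cost — terminal precision
`Q_T = diag(2·10⁴, 2·10⁴, 2·10², 2·10²)` against control effort
`R = 10⁻³ I` — is minimized by a backward Riccati recursion. Because a goal
state with zero velocity is invariant under the plant, the feedback gains
depend only on steps-to-go and are shared across all 181 per-neuron
controllers (computed once, cached); for general plants an affine
feedforward is computed so the law stays exactly optimal (verified against
brute-force enumeration on small instances).

Execution is receding-horizon: movement initiates when a reach neuron
crosses `gamma` (plus a 50 ms motor latency); the active policy set
(supra-threshold neurons, goals, remaining horizon) is refreshed every 9
plant steps, while the desirability weights `d_j = f(u_j)/Σ f(u_k)` track
the field at every step. The policy goal is the stimulus location of the
neuron's preferred direction (identical to the hand-distance construction at
policy creation from the start position, and well-defined mid-movement,
which the literal distance-based form is not). Remaining-time horizons are
kept under re-planning (floor 60 steps; extended by 300 ms if exhausted
before a response registers). A response registers when hand displacement
along the choice axis exceeds 78% of target distance — mirroring the
±25,000-of-±32,000 joystick criterion; a stop trial succeeds iff no response
registers before the 1500 ms timeout. When no neuron is supra-threshold the
plant holds (zero command, damping decelerates the hand): a successful stop
freezes the hand mid-reach; a sufficiently late stop cue fails because the
accrued momentum still carries the hand across the response threshold.

Noise on the reach field (`σ = 0.055` per √ms) is spatially correlated
(Gaussian-smoothed over 6°, rescaled to preserve per-neuron variance) so
that neighboring direction-tuned neurons fluctuate coherently; independent
noise across 181 neurons would make the first threshold crossing an
extreme-value statistic and shrink RT variability unrealistically.

## Task protocols

All timelines are relative to target onset. The human protocol's long
fixation intervals are compressed to a 200 ms settling period (fields start
at rest, so nothing happens during fixation); stimulus display/timeout is
1500 ms. The flanker precedes its target by 100 ms; conflict is routed from
the protocol layer (the conflict-context field is driven whenever flanker
and target directions differ, from target onset) rather than computed from a
sensory mismatch, keeping the mechanism explicit. The expected-outcome field
is silent in the decision task (both options equally rewarded) and carries a
bump at the correct target (gain `eta_reward = 1.6`) in the flanker task,
biasing the competition toward the instructed direction. The stop-signal
staircase starts at SSD 200 ms, steps ±50 ms on stop-trial outcome, clamped
to [0, 1500] ms. Session presets: 200 decision trials (50% choice), 200
flanker trials (50% incongruent), 100 go + 250 stop trials — plus a
human-protocol preset (2×52, 2×52, 3×60 with 40/20 go/stop).

Choice trials use perfectly symmetric drives; field noise alone breaks the
tie. One master seed spawns named substreams per field and per trial
(`SeedSequence([seed, trial_index, stream_id])`), so any single trial is
reproducible in isolation and sessions are bit-identical across reruns.

## Behavioral reduction

RT is computed from the trajectory: natural cubic interpolating spline,
speed from the spline's analytic derivative, RT = first post-onset crossing
of 10% of the per-trial maximum speed (per-trial normalization). Exclusions,
in order: trials without an RT, change-of-mind trials (past 5% of the
response range toward one side, final response on the other), RT < 100 ms,
RT > 1500 ms, then a single-pass |RT − mean| > 3 SD cut with mean/SD per
(task, group, trial-type) cell computed after the absolute cuts. Counts
reconcile exactly by construction. Group statistics: two-way type-II ANOVA
(group × trial type) per decision/flanker task — type II because simulated
exclusions unbalance the cells — and two-tailed t-tests for go-trial
contrasts. Stop psychometrics: P(stop) per SSD bin aligned to the 50 ms
staircase grid; bins with ≥ 5 trials enter monotonicity and group
comparisons.

The velocity-rule RT is the primary readout; the threshold-crossing RT
(gamma crossing + 50 ms latency) is logged beside it. For the default
controller the two agree to ~10–30 ms, the analytic 10%-of-peak crossing
offset of the speed profile; the offset is constant across conditions, so
all contrasts are unaffected by the choice of readout.

## Calibration and what the defaults represent

Numerical parameter values for the architecture are not prescribed by the
theory, which makes qualitative predictions; the shipped defaults were
hand-tuned (`scripts/calibrate.py`, documented there) until the qualitative
battery holds under the study conditions: choice > instructed and
incongruent > congruent RT; go > instructed (response-delay effect); PD
slower on instructed/congruent/incongruent; neurotypical slower than PD on
go trials; PD stop probability ≤ neurotypical per SSD bin; P(stop) falling
with SSD; staircase success ≈ 50%; change-of-mind on a few percent of choice
trials. Simulated RTs land on a realistic scale (instructed ≈ 260 ms, go ≈
400–480 ms) but no attempt is made to fit human means — the human datasets
are not part of this package, and the model (by design) cannot reproduce
right-skewed RT tails, which would require attention-lapse mechanisms it
does not contain.

## What the synthetic trajectories do and do not show

`metrics.generate_synthetic_trajectory` produces closed-form minimum-jerk,
change-of-mind, and stationary trajectories with known ground truth so the
behavioral reduction is testable without the simulator. They emulate smooth
joystick reaches, not tremor, submovement corrections, or measurement noise
of real recordings; passing metric tests therefore certifies the reduction
pipeline's arithmetic, not its robustness to raw-lab artifacts.

## Known limitations

* One-dimensional fields; rate-based units; no plasticity.
* The pause acts only by suppressing reach-planning activity; the
  alternative threshold-raising account is expressible (raise `gamma`) but
  not parameterized here.
* Stop-task dynamics produce a stopping latency of ~150–250 ms after the
  cue; the staircase therefore settles at lower SSDs than typical human
  experiments when simulated RTs are fast.
* Simulated RT distributions are roughly symmetric (no right skew), so
  distribution-level comparisons with human data are out of scope.
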