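# actionreg

A neurodynamical simulator of **action regulation** — how the brain selects
between competing reaches, delays movement under conflicting information,
and outright stops actions — and of how a dysfunctional basal-ganglia
"pause" mechanism reproduces the motor slowing seen in Parkinson's disease
(PD).

The model couples **dynamic neural fields** (DNFs) with **stochastic optimal
feedback control**. Each field describes population activity `u(x, t)` over
movement direction (or an abstract context index) evolving as

    tau du/dt = -u + h + S(x, t) + [w ⊛ f(u)](x, t) + Σ_k [w_jk ⊛ f_k(u_k)](x, t)

with a difference-of-Gaussians interaction kernel
`w(Δx) = C_exc exp(-Δx²/2σ_exc²) - C_inh exp(-Δx²/2σ_inh²)` and logistic
output `f(u) = 1/(1 + e^{-β(u-u0)})`. The reach-planning field receives

    S_action = η_pos v_pos + η_reward v_reward - η_pau v_pau + ξ

where `v_pau` is the output of a three-subpopulation *pause field* (an STN
analog) with dedicated routes for action selection, conflict, and stopping.
Reach neurons above the initiation threshold `γ` each engage a
finite-horizon LQ controller toward their preferred direction
(`J = (x_T - g)' Q_T (x_T - g) + Σ u' R u`); the executed command is the
mixture of active policies weighted by **relative desirability**
`d_j = f(u_j)/Σ f(u_k)`, re-planned every 9 steps (receding-horizon
control). Group differences (neurotypical vs PD) are carried *entirely* by
per-task tonic pause drives.

Three tasks are built in, with their staircases and trial mixes:
free-choice/instructed decision, arrow flanker (congruent/incongruent, 100 ms
flanker lead), and stop-signal (1-up/1-down ±50 ms SSD staircase). Behavior
is reduced exactly as in joystick experiments: cubic-spline smoothing,
RT = first crossing of 10% of peak speed, exclusion of RT < 100 ms,
RT > 1500 ms, |RT − mean| > 3 SD, and change-of-mind trials (5%-of-range
reversals).

## Worked example

```python
from actionreg import SimConfig, tasks, metrics

cfg = SimConfig()
specs = tasks.make_session("decision", "neurotypical", cfg, seed=11)
table = tasks.run_session(specs, "neurotypical", cfg, seed=11)  # 200 trials
analyzed, excluded = metrics.filter_trials(table)
print(analyzed.groupby("trial_type")["rt_ms"].agg(["mean", "std", "size"]).round(1))
print("change-of-mind rate:",
      table[table.trial_type == "choice"]["change_of_mind"].mean())
```

prints (default parameters, seed 11):

```
             mean    std  size
trial_type
choice      414.3  106.0    95
instructed  258.8   23.9    99
change-of-mind rate: 0.03
```

Free-choice reaches are ~155 ms slower than instructed ones — the pause
field's selection subpopulation brakes the reach-planning field while the
two direction-tuned populations compete — and about 3% of choice trials show
a change of mind, where the hand starts toward one target and reverses.
`tasks.run_session("stop_signal", ...)` likewise yields go-trial RTs, the
realized SSD staircase and the falling P(stop|SSD) curve, and the CLI wraps
the same calls (`actionreg run --task stop --group pd --seed 1 --out DIR`,
`actionreg campaign run`, `... stats`, `... plot`, `... sweep`).

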