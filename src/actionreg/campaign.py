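"""End-to-end simulation campaign: all task x group batteries, summary
statistics, representative field traces, and the qualitative-prediction
verdict table.

A campaign runs the three tasks for both parameterizations at the
simulation-campaign trial counts, writes one SessionTable CSV per run plus a
metadata JSON (configuration hash, seed, package version) so reruns with the
same hash and seed are bit-identical, and evaluates the behavioral battery:
the directional RT orderings across trial types and groups, the stop-signal
psychometrics, and the pairwise statistical contrasts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, metrics, tasks
from .architecture import GroupTaskParams, build_architecture
from .config import SimConfig, config_hash
from .errors import ConfigurationError

__all__ = ["Campaign", "run_campaign", "acceptance_report", "battery_from_tables",
           "representative_traces"]

RUNS = [(task, group) for task in ("decision", "flanker", "stop_signal")
        for group in ("neurotypical", "pd")]


@dataclass
class Campaign:
    """A set of (task, group) runs with shared config and base seed."""

    config: SimConfig
    seed: int = 0
    preset: str = "paper"
    runs: list = None

    def __post_init__(self):
        if self.runs is None:
            self.runs = list(RUNS)


def _run_seed(base_seed: int, task: str, group: str) -> int:
    offset = {"decision": 0, "flanker": 1, "stop_signal": 2}[task]
    return int(base_seed) * 101 + offset * 2 + (0 if group == "neurotypical" else 1)


def run_campaign(config: SimConfig | None = None, out_dir: str | Path = "campaign_out",
                 seed: int = 0, preset: str = "paper",
                 traces: bool = True) -> Path:
    """Execute the full campaign and write its artifact directory.

    Emits ``session_<task>_<group>.csv`` per run, ``summary.csv`` (mean/SE RT
    per cell after exclusions), ``stats.json`` (contrasts, ANOVA, battery),
    ``traces_*.csv`` (representative reach/pause field time courses), and
    ``metadata.json``.
    """
    cfg = config or SimConfig()
    camp = Campaign(config=cfg, seed=seed, preset=preset)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sessions = {}
    for task, group in camp.runs:
        run_seed = _run_seed(seed, task, group)
        specs = tasks.make_session(task, group, cfg, seed=run_seed, preset=preset)
        df = tasks.run_session(specs, group, cfg, seed=run_seed)
        sessions[(task, group)] = df
        df.to_csv(out / f"session_{task}_{group}.csv", index=False)

    combined = pd.concat(sessions.values(), ignore_index=True)
    analyzed, exclusions = metrics.filter_trials(combined)
    summary = (analyzed.groupby(["task", "group", "trial_type"])["rt_ms"]
               .agg(mean_rt="mean", se_rt=lambda s: s.std(ddof=1) / np.sqrt(len(s)),
                    n="size").reset_index())
    summary.to_csv(out / "summary.csv", index=False)

    report = battery_from_tables(sessions)
    stats_payload = {
        "battery": report.to_dict(orient="records"),
        "exclusions": exclusions,
        "group_stats": {k: (v.to_dict() if isinstance(v, pd.DataFrame) else v)
                        for k, v in metrics.group_stats(analyzed).items()},
    }
    (out / "stats.json").write_text(json.dumps(stats_payload, indent=2, default=float))

    if traces:
        for name, tr in representative_traces(cfg, seed).items():
            pd.DataFrame(tr).to_csv(out / f"traces_{name}.csv", index=False)

    meta = {"config_hash": config_hash(cfg), "seed": int(seed), "preset": preset,
            "version": __version__, "runs": [list(r) for r in camp.runs]}
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))
    return out


def representative_traces(cfg: SimConfig, seed: int = 0) -> dict:
    """Reach-planning and pause field time courses for one representative
    trial per condition, using the same trial seed across groups so the
    traces are directly comparable."""
    conditions = [
        ("decision", "instructed"), ("decision", "choice"),
        ("flanker", "congruent"), ("flanker", "incongruent"),
        ("stop_signal", "go"), ("stop_signal", "stop"),
    ]
    out = {}
    for task, trial_type in conditions:
        for group in ("neurotypical", "pd"):
            arch = build_architecture(cfg)
            gt = GroupTaskParams.from_config(cfg, group, task)
            spec = tasks.TrialSpec(task=task, trial_type=trial_type, direction="right",
                                   flanker_direction=("left" if trial_type == "incongruent"
                                                      else ("right" if task == "flanker" else None)),
                                   timeout=cfg.display_ms)
            stair = tasks.StaircaseState(cfg.ssd_initial, cfg.ssd_step,
                                         cfg.ssd_floor, cfg.ssd_ceiling)
            rec = tasks.run_trial(spec, arch, gt, staircase=stair, seed=seed,
                                  trial_index=7, keep_result=True, record_fields=True)
            tr = rec.result.traces
            out[f"{task}_{trial_type}_{group}"] = {
                "t_ms": tr["t"], "reach_max": tr["reach_max"],
                "pause_mean": tr["pause_mean"]}
    return out


def _ordering(name, lhs, rhs, lhs_val, rhs_val):
    ok = bool(np.isfinite(lhs_val) and np.isfinite(rhs_val) and lhs_val > rhs_val)
    return {"check": name, "lhs": lhs, "rhs": rhs,
            "lhs_value": float(lhs_val), "rhs_value": float(rhs_val), "passed": ok}


def battery_from_tables(sessions: dict) -> pd.DataFrame:
    """Evaluate the qualitative behavioral battery on session tables.

    ``sessions`` maps (task, group) to SessionTables.  Rows cover the RT
    orderings across trial types and groups, the stop-psychometric
    monotonicity, and the staircase convergence; the ``passed`` column gives
    the machine-readable verdict.
    """
    def mean_rt(task, group, trial_type):
        df = sessions.get((task, group))
        if df is None:
            return np.nan
        analyzed, _ = metrics.filter_trials(df)
        vals = analyzed[analyzed["trial_type"] == trial_type]["rt_ms"]
        return float(vals.mean()) if len(vals) else np.nan

    rows = [
        _ordering("rt_choice_gt_instructed_nt", "choice", "instructed",
                  mean_rt("decision", "neurotypical", "choice"),
                  mean_rt("decision", "neurotypical", "instructed")),
        _ordering("rt_incongruent_gt_congruent_nt", "incongruent", "congruent",
                  mean_rt("flanker", "neurotypical", "incongruent"),
                  mean_rt("flanker", "neurotypical", "congruent")),
        _ordering("rt_go_gt_instructed_nt", "go(stop task)", "instructed(decision)",
                  mean_rt("stop_signal", "neurotypical", "go"),
                  mean_rt("decision", "neurotypical", "instructed")),
        _ordering("rt_pd_gt_nt_instructed", "pd instructed", "nt instructed",
                  mean_rt("decision", "pd", "instructed"),
                  mean_rt("decision", "neurotypical", "instructed")),
        _ordering("rt_pd_gt_nt_congruent", "pd congruent", "nt congruent",
                  mean_rt("flanker", "pd", "congruent"),
                  mean_rt("flanker", "neurotypical", "congruent")),
        _ordering("rt_pd_gt_nt_incongruent", "pd incongruent", "nt incongruent",
                  mean_rt("flanker", "pd", "incongruent"),
                  mean_rt("flanker", "neurotypical", "incongruent")),
        _ordering("rt_nt_gt_pd_go", "nt go", "pd go",
                  mean_rt("stop_signal", "neurotypical", "go"),
                  mean_rt("stop_signal", "pd", "go")),
        _ordering("rt_pd_go_gt_pd_instructed", "pd go", "pd instructed",
                  mean_rt("stop_signal", "pd", "go"),
                  mean_rt("decision", "pd", "instructed")),
    ]

    # stop psychometrics: per-bin PD <= NT, curves non-increasing, staircase ~50%
    curves = {}
    for group in ("neurotypical", "pd"):
        df = sessions.get(("stop_signal", group))
        if df is not None:
            curves[group] = metrics.stop_probability_curve(df)
            mono_dev = metrics.isotonic_deviation(curves[group])
            rows.append({"check": f"pstop_nonincreasing_{group}", "lhs": "0.05",
                         "rhs": "max increase", "lhs_value": 0.05,
                         "rhs_value": mono_dev, "passed": bool(mono_dev <= 0.05)})
            stops = df[df["stop_outcome"].isin(["success", "fail"])]
            rate = float((stops["stop_outcome"] == "success").mean())
            rows.append({"check": f"staircase_rate_{group}", "lhs": "success rate",
                         "rhs": "0.5 +/- 0.1", "lhs_value": rate, "rhs_value": 0.5,
                         "passed": bool(abs(rate - 0.5) <= 0.10)})
    if len(curves) == 2:
        merged = curves["neurotypical"].merge(curves["pd"], on="ssd_bin",
                                              suffixes=("_nt", "_pd"))
        merged = merged[(merged["n_nt"] >= 5) & (merged["n_pd"] >= 5)]
        ok = bool((merged["p_stop_pd"] <= merged["p_stop_nt"] + 1e-12).all())
        rows.append({"check": "pstop_pd_le_nt_per_bin", "lhs": "pd", "rhs": "nt",
                     "lhs_value": float(merged["p_stop_pd"].mean()) if len(merged) else np.nan,
                     "rhs_value": float(merged["p_stop_nt"].mean()) if len(merged) else np.nan,
                     "passed": ok})
    return pd.DataFrame(rows)


def acceptance_report(artifact_dir: str | Path) -> pd.DataFrame:
    """Re-evaluate the behavioral battery from a campaign artifact directory."""
    art = Path(artifact_dir)
    sessions = {}
    for task, group in RUNS:
        path = art / f"session_{task}_{group}.csv"
        if not path.exists():
            raise ConfigurationError(f"incomplete campaign: missing {path.name}")
        sessions[(task, group)] = pd.read_csv(path)
    return battery_from_tables(sessions)
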