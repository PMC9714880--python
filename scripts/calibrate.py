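"""Hand-tuning helper for the default parameter set.

Runs reduced task x group batteries and prints the quantities the shipped
defaults are calibrated against: mean RT per condition, the directional RT
orderings, the change-of-mind rate on choice trials, and the stop-signal
psychometrics.  Usage:

    python scripts/calibrate.py [--trials N] [--seed S] [--full]

Edit ``actionreg.config.SimConfig`` defaults (or pass --override key=value),
re-run, and inspect.  The battery printed here is the same one evaluated by
``actionreg.campaign.battery_from_tables``.
"""

from __future__ import annotations

import argparse
import time

import numpy as np

from actionreg import metrics, tasks
from actionreg.campaign import battery_from_tables
from actionreg.config import SimConfig


def parse_overrides(pairs):
    out = {}
    for pair in pairs or []:
        key, val = pair.split("=", 1)
        out[key] = float(val)
    return out


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--trials", type=int, default=60,
                    help="trials per condition (per trial type) in reduced mode")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--full", action="store_true",
                    help="use the full simulation-campaign counts")
    ap.add_argument("--override", action="append", default=[],
                    help="config override, e.g. --override eta_pau=0.05")
    args = ap.parse_args()

    cfg = SimConfig(**parse_overrides(args.override)) if args.override else SimConfig()
    sessions = {}
    t0 = time.time()
    for task in ("decision", "flanker", "stop_signal"):
        for group in ("neurotypical", "pd"):
            specs = tasks.make_session(task, group, cfg, seed=args.seed)
            if not args.full:
                # keep the per-type mix while truncating
                by_type: dict = {}
                keep = []
                for s in specs:
                    c = by_type.get(s.trial_type, 0)
                    if c < args.trials:
                        keep.append(s)
                        by_type[s.trial_type] = c + 1
                specs = keep
            df = tasks.run_session(specs, group, cfg, seed=args.seed)
            sessions[(task, group)] = df
            analyzed, excl = metrics.filter_trials(df)
            means = analyzed.groupby("trial_type")["rt_ms"].agg(["mean", "std", "size"])
            print(f"== {task} / {group} ({len(df)} trials, "
                  f"excluded {sum(excl.values())}: {excl})")
            print(means.round(1).to_string())
            if task == "decision":
                choice = df[df.trial_type == "choice"]
                if len(choice):
                    print(f"   change-of-mind rate (choice): "
                          f"{choice.change_of_mind.mean():.3f}")
            if task == "stop_signal":
                print(metrics.stop_probability_curve(df).to_string(index=False))

    print(f"\n-- battery ({time.time() - t0:.0f} s) --")
    rep = battery_from_tables(sessions)
    print(rep.round(3).to_string(index=False))
    print("ALL PASS" if rep["passed"].all() else "FAILURES PRESENT")


if __name__ == "__main__":
    main()
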