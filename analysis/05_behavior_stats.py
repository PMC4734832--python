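#!/usr/bin/env python
"""Score synthetic water-maze behavior and run the session x group ANOVA.

Simulates learning-curve trial logs for two animal groups (with/without the
recording system, which does not affect behavior by construction), scores
errors and latencies, writes the per-session summary, and runs the two-way
ANOVA per metric: the training-session effect should be strong and the
group effect null.
"""

import argparse
from pathlib import Path

from mazelfp.behavior import session_summary, simulate_trial_logs
from mazelfp.stats import two_way_anova

METRICS = ("initial_errors", "repetitive_errors", "goal_arm_latency", "platform_latency")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/behavior_summary.csv"))
    args = ap.parse_args()

    df = simulate_trial_logs(seed=args.seed)
    summary = session_summary(df)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    summary.to_csv(args.out, index=False)
    print(summary.round(2).to_string(index=False))

    for metric in METRICS:
        res = two_way_anova(df[metric], df["session"], df["group"])
        s, g = res["a"], res["b"]
        print(
            f"\n{metric}: session F({s.df_num},{s.df_den}) = {s.F:.2f}, p = {s.p:.3g}; "
            f"group F({g.df_num},{g.df_den}) = {g.F:.2f}, p = {g.p:.3g}"
        )
    print(f"\nwrote {args.out}")


if __name__ == "__main__":
    main()
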