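#!/usr/bin/env python
"""Compare genomic prediction accuracy and bias across the five mating
designs at a fixed genetic architecture (650 markers, 50 QTL, h2 = 0.30).

Runs desk-preset replicates with shared historical populations, so the
designs are compared on identical genetic backgrounds, and writes
results/accuracy_by_design.csv (replicate rows) and
results/accuracy_by_design_summary.csv (mean +/- SE per design).
"""
import argparse
from pathlib import Path

from matesim import DESIGNS, run_grid, summarize

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--replicates", type=int, default=3)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

scenarios = [(650, 50, 0.30, d) for d in DESIGNS]
rows = run_grid(scenarios, "desk", args.seed, n_replicates=args.replicates,
                share_history=True)
summary = summarize(rows, by=("design",)).sort_values("a_v", ascending=False)

args.out.mkdir(exist_ok=True)
rows.to_csv(args.out / "accuracy_by_design.csv", index=False)
summary.to_csv(args.out / "accuracy_by_design_summary.csv", index=False)

print(summary.round(4).to_string(index=False))
best, worst = summary.iloc[0], summary.iloc[-1]
print(f"\nHighest validation accuracy: {best.design} "
      f"(A_V = {best.a_v:.3f} +/- {best.a_v_se:.3f}); "
      f"lowest: {worst.design} (A_V = {worst.a_v:.3f} +/- {worst.a_v_se:.3f}).")
print(f"Mean inbreeding in generation 10 spans "
      f"{rows.groupby('design').mean_f_val.mean().min():.3f} "
      f"(min_inbreeding) to "
      f"{rows.groupby('design').mean_f_val.mean().max():.3f} (max_inbreeding).")
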