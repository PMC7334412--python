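#!/usr/bin/env python
"""Build every figure-analog table, plot and statistical comparison.

Reads results/donor_stats.csv (written by 02_gate_and_metrics.py), produces
per-figure per-donor tables, summaries, comparison results and rendered
plots under results/figures/, and prints which qualitative assertions hold.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from nkgate.figures import FIGURE_IDS, render, reproduce

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--stats", type=Path, default=Path("results/donor_stats.csv"))
parser.add_argument("--out", type=Path, default=Path("results/figures"))
args = parser.parse_args()

stats = pd.read_csv(args.stats)
args.out.mkdir(parents=True, exist_ok=True)

index_rows = []
for fid in FIGURE_IDS:
    result = reproduce(fid, stats)
    slug = fid.replace("-", "_")
    result.per_donor.to_csv(args.out / f"fig{slug}_per_donor.csv")
    result.summary.to_csv(args.out / f"fig{slug}_summary.csv", index=False)
    pd.DataFrame([c.__dict__ for c in result.comparisons]).to_csv(
        args.out / f"fig{slug}_comparisons.csv", index=False)
    render(result, args.out / f"fig{slug}.png")
    index_rows.append({"figure_id": fid, "description": result.description,
                       "assertions_pass": result.all_assertions_pass,
                       "assertions": json.dumps(result.assertions)})
    status = "PASS" if result.all_assertions_pass else "FAIL"
    print(f"{fid:13s} {status}  {result.description}")
    for c in result.comparisons:
        star = "*" if c.significant else " "
        print(f"    {star} {c.label}: p={c.p_value:.3g} favours={c.direction}")

pd.DataFrame(index_rows).to_csv(args.out / "index.csv", index=False)
n_pass = sum(r["assertions_pass"] for r in index_rows)
print(f"\n{n_pass}/{len(index_rows)} figure analogs pass their qualitative assertions")
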