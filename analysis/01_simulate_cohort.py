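#!/usr/bin/env python
"""Generate a demonstration synthetic cohort and write it to disk.

Writes one FCS 3.1 file plus a truth-label CSV per donor, and a manifest of
resolved parameters, under results/cohort_<condition>/.  The downstream
analysis scripts regenerate cohorts in memory at full scale; this script
exists to produce portable files for inspection in external cytometry tools.
"""

import argparse
from pathlib import Path

import yaml

from nkgate.fcs import write_fcs, write_truth_csv
from nkgate.populations import CohortConfig
from nkgate.simulate import build_cohort

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--condition", default="HD")
parser.add_argument("--donors", type=int, default=4)
parser.add_argument("--events", type=int, default=10_000)
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

outdir = args.out / f"cohort_{args.condition}"
outdir.mkdir(parents=True, exist_ok=True)
cohort = build_cohort(CohortConfig(condition=args.condition, n_donors=args.donors,
                                   n_events=args.events, seed=args.seed))
for dc, table in cohort.donors:
    write_fcs(table, outdir / f"{dc.donor_id}.fcs")
    write_truth_csv(table, outdir / f"{dc.donor_id}.truth.csv")
with open(outdir / "manifest.yaml", "w") as fh:
    yaml.safe_dump(cohort.manifest, fh, sort_keys=True)

n_cd56neg = sum(
    table.truth["population"].isin(["NK_neg_CD16pos", "NK_neg_CD16neg"]).sum()
    for _, table in cohort.donors)
print(f"wrote {args.donors} donors ({args.condition}, {args.events} events each) "
      f"to {outdir}")
print(f"total true CD56neg NK events across the cohort: {n_cd56neg}")
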