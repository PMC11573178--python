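#!/usr/bin/env python
"""Simulate the task and a paired test-retest cohort.

Builds the default 153-trial design (35 stable + 118 volatile trials,
probes at 14/49/73/99/134) and a 39-subject paired cohort of
mean-reverting HGF agents with prior-drawn parameters, then writes the
design, all sessions and the generating parameters as tidy CSV/JSON
under results/cohort/.
"""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from advicehgf import task

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--subjects", type=int, default=39)
ap.add_argument("--out", type=Path, default=Path(__file__).resolve().parents[1] / "results" / "cohort")
args = ap.parse_args()

args.out.mkdir(parents=True, exist_ok=True)
design = task.make_task_design()
design.to_csv(args.out / "design.csv")

spec = task.CohortSpec(n_subjects=args.subjects, seed=args.seed)
spec.to_json(args.out / "cohort_spec.json")
cohort = task.generate_retest_cohort(spec, design)

rows, params = [], []
for subj, entry in enumerate(cohort):
    for s in (1, 2):
        df = entry[f"session{s}"].to_frame()
        df.insert(0, "session", s)
        df.insert(0, "subject", subj)
        rows.append(df)
        params.append({"subject": subj, "session": s, **entry[f"params{s}"]})
pd.concat(rows).to_csv(args.out / "sessions.csv", index=False)
pd.DataFrame(params).to_csv(args.out / "generating_params.csv", index=False)
with open(args.out / "metadata.json", "w") as fh:
    json.dump({"seed": args.seed, "n_subjects": args.subjects,
               "n_trials": design.n_trials}, fh, indent=1)

follow = pd.concat(rows).groupby("session")["y"].mean()
print(f"wrote design + {len(cohort)} paired sessions to {args.out}")
print(f"mean advice taking: session 1 = {follow[1]:.3f}, session 2 = {follow[2]:.3f}")
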