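#!/usr/bin/env python
"""Practice effects and face validity of the assay.

From the paired cohort and its test-retest report: (i) paired t / BF01
per measure and the correlation map between per-subject parameter
changes and behavioral changes; (ii) cross-tabulation of probe-trial
fidelity reports against true adviser fidelity, and the
helpful-vs-misleading contrast of the refitted fidelity belief.
"""

import argparse
import json
import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from advicehgf import pipelines, task
from advicehgf.task import SessionData

root = Path(__file__).resolve().parents[1]
ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--subjects", type=int, default=None)
ap.add_argument("--cohort", type=Path, default=root / "results" / "cohort")
ap.add_argument("--out", type=Path, default=root / "results" / "validity")
args = ap.parse_args()

design = task.TaskDesign.from_csv(args.cohort / "design.csv")
sessions = pd.read_csv(args.cohort / "sessions.csv")
params = pd.read_csv(args.cohort / "generating_params.csv")
subjects = sorted(sessions.subject.unique())
if args.subjects:
    subjects = subjects[: args.subjects]
cohort = []
for subj in subjects:
    entry = {}
    for s in (1, 2):
        df = sessions[(sessions.subject == subj) & (sessions.session == s)]
        entry[f"session{s}"] = SessionData.from_frame(df)
        prow = params[(params.subject == subj) & (params.session == s)].iloc[0]
        entry[f"params{s}"] = prow.drop(["subject", "session"]).to_dict()
    cohort.append(entry)

args.out.mkdir(parents=True, exist_ok=True)
t0 = time.time()
retest = pipelines.run_test_retest(cohort, "m2", seed=args.seed)
practice = pipelines.run_practice_effects(retest)
practice["paired_tests"].to_csv(args.out / "practice_paired_tests.tsv", sep="\t")
practice["delta_correlations"].to_csv(args.out / "delta_correlations.tsv", sep="\t")
practice["delta_pvalues"].to_csv(args.out / "delta_pvalues.tsv", sep="\t")
print(f"practice effects ({time.time() - t0:.0f}s): paired tests per measure")
print(practice["paired_tests"].round(3))
print("correlation of parameter changes with behavioral changes:")
print(practice["delta_correlations"].round(3))

t0 = time.time()
face = pipelines.run_face_validity(cohort, design, "m2", seed=args.seed, refit=True)
face["crosstab"].to_csv(args.out / "probe_crosstab.tsv", sep="\t")
with open(args.out / "face_validity.json", "w") as fh:
    json.dump({"helpful_vs_misleading": face["helpful_vs_misleading"],
               "mu2hat_group_means": face["mu2hat_group_means"]}, fh, indent=1)
print(f"face validity ({time.time() - t0:.0f}s): probe reports by trial")
print(face["crosstab"])
c = face["helpful_vs_misleading"]
print(f"fidelity belief (log-odds) when reported helpful vs misleading: "
      f"{c['mean_helpful']:.2f} vs {c['mean_misleading']:.2f} "
      f"(t = {c['t']:.2f}, p = {c['p']:.2g})")
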