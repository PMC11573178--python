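#!/usr/bin/env python
"""Test-retest reliability of behavioral and computational measures.

Reads the simulated paired cohort, fits the winning model to every
session independently, and reports ICC(A,1) with 95% CI, Pearson's r and
the paired t / BF01 block for the six behavioral measures and the seven
model parameters, after Tukey extreme-outlier screening.
"""

import argparse
import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from advicehgf import pipelines
from advicehgf.task import SessionData

root = Path(__file__).resolve().parents[1]
ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--subjects", type=int, default=None)
ap.add_argument("--cohort", type=Path, default=root / "results" / "cohort")
ap.add_argument("--out", type=Path, default=root / "results" / "reliability")
args = ap.parse_args()

sessions = pd.read_csv(args.cohort / "sessions.csv")
subjects = sorted(sessions.subject.unique())
if args.subjects:
    subjects = subjects[: args.subjects]
cohort = []
for subj in subjects:
    entry = {}
    for s in (1, 2):
        df = sessions[(sessions.subject == subj) & (sessions.session == s)]
        entry[f"session{s}"] = SessionData.from_frame(df)
    cohort.append(entry)

t0 = time.time()
report = pipelines.run_test_retest(cohort, "m2", seed=args.seed)
args.out.mkdir(parents=True, exist_ok=True)
report.to_json(args.out / "reliability.json")
report.table.to_csv(args.out / "reliability.tsv", sep="\t")
report.per_subject.to_csv(args.out / "per_subject_measures.tsv", sep="\t", index=False)

print(f"test-retest reliability over {len(cohort)} subjects ({time.time() - t0:.0f}s):")
cols = ["icc", "ci_low", "ci_high", "pearson", "n", "outliers_removed"]
print(report.table[cols].round(3))
poor = report.table[report.table.icc < 0.5].index.tolist()
print(f"measures in the poor range (ICC < 0.5): {poor}")
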