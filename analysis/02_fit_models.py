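#!/usr/bin/env python
"""Fit the four-model space to every simulated session.

Reads the cohort written by 01_simulate_cohort.py, MAP-fits models
m1/m1b/m2/m2b to each session under the fixed priors, and writes one
tidy TSV row per subject x session x model (parameter estimates, log
joint, Laplace log evidence) plus per-session evidence matrices for
model selection. Fitting all four models to a full 39-subject paired
cohort takes a while; --subjects trims the cohort for quick looks.
"""

import argparse
import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd

from advicehgf.fitting import MODELS, fit_map, ideal_observer_params
from advicehgf.task import SessionData

root = Path(__file__).resolve().parents[1]
ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--subjects", type=int, default=None, help="fit only the first N subjects")
ap.add_argument("--cohort", type=Path, default=root / "results" / "cohort")
ap.add_argument("--out", type=Path, default=root / "results" / "fits")
args = ap.parse_args()

sessions = pd.read_csv(args.cohort / "sessions.csv")
subjects = sorted(sessions.subject.unique())
if args.subjects:
    subjects = subjects[: args.subjects]
args.out.mkdir(parents=True, exist_ok=True)

rows = []
t0 = time.time()
for subj in subjects:
    for sess_id in (1, 2):
        df = sessions[(sessions.subject == subj) & (sessions.session == sess_id)]
        session = SessionData.from_frame(df)
        io_cache = {}
        for name, model in MODELS.items():
            fixed = None
            if model.perceptual_mode == "ideal_fixed":
                if model.variant not in io_cache:
                    io_cache[model.variant] = ideal_observer_params(session.u, model)
                fixed = io_cache[model.variant]
            fit = fit_map(session, model, seed=args.seed + subj, fixed_perceptual=fixed)
            rows.append({"subject": subj, "session": sess_id, "model": name,
                         "lme": fit.lme, "log_joint": fit.log_joint,
                         **{f"est_{k}": v for k, v in fit.params_native.items()}})
    print(f"subject {subj} done ({time.time() - t0:.0f}s)", file=sys.stderr)

fits = pd.DataFrame(rows)
fits.to_csv(args.out / "fits.tsv", sep="\t", index=False)
for sess_id in (1, 2):
    mat = fits[fits.session == sess_id].pivot(index="subject", columns="model", values="lme")
    mat[list(MODELS)].to_csv(args.out / f"evidence_session{sess_id}.tsv", sep="\t", index=False)

best = fits.loc[fits.groupby(["subject", "session"])["lme"].idxmax(), "model"].value_counts()
print(f"wrote {len(fits)} fits to {args.out}")
print("per-session best model counts:", best.to_dict())
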