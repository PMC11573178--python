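#!/usr/bin/env python
"""Random-effects Bayesian model selection per session.

Reads the evidence matrices written by 02_fit_models.py and reports, for
each session, the expected model frequencies, the protected exceedance
probabilities and the Bayes omnibus risk.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from advicehgf.bms import EvidenceMatrix, rfx_bms

root = Path(__file__).resolve().parents[1]
ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--fits", type=Path, default=root / "results" / "fits")
ap.add_argument("--out", type=Path, default=root / "results" / "model_selection")
args = ap.parse_args()

args.out.mkdir(parents=True, exist_ok=True)
for sess_id in (1, 2):
    mat = EvidenceMatrix.from_tsv(args.fits / f"evidence_session{sess_id}.tsv")
    res = rfx_bms(mat, seed=args.seed)
    res.to_json(args.out / f"bms_session{sess_id}.json")
    pep = {m: round(float(p), 3) for m, p in zip(res.models, res.protected_exceedance)}
    f = {m: round(float(v), 3) for m, v in zip(res.models, res.frequencies)}
    print(f"session {sess_id}: PEP {pep} | f {f} | BOR {res.bor:.3f}")
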