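#!/usr/bin/env python
"""Apply the docking-score selection cascade to a synthetic score table.

Docking itself is consumed, not computed: this driver fabricates an
externally-produced score table (kJ/mol) with known composition, then
runs the two-stage cascade — scores strictly below -20 kJ/mol survive
the screen; top hits additionally need scores below -25 kJ/mol, at
least three key-residue contacts and a rule-of-five pass — and prints
the funnel counts.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from ppi_pharmscreen import screening as sc, selection as sel

OUT = Path(__file__).resolve().parent.parent / "results"
rng = np.random.default_rng(20220406)

KEY = sorted(sel.KEY_RESIDUES_RECEPTOR)
LIP_PASS = sc.LipinskiReport(360.0, 2.4, 6, 2, True, [])
LIP_FAIL = sc.LipinskiReport(615.0, 5.8, 6, 2, False, ["MW", "logP"])

records = []
for i in range(60):
    score = float(rng.uniform(-30.0, -12.0))
    n_contacts = int(rng.integers(0, 6))
    contacts = frozenset(rng.choice(KEY, size=n_contacts, replace=False).tolist())
    lip = LIP_PASS if rng.random() < 0.85 else LIP_FAIL
    records.append(sel.CandidateRecord(
        molecule_id=f"SYN{i:04d}", docking_score_kj=score,
        key_residue_contacts=contacts, lipinski=lip,
        dG_bind=float(rng.uniform(-35.0, -2.0))))

survivors = sel.screen_stage_filter(records)
tops = sel.top_hit_rule(survivors, key_residues=sel.KEY_RESIDUES_RECEPTOR)

print(f"docked candidates:                    {len(records)}")
print(f"score < {sel.SCREEN_SCORE_CUTOFF_KJ:.0f} kJ/mol:                  {len(survivors)}")
print(f"top hits (< {sel.TOP_HIT_SCORE_CUTOFF_KJ:.0f} kJ/mol, >= "
      f"{sel.MIN_KEY_CONTACTS} key contacts, rule-of-five): {len(tops)}")

pd.DataFrame([{
    "molecule": r.molecule_id, "docking_score_kj_mol": round(r.docking_score_kj, 2),
    "key_contacts": ",".join(sorted(r.key_residue_contacts)),
    "lipinski_pass": r.lipinski.passes,
    "stage": ("top_hit" if r in tops else "screened" if r in survivors else "rejected"),
} for r in records]).to_csv(OUT / "docking_cascade.tsv", sep="\t", index=False)
print(f"wrote {OUT / 'docking_cascade.tsv'}")
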