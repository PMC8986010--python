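#!/usr/bin/env python
"""MM-GBSA decomposition for a tight and a loose probe complex.

Runs the single-trajectory decomposition over 20-frame trajectories of
the salt-bridged probe (contact always present) and a mostly-unbound
variant (contact in 10% of frames), with toy force-field parameters.
The tight complex should show the larger (more negative) electrostatic
cross term and the larger compensating polar-solvation penalty.
"""
from pathlib import Path

from ppi_pharmscreen import mmgbsa as mg, synthetic as syn

OUT = Path(__file__).resolve().parent.parent / "results"

rows = []
for label, p in (("tight", 1.0), ("loose", 0.1)):
    traj, _, _ = syn.make_probe_complex(
        [{"contact_class": "salt_bridge", "residue": ("R", 277), "p": p}],
        n_frames=20, seed=syn.DEFAULT_SEED + 1)
    params = syn.assign_toy_forcefield(traj.topology, seed=syn.DEFAULT_SEED + 2)
    dec = mg.binding_energy(traj, params)
    summary = dec.summary()
    summary.insert(0, "complex", label)
    rows.append(summary)
    print(f"{label} complex ({int(p * 100)}% contact presence):")
    for t in dec.TERMS:
        print(f"  {t:8s} {dec.mean(t):10.2f} +/- {dec.sd(t):6.2f} kcal/mol")

import pandas as pd
pd.concat(rows).to_csv(OUT / "mmgbsa_summary.tsv", sep="\t", index=False)
print(f"wrote {OUT / 'mmgbsa_summary.tsv'}")
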