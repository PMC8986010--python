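#!/usr/bin/env python
"""Build the synthetic two-chain interface and its two pharmacophore models.

Writes the interface structure, the receptor-side model (2 anion, 2
aromatic, 1 essential hydrophobic point) and the cytokine-side model
(2 aromatic, 2 cation, 1 essential hydrophobic) under results/.
"""
from pathlib import Path

import pandas as pd

import ppi_pharmscreen as pp
from ppi_pharmscreen import core, synthetic as syn

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

interface, hotspots = syn.make_toy_interface()
core.write_pdb(interface, OUT / "interface.pdb")
print(f"interface: {len(interface)} atoms, residues "
      f"{sorted(set((k[0], k[1]) for k in interface.residue_keys))}")

rows = []
for side, name in (("receptor", "receptor_model"), ("cytokine", "cytokine_model")):
    model = pp.build_interface_model(interface, hotspots[side], name=name)
    model.constraints = pp.either_or_constraints([("F1", "F2"), ("F3", "F4")], ["F5"])
    (OUT / f"{name}.json").write_text(model.to_json())
    for f in model.features:
        rows.append({"model": name, "label": f.label, "type": f.ftype,
                     "source": f"{f.source_residue[2]}{f.source_residue[1]}",
                     "x": round(f.center[0], 3), "y": round(f.center[1], 3),
                     "z": round(f.center[2], 3), "radius": f.radius})
    print(f"{name}: " + ", ".join(f"{f.label}:{f.ftype}({f.source_residue[2]}{f.source_residue[1]})"
                                  for f in model.features))

pd.DataFrame(rows).to_csv(OUT / "pharmacophore_features.tsv", sep="\t", index=False)
print(f"wrote {OUT / 'pharmacophore_features.tsv'}")
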