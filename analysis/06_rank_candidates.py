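#!/usr/bin/env python
"""Final multi-evidence ranking of a planted binder among decoys.

Combines everything upstream: a planted candidate with strong (>75%)
contact occupancies at two key residues and a favourable binding
energy is ranked against a transient binder and two cascade failures.
The planted binder must come out first.
"""
from pathlib import Path

from ppi_pharmscreen import screening as sc, selection as sel, synthetic as syn, trajectory as tr
from ppi_pharmscreen.pharmacophore import PharmacophoreModel

OUT = Path(__file__).resolve().parent.parent / "results"


def strong_residues(p, n_frames=50):
    traj, _, lgroups = syn.make_probe_complex(
        [{"contact_class": "hbond", "residue": ("R", 278), "p": p},
         {"contact_class": "salt_bridge", "residue": ("R", 277), "p": p}],
        n_frames=n_frames)
    pidx = list(traj.protein_indices)
    pgroups = tr.groups_from_structure(traj.topology, pidx)
    events = tr.detect_contacts(traj, pgroups, lgroups, classes=("hbond", "salt_bridge"))
    occ = tr.occupancy(events, traj.n_frames).residue_level()
    return frozenset(tr.strong_hbond_flag(occ).residue)


model = PharmacophoreModel.from_json((OUT / "receptor_model.json").read_text())
lip_pass = sc.LipinskiReport(360.0, 2.4, 6, 2, True, [])

candidates = [
    sel.CandidateRecord(
        "planted-binder", docking_score_kj=-26.5,
        key_residue_contacts=frozenset({"Glu277", "Glu278", "Phe229"}),
        lipinski=sc.lipinski_filter(syn.make_matching_ligand(model, ["F1", "F3", "F5"])),
        strong_contact_residues=strong_residues(0.9), dG_bind=-24.0, dG_bind_sd=3.1),
    sel.CandidateRecord(
        "transient-binder", docking_score_kj=-25.5,
        key_residue_contacts=frozenset({"Glu277", "Glu278", "Phe229"}),
        lipinski=lip_pass, strong_contact_residues=strong_residues(0.3),
        dG_bind=-6.0, dG_bind_sd=4.0),
    sel.CandidateRecord("poor-score", docking_score_kj=-19.0,
                        key_residue_contacts=frozenset({"Glu278"}), lipinski=lip_pass),
    sel.CandidateRecord("few-contacts", docking_score_kj=-26.0,
                        key_residue_contacts=frozenset({"Glu278", "Phe229"}),
                        lipinski=lip_pass),
]

print(f"candidates: {len(candidates)}")
survivors = sel.screen_stage_filter(candidates)
print(f"after score screen (< -20 kJ/mol): {len(survivors)}")
tops = sel.top_hit_rule(survivors)
print(f"top hits: {len(tops)}")
ordered, report = sel.rank_candidates(tops)
report.to_csv(OUT / "final_ranking.tsv", sep="\t", index=False)
print(report.to_string(index=False))
print(f"wrote {OUT / 'final_ranking.tsv'}")
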