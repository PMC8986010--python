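"""Candidate-selection cascade over screening and analysis outputs.

Docking is consumed, not computed: records arrive with externally
produced docking scores in kJ/mol.  The cascade keeps ligands with a
score strictly below -20 kJ/mol, promotes to "top hit" those below
-25 kJ/mol that pass the rule-of-five and contact at least three key
interface residues, and finally ranks top hits by the number of key
residues held with a strong (>75% occupancy) contact, breaking ties by
ascending mean binding free energy.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .screening import LipinskiReport

SCREEN_SCORE_CUTOFF_KJ = -20.0
TOP_HIT_SCORE_CUTOFF_KJ = -25.0
MIN_KEY_CONTACTS = 3

# hot-spot residues of the two interface sides
KEY_RESIDUES_CYTOKINE = frozenset({"Phe74", "Phe78", "Leu178", "Arg179", "Arg182"})
KEY_RESIDUES_RECEPTOR = frozenset({"Phe229", "Tyr230", "Glu277", "Glu278", "Phe279"})


@dataclass
class CandidateRecord:
    molecule_id: str
    docking_score_kj: float | None = None
    matched_labels: frozenset[str] = frozenset()
    key_residue_contacts: frozenset[str] = frozenset()
    lipinski: LipinskiReport | None = None
    strong_contact_residues: frozenset[str] = frozenset()
    dG_bind: float | None = None
    dG_bind_sd: float | None = None
    notes: dict = field(default_factory=dict)


def screen_stage_filter(records, score_cutoff: float = SCREEN_SCORE_CUTOFF_KJ):
    """Keep records whose docking score is strictly below the cutoff (kJ/mol)."""
    return [r for r in records if r.docking_score_kj is not None and r.docking_score_kj < score_cutoff]


def top_hit_rule(
    records,
    score_cutoff: float = TOP_HIT_SCORE_CUTOFF_KJ,
    min_key_contacts: int = MIN_KEY_CONTACTS,
    key_residues=KEY_RESIDUES_RECEPTOR,
    require_lipinski: bool = True,
):
    """Top hits: score strictly < cutoff, >= min contacts among key residues, rule-of-five pass."""
    if not key_residues:
        raise ValueError("key_residues must be non-empty")
    key = set(key_residues)
    out = []
    for r in records:
        if r.docking_score_kj is None or not r.docking_score_kj < score_cutoff:
            continue
        if len(set(r.key_residue_contacts) & key) < min_key_contacts:
            continue
        if require_lipinski and not (r.lipinski is not None and r.lipinski.passes):
            continue
        out.append(r)
    return out


def rank_candidates(records, key_residues=KEY_RESIDUES_RECEPTOR) -> tuple[list[CandidateRecord], pd.DataFrame]:
    """Order top hits by strong-contact evidence, then binding energy.

    Primary key: number of key residues held with a strong (>75%
    occupancy) contact, descending.  Secondary: mean dG_bind ascending
    (more negative = stronger).  Ties beyond that break on the molecule
    id for reproducibility.  Returns the ordered records and a report
    table of the per-candidate evidence.
    """
    key = set(key_residues)

    def strong_count(r: CandidateRecord) -> int:
        return len(set(r.strong_contact_residues) & key)

    ordered = sorted(
        records,
        key=lambda r: (-strong_count(r),
                       r.dG_bind if r.dG_bind is not None else float("inf"),
                       r.molecule_id),
    )
    rows = []
    for rank, r in enumerate(ordered, start=1):
        rows.append({
            "rank": rank,
            "molecule_id": r.molecule_id,
            "docking_score_kj_mol": r.docking_score_kj,
            "key_residue_contacts": ",".join(sorted(r.key_residue_contacts)),
            "strong_contact_key_residues": strong_count(r),
            "lipinski_pass": bool(r.lipinski.passes) if r.lipinski else None,
            "dG_bind_kcal_mol": r.dG_bind,
            "dG_bind_sd_kcal_mol": r.dG_bind_sd,
        })
    return ordered, pd.DataFrame(rows)
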