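# Methods

This note documents the models, conventions and design choices behind
each stage of the pipeline, and what the synthetic study conditions do
and do not establish about real data.

## Interface pharmacophore models

A PPI pharmacophore is derived from hot-spot residues of a known
complex structure rather than from ligand sets. Feature centers are
deterministic functions of PDB atom names:

| type | derivation | residues handled |
|------|------------|------------------|
| Aro  | centroid of the side-chain ring heavy atoms | Phe/Tyr 6-ring, Trp 6-ring, His 5-ring |
| Ani  | midpoint of the carboxylate oxygens | Glu (OE1/OE2), Asp (OD1/OD2) |
| Cat  | guanidinium carbon CZ (Arg) or amine nitrogen NZ (Lys) | Arg, Lys |
| Hyd  | centroid of side-chain carbons beyond Cβ | any |

Whether charged features sit on atoms or group centroids is a
convention of this package (the interactive tools used in the original
campaigns print no coordinates); the midpoint/anchor choices above are
standard functional-group anchors and keep model building bit-for-bit
reproducible. The default tolerance radius is 1.0 Å per feature
(configurable per feature); this matches common pharmacophore-search
defaults.

Constraints are encoded generically as an essential label set plus
"at least k of this group" choice groups, because both canonical
interface models share that shape: one of the two charged points, one
of the two aromatic points, and the hydrophobic point always.

## Ligand feature perception

Perception is deliberately rule-based and electronics-free so that it
is deterministic on arbitrary input topologies:

* aromatic rings: smallest-ring-basis rings (≥5 atoms) in which every
  member carries at least one bond of order ≥ 1.5. This Hückel-free
  approximation types phenyl and kekulised heteroaromatics correctly
  and rejects saturated rings (piperazine), which is the chemistry the
  screening campaign turns on; exotic aromatics (azulenes, charged
  rings) are out of scope.
* cations: charged/protonatable nitrogens — quaternary or protonated N,
  guanidinium (anchored at the central carbon), aliphatic amines.
* anions: carboxylate (anchor = O–O midpoint), sulfonate, phosphate and
  nitro groups; the nitro group contributes a single anion anchor at
  the O–O midpoint because the campaign's own analysis treats −N⁺OO⁻ as
  one ionic/H-bond partner.
* hydrophobic: each maximal connected set of ≥3 carbons with no bonded
  heteroatom, anchored at its centroid; aromatic-ring carbons are
  excluded so benzene perceives as exactly one feature.
* donors: N/O with ≥1 hydrogen (implicit hydrogens inferred from
  standard valences adjusted by formal charge when no explicit H is
  present); acceptors: oxygens, plus nitrogens that retain a lone pair
  (total valence < 4).

## Matching

`match_model` enumerates every label subset of size ≥ 3 that satisfies
the model constraints and every injective type-compatible assignment of
ligand features to it, superposes the assigned positions onto the
model centers (Kabsch, proper rotations only) and accepts when every
feature lies within its label's sphere. Subsets smaller than 3 are
rejected as geometrically underdetermined — both canonical models
require ≥ 3 points anyway. Results are sorted by fit RMSD with a
lexicographic tie-break for reproducibility. The exhaustive strategy is
exact; it is intended for desk-scale feature counts (≤ ~8 model
features), not for library-scale indexing.

## Trajectory analysis

RMSD fits each frame onto a reference frame using a fit selection
(typically the protein backbone) and measures over a separate selection
(backbone, or ligand heavy atoms), so ligand mobility is reported in
the protein frame. RMSF uses the standard two-pass scheme: fit to
frame 0, form the average structure, re-fit to the average, measure
fluctuations about it; an optional separate fit selection allows
fitting on a rigid core. Means are reported ± population SD over frames.

Contact criteria: H-bond D–A < 3.5 Å and ∠D–H⋯A > 120° (strict
inequalities, explicit donor hydrogens required); salt bridge ≤ 4.0 Å
between opposite-charge group heavy atoms; hydrophobic ≤ 4.5 Å
carbon–carbon; aromatic ring-centroid distance ≤ 5.5 Å with no plane
angle term (π-π and π-alkyl are reported as one aromatic class). The
H-bond criteria are the published ones; the other three cutoffs follow
common structural-biology conventions, as the defining software for the
original analyses is not documented in text, and are config-overridable.

Occupancy of a contact pair is 100/N times the number of satisfying
events over N frames, *counting multiplicity*: one donor bridging both
carboxylate oxygens in the same frame contributes two events. This is
the only counting convention under which published per-pair rows exceed
100%, and it makes per-residue occupancies exactly the sum of the
residue's pair rows (the consistency rule the acceptance suite checks
against the published worked examples: 392.92 + 99.22 = 492.14 and
171.67 + 54.84 = 226.51). Occupancies are reported to 2 decimals.
Contacts above 75% occupancy (strictly) are flagged strong.

## MM-GBSA

Single-trajectory end-state estimate: complex, protein and ligand
geometries all come from the complex frame, so intramolecular bonded
terms cancel identically (ΔE_bond ≡ 0) and the gas-phase terms reduce
to the protein–ligand cross sums, computed without cutoff:
E_elec = 332.0636 q_iq_j/(ε_in r), LJ 12-6 in the Rmin/ε convention with
geometric ε and arithmetic Rmin combination.

Polar solvation is generalized Born with OBC-rescaled effective radii
(parameter set I: α = 0.8, β = 0, γ = 2.909125), HCT pairwise
descreening with a uniform screening factor 0.8, and the canonical
f_GB = sqrt(r² + R_iR_j exp(−r²/4R_iR_j)); ε_in = 1, ε_out = 78.5. The
radius offset is 0 by default, so a single atom's effective radius
equals its intrinsic radius and the one-ion energy is exactly the Born
equation — convenient for validation, and immaterial for toy
parameters; it is configurable for users supplying real intrinsic
radii. Nonpolar solvation is γ·SASA + β with γ = 0.0072 kcal/mol/Å²,
β = 0; SASA is Shrake–Rupley over a deterministic Fibonacci-spiral
point set (960 points/atom by default; doubling changes totals < 0.5%).
Because the quadrature grid is lab-fixed, SASA-bearing terms are
rigid-motion invariant only to quadrature resolution.

The conformational-entropy term is omitted: for ranking ligands against
one target its contribution to the *differences* is small. Energies are
reported as mean ± population SD over (strided) frames, in kcal/mol;
docking scores stay in kJ/mol with an explicit 4.184 conversion
utility, since the two scales coexist in this workflow.

## Selection cascade

Stage 1 keeps docking scores strictly below −20 kJ/mol; stage 2 (top
hits) requires strictly below −25 kJ/mol, ≥ 3 contacts among the key
interface residues and a rule-of-five pass. The final ranking orders
top hits by the number of key residues held with a strong (>75%)
contact, then by ascending mean ΔG_bind, then by id. The original
campaign combined this evidence narratively; the explicit
(strong-contact count, energy) lexicographic rule is this package's
formalisation and both keys are configurable.

## Synthetic study conditions

The generators define the test conditions; they are not tuning knobs.

* `make_toy_interface` (default seed 20220406): five partner-residue
  rows, 9 Å apart, each posed by bisection to a target geometry inside
  its detector cutoff — salt bridges at 3.2 Å heavy-atom separation,
  aromatic centroids at 4.6 Å, hydrophobic carbons at 3.9 Å — followed
  by a seeded global rigid motion. Real amino-acid atom names, minimal
  backbone (N/H/CA/C/O).
* probe ligands: one chemically plausible fragment per requested model
  label (benzene for Aro, propane for Hyd, acetate for Ani,
  methylammonium for Cat, methanol/formaldehyde for Don/Acc), each
  anchored exactly on its feature center with a seeded random
  orientation. Fragments are deliberately left unlinked: connectivity
  is irrelevant to matching, and linkers would perturb the perception
  classes being tested.
* scheduled trajectories: each contact entry owns a dedicated ligand
  group posed inside its criteria when present (bidentate geometry for
  multiplicity 2) and ~10 Å outside when absent; deterministic
  schedules occupy the first round(p·N) frames, Bernoulli schedules
  draw per frame. Gaussian jitter (σ = 0.1 Å, small against the
  0.3–1 Å margins the poses reserve) is applied everywhere and redrawn
  for a frame if it would flip a scheduled state; an unrealisable
  schedule raises rather than silently degrading.
* toy force field: charges drawn then shifted to sum exactly to each
  molecule's formal charge; LJ ε ∈ [0.015, 0.2] kcal/mol,
  Rmin/2 ∈ [0.6, 2.1] Å, GB radii ∈ [1.0, 2.5] Å (hydrogens at the small
  end of each range).

Passing on these conditions demonstrates the *computational* claims —
detector/criteria fidelity, occupancy bookkeeping, superposition
optimality, energy-term closed forms and cascade semantics. It does not
demonstrate force-field accuracy, conformational sampling or docking
quality on real systems: trajectories here are posed, not propagated,
and docking scores are synthetic inputs by design.

## Problem sizes

The shipped analyses use a 125-atom interface, ≤ 69-atom complexes,
500-frame narrative trajectories and a 2,000-frame Bernoulli-recovery
run; these sizes exercise every code path while keeping the whole
suite interactive-fast, and all scale parameters (frames, atoms,
quadrature points) are function arguments.

## Known limitations

* Feature perception has no electronic structure model: tautomers,
  charged aromatics and unusual valences fall outside the rules.
* The aromatic detector ignores ring-plane orientation.
* GB uses a uniform screening factor rather than element-specific HCT
  screens; PB solvation, normal-mode entropy and per-residue energy
  decomposition are out of scope.
* The PDB reader handles ATOM/HETATM/MODEL records only (no mmCIF, no
  binary trajectory formats); bond orders are never perceived from
  geometry — small molecules must arrive with connection tables.
* Ligand occupancy partners are labelled by group (Main/Side or an
  explicit group tag), not by any main/side-chain split of the ligand
  itself.
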