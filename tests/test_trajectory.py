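"""Superposition, stability metrics, contact detectors and occupancy."""
import math

import numpy as np
import pytest

from ppi_pharmscreen import synthetic as syn
from ppi_pharmscreen import trajectory as tr
from ppi_pharmscreen.core import AtomRecord, MolecularStructure, TrajectoryEnsemble


def _rotation_z(deg):
    a = math.radians(deg)
    return np.array([[math.cos(a), -math.sin(a), 0], [math.sin(a), math.cos(a), 0], [0, 0, 1]])


class TestKabsch:
    def test_identity(self, rng):
        pts = rng.uniform(-5, 5, size=(6, 3))
        sup = tr.kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_recovered_exactly(self, rng):
        pts = rng.uniform(-5, 5, size=(7, 3))
        moved = pts @ _rotation_z(90).T + np.array([1.0, 2.0, 3.0])
        sup = tr.kabsch_superpose(pts, moved)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_rotation_grid_search_oracle(self, rng):
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        for _ in range(3):
            ref = rng.uniform(-4, 4, size=(5, 3))
            mob = rng.uniform(-4, 4, size=(5, 3))
            got = tr.kabsch_superpose(ref, mob).rmsd

            ref_c = ref - ref.mean(axis=0)
            mob_c = mob - mob.mean(axis=0)

            def rmsd_of(rot):
                return math.sqrt(((rot.apply(mob_c) - ref_c) ** 2).sum(axis=1).mean())

            grid = Rotation.random(4000, random_state=np.random.RandomState(0))
            vals = [rmsd_of(g) for g in grid]
            best = grid[int(np.argmin(vals))]
            res = minimize(lambda v: rmsd_of(Rotation.from_rotvec(v)),
                           best.as_rotvec(), method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000})
            assert got == pytest.approx(res.fun, abs=1e-3)

    def test_reflection_is_never_returned(self, rng):
        pts = rng.uniform(-5, 5, size=(5, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        sup = tr.kabsch_superpose(pts, mirrored)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
        assert sup.rmsd > 0.1

    def test_degenerate_inputs_are_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError):
            tr.kabsch_superpose(line, line)
        with pytest.raises(ValueError):
            tr.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def _static_traj(rng, n_atoms=8, n_frames=5):
    base = rng.uniform(-5, 5, size=(n_atoms, 3))
    atoms = [AtomRecord(serial=i + 1, name="CA", element="C", residue_name="ALA",
                        residue_seq=i + 1, chain_id="A", coords=c) for i, c in enumerate(base)]
    frames = np.repeat(base[None], n_frames, axis=0)
    return TrajectoryEnsemble(MolecularStructure(atoms), frames)


class TestRmsdRmsf:
    def test_static_trajectory_rmsd_zero(self, rng):
        traj = _static_traj(rng)
        rs = tr.rmsd_series(traj, range(8), range(8))
        assert np.allclose(rs.values, 0.0, atol=1e-12)
        assert rs.mean == pytest.approx(0.0, abs=1e-12)
        assert rs.sd == pytest.approx(0.0, abs=1e-12)

    def test_rigidly_moved_frames_have_zero_rmsd(self, rng):
        traj = _static_traj(rng)
        frames = traj.frames.copy()
        for k in range(traj.n_frames):
            R = syn._random_rotation(rng)
            frames[k] = frames[k] @ R.T + rng.uniform(-10, 10, 3)
        moved = TrajectoryEnsemble(traj.topology, frames)
        rs = tr.rmsd_series(moved, range(8), range(8))
        assert np.allclose(rs.values, 0.0, atol=1e-9)

    def test_ligand_displacement_appears_at_full_magnitude_after_protein_fit(self):
        d = 1.7
        traj = syn.make_ligand_shift_trajectory(displacement=d)
        prot = list(traj.protein_indices)
        lig = list(traj.ligand_indices)
        rs = tr.rmsd_series(traj, prot, lig)
        assert rs.values[0] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rs.values[1:], d, atol=1e-9)

    def test_rmsd_equals_bruteforce_on_small_toy(self, rng):
        traj = _static_traj(rng, n_atoms=6, n_frames=4)
        frames = traj.frames + rng.normal(scale=0.3, size=traj.frames.shape)
        noisy = TrajectoryEnsemble(traj.topology, frames)
        rs = tr.rmsd_series(noisy, range(6), range(6))
        for k in range(4):
            sup = tr.kabsch_superpose(frames[0], frames[k])
            moved = sup.apply(frames[k])
            brute = math.sqrt(((moved - frames[0]) ** 2).sum(axis=1).mean())
            assert rs.values[k] == pytest.approx(brute, abs=1e-6)

    def test_static_trajectory_rmsf_zero(self, rng):
        traj = _static_traj(rng)
        assert np.allclose(tr.rmsf(traj, range(8)), 0.0, atol=1e-12)

    def test_single_frame_rmsf_is_an_error(self, rng):
        traj = _static_traj(rng, n_frames=1)
        with pytest.raises(ValueError):
            tr.rmsf(traj, range(8))

    def test_planted_oscillation_amplitude_is_recovered(self):
        amp = 0.8
        traj = syn.make_oscillation_trajectory(n_atoms=12, n_frames=60, amplitude=amp,
                                               moving_atom=3)
        rigid = [i for i in range(12) if i != 3]
        fl = tr.rmsf(traj, range(12), fit_selection=rigid)
        assert fl[3] == pytest.approx(amp, abs=1e-9)
        assert np.delete(fl, 3).max() < 1e-9
        # fitting on all atoms absorbs part of the motion but stays close
        fl_all = tr.rmsf(traj, range(12))
        assert 0.6 * amp < fl_all[3] <= amp

    def test_rmsf_invariant_under_global_rigid_motion(self):
        a = tr.rmsf(syn.make_oscillation_trajectory(seed=3, rigid_motion=False), range(10))
        b = tr.rmsf(syn.make_oscillation_trajectory(seed=3, rigid_motion=True), range(10))
        assert np.allclose(a, b, atol=1e-9)


# --------------------------------------------------------------------------
# contact detectors
# --------------------------------------------------------------------------

def _hbond_frame(d_a=3.4, angle_deg=150.0):
    """Serine donor OG-HG against a one-atom ligand acceptor at given geometry."""
    d = np.zeros(3)
    h = np.array([1.0, 0.0, 0.0])
    theta = math.radians(180.0 - angle_deg)
    direction = np.array([math.cos(theta), math.sin(theta), 0.0])
    # choose the acceptor so |D-A| = d_a along a ray giving the requested D-H...A angle
    from numpy.polynomial import polynomial as P
    # |h + t*direction| = d_a  ->  t^2 + 2 t (h . direction) + 1 - d_a^2 = 0
    b = 2 * float(h @ direction)
    t = (-b + math.sqrt(b * b - 4 * (1 - d_a ** 2))) / 2
    a = h + t * direction
    atoms = [
        AtomRecord(serial=1, name="OG", element="O", residue_name="SER", residue_seq=10,
                   chain_id="A", coords=d),
        AtomRecord(serial=2, name="HG", element="H", residue_name="SER", residue_seq=10,
                   chain_id="A", coords=h),
        AtomRecord(serial=3, name="O1", element="O", residue_name="LIG", residue_seq=1,
                   chain_id="Z", coords=a),
    ]
    topo = MolecularStructure(atoms)
    protein = tr.InteractionGroups(donors=[(0, 1)], acceptors=[0])
    ligand = tr.InteractionGroups(acceptors=[2])
    return topo, protein, ligand


@pytest.mark.parametrize("d_a, angle, expected", [
    (3.4, 150.0, 1),   # inside both criteria
    (3.6, 179.0, 0),   # distance fails
    (3.4, 110.0, 0),   # angle fails
    (3.49, 120.5, 1),  # just inside both
])
def test_hbond_criteria(d_a, angle, expected):
    topo, protein, ligand = _hbond_frame(d_a, angle)
    events = tr.detect_hbonds(topo.coords, topo, protein, ligand)
    assert len(events) == expected
    if expected:
        ev = events[0]
        assert ev.role == "donor"
        assert ev.distance == pytest.approx(d_a, abs=1e-6)
        assert ev.angle == pytest.approx(angle, abs=1e-4)


def test_hbond_detector_equals_bruteforce_on_random_triples(rng):
    hits_pkg, hits_oracle = [], []
    for i in range(1000):
        d = rng.uniform(-2, 2, 3)
        h = d + rng.normal(size=3) * 0.4
        a = rng.uniform(-4, 4, 3)
        atoms = [
            AtomRecord(serial=1, name="N", element="N", residue_name="GLY", residue_seq=1,
                       chain_id="A", coords=d),
            AtomRecord(serial=2, name="H", element="H", residue_name="GLY", residue_seq=1,
                       chain_id="A", coords=h),
            AtomRecord(serial=3, name="O1", element="O", residue_name="LIG", residue_seq=1,
                       chain_id="Z", coords=a),
        ]
        topo = MolecularStructure(atoms)
        protein = tr.InteractionGroups(donors=[(0, 1)])
        ligand = tr.InteractionGroups(acceptors=[2])
        got = len(tr.detect_hbonds(topo.coords, topo, protein, ligand)) == 1
        # independent restatement of the two inequalities
        r = np.linalg.norm(d - a)
        v1, v2 = d - h, a - h
        cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        want = bool(r < 3.5 and math.degrees(math.acos(np.clip(cosang, -1, 1))) > 120.0)
        hits_pkg.append(got)
        hits_oracle.append(want)
    assert hits_pkg == hits_oracle
    assert 0 < sum(hits_oracle) < 1000  # the sample exercises both outcomes


def _two_group_frame(distance, p_cls, l_cls):
    atoms = [
        AtomRecord(serial=1, name="NH1", element="N", residue_name="ARG", residue_seq=5,
                   chain_id="A", coords=np.zeros(3)),
        AtomRecord(serial=2, name="O1", element="O", residue_name="LIG", residue_seq=1,
                   chain_id="Z", coords=np.array([distance, 0.0, 0.0])),
    ]
    topo = MolecularStructure(atoms)
    protein = tr.InteractionGroups()
    ligand = tr.InteractionGroups()
    getattr(protein, p_cls).append(tr.ChargedGroup(1, (0,), "Arg5-Side")
                                   if p_cls == "charged" else ((0,), "Arg5-Side"))
    getattr(ligand, l_cls).append(tr.ChargedGroup(-1, (1,), "LIG-grp1")
                                  if l_cls == "charged" else ((1,), "LIG-grp1"))
    return topo, protein, ligand


def test_salt_bridge_cutoff_application():
    topo, p, l = _two_group_frame(3.5, "charged", "charged")
    assert len(tr.detect_salt_bridges(topo.coords, topo, p, l)) == 1
    topo, p, l = _two_group_frame(4.2, "charged", "charged")
    assert tr.detect_salt_bridges(topo.coords, topo, p, l) == []


def test_same_sign_groups_never_form_a_salt_bridge():
    topo, p, l = _two_group_frame(3.0, "charged", "charged")
    l.charged[0] = tr.ChargedGroup(1, (1,), "LIG-grp1")
    assert tr.detect_salt_bridges(topo.coords, topo, p, l) == []


def test_aromatic_centroid_cutoff():
    topo, p, l = _two_group_frame(6.0, "rings", "rings")
    assert tr.detect_aromatic(topo.coords, topo, p, l) == []
    topo, p, l = _two_group_frame(5.2, "rings", "rings")
    assert len(tr.detect_aromatic(topo.coords, topo, p, l)) == 1


def test_cutoff_detectors_equal_bruteforce_on_random_distances(rng):
    for cls, detector, cutoff in [
        ("charged", tr.detect_salt_bridges, tr.SALT_BRIDGE_CUTOFF),
        ("hydrophobic", tr.detect_hydrophobic, tr.HYDROPHOBIC_CUTOFF),
        ("rings", tr.detect_aromatic, tr.AROMATIC_CENTROID_CUTOFF),
    ]:
        dists = rng.uniform(1.0, 8.0, size=1000)
        got = []
        for dist in dists:
            topo, p, l = _two_group_frame(float(dist), cls, cls)
            got.append(len(detector(topo.coords, topo, p, l)) == 1)
        assert got == [bool(d <= cutoff) for d in dists]


def test_one_constructed_pair_per_class_gives_three_events():
    traj, schedule, lgroups = syn.make_probe_complex(
        [{"contact_class": "salt_bridge", "residue": ("R", 277), "p": 1.0},
         {"contact_class": "hydrophobic", "residue": ("R", 279), "p": 1.0},
         {"contact_class": "aromatic", "residue": ("R", 229), "p": 1.0}],
        n_frames=1, jitter_sigma=0.05)
    pidx = [i for i, a in enumerate(traj.topology.atoms) if a.residue_name != "LIG"]
    pgroups = tr.groups_from_structure(traj.topology, pidx)
    events = tr.detect_contacts(traj, pgroups, lgroups,
                                classes=("salt_bridge", "hydrophobic", "aromatic"))
    assert sorted(e.contact_class for e in events) == ["aromatic", "hydrophobic", "salt_bridge"]
    assert {e.residue[1] for e in events} == {277, 279, 229}


def test_detectors_invariant_under_global_rigid_motion(rng):
    traj, schedule, lgroups = syn.make_probe_complex(
        [{"contact_class": "hbond", "residue": ("R", 278), "p": 1.0}],
        n_frames=1, jitter_sigma=0.05)
    topo = traj.topology
    pidx = [i for i, a in enumerate(topo.atoms) if a.residue_name != "LIG"]
    pgroups = tr.groups_from_structure(topo, pidx)
    coords = traj.frames[0]
    base = tr.detect_hbonds(coords, topo, pgroups, lgroups)
    R = syn._random_rotation(rng)
    moved = coords @ R.T + rng.uniform(-20, 20, 3)
    after = tr.detect_hbonds(moved, topo, pgroups, lgroups)
    assert len(base) == len(after) == 1
    assert base[0].distance == pytest.approx(after[0].distance, abs=1e-9)
    assert base[0].angle == pytest.approx(after[0].angle, abs=1e-7)


# --------------------------------------------------------------------------
# occupancy
# --------------------------------------------------------------------------

def test_pair_rows_sum_to_quoted_residue_occupancies():
    # the two recomputable worked examples of the published occupancy table
    table = tr.OccupancyTable.from_pair_rows([
        ("Glu278", "LIG299-Main", "Glu278-Side", "hbond", 392.92),
        ("Glu278", "LIG299-Side", "Glu278-Side", "hbond", 99.22),
    ], n_frames=5000)
    assert table.residue_level().occupancy_of("Glu278") == pytest.approx(492.14)
    table = tr.OccupancyTable.from_pair_rows([
        ("Arg179", "Arg179-Side", "LIG185-Side", "hbond", 171.67),
        ("Arg179", "Arg179-Side", "LIG185-Main", "hbond", 54.84),
    ], n_frames=5000)
    assert table.residue_level().occupancy_of("Arg179") == pytest.approx(226.51)


def test_simple_fraction_occupancy(rng):
    traj, schedule, lgroups = syn.make_probe_complex(
        [{"contact_class": "hbond", "residue": ("R", 278), "p": 0.4}], n_frames=10)
    pidx = [i for i, a in enumerate(traj.topology.atoms) if a.residue_name != "LIG"]
    pgroups = tr.groups_from_structure(traj.topology, pidx)
    events = tr.detect_contacts(traj, pgroups, lgroups, classes=("hbond",))
    occ = tr.occupancy(events, traj.n_frames)
    assert occ.occupancy_of("Glu278", "hbond") == pytest.approx(40.00)


def test_residue_level_equals_sum_of_pair_rows():
    traj, schedule, lgroups = syn.make_probe_complex(
        [{"contact_class": "hbond", "residue": ("R", 278), "p": 0.6},
         {"contact_class": "hbond", "residue": ("R", 278), "p": 1.0, "multiplicity": 2}],
        n_frames=10)
    pidx = [i for i, a in enumerate(traj.topology.atoms) if a.residue_name != "LIG"]
    pgroups = tr.groups_from_structure(traj.topology, pidx)
    occ = tr.occupancy(tr.detect_contacts(traj, pgroups, lgroups, classes=("hbond",)),
                       traj.n_frames)
    pair_sum = occ.table[occ.table.residue == "Glu278"].occupancy_percent.sum()
    res = occ.residue_level().occupancy_of("Glu278", "hbond")
    assert res == pytest.approx(pair_sum)
    assert res == pytest.approx(100 * (0.6 + 2.0))  # additivity of the planted schedules


def test_zero_frames_is_an_error():
    with pytest.raises(ValueError):
        tr.occupancy([], 0)


def test_strong_hbond_threshold_is_strict():
    table = tr.OccupancyTable.from_pair_rows([
        ("Phe229", "LIG-Side", "Phe229-Main", "hbond", 92.34),
        ("Glu277", "LIG-Side", "Glu277-Side", "hbond", 75.00),
        ("Tyr230", "LIG-Side", "Tyr230-Side", "hbond", 20.95),
    ], n_frames=5000)
    strong = tr.strong_hbond_flag(table)
    assert list(strong.residue) == ["Phe229"]
    none = tr.strong_hbond_flag(tr.OccupancyTable.from_pair_rows(
        [("Tyr230", "a", "b", "hbond", 40.0)], n_frames=10))
    assert len(none) == 0
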