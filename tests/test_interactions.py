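import numpy as np
import pytest

from helixrope import (Atom, ContactCriteria, CrystalStructure, HBondCriteria,
                       R_GAS, UnitCell, contact_map, detect_hbonds, detect_pipi,
                       classify_pipi, free_energy_landscape, gen_jitter_trajectory,
                       per_unit, rmsd_series)
from helixrope.groups import AromaticRing

from conftest import random_molecular_frame


def make_dha(a_pos, h_pos=(1.0, 0.0, 0.0), cell=20.0):
    """Two molecules: donor N-H in one, acceptor O in the other."""
    atoms = [Atom(0, "N", "N", "MOL", 0, (0.0, 0.0, 0.0)),
             Atom(1, "H", "H", "MOL", 0, h_pos),
             Atom(2, "O", "O", "MOL", 1, a_pos)]
    return CrystalStructure(atoms, UnitCell(cell, cell, cell))


class TestDetectHbonds:
    def test_collinear_bond_detected(self):
        bonds = detect_hbonds(make_dha((2.9, 0, 0)))
        assert len(bonds) == 1
        assert bonds[0].da_distance == pytest.approx(2.9)
        assert bonds[0].dha_angle == pytest.approx(180.0)

    def test_distance_beyond_cutoff_rejected(self):
        assert detect_hbonds(make_dha((3.6, 0, 0))) == []

    def test_angle_below_150_rejected(self):
        # acceptor placed so that D···A = 2.9 Å while the D-H···A angle
        # at the hydrogen is exactly 140 degrees (law of cosines for the
        # H-A arm length)
        dha = np.radians(140.0)
        t = (2 * np.cos(dha) + np.sqrt(4 * np.cos(dha) ** 2
                                       - 4 * (1 - 2.9**2))) / 2
        a = np.array([1.0, 0.0, 0.0]) + t * np.array(
            [np.cos(np.pi - dha), np.sin(np.pi - dha), 0.0])
        assert np.linalg.norm(a) == pytest.approx(2.9)
        assert detect_hbonds(make_dha(tuple(a))) == []

    def test_no_polar_atoms_is_empty_not_error(self):
        s = CrystalStructure([Atom(0, "C", "C", "MOL", 0, (0, 0, 0)),
                              Atom(1, "C", "C", "MOL", 1, (2, 0, 0))],
                             UnitCell(10, 10, 10))
        assert detect_hbonds(s) == []

    def test_heavy_atom_fallback_for_waters(self):
        atoms = [Atom(0, "O", "OW", "HOH", 0, (0.0, 0.0, 0.0)),
                 Atom(1, "O", "O", "MOL", 1, (2.96, 0.0, 0.0))]
        s = CrystalStructure(atoms, UnitCell(20, 20, 20))
        bonds = detect_hbonds(s, HBondCriteria(heavy_atom_fallback=True))
        assert any(b.fallback and b.da_distance == pytest.approx(2.96)
                   for b in bonds)
        strict = detect_hbonds(s, HBondCriteria(heavy_atom_fallback=False))
        assert strict == []


def brute_force_hbonds(structure, criteria, n_images=2):
    """All-pairs, all-images H-bond oracle (independent of the package's
    neighbour search)."""
    from helixrope.structures import COVALENT_RADII

    cell = structure.cell
    vecs = cell.lattice_vectors
    atoms = structure.atoms
    # donor hydrogens by the same covalent rule, reimplemented directly
    hyd = {}
    for d in atoms:
        if d.element not in ("N", "O"):
            continue
        for h in atoms:
            if h.element != "H" or h.molecule_id != d.molecule_id:
                continue
            cut = 1.2 * (COVALENT_RADII[d.element.upper()] + 0.31)
            if np.linalg.norm(h.position - d.position) < cut:
                hyd.setdefault(d.atom_id, []).append(h)
    found = set()
    rng = range(-n_images, n_images + 1)
    shifts = np.array([i * vecs[0] + j * vecs[1] + k * vecs[2]
                       for i in rng for j in rng for k in rng])
    zero_shift = int(np.flatnonzero(np.all(shifts == 0, axis=1))[0])
    acceptors = [a for a in atoms if a.element in ("N", "O")]
    apos = np.array([a.position for a in acceptors])
    for d in atoms:
        if d.atom_id not in hyd:
            continue
        # distance to every acceptor image: (n_acc, n_images)
        imgs = apos[:, None, :] + shifts[None, :, :]
        dist = np.linalg.norm(imgs - d.position, axis=2)
        best = np.argmin(dist, axis=1)
        for ai, a in enumerate(acceptors):
            if a.atom_id == d.atom_id:
                continue
            bd = dist[ai, best[ai]]
            if bd > criteria.donor_acceptor_max:
                continue
            if a.molecule_id == d.molecule_id and best[ai] == zero_shift:
                continue
            img = imgs[ai, best[ai]]
            angles = []
            for h in hyd[d.atom_id]:
                v1 = d.position - h.position
                v2 = img - h.position
                c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angles.append(np.degrees(np.arccos(np.clip(c, -1, 1))))
            if max(angles) >= criteria.dha_angle_min:
                found.add((d.atom_id, a.atom_id))
    return found


class TestHbondOracle:
    def test_matches_brute_force_on_random_periodic_frames(self):
        """50 random 200-atom periodic frames: exact set equality with
        the all-pairs all-images oracle."""
        rng = np.random.default_rng(11)
        criteria = HBondCriteria(heavy_atom_fallback=False)
        total = 0
        for _ in range(50):
            frame = random_molecular_frame(rng, n_molecules=40)
            got = {(b.donor_atom, b.acceptor_atom)
                   for b in detect_hbonds(frame, criteria)}
            expected = brute_force_hbonds(frame, criteria)
            assert got == expected
            total += len(got)
        assert total > 50   # the comparison must not be vacuous


def brute_force_contacts(structure, criteria, n_images=2):
    cell = structure.cell
    vecs = cell.lattice_vectors
    heavy = [a for a in structure.atoms if not a.is_hydrogen]
    rng = range(-n_images, n_images + 1)
    shifts = np.array([i * vecs[0] + j * vecs[1] + k * vecs[2]
                       for i in rng for j in rng for k in rng])
    hpos = np.array([a.position for a in heavy])
    found = set()
    for x, a in enumerate(heavy):
        rest = hpos[x + 1:]
        dist = np.linalg.norm(rest[:, None, :] + shifts[None, :, :]
                              - a.position, axis=2).min(axis=1)
        for y, b in enumerate(heavy[x + 1:]):
            if a.molecule_id == b.molecule_id:
                continue
            cut = (criteria.cc_cutoff if a.element == b.element == "C"
                   else criteria.other_cutoff)
            if dist[y] <= cut:
                found.add((a.atom_id, b.atom_id))
    return found


class TestContacts:
    def test_cc_pair_at_5p3_counts(self):
        atoms = [Atom(0, "C", "C1", "MOL", 0, (0, 0, 0)),
                 Atom(1, "C", "C2", "MOL", 1, (5.3, 0, 0))]
        s = CrystalStructure(atoms, UnitCell(30, 30, 30))
        cmap = contact_map([s], {0: "A", 1: "B"})
        assert cmap.entry("A", "B") == (1.0, 1.0)

    def test_cn_pair_at_5p0_does_not_count(self):
        atoms = [Atom(0, "C", "C1", "MOL", 0, (0, 0, 0)),
                 Atom(1, "N", "N1", "MOL", 1, (5.0, 0, 0))]
        s = CrystalStructure(atoms, UnitCell(30, 30, 30))
        cmap = contact_map([s], {0: "A", 1: "B"})
        assert cmap.entry("A", "B") == (0.0, 0.0)

    def test_static_frames_probability_binary(self, helix_structure):
        structure, _ = helix_structure
        from helixrope import assign_groups
        groups = assign_groups(structure)
        traj = gen_jitter_trajectory(structure, 0.0, 3)
        cmap = contact_map(traj, groups)
        assert set(np.unique(cmap.probability)) <= {0.0, 1.0}
        single = contact_map([structure], groups)
        assert np.allclose(cmap.mean_counts, single.mean_counts)

    def test_matrix_symmetric(self, helix_structure):
        structure, _ = helix_structure
        from helixrope import assign_groups
        cmap = contact_map([structure], assign_groups(structure))
        assert np.allclose(cmap.mean_counts, cmap.mean_counts.T)
        assert np.allclose(cmap.probability, cmap.probability.T)

    def test_matches_brute_force_on_random_frames(self):
        rng = np.random.default_rng(13)
        criteria = ContactCriteria()
        total = 0
        for _ in range(50):
            frame = random_molecular_frame(rng, n_molecules=40)
            groups = {a.atom_id: f"g{a.atom_id}" for a in frame.atoms}
            cmap = contact_map([frame], groups, criteria)
            got = set()
            for i, g1 in enumerate(cmap.labels):
                for j, g2 in enumerate(cmap.labels):
                    if cmap.mean_counts[i, j] > 0 and g1 < g2:
                        a1 = int(g1[1:])
                        a2 = int(g2[1:])
                        got.add((min(a1, a2), max(a1, a2)))
            expected = brute_force_contacts(frame, criteria)
            assert got == expected
            total += len(got)
        assert total > 50


def ring_at(idx, centroid, normal, mol):
    normal = np.asarray(normal, float)
    return AromaticRing([idx], np.asarray(centroid, float),
                        normal / np.linalg.norm(normal), mol, "generic", 0.0)


class TestPiPi:
    def test_cofacial_parallel_rings(self):
        rings = [ring_at(0, (0, 0, 0), (0, 0, 1), 0),
                 ring_at(1, (0, 0, 3.5), (0, 0, 1), 1)]
        pairs = detect_pipi(rings, UnitCell(30, 30, 30))
        assert len(pairs) == 1
        assert pairs[0].centroid_distance == pytest.approx(3.5)
        assert pairs[0].interplanar_angle == pytest.approx(0.0)

    def test_t_shaped_perpendicular(self):
        rings = [ring_at(0, (0, 0, 0), (0, 0, 1), 0),
                 ring_at(1, (5.0, 0, 0), (1, 0, 0), 1)]
        pairs = detect_pipi(rings, UnitCell(30, 30, 30))
        assert len(pairs) == 1
        assert pairs[0].interplanar_angle == pytest.approx(90.0)

    def test_beyond_cutoff_none(self):
        rings = [ring_at(0, (0, 0, 0), (0, 0, 1), 0),
                 ring_at(1, (7.0, 0, 0), (0, 0, 1), 1)]
        assert detect_pipi(rings, UnitCell(30, 30, 30)) == []

    def test_same_molecule_excluded(self):
        rings = [ring_at(0, (0, 0, 0), (0, 0, 1), 0),
                 ring_at(1, (4.0, 0, 0), (0, 0, 1), 0)]
        assert detect_pipi(rings, UnitCell(30, 30, 30)) == []

    @pytest.mark.parametrize("dist,same,expected", [
        (5.0, False, "I"), (7.5, False, "II"), (8.5, True, "III"),
        (5.0, True, "unclassified")])
    def test_pattern_bands(self, dist, same, expected):
        rings = [ring_at(0, (0, 0, 0), (0, 0, 1), 0),
                 ring_at(1, (dist, 0, 0), (0, 0, 1), 1)]
        pairs = detect_pipi(rings, UnitCell(40, 40, 40), cutoff=10.0)
        membership = {0: 0, 1: 0 if same else 1}
        out = classify_pipi(pairs, rings, membership)
        assert out[0].pattern == expected

    def test_missing_membership_errors(self):
        rings = [ring_at(0, (0, 0, 0), (0, 0, 1), 0),
                 ring_at(1, (5.0, 0, 0), (0, 0, 1), 1)]
        pairs = detect_pipi(rings, UnitCell(30, 30, 30))
        with pytest.raises(ValueError):
            classify_pipi(pairs, rings, {0: 0})

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(4)
        rot = Rotation.random(rng=rng)
        shift = rng.uniform(-5, 5, 3)
        rings = [ring_at(0, (1, 2, 3), (0, 0, 1), 0),
                 ring_at(1, (4, 2, 0), (0, 1, 1), 1)]
        moved = [ring_at(r.member_atom_ids[0], rot.apply(r.centroid) + shift,
                         rot.apply(r.normal), r.molecule_id) for r in rings]
        p1 = detect_pipi(rings, UnitCell(60, 60, 60))
        p2 = detect_pipi(moved, UnitCell(60, 60, 60))
        assert p1[0].centroid_distance == pytest.approx(p2[0].centroid_distance)
        assert p1[0].interplanar_angle == pytest.approx(p2[0].interplanar_angle)


class TestPerUnit:
    def test_normalisation_and_linearity(self):
        assert per_unit(432, 216) == pytest.approx(2.0)
        assert per_unit(0, 216) == 0.0
        assert per_unit(2 * 37.0, 9) == pytest.approx(2 * per_unit(37.0, 9))
        with pytest.raises(ValueError):
            per_unit(1, 0)


class TestFEL:
    def test_single_bin_has_zero_free_energy(self):
        fel = free_energy_landscape([(3.0, 10.0)] * 20, distance_bins=1,
                                    angle_bins=1, temperature=300.0)
        assert fel.free_energy[0, 0] == pytest.approx(0.0)

    def test_two_equal_bins_at_300K(self):
        obs = [(1.0, 10.0)] * 10 + [(3.0, 10.0)] * 10
        fel = free_energy_landscape(obs, distance_bins=2, angle_bins=1,
                                    temperature=300.0)
        # G = -RT ln(1/2), RT = 2.4943 kJ/mol
        assert R_GAS * 300.0 == pytest.approx(2.4943, abs=5e-4)
        assert fel.free_energy[0, 0] == pytest.approx(1.729, abs=1e-3)
        assert fel.free_energy[1, 0] == pytest.approx(1.729, abs=1e-3)

    def test_minimum_at_most_probable_bin(self):
        rng = np.random.default_rng(5)
        obs = np.column_stack([rng.normal(5, 1, 500), rng.uniform(0, 90, 500)])
        fel = free_energy_landscape(obs, distance_bins=10, angle_bins=6)
        i, j = np.unravel_index(np.nanargmin(fel.free_energy),
                                fel.free_energy.shape)
        assert fel.probability[i, j] == fel.probability.max()

    def test_boltzmann_inversion_is_exact(self):
        rng = np.random.default_rng(6)
        obs = np.column_stack([rng.normal(5, 1, 300), rng.uniform(0, 90, 300)])
        fel = free_energy_landscape(obs, temperature=300.0)
        P = np.exp(-np.nan_to_num(fel.free_energy, nan=np.inf)
                   / (fel.gas_constant * fel.temperature))
        assert np.nansum(P) == pytest.approx(1.0)
        mask = fel.probability > 0
        assert np.allclose(P[mask], fel.probability[mask])

    def test_empty_observations_error(self):
        with pytest.raises(ValueError):
            free_energy_landscape([])


class TestRMSD:
    def test_identical_frames_zero(self, helix_structure):
        structure, _ = helix_structure
        traj = gen_jitter_trajectory(structure, 0.0, 4)
        assert np.allclose(rmsd_series(traj), 0.0)

    def test_rigid_translation(self, helix_structure):
        structure, _ = helix_structure
        pos = structure.positions
        traj_pos = np.stack([pos, pos + [1.0, 0, 0]])
        from helixrope import Trajectory
        traj = Trajectory([0.0, 1.0], traj_pos, [structure.cell] * 2,
                          structure.atoms)
        assert rmsd_series(traj, superpose=False)[1] == pytest.approx(1.0)
        assert rmsd_series(traj, superpose=True)[1] == pytest.approx(0.0, abs=1e-9)

    def test_random_rotation_superposes_to_zero(self, helix_structure):
        from scipy.spatial.transform import Rotation
        structure, _ = helix_structure
        pos = structure.positions
        rot = Rotation.random(rng=np.random.default_rng(7))
        center = pos.mean(axis=0)
        rotated = rot.apply(pos - center) + center + [2.0, -1.0, 0.5]
        from helixrope import Trajectory
        traj = Trajectory([0.0, 1.0], np.stack([pos, rotated]),
                          [structure.cell] * 2, structure.atoms)
        assert rmsd_series(traj, superpose=True)[1] == pytest.approx(0.0, abs=1e-6)
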