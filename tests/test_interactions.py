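"""Contact / H-bond / pi detectors, salt bridges, contact tables, ligand axis."""

import numpy as np
import pytest

from carriermd import Frame, Selection, detect_contact, detect_hbond, detect_pi_stack
from carriermd import interactions as ia
from carriermd.errors import AnalysisError, EmptySelectionError
from carriermd.traj_core import Topology, min_image_distance


def make_topology(atoms):
    """atoms: list of (name, element, resid, resname)."""
    return Topology(
        atom_names=np.array([a[0] for a in atoms]),
        elements=np.array([a[1] for a in atoms]),
        residue_numbers=np.array([a[2] for a in atoms]),
        residue_names=np.array([a[3] for a in atoms]),
        segments=np.array(["X"] * len(atoms)))


def two_group_frame(coords, box=None):
    return Frame(coordinates=np.array(coords, dtype=float), box=box)


class TestDetectContact:
    @pytest.fixture()
    def pair_top(self):
        return make_topology([("C1", "C", 1, "LIG"), ("C2", "C", 2, "RES")])

    @pytest.mark.parametrize("distance,expected", [
        (2.5, True),
        (3.0, False),      # strict inequality at the threshold
        (2.999, True),
        (3.001, False),
    ])
    def test_threshold_is_strict(self, pair_top, distance, expected):
        frame = two_group_frame([[0, 0, 0], [distance, 0, 0]])
        a = pair_top.select("resid 1")
        b = pair_top.select("resid 2")
        assert detect_contact(pair_top, frame, a, b) is expected

    def test_empty_selection_names_group(self, pair_top):
        frame = two_group_frame([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(EmptySelectionError, match="group_b"):
            detect_contact(pair_top, frame, pair_top.select("resid 1"),
                           pair_top.select("resid 99"))

    def test_matches_all_pairs_oracle(self, rng):
        box = np.array([30.0, 30.0, 30.0])
        atoms = [("C", "C", 1, "LIG")] * 50 + [("C", "C", 2, "RES")] * 50
        top = make_topology(atoms)
        a, b = top.select("resid 1"), top.select("resid 2")
        for _ in range(40):
            coords = rng.uniform(0, 30, (100, 3))
            frame = Frame(coordinates=coords, box=box)
            truth = min(
                min_image_distance(coords[i], coords[j], box)
                for i in range(50) for j in range(50, 100)) < 3.0
            assert detect_contact(top, frame, a, b) == truth


class TestDetectHbond:
    def test_collinear_geometry(self):
        # D at origin, H at 1 A, A at 2.9 A: angle 180 deg
        frame = two_group_frame([[0, 0, 0], [1, 0, 0], [2.9, 0, 0]])
        assert detect_hbond(frame, 0, 1, 2) is True

    def test_distance_boundary_exclusive(self):
        frame = two_group_frame([[0, 0, 0], [1, 0, 0], [3.3, 0, 0]])
        assert detect_hbond(frame, 0, 1, 2) is False

    @pytest.mark.parametrize("angle_deg,expected", [(150.0, True),
                                                    (139.0, False),
                                                    (140.0, False)])
    def test_angle_criterion(self, angle_deg, expected):
        # H at origin; D and A both 1.5 A away at the given mutual angle
        theta = np.radians(angle_deg)
        d = np.array([1.5, 0.0, 0.0])
        a = 1.5 * np.array([np.cos(theta), np.sin(theta), 0.0])
        frame = two_group_frame([d, [0, 0, 0], a])
        assert detect_hbond(frame, 0, 1, 2) is expected

    def test_matches_geometric_oracle(self, rng):
        for _ in range(200):
            coords = rng.uniform(0, 6, (3, 3))
            frame = two_group_frame(coords)
            d_da = np.linalg.norm(coords[0] - coords[2])
            v1 = coords[0] - coords[1]
            v2 = coords[2] - coords[1]
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            truth = d_da < 3.3 and np.degrees(np.arccos(
                np.clip(cosang, -1, 1))) > 140.0
            assert detect_hbond(frame, 0, 1, 2) == truth


def hexagon(radius=1.39, center=(0.0, 0.0, 0.0)):
    ang = 2 * np.pi * np.arange(6) / 6
    ring = np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            np.zeros(6)])
    return ring + np.asarray(center)


class TestDetectPiStack:
    def ring_system(self, protein_ring_coords):
        atoms = [(n, "C", 88, "PHE") for n in
                 ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")]
        atoms += [(n, n[0], 1, "GDP") for n in
                  ("N1", "C2", "N3", "C4", "C5", "C6")]
        top = make_topology(atoms)
        coords = np.vstack([protein_ring_coords, hexagon()])
        frame = Frame(coordinates=coords)
        return top, frame, top.select("resid 88"), top.select("resid 1")

    def test_parallel_stack_detected(self):
        top, frame, prot, lig = self.ring_system(hexagon(center=(0, 0, 3.4)))
        assert detect_pi_stack(top, frame, prot, lig) is True

    def test_single_close_atom_insufficient(self):
        ring = hexagon(center=(7.0, 0, 0))
        ring[0] = [1.39 + 2.0, 0, 0]   # one atom within 3.8 A of a ring atom
        top, frame, prot, lig = self.ring_system(ring)
        assert detect_pi_stack(top, frame, prot, lig) is False

    def test_non_aromatic_residue_rejected(self):
        atoms = [("CB", "C", 12, "ALA")] + \
            [(n, n[0], 1, "GDP") for n in ("N1", "C2", "N3")]
        top = make_topology(atoms)
        frame = Frame(coordinates=np.zeros((4, 3)))
        with pytest.raises(AnalysisError, match="12"):
            detect_pi_stack(top, frame, top.select("resid 12"),
                            top.select("resid 1"))

    def test_matches_counting_oracle(self, rng):
        for _ in range(100):
            prot_ring = rng.uniform(0, 8, (6, 3))
            top, frame, prot, lig = self.ring_system(prot_ring)
            lig_coords = frame.coordinates[6:]
            n_close = sum(
                1 for p in prot_ring
                if min(np.linalg.norm(p - q) for q in lig_coords) < 3.8)
            assert detect_pi_stack(top, frame, prot, lig) == (n_close >= 3)


class TestSaltBridge:
    def build(self, bonded_flags, times):
        """ARG NH1/HH11 vs GLU OE1; bonded frames put OE1 at 2.8 A."""
        atoms = [("NH1", "N", 92, "ARG"), ("HH11", "H", 92, "ARG"),
                 ("OE1", "O", 191, "GLU"), ("CD", "C", 191, "GLU")]
        top = make_topology(atoms)
        frames = []
        for bonded, t in zip(bonded_flags, times):
            d = 2.8 if bonded else 6.0
            coords = np.array([[0, 0, 0], [1, 0, 0], [d, 0, 0], [d + 1, 0, 0]],
                              dtype=float)
            frames.append(Frame(coordinates=coords, time=t))
        return top, frames

    def test_always_bonded_fraction_one(self):
        top, frames = self.build([True] * 10, np.arange(200, 210.0))
        series = ia.salt_bridge_bonded_fraction(top, frames, 92, 191)
        assert series.bonded_fraction == 1.0

    def test_planted_alternation_half(self):
        top, frames = self.build([True, False] * 10, np.arange(200, 220.0))
        series = ia.salt_bridge_bonded_fraction(top, frames, 92, 191)
        assert series.bonded_fraction == 0.5

    def test_window_excludes_early_frames(self):
        flags = [True] * 10 + [False] * 10
        top, frames = self.build(flags, np.arange(190, 210.0))
        series = ia.salt_bridge_bonded_fraction(top, frames, 92, 191)
        assert series.bonded_fraction == 0.0

    def test_window_excluding_everything_raises(self):
        top, frames = self.build([True] * 5, np.arange(0, 5.0))
        with pytest.raises(AnalysisError):
            ia.salt_bridge_bonded_fraction(top, frames, 92, 191)

    def test_residue_type_validation(self):
        top, frames = self.build([True], [200.0])
        with pytest.raises(AnalysisError):
            ia.salt_bridge_bonded_fraction(top, frames, 191, 92)


class TestContactTimeTable:
    def test_planted_fractions_and_sem(self):
        """Replicas with planted contact fractions 0.2/0.4/0.6 -> mean 0.4,
        SEM 0.2/sqrt(3)."""
        from carriermd import PocketSpec, generate_ligand_pocket

        replicas = []
        top = None
        for frac in (0.2, 0.4, 0.6):
            n = 20
            k = int(frac * n)
            spec = PocketSpec(residues={85: "GLN"},
                              schedule={85: ["contact"] * k + ["none"] * (n - k)},
                              n_frames=n, seed=1)
            res = generate_ligand_pocket(spec)
            top = res.topology
            replicas.append(res.frames)
        table = ia.contact_time_table(top, replicas, top.select("resname GDP"),
                                      [85])
        row = table.iloc[0]
        assert row["mean_total"] == pytest.approx(0.4)
        assert row["sem_total"] == pytest.approx(0.2 / np.sqrt(3))
        assert row["n_replicas"] == 3

    def test_hbond_component_equals_scripted_fraction(self, pocket_scheduled):
        res = pocket_scheduled
        top = res.topology
        table = ia.contact_time_table(top, [res.frames],
                                      top.select("resname GDP"),
                                      [92, 191, 281, 85, 88])
        by_resid = table.set_index("resid")
        assert by_resid.loc[92, "mean_hbond"] == pytest.approx(0.5)
        assert by_resid.loc[281, "mean_pi"] == pytest.approx(0.4)
        assert by_resid.loc[85, "mean_total"] == pytest.approx(0.2)
        assert by_resid.loc[85, "mean_hbond"] == 0.0
        assert by_resid.loc[88, "mean_total"] == 0.0
        # exclusive decomposition: components never exceed the total
        assert ((table["mean_hbond"] + table["mean_pi"])
                <= table["mean_total"] + 1e-12).all()

    def test_single_replica_sem_absent(self, pocket_scheduled):
        res = pocket_scheduled
        table = ia.contact_time_table(res.topology, [res.frames],
                                      res.topology.select("resname GDP"), [92])
        assert np.isnan(table.iloc[0]["sem_total"])

    def test_frame_order_permutation_invariant(self, pocket_scheduled, rng):
        res = pocket_scheduled
        top = res.topology
        lig = top.select("resname GDP")
        shuffled = list(res.frames)
        rng.shuffle(shuffled)
        t1 = ia.contact_time_table(top, [res.frames], lig, [92, 281])
        t2 = ia.contact_time_table(top, [shuffled], lig, [92, 281])
        assert np.allclose(t1["mean_total"], t2["mean_total"])
        assert np.allclose(t1["mean_hbond"], t2["mean_hbond"])

    def test_moiety_restriction(self, pocket_scheduled):
        """GLN contacts the ribose, so its base-only contact time is 0."""
        res = pocket_scheduled
        top = res.topology
        lig = top.select("resname GDP")
        base_only = ia.contact_time_table(top, [res.frames], lig, [85],
                                          moiety="base")
        assert base_only.iloc[0]["mean_total"] == 0.0


class TestProteinCenterAndLigandAxis:
    def axis_system(self):
        atoms = [("CA", "C", i, "ALA") for i in range(1, 19)]
        atoms += [("PA", "P", 99, "GDP"), ("N1", "N", 99, "GDP")]
        return make_topology(atoms)

    def test_center_is_ca_mean(self, rng):
        top = self.axis_system()
        coords = rng.uniform(0, 20, (20, 3))
        frame = Frame(coordinates=coords)
        center = ia.protein_center(top, frame, list(range(1, 19)))
        assert np.allclose(center, coords[:18].mean(axis=0))

    def test_missing_ca_raises(self):
        top = self.axis_system()
        frame = Frame(coordinates=np.zeros((20, 3)))
        with pytest.raises(AnalysisError, match="42"):
            ia.protein_center(top, frame, [1, 2, 42])

    @pytest.mark.parametrize("base_offset,expected_cos", [
        ((0, 0, 4.0), 1.0),       # phosphate->base along +z
        ((0, 0, -4.0), -1.0),
        ((4.0, 0, 0), 0.0),       # vector in the membrane plane
    ])
    def test_orientation_cosine(self, base_offset, expected_cos):
        top = self.axis_system()
        coords = np.zeros((20, 3))
        coords[18] = [5.0, 5.0, 2.0]                      # phosphate
        coords[19] = coords[18] + np.array(base_offset)   # base
        frame = Frame(coordinates=coords)
        geom = ia.ligand_axis_metrics(top, [frame], top.select("resid 99"),
                                      top.select("name PA"),
                                      top.select("name N1"),
                                      list(range(1, 19)))
        assert geom.orientation_cosine[0] == pytest.approx(expected_cos)

    def test_z_distance_and_rotation_invariance(self, rng):
        top = self.axis_system()
        coords = rng.uniform(0, 20, (20, 3))
        frame = Frame(coordinates=coords)
        sel = top.select("resid 99")
        geom = ia.ligand_axis_metrics(top, [frame], sel,
                                      top.select("name PA"),
                                      top.select("name N1"),
                                      list(range(1, 19)))
        com = ia.center_of_mass(top, frame, sel)
        pc = coords[:18].mean(axis=0)
        assert geom.z_distance[0] == pytest.approx(com[2] - pc[2])
        # rigid rotation about z leaves both observables unchanged
        theta = rng.uniform(0, 2 * np.pi)
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        rotated = Frame(coordinates=coords @ rot.T)
        geom_rot = ia.ligand_axis_metrics(top, [rotated], sel,
                                          top.select("name PA"),
                                          top.select("name N1"),
                                          list(range(1, 19)))
        assert geom_rot.z_distance[0] == pytest.approx(geom.z_distance[0])
        assert geom_rot.orientation_cosine[0] == pytest.approx(
            geom.orientation_cosine[0])
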