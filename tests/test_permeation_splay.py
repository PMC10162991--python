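"""Water permeation counting and helix splay profiles."""

from collections import Counter

import numpy as np
import pytest

from carriermd import (
    BundleSpec,
    MembraneSlab,
    count_permeation_events,
    generate_bundle_trajectory,
    helix_splay_profile,
    slab_from_phosphorus,
)
from carriermd.errors import AnalysisError, EmptySelectionError
from carriermd.permeation_splay import average_profiles
from carriermd.synthetic_data import WaterScript
from carriermd.traj_core import Frame, Topology


def splay_oracle(coords, helix_ca_ids, z0, half=6.0):
    """Independent direct evaluation of the in-plane radius of gyration."""
    centers = []
    for ids in helix_ca_ids:
        sub = [coords[i] for i in ids if abs(coords[i][2] - z0) <= half]
        if sub:
            centers.append(np.mean([p[:2] for p in sub], axis=0))
    if not centers:
        return None
    rbar = np.mean(centers, axis=0)
    return np.sqrt(sum(np.sum((c - rbar) ** 2) for c in centers) / len(centers))


class TestHelixSplay:
    def test_zero_splay_when_helices_coincide(self):
        spec = BundleSpec(placement=lambda i, z: (50.0, 50.0), n_frames=3)
        res = generate_bundle_trajectory(spec)
        prof = helix_splay_profile(res.topology, res.frames,
                                   res.truth.helix_ranges)
        assert np.nanmax(np.abs(prof.values)) < 1e-12

    @pytest.mark.parametrize("radius", [5.0, 20.0, 35.0])
    def test_symmetric_circle_gives_radius(self, radius):
        res = generate_bundle_trajectory(BundleSpec(radius=radius, n_frames=2))
        prof = helix_splay_profile(res.topology, res.frames,
                                   res.truth.helix_ranges)
        covered = ~np.isnan(prof.values)
        assert covered.any()
        assert np.max(np.abs(prof.values[covered] - radius)) < 1e-9

    def test_in_plane_rotation_and_translation_invariance(self, bundle, rng):
        frame = bundle.frames[0]
        prof = helix_splay_profile(bundle.topology, frame,
                                   bundle.truth.helix_ranges)
        theta = rng.uniform(0, 2 * np.pi)
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        shift = np.array([rng.uniform(-30, 30), rng.uniform(-30, 30), 0.0])
        moved = Frame(coordinates=frame.coordinates @ rot.T + shift,
                      box=frame.box, time=frame.time)
        prof2 = helix_splay_profile(bundle.topology, moved,
                                    bundle.truth.helix_ranges)
        assert np.nanmax(np.abs(prof.values - prof2.values)) < 1e-9

    def test_in_plane_scaling_scales_profile(self, bundle):
        frame = bundle.frames[0]
        k = 1.7
        scaled_coords = frame.coordinates.copy()
        scaled_coords[:, :2] *= k
        scaled = Frame(coordinates=scaled_coords, box=frame.box)
        prof = helix_splay_profile(bundle.topology, frame,
                                   bundle.truth.helix_ranges)
        prof_k = helix_splay_profile(bundle.topology, scaled,
                                     bundle.truth.helix_ranges)
        assert np.nanmax(np.abs(prof_k.values - k * prof.values)) < 1e-9

    def test_random_clouds_match_formula_oracle(self, rng):
        n_helices, per_helix = 4, 12
        atoms = n_helices * per_helix
        top = Topology(
            atom_names=np.array(["CA"] * atoms),
            elements=np.array(["C"] * atoms),
            residue_numbers=np.arange(1, atoms + 1),
            residue_names=np.array(["ALA"] * atoms),
            segments=np.array(["PROT"] * atoms))
        coords = rng.uniform(0, 30, (atoms, 3))
        frame = Frame(coordinates=coords)
        ranges = [(i * per_helix + 1, (i + 1) * per_helix)
                  for i in range(n_helices)]
        ca_ids = [list(range(i * per_helix, (i + 1) * per_helix))
                  for i in range(n_helices)]
        prof = helix_splay_profile(top, frame, ranges)
        for z0, value in zip(prof.z_grid, prof.values):
            expected = splay_oracle(coords, ca_ids, z0)
            if expected is None:
                assert np.isnan(value)
            else:
                assert value == pytest.approx(expected, abs=1e-9)

    def test_replica_average(self, bundle):
        p1 = helix_splay_profile(bundle.topology, bundle.frames[0],
                                 bundle.truth.helix_ranges)
        p2 = helix_splay_profile(bundle.topology, bundle.frames[1],
                                 bundle.truth.helix_ranges)
        avg = average_profiles([p1, p2])
        assert np.allclose(avg.values, (p1.values + p2.values) / 2,
                           equal_nan=True)

    def test_requires_two_helices(self, bundle):
        with pytest.raises(AnalysisError):
            helix_splay_profile(bundle.topology, bundle.frames[0],
                                bundle.truth.helix_ranges[:1])


class TestPermeation:
    def selections(self, res):
        top = res.topology
        return (top.select("resname TIP3 and name OH2"),
                top.select("segid PROT"))

    def test_planted_events_recovered_exactly(self, bundle):
        water, protein = self.selections(bundle)
        slab = slab_from_phosphorus(bundle.topology, bundle.frames[0])
        events = count_permeation_events(bundle.topology, bundle.frames,
                                         water, protein, slab)
        got = sorted((e.molecule_id, e.direction) for e in events)
        expected = sorted((t["molecule_id"], t["direction"])
                          for t in bundle.truth.countable_events)
        assert got == expected

    def test_event_frames_ordered(self, bundle):
        water, protein = self.selections(bundle)
        slab = slab_from_phosphorus(bundle.topology, bundle.frames[0])
        for e in count_permeation_events(bundle.topology, bundle.frames,
                                         water, protein, slab):
            assert e.entry_frame < e.exit_frame

    def test_far_crossing_not_counted(self):
        spec = BundleSpec(waters=[
            WaterScript("far_cross", (95.0, 95.0), 25.0, 65.0, 2, 50)],
            n_frames=55)
        res = generate_bundle_trajectory(spec)
        water, protein = self.selections(res)
        slab = MembraneSlab(*res.truth.membrane_z)
        assert count_permeation_events(res.topology, res.frames, water,
                                       protein, slab) == []

    def test_pbc_wrapping_water_not_counted(self):
        spec = BundleSpec(waters=[WaterScript("pbc_wrap", (65.0, 50.0))],
                          n_frames=40)
        res = generate_bundle_trajectory(spec)
        water, protein = self.selections(res)
        slab = MembraneSlab(*res.truth.membrane_z)
        assert count_permeation_events(res.topology, res.frames, water,
                                       protein, slab) == []

    def test_mid_crossing_teleport_resets_state(self):
        """A z-jump > Lz/2 during a crossing voids the whole crossing."""
        top = Topology(atom_names=np.array(["CA", "OH2"]),
                       elements=np.array(["C", "O"]),
                       residue_numbers=np.array([1, 2]),
                       residue_names=np.array(["ALA", "TIP3"]),
                       segments=np.array(["PROT", "WAT"]))
        slab = MembraneSlab(20.0, 50.0)
        box = np.array([90.0, 90.0, 90.0])
        # enters R1 from below, reaches R2, teleports to above the slab
        z_path = [15.0, 25.0, 35.0, 85.0, 88.0]
        frames = [Frame(coordinates=np.array([[0.0, 0.0, 35.0],
                                              [0.0, 1.0, z]]),
                        box=box, time=float(t))
                  for t, z in enumerate(z_path)]
        water = top.select("name OH2")
        protein = top.select("name CA")
        assert count_permeation_events(top, frames, water, protein, slab) == []

    def test_time_reversal_swaps_direction_counts(self, bundle):
        water, protein = self.selections(bundle)
        slab = slab_from_phosphorus(bundle.topology, bundle.frames[0])
        fwd = Counter(e.direction for e in count_permeation_events(
            bundle.topology, bundle.frames, water, protein, slab))
        rev = Counter(e.direction for e in count_permeation_events(
            bundle.topology, list(reversed(bundle.frames)), water, protein,
            slab))
        assert fwd["+z"] == rev["-z"] and fwd["-z"] == rev["+z"]

    def test_cutoff_monotonicity(self, bundle):
        water, protein = self.selections(bundle)
        slab = slab_from_phosphorus(bundle.topology, bundle.frames[0])
        counts = [len(count_permeation_events(bundle.topology, bundle.frames,
                                              water, protein, slab,
                                              proximity_cutoff=c))
                  for c in (5.0, 15.0, 60.0)]
        assert counts[0] <= counts[1] <= counts[2]
        assert counts[2] == 7    # far crossings admitted by a huge cutoff

    def test_empty_selection_errors(self, bundle):
        water, protein = self.selections(bundle)
        slab = slab_from_phosphorus(bundle.topology, bundle.frames[0])
        from carriermd.traj_core import Selection

        with pytest.raises(EmptySelectionError):
            count_permeation_events(bundle.topology, bundle.frames,
                                    Selection("none"), protein, slab)
        with pytest.raises(EmptySelectionError):
            count_permeation_events(bundle.topology, bundle.frames,
                                    water, Selection("none"), slab)

    def test_slab_regions_partition(self):
        slab = MembraneSlab(0.0, 30.0)
        assert [slab.region_of(z) for z in (-1, 5, 15, 25, 31)] == \
            [0, 1, 2, 3, 4]
        assert np.allclose(slab.edges, [0, 10, 20, 30])
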