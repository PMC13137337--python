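import numpy as np
import pytest

from aptabench.interface_metrics import (classify_interface, classify_iptm,
                                         define_pocket, lddt_score,
                                         map_pocket, pocket_occupancy)
from aptabench.seq_mapping import ResidueMap, identity_residue_map
from aptabench.structure import Structure, Trajectory
from aptabench.synthetic import ToyComplexSpec, make_toy_complex, make_toy_trajectory

from conftest import simple_structure
from oracles import brute_lddt, brute_pocket, brute_po


def _two_residue_complex(gap):
    """One ALA CB at distance `gap` from one aptamer C1'."""
    return simple_structure([
        ("A", 1, "ALA", {"N": (-1.4, 0, 0), "CA": (0, 0, 0), "CB": (1.5, 0, 0)}),
        ("B", 1, "DT", {"C1'": (1.5 + gap, 0, 0), "N1": (1.5 + gap + 1.4, 0, 0)}),
    ])


class TestDefinePocket:
    def test_inclusive_boundary_at_cutoff(self):
        s = _two_residue_complex(gap=4.5)
        pocket = define_pocket(s, cutoff=4.5)
        assert pocket.gt_pocket_residues == {("A", 1, "")}

    def test_just_beyond_cutoff_excluded(self):
        s = _two_residue_complex(gap=4.5001)
        assert define_pocket(s).gt_pocket_residues == set()

    def test_distant_aptamer_gives_empty_pocket(self):
        s = _two_residue_complex(gap=20.0)
        assert define_pocket(s).gt_pocket_residues == set()

    def test_planted_contacts_recovered(self, toy):
        gt, _, truth = toy
        assert define_pocket(gt).gt_pocket_residues == truth.pocket_keys

    def test_matches_brute_force(self, toy):
        gt, _, _ = toy
        assert define_pocket(gt).gt_pocket_residues == brute_pocket(gt)

    def test_requires_nucleic_chain(self):
        s = simple_structure([("A", 1, "ALA", {"CA": (0, 0, 0)})])
        with pytest.raises(ValueError, match="aptamer"):
            define_pocket(s)


class TestMapPocket:
    def test_identity_map(self, toy):
        gt, _, _ = toy
        p = define_pocket(gt)
        mapped = map_pocket(p, identity_residue_map(gt))
        assert mapped.mapped_pocket_residues == p.gt_pocket_residues
        assert mapped.unmapped == []

    def test_missing_residue_goes_to_unmapped(self, toy):
        gt, _, _ = toy
        p = define_pocket(gt)
        keys = sorted(p.gt_pocket_residues)
        partial = ResidueMap([(k, k) for k in gt.residue_keys()
                              if k != keys[0]], 1.0)
        with pytest.warns(UserWarning):
            mapped = map_pocket(p, partial)
        assert keys[0] in mapped.unmapped
        assert mapped.mapped_pocket_residues == set(keys[1:])


class TestPocketOccupancy:
    def test_all_in_and_all_out(self, toy):
        gt, _, truth = toy
        far = gt.coords.copy()
        apt = np.array([gt.chain_entities[a.chain_id] == "nucleic"
                        for a in gt.atoms])
        far[apt] += 100.0
        traj = Trajectory(gt, [10.0, 20.0], [gt.coords, far])
        ts = pocket_occupancy(traj, truth.pocket_keys)
        assert ts.values[1] == 0.0
        assert 0 < ts.values[0] <= 1.0

    def test_fraction_matches_brute_force_per_frame(self, toy):
        gt, _, truth = toy
        traj, _ = make_toy_trajectory(gt, "dissociate", n_frames=6, seed=3)
        ts = pocket_occupancy(traj, truth.pocket_keys)
        for xyz, got in zip(traj.frames, ts.values):
            assert got == pytest.approx(brute_po(gt, xyz, truth.pocket_keys))

    def test_monotone_in_cutoff(self, toy):
        gt, _, truth = toy
        traj = Trajectory(gt, [10.0], [gt.coords])
        values = [pocket_occupancy(traj, truth.pocket_keys, cutoff=c).values[0]
                  for c in (3.0, 4.5, 6.0, 10.0, 30.0)]
        assert values == sorted(values)

    def test_rigid_motion_invariance(self, toy, rng):
        gt, _, truth = toy
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = gt.coords @ R.T + np.array([5.0, -3.0, 11.0])
        traj = Trajectory(gt, [10.0, 20.0], [gt.coords, moved])
        ts = pocket_occupancy(traj, truth.pocket_keys)
        assert ts.values[0] == pytest.approx(ts.values[1], abs=1e-12)

    def test_empty_pocket_warns_all_zero(self, toy):
        gt, _, _ = toy
        traj = Trajectory(gt, [10.0], [gt.coords])
        with pytest.warns(UserWarning):
            ts = pocket_occupancy(traj, set())
        assert list(ts.values) == [0.0]


class TestLddt:
    def test_identical_structures_score_100(self, toy):
        gt, _, _ = toy
        m = identity_residue_map(gt)
        assert lddt_score(gt, gt, m) == pytest.approx(100.0)
        assert lddt_score(gt, gt, m, interface_only=True) == pytest.approx(100.0)

    def test_single_pair_with_0p7_error_scores_75(self):
        """0.7 A error passes thresholds 1, 2, 4 and fails 0.5 -> 75."""
        ref = simple_structure([
            ("A", 1, "GLY", {"CA": (0, 0, 0)}),
            ("B", 1, "DT", {"C1'": (5.0, 0, 0)}),
        ])
        model = simple_structure([
            ("A", 1, "GLY", {"CA": (0, 0, 0)}),
            ("B", 1, "DT", {"C1'": (5.7, 0, 0)}),
        ])
        m = identity_residue_map(ref)
        assert lddt_score(ref, model, m) == pytest.approx(75.0)

    def test_interface_only_without_contacts_is_none(self):
        ref = simple_structure([
            ("A", 1, "GLY", {"CA": (0, 0, 0), "N": (1.4, 0, 0)}),
            ("A", 2, "GLY", {"CA": (4.0, 0, 0), "N": (5.4, 0, 0)}),
            ("B", 1, "DT", {"C1'": (100.0, 0, 0), "N1": (101.4, 0, 0)}),
        ])
        m = identity_residue_map(ref)
        assert lddt_score(ref, ref, m, interface_only=True) is None
        assert lddt_score(ref, ref, m) == pytest.approx(100.0)

    def test_matches_brute_force(self, toy):
        gt, pred, _ = toy
        m = identity_residue_map(gt)
        for interface_only in (False, True):
            got = lddt_score(gt, pred, m, interface_only=interface_only)
            want = brute_lddt(gt, pred, interface_only=interface_only)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, rel=1e-9)

    def test_rigid_motion_invariance(self, toy):
        gt, pred, _ = toy
        theta = 1.1
        R = np.array([[np.cos(theta), 0, np.sin(theta)], [0, 1, 0],
                      [-np.sin(theta), 0, np.cos(theta)]])
        moved = pred.with_coords(pred.coords @ R.T + np.array([3.0, 4.0, 5.0]))
        m = identity_residue_map(gt)
        assert lddt_score(gt, pred, m) == pytest.approx(
            lddt_score(gt, moved, m), rel=1e-9)


class TestClassification:
    @pytest.mark.parametrize("value,label", [
        (0.0, "incorrect"), (23.5999, "incorrect"), (23.6, "correct"),
        (50.0, "correct"), (77.5999, "correct"), (77.6, "very_high"),
        (100.0, "very_high"),
    ])
    def test_interface_thresholds(self, value, label):
        assert classify_interface(value) == label

    @pytest.mark.parametrize("value,label", [
        (0.0, "incorrect"), (0.59, "incorrect"), (0.6, "uncertain"),
        (0.7, "uncertain"), (0.8, "uncertain"), (0.80001, "high"),
        (0.85, "high"), (1.0, "high"),
    ])
    def test_iptm_thresholds(self, value, label):
        assert classify_iptm(value) == label

    def test_iptm_rescaling(self):
        assert classify_iptm(0.85, scale_to_100=True) == ("high", 85.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_interface(101.0)
        with pytest.raises(ValueError):
            classify_iptm(-0.1)

    def test_partitions_cover_domain(self):
        for v in np.linspace(0, 100, 201):
            assert classify_interface(float(v)) in ("incorrect", "correct",
                                                    "very_high")
        for v in np.linspace(0, 1, 101):
            assert classify_iptm(float(v)) in ("incorrect", "uncertain", "high")
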