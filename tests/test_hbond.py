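import math

import numpy as np
import pytest

from aptabench.hbond import (HBondCriteria, compare_hbonds, detect_hbonds_md,
                             detect_hbonds_static, donor_acceptor_tables,
                             filter_interfacial, hbond_timeseries,
                             infer_polar_hydrogens, lookup_residue)
from aptabench.seq_mapping import identity_residue_map
from aptabench.structure import Structure, Trajectory
from aptabench.synthetic import ToyComplexSpec, make_toy_complex

from conftest import simple_structure
from oracles import brute_hbonds_static


class TestChemistryTables:
    def test_serine_hydroxyl(self):
        donors, acceptors = donor_acceptor_tables()["SER"]
        assert any(d.atom == "OG" for d in donors)
        og = [a for a in acceptors if a.atom == "OG"]
        assert og and og[0].antecedent == "CB"

    def test_adenine_base_sites(self):
        donors, acceptors = donor_acceptor_tables()["DA"]
        acc_names = {a.atom for a in acceptors}
        assert {"N1", "N3", "N7"} <= acc_names
        assert any(d.atom == "N6" for d in donors)

    def test_water_absent_and_warns(self):
        assert "HOH" not in donor_acceptor_tables()
        with pytest.warns(UserWarning):
            donors, acceptors = lookup_residue("HOH")
        assert donors == [] and acceptors == []


def _dipeptide():
    """GLY-SER with a well-formed backbone frame on residue 2."""
    return simple_structure([
        ("A", 1, "GLY", {"N": (-2.5, 1.0, 0), "CA": (-1.5, 0, 0),
                         "C": (0.0, 0.3, 0), "O": (0.4, 1.45, 0)}),
        ("A", 2, "SER", {"N": (0.9, -0.7, 0), "CA": (2.3, -0.5, 0),
                         "C": (3.1, 0.7, 0), "O": (4.3, 0.8, 0),
                         "CB": (2.9, -1.9, 0), "OG": (4.2, -2.1, 0.6)}),
    ])


class TestInferHydrogens:
    def test_backbone_amide_h_geometry(self):
        s = infer_polar_hydrogens(_dipeptide())
        hs = [a for a in s.atoms if a.is_hydrogen and a.residue_index == 2]
        assert len(hs) == 1
        n = next(a for a in s.atoms if a.atom_name == "N" and a.residue_index == 2)
        d = np.linalg.norm(np.array(hs[0].coords) - np.array(n.coords))
        assert d == pytest.approx(1.01, abs=0.02)
        assert abs(hs[0].coords[2]) < 1e-9  # in the C-N-CA plane

    def test_hydroxyl_left_bare(self):
        s = infer_polar_hydrogens(_dipeptide())
        og = next(a for a in s.atoms if a.atom_name == "OG")
        near = [a for a in s.atoms if a.is_hydrogen and
                np.linalg.norm(np.array(a.coords) - np.array(og.coords)) < 1.3]
        assert near == []

    def test_idempotent_existing_h_kept(self):
        once = infer_polar_hydrogens(_dipeptide())
        twice = infer_polar_hydrogens(once)
        assert len(twice.atoms) == len(once.atoms)

    def test_chain_start_amide_skipped(self):
        s = infer_polar_hydrogens(_dipeptide())
        hs1 = [a for a in s.atoms if a.is_hydrogen and a.residue_index == 1]
        assert hs1 == []  # no preceding carbonyl to define the frame


def _planted_bond_pair(d_da=2.9, d_offset=(0.0, 0.0, 0.0)):
    """Backbone N-H donor (residue A2) facing a DT O4 acceptor (B1).

    The acceptor sits along the idealized N-H direction at distance d_da,
    its antecedent C4 collinear beyond it: every static angle is ~180 deg.
    """
    base = _dipeptide()
    protonated = infer_polar_hydrogens(base)
    n = next(a for a in protonated.atoms
             if a.atom_name == "N" and a.residue_index == 2)
    h = next(a for a in protonated.atoms
             if a.is_hydrogen and a.residue_index == 2)
    npos, hpos = np.array(n.coords), np.array(h.coords)
    u = (hpos - npos) / np.linalg.norm(hpos - npos)
    o4 = npos + d_da * u + np.asarray(d_offset)
    c4 = npos + (d_da + 1.23) * u + np.asarray(d_offset)
    nt = simple_structure([("B", 1, "DT", {"O4": tuple(o4), "C4": tuple(c4)})])
    return Structure(protonated.atoms + nt.atoms, {})


class TestStaticDetection:
    def test_ideal_geometry_detected(self):
        s = _planted_bond_pair(d_da=2.9)
        bonds = detect_hbonds_static(s)
        keys = {(b.donor.atom_name, b.acceptor.atom_name) for b in bonds
                if b.acceptor.chain_id == "B"}
        assert ("N", "O4") in keys
        bond = next(b for b in bonds if b.acceptor.chain_id == "B")
        assert bond.d_DA == pytest.approx(2.9, abs=1e-6)
        assert bond.d_HA == pytest.approx(2.9 - 1.01, abs=0.02)

    def test_da_beyond_3p9_rejected(self):
        s = _planted_bond_pair(d_da=4.0)
        bonds = detect_hbonds_static(s)
        assert not any(b.acceptor.chain_id == "B" for b in bonds)

    def test_ha_beyond_2p5_rejected(self):
        # push the acceptor sideways: d_DA stays < 3.9 but d_HA > 2.5
        s = _planted_bond_pair(d_da=3.2, d_offset=(0, 0, 2.2))
        bonds = [b for b in detect_hbonds_static(s) if b.acceptor.chain_id == "B"]
        for b in bonds:
            assert b.d_HA is None or b.d_HA <= 2.5

    def test_matches_brute_force_on_planted_complex(self, toy):
        gt, _, _ = toy
        protonated = infer_polar_hydrogens(gt)
        got = {(b.donor.residue_key, b.donor.atom_name,
                b.acceptor.residue_key, b.acceptor.atom_name)
               for b in detect_hbonds_static(protonated)}
        assert got == brute_hbonds_static(protonated)

    def test_rigid_motion_invariance(self):
        s = _planted_bond_pair()
        theta = 0.9
        R = np.array([[math.cos(theta), -math.sin(theta), 0],
                      [math.sin(theta), math.cos(theta), 0], [0, 0, 1]])
        moved = s.with_coords(s.coords @ R.T + np.array([7.0, -2.0, 3.0]))
        key = lambda bonds: {(b.donor.atom_key, b.acceptor.atom_key)
                             for b in bonds}
        assert key(detect_hbonds_static(moved)) == key(detect_hbonds_static(s))

    @pytest.mark.parametrize("tighter", [
        HBondCriteria.static(max_DA=3.0),
        HBondCriteria.static(max_HA=2.0),
        HBondCriteria.static(min_angle_deg=120.0),
    ])
    def test_tightening_never_adds_bonds(self, toy, tighter):
        gt, _, _ = toy
        s = infer_polar_hydrogens(gt)
        loose = {(b.donor.atom_key, b.acceptor.atom_key)
                 for b in detect_hbonds_static(s)}
        tight = {(b.donor.atom_key, b.acceptor.atom_key)
                 for b in detect_hbonds_static(s, tighter)}
        assert tight <= loose


class TestInterfacialFilter:
    def test_keeps_only_cross_entity_bonds(self, toy):
        gt, _, truth = toy
        s = infer_polar_hydrogens(gt)
        bonds = detect_hbonds_static(s)
        inter = filter_interfacial(bonds, gt.protein_chains, gt.nucleic_chains)
        for b in inter:
            assert {b.donor.chain_id, b.acceptor.chain_id} == {"A", "B"}
            assert b.interfacial
        got = {(b.donor.residue_key, b.donor.atom_name,
                b.acceptor.residue_key, b.acceptor.atom_name) for b in inter}
        assert got == set(map(tuple, truth.hbond_keys))


class TestCompare:
    def _interfacial(self, s):
        protonated = infer_polar_hydrogens(s)
        return filter_interfacial(detect_hbonds_static(protonated),
                                  s.protein_chains, s.nucleic_chains)

    def test_self_comparison_is_perfect(self, toy):
        gt, _, _ = toy
        bonds = self._interfacial(gt)
        cmp_ = compare_hbonds(bonds, bonds, identity_residue_map(gt))
        assert (cmp_.precision, cmp_.recall, cmp_.f1) == (1.0, 1.0, 1.0)

    def test_empty_prediction_convention(self, toy):
        gt, _, _ = toy
        bonds = self._interfacial(gt)
        cmp_ = compare_hbonds(bonds, [], identity_residue_map(gt))
        assert (cmp_.precision, cmp_.recall, cmp_.f1) == (0.0, 0.0, 0.0)

    def test_partial_overlap_counts(self):
        gt, _, _ = make_toy_complex(ToyComplexSpec(
            n_protein_res=12, n_apt_nt=6, n_contact_res=4, n_hbonds=4, seed=5))
        bonds = self._interfacial(gt)
        assert len(bonds) == 4
        cmp_ = compare_hbonds(bonds, bonds[:2], identity_residue_map(gt))
        assert cmp_.precision == 1.0
        assert cmp_.recall == 0.5
        assert cmp_.f1 == pytest.approx(2 / 3)

    def test_metrics_within_bounds(self, toy):
        gt, pred, _ = toy
        cmp_ = compare_hbonds(self._interfacial(gt), self._interfacial(pred),
                              identity_residue_map(gt))
        for v in (cmp_.precision, cmp_.recall, cmp_.f1):
            assert 0.0 <= v <= 1.0
        assert cmp_.f1 <= max(cmp_.precision, cmp_.recall) + 1e-12


class TestMdCriteria:
    def test_ideal_bond_counted(self):
        s = _planted_bond_pair(d_da=2.9)
        bonds = [b for b in detect_hbonds_md(s) if b.acceptor.chain_id == "B"]
        assert len(bonds) == 1
        assert bonds[0].angles["H-D-A"] <= 30.0

    def test_displaced_aptamer_not_counted(self):
        s = _planted_bond_pair(d_da=2.9)
        xyz = s.coords.copy()
        for i, a in enumerate(s.atoms):
            if a.chain_id == "B":
                xyz[i] += 50.0
        moved = s.with_coords(xyz)
        assert not any(b.acceptor.chain_id == "B" for b in detect_hbonds_md(moved))

    def test_alternating_trajectory_series(self):
        s = _planted_bond_pair(d_da=2.9)
        bonded = s.coords
        unbonded = bonded.copy()
        for i, a in enumerate(s.atoms):
            if a.chain_id == "B":
                unbonded[i] += 50.0
        frames = [bonded, unbonded, bonded, unbonded]
        traj = Trajectory(s, [10.0, 20.0, 30.0, 40.0], list(frames))
        ts = hbond_timeseries(traj, protein_chains=["A"], aptamer_chains=["B"])
        assert list(ts.values) == [1.0, 0.0, 1.0, 0.0]
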