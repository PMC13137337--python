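import numpy as np
import pytest

from aptabench.structure import AtomRecord, Structure, Trajectory
from aptabench.structure_io import (ParseError, classify_chains,
                                    read_structure, read_trajectory,
                                    sanitize_structure, write_structure,
                                    write_trajectory)

from conftest import make_atom, simple_structure


class TestReadStructure:
    def test_minimal_pdb_transcription(self, minimal_pdb):
        s = read_structure(minimal_pdb, format="pdb")
        assert len(s.atoms) == 3
        assert s.chains() == ["A"]
        assert [a.atom_name for a in s.atoms] == ["N", "CA", "C"]
        assert s.atoms[0].residue_name == "ALA"
        np.testing.assert_allclose(s.atoms[0].coords, (11.104, 6.134, -6.504))
        assert s.atoms[0].element == "N"

    def test_mmcif_equals_pdb_parse(self, minimal_pdb, minimal_mmcif):
        """Cross-format round trip: same keys, same coordinates."""
        spdb = read_structure(minimal_pdb, format="pdb")
        scif = read_structure(minimal_mmcif, format="mmcif")
        assert [a.atom_key for a in spdb.atoms] == [a.atom_key for a in scif.atoms]
        np.testing.assert_allclose(spdb.coords, scif.coords, atol=1e-6)

    def test_multi_model_keeps_first(self, tmp_path):
        text = "MODEL        1\n" + \
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n" + \
            "ENDMDL\nMODEL        2\n" + \
            "ATOM      1  N   ALA A   1       5.000   0.000   0.000  1.00  0.00           N\n" + \
            "ENDMDL\nEND\n"
        p = tmp_path / "two_models.pdb"
        p.write_text(text)
        s = read_structure(p)
        assert len(s.atoms) == 1
        assert s.atoms[0].coords[0] == 0.0

    def test_missing_file_and_bad_format(self, tmp_path, minimal_pdb):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "absent.pdb")
        with pytest.raises(ValueError):
            read_structure(minimal_pdb, format="xyz")

    def test_garbage_mmcif_raises_parse_error(self, tmp_path):
        p = tmp_path / "bad.cif"
        p.write_text("this is not a structure file\n")
        with pytest.raises(ParseError):
            read_structure(p, format="mmcif")

    def test_write_read_round_trip(self, toy, tmp_path):
        gt, _, _ = toy
        path = tmp_path / "gt.pdb"
        write_structure(gt, path)
        back = read_structure(path, format="pdb")
        assert [a.atom_key for a in back.atoms] == [a.atom_key for a in gt.atoms]
        np.testing.assert_allclose(back.coords, gt.coords, atol=1e-3)


class TestClassifyChains:
    @pytest.mark.parametrize("resnames,expected", [
        (["DA", "DG", "DT"], "nucleic"),
        (["ALA", "GLY", "SER"], "protein"),
        (["HOH"], "other"),
    ])
    def test_majority_rule(self, resnames, expected):
        residues = [("A", i + 1, rn, {"C1": (float(i), 0, 0)})
                    for i, rn in enumerate(resnames)]
        s = simple_structure(residues)
        assert classify_chains(s)["A"] == expected

    def test_invariant_to_atom_order(self, toy):
        gt, _, _ = toy
        reversed_struct = Structure(list(reversed(gt.atoms)), {})
        assert classify_chains(reversed_struct) == classify_chains(gt)

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            classify_chains(Structure([], {}))


class TestSanitize:
    def test_removes_waters_and_ions(self):
        s = simple_structure([
            ("A", 1, "ALA", {"N": (0, 0, 0), "CA": (1.5, 0, 0)}),
            ("A", 2, "GLY", {"N": (3, 0, 0), "CA": (4.5, 0, 0)}),
            ("W", 1, "HOH", {"O": (9, 9, 9)}),
            ("W", 2, "HOH", {"O": (9, 9, 12)}),
            ("M", 1, "MG", {"MG": (5, 5, 5)}),
        ])
        with pytest.warns(UserWarning):
            out = sanitize_structure(s)
        assert len(out.atoms) == 4
        assert out.chains() == ["A"]

    def test_removes_hydrogens(self):
        s = simple_structure([
            ("A", 1, "SER", {"N": (0, 0, 0), "CA": (1.5, 0, 0),
                             "H": (-0.5, 0.8, 0), "HA": (1.6, 1.0, 0)}),
        ])
        with pytest.warns(UserWarning):
            out = sanitize_structure(s)
        assert all(not a.is_hydrogen for a in out.atoms)
        assert len(out.atoms) == 2

    def test_planted_composition_count(self, toy):
        """P protein + A aptamer heavy atoms + decorations -> P + A."""
        gt, _, _ = toy
        p = sum(1 for a in gt.atoms if a.chain_id == "A")
        n = sum(1 for a in gt.atoms if a.chain_id == "B")
        decorated = Structure(
            gt.atoms
            + [make_atom("W", i, "HOH", "O", (200 + i, 0, 0)) for i in range(5)]
            + [make_atom("A", 1, "ALA", "H", (300, 0, 0), element="H")],
            {})
        out = sanitize_structure(decorated)
        assert len(out.atoms) == p + n

    def test_idempotent(self, toy):
        gt, _, _ = toy
        once = sanitize_structure(gt)
        twice = sanitize_structure(once)
        assert [a.atom_key for a in twice.atoms] == [a.atom_key for a in once.atoms]

    def test_altloc_resolution_highest_occupancy_then_letter(self):
        atoms = [
            make_atom("A", 1, "ALA", "CA", (0, 0, 0), alt="A", occ=0.4),
            make_atom("A", 1, "ALA", "CA", (1, 0, 0), alt="B", occ=0.6),
            make_atom("A", 1, "ALA", "CB", (2, 0, 0), alt="A", occ=0.5),
            make_atom("A", 1, "ALA", "CB", (3, 0, 0), alt="B", occ=0.5),
            make_atom("A", 1, "ALA", "N", (4, 0, 0)),
        ]
        with pytest.warns(UserWarning):
            out = sanitize_structure(Structure(atoms, {}))
        kept = {a.atom_name: a for a in out.atoms}
        assert kept["CA"].alt_loc == "B"  # higher occupancy wins
        assert kept["CB"].alt_loc == "A"  # tie broken by letter order


class TestTrajectory:
    def _write_models(self, tmp_path, structure, frames):
        traj = Trajectory(structure, [10.0 * (i + 1) for i in range(len(frames))],
                          list(frames))
        path = tmp_path / "traj.pdb"
        write_trajectory(traj, path)
        return path

    def test_read_counts_and_timestamps(self, toy, tmp_path):
        gt, _, _ = toy
        base = gt.coords
        frames = [base + i for i in range(5)]
        path = self._write_models(tmp_path, gt, frames)
        traj = read_trajectory(gt, path, frame_dt_ps=10.0)
        assert len(traj) == 5
        assert traj.times_ps == [10.0, 20.0, 30.0, 40.0, 50.0]
        assert traj.frames[0].shape == (len(gt.atoms), 3)

    def test_round_trip_coordinates(self, toy, tmp_path, rng):
        gt, _, _ = toy
        frames = [gt.coords + rng.normal(0, 1, (len(gt.atoms), 3))
                  for _ in range(3)]
        path = self._write_models(tmp_path, gt, frames)
        traj = read_trajectory(gt, path)
        for written, back in zip(frames, traj.frames):
            np.testing.assert_allclose(back, written, atol=1e-3)

    def test_atom_count_mismatch_names_model(self, toy, tmp_path):
        gt, _, _ = toy
        path = self._write_models(tmp_path, gt, [gt.coords])
        truncated = Structure(gt.atoms[:-1], {})
        with pytest.raises(ValueError, match="model 1"):
            read_trajectory(truncated, path)

    def test_timestamps_must_increase(self, toy):
        gt, _, _ = toy
        with pytest.raises(ValueError):
            Trajectory(gt, [10.0, 10.0], [gt.coords, gt.coords])
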