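import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from aptabench.structure import AtomRecord, Structure
from aptabench.synthetic import ToyComplexSpec, make_toy_complex

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      12.560   6.351  -6.509  1.00  0.00           C
ATOM      3  C   ALA A   1      13.059   6.660  -7.908  1.00  0.00           C
END
"""

MINIMAL_MMCIF = """\
data_minimal
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 N N . ALA A 1 1 ? 11.104 6.134 -6.504 1.00 0.00 1 A 1
ATOM 2 C CA . ALA A 1 1 ? 12.560 6.351 -6.509 1.00 0.00 1 A 1
ATOM 3 C C . ALA A 1 1 ? 13.059 6.660 -7.908 1.00 0.00 1 A 1
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def minimal_mmcif(tmp_path):
    p = tmp_path / "minimal.cif"
    p.write_text(MINIMAL_MMCIF)
    return p


@pytest.fixture(scope="session")
def toy():
    """A default planted complex: 4 contacts, 2 interfacial H-bonds."""
    return make_toy_complex(ToyComplexSpec(n_protein_res=12, n_apt_nt=8,
                                           n_contact_res=4, n_hbonds=2,
                                           perturbation=0.15, seed=7))


def make_atom(chain, resi, resname, name, xyz, element=None, icode="",
              alt="", occ=1.0):
    return AtomRecord(chain, resi, icode, resname, name,
                      element or name[0], tuple(float(v) for v in xyz),
                      alt, occ)


def simple_structure(residues):
    """Build a Structure from [(chain, resi, resname, {atom: xyz})]."""
    atoms = []
    for chain, resi, resname, atom_map in residues:
        for name, xyz in atom_map.items():
            element = "H" if name.startswith("H") else name[0]
            atoms.append(make_atom(chain, resi, resname, name, xyz, element))
    return Structure(atoms, {})


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)
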