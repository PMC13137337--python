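"""Reading, writing, sanitizing and classifying molecular structures.

PDB and mmCIF parsing is delegated to :mod:`gemmi`; this module converts
between gemmi's hierarchy and the flat :class:`~aptabench.structure.Structure`
model used by the metrics. A multi-model file read as a *structure* keeps
model 1 only (PDB convention; experimental references are single assemblies);
read as a *trajectory* every MODEL block becomes one frame.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import gemmi
import numpy as np

from .structure import (
    STANDARD_AMINO_ACIDS,
    STANDARD_NUCLEOTIDES,
    WATER_NAMES,
    AtomRecord,
    Structure,
    Trajectory,
)

__all__ = [
    "read_structure", "write_structure", "sanitize_structure",
    "classify_chains", "read_trajectory", "write_trajectory", "ParseError",
]


class ParseError(ValueError):
    """A structure file could not be parsed in the declared format."""


_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def _element_of(atom: gemmi.Atom) -> str:
    name = atom.element.name
    if name and name != "X":
        return name
    # element column absent: infer from the atom name, PDB-style
    stripped = atom.name.strip().lstrip("0123456789")
    if not stripped:
        raise ParseError(f"cannot infer element for atom named {atom.name!r}")
    if stripped[0] in "HD" and any(c.isdigit() for c in atom.name):
        return "H"
    return stripped[0].upper()


def _from_gemmi_model(model: gemmi.Model, label: str) -> Structure:
    atoms: list[AtomRecord] = []
    seen: set[tuple] = set()
    for chain in model:
        for res in chain:
            icode = res.seqid.icode.strip()
            for atom in res:
                alt = atom.altloc if atom.altloc and atom.altloc != "\x00" else ""
                rec = AtomRecord(
                    chain_id=chain.name,
                    residue_index=res.seqid.num,
                    insertion=icode,
                    residue_name=res.name.strip(),
                    atom_name=atom.name.strip(),
                    element=_element_of(atom),
                    coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                    alt_loc=alt,
                    occupancy=atom.occ,
                )
                if not all(np.isfinite(rec.coords)):
                    raise ParseError(f"non-finite coordinates for atom {rec.atom_key}")
                if rec.atom_key in seen:
                    continue  # duplicated record, keep first
                seen.add(rec.atom_key)
                atoms.append(rec)
    s = Structure(atoms, {}, source_label=label)
    return s


def read_structure(path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure` (model 1 only).

    Parameters
    ----------
    path : path-like
        File to read.
    format : {"pdb", "mmcif", "auto"}
        Declared format; ``auto`` detects from extension/content.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected pdb, mmcif or auto")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    st.setup_entities()
    return _from_gemmi_model(st[0], label=st.name or path.stem)


def _to_gemmi(structures: list[Structure], name: str = "") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    for imodel, s in enumerate(structures, start=1):
        model = gemmi.Model(imodel)
        for chain_id in s.chains():
            chain = gemmi.Chain(chain_id)
            for key, resname, res_atoms in s.residues():
                if key[0] != chain_id:
                    continue
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(key[1], key[2] or " ")
                for a in res_atoms:
                    atom = gemmi.Atom()
                    atom.name = a.atom_name
                    atom.element = gemmi.Element(a.element)
                    atom.pos = gemmi.Position(*a.coords)
                    atom.occ = a.occupancy
                    if a.alt_loc:
                        atom.altloc = a.alt_loc
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    return st


def write_structure(s: Structure, path) -> None:
    """Write a structure as a PDB file."""
    st = _to_gemmi([s], name=s.source_label)
    st.write_pdb(str(path))


def classify_chains(s: Structure) -> dict[str, str]:
    """Label each chain protein / nucleic / other by residue majority.

    A chain is ``protein`` when most of its residues are standard amino
    acids, ``nucleic`` when most are standard (deoxy)ribonucleotides,
    otherwise ``other``.
    """
    if not s.atoms:
        raise ValueError("cannot classify an empty structure")
    counts: dict[str, dict[str, int]] = {}
    for key, resname, _ in s.residues():
        c = counts.setdefault(key[0], {"protein": 0, "nucleic": 0, "other": 0})
        if resname in STANDARD_AMINO_ACIDS:
            c["protein"] += 1
        elif resname in STANDARD_NUCLEOTIDES:
            c["nucleic"] += 1
        else:
            c["other"] += 1
    out: dict[str, str] = {}
    for chain_id, c in counts.items():
        total = sum(c.values())
        if c["protein"] * 2 > total:
            out[chain_id] = "protein"
        elif c["nucleic"] * 2 > total:
            out[chain_id] = "nucleic"
        else:
            out[chain_id] = "other"
    return out


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    # keep, per (residue, atom name), the conformer with highest occupancy;
    # ties broken by alt-loc character order
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in atoms:
        k = (a.chain_id, a.residue_index, a.insertion, a.atom_name)
        cur = best.get(k)
        if cur is None:
            best[k] = a
            order.append(k)
        elif (a.occupancy, _alt_rank(a.alt_loc)) > (cur.occupancy, _alt_rank(cur.alt_loc)):
            best[k] = a
    return [best[k] for k in order]


def _alt_rank(alt: str) -> float:
    # '' (no alt) ranks above any lettered conformer; then reverse alphabetical
    # so that under max() 'A' beats 'B'
    if not alt:
        return float("inf")
    return -ord(alt)


def sanitize_structure(s: Structure) -> Structure:
    """Strip a complex down to protein and nucleic heavy atoms.

    Removes hydrogens (and deuteriums), waters, ions, ligands and any chain
    that is neither protein nor nucleic; collapses alternate locations to a
    single conformer. Idempotent. A result lacking a protein or a nucleic
    component is legitimate (aptamer-only mode) and only recorded as a
    warning on the returned structure.
    """
    entities = classify_chains(s)
    kept: list[AtomRecord] = []
    for a in s.atoms:
        if a.is_hydrogen:
            continue
        if a.residue_name in WATER_NAMES:
            continue
        if a.residue_name not in STANDARD_AMINO_ACIDS and \
           a.residue_name not in STANDARD_NUCLEOTIDES:
            continue  # ion or ligand
        if entities.get(a.chain_id) not in ("protein", "nucleic"):
            continue
        kept.append(a)
    kept = _resolve_altlocs(kept)
    out = Structure(kept, {}, source_label=s.source_label)
    if kept:
        if not out.protein_chains:
            out.warnings.append("no protein chain after sanitization")
            warnings.warn(f"{s.source_label or 'structure'}: no protein chain "
                          "after sanitization", stacklevel=2)
        if not out.nucleic_chains:
            out.warnings.append("no nucleic chain after sanitization")
            warnings.warn(f"{s.source_label or 'structure'}: no nucleic chain "
                          "after sanitization", stacklevel=2)
    return out


def read_trajectory(topology: Structure, frames_path, frame_dt_ps: float = 10.0) -> Trajectory:
    """Read a multi-model PDB as an ordered trajectory over ``topology``.

    Every MODEL block becomes one frame; the atom order of each model must
    match the topology exactly. Timestamps are ``frame_dt_ps`` apart, with
    the first frame at ``frame_dt_ps`` (one trajectory frame every 10 ps by
    default).
    """
    frames_path = Path(frames_path)
    if not frames_path.exists():
        raise FileNotFoundError(str(frames_path))
    try:
        st = gemmi.read_structure(str(frames_path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{frames_path}: {exc}") from exc
    n = len(topology.atoms)
    frames: list[np.ndarray] = []
    for imodel, model in enumerate(st, start=1):
        xyz = []
        for chain in model:
            for res in chain:
                for atom in res:
                    xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
        if len(xyz) != n:
            raise ValueError(f"model {imodel}: {len(xyz)} atoms, topology has {n}")
        frames.append(np.asarray(xyz, dtype=float))
    times = [frame_dt_ps * (i + 1) for i in range(len(frames))]
    return Trajectory(topology, times, frames)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB file."""
    structures = [traj.topology.with_coords(f) for f in traj.frames]
    st = _to_gemmi(structures, name=traj.topology.source_label)
    st.write_pdb(str(path))
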