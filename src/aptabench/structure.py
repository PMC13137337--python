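"""Core in-memory model: atoms, structures, trajectories, time series.

Coordinates are stored in Angstrom throughout. Residues are identified by
author numbering plus insertion code, exactly as deposited; no renumbering
is ever performed (numbering mismatches between experimental and predicted
structures are resolved downstream by sequence mapping).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

#: Three-letter codes of the 20 standard amino acids.
STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Standard (deoxy)ribonucleotide residue names.
STANDARD_NUCLEOTIDES = frozenset("DA DC DG DT A C G U".split())

#: Residue names treated as water during sanitization.
WATER_NAMES = frozenset({"HOH", "WAT", "H2O", "DOD"})

#: A residue key: (chain_id, residue_index, insertion_code).
ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class AtomRecord:
    """One atom with its full PDB-style identity.

    ``residue_index`` is the author residue number; ``insertion`` is the
    insertion code ('' when absent). ``element`` is always populated after
    parsing (inferred from the atom name when the file lacks an element
    column).
    """

    chain_id: str
    residue_index: int
    insertion: str
    residue_name: str
    atom_name: str
    element: str
    coords: tuple[float, float, float]
    alt_loc: str = ""
    occupancy: float = 1.0

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_index, self.insertion)

    @property
    def atom_key(self) -> tuple[str, int, str, str, str]:
        return (self.chain_id, self.residue_index, self.insertion,
                self.atom_name, self.alt_loc)

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    def moved(self, xyz) -> "AtomRecord":
        return dataclasses.replace(self, coords=(float(xyz[0]), float(xyz[1]), float(xyz[2])))


@dataclass
class Structure:
    """An ordered atom list with per-chain entity labels.

    ``chain_entities`` maps every chain id present in ``atoms`` to one of
    ``"protein"``, ``"nucleic"`` or ``"other"``.
    """

    atoms: list[AtomRecord]
    chain_entities: dict[str, str] = field(default_factory=dict)
    source_label: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chain_entities and self.atoms:
            from .structure_io import classify_chains  # deferred: avoid cycle
            self.chain_entities = classify_chains(self)

    # -- basic accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """All coordinates as an (n_atoms, 3) float array, in atom order."""
        return np.asarray([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def with_coords(self, xyz: np.ndarray) -> "Structure":
        """Copy of the structure with replaced coordinates (same atoms)."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate array shape {xyz.shape} does not match "
                             f"{len(self.atoms)} atoms")
        atoms = [a.moved(x) for a, x in zip(self.atoms, xyz)]
        return Structure(atoms, dict(self.chain_entities), self.source_label)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def chain_ids_of(self, entity: str) -> list[str]:
        return [c for c in self.chains() if self.chain_entities.get(c) == entity]

    @property
    def protein_chains(self) -> list[str]:
        return self.chain_ids_of("protein")

    @property
    def nucleic_chains(self) -> list[str]:
        return self.chain_ids_of("nucleic")

    def residues(self) -> Iterator[tuple[ResidueKey, str, list[AtomRecord]]]:
        """Yield (residue_key, residue_name, atoms) in atom order."""
        current: ResidueKey | None = None
        bucket: list[AtomRecord] = []
        for a in self.atoms:
            if a.residue_key != current:
                if bucket:
                    yield current, bucket[0].residue_name, bucket
                current, bucket = a.residue_key, []
            bucket.append(a)
        if bucket:
            yield current, bucket[0].residue_name, bucket

    def residue_keys(self) -> list[ResidueKey]:
        return [k for k, _, _ in self.residues()]

    def atom_lookup(self) -> dict[tuple, AtomRecord]:
        """Map (chain, resnum, icode, atom_name) -> AtomRecord (first wins)."""
        out: dict[tuple, AtomRecord] = {}
        for a in self.atoms:
            out.setdefault((a.chain_id, a.residue_index, a.insertion, a.atom_name), a)
        return out

    # -- selections ------------------------------------------------------

    def select(self, *, chains=None, entity=None, heavy_only=False,
               atom_names=None) -> np.ndarray:
        """Boolean mask over atoms for the given filters (AND-combined)."""
        chain_set = set(chains) if chains is not None else None
        name_set = set(atom_names) if atom_names is not None else None
        mask = np.zeros(len(self.atoms), dtype=bool)
        for i, a in enumerate(self.atoms):
            if chain_set is not None and a.chain_id not in chain_set:
                continue
            if entity is not None and self.chain_entities.get(a.chain_id) != entity:
                continue
            if heavy_only and a.is_hydrogen:
                continue
            if name_set is not None and a.atom_name not in name_set:
                continue
            mask[i] = True
        return mask

    def subset(self, mask: np.ndarray) -> "Structure":
        atoms = [a for a, keep in zip(self.atoms, mask) if keep]
        ents = {c: e for c, e in self.chain_entities.items()
                if any(a.chain_id == c for a in atoms)}
        return Structure(atoms, ents, self.source_label)


@dataclass
class Trajectory:
    """A topology plus an ordered series of timestamped coordinate frames.

    Frame coordinate arrays are (n_atoms, 3) in Angstrom; timestamps are in
    picoseconds and strictly increase.
    """

    topology: Structure
    times_ps: list[float]
    frames: list[np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.topology.atoms)
        for i, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise ValueError(f"frame {i}: {f.shape[0] if f.ndim else 0} coordinate "
                                 f"triples, topology has {n} atoms")
            self.frames[i] = f
        t = np.asarray(self.times_ps, dtype=float)
        if len(t) != len(self.frames):
            raise ValueError("timestamp count does not match frame count")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must strictly increase")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[tuple[float, np.ndarray]]:
        return iter(zip(self.times_ps, self.frames))


@dataclass
class TimeSeries:
    """Timestamped scalar metric values (PO, RMSD, Rg, H-bond counts...)."""

    label: str
    times_ps: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_ps.shape != self.values.shape:
            raise ValueError("timestamps and values must have equal length")
        if len(self.times_ps) > 1 and not np.all(np.diff(self.times_ps) > 0):
            raise ValueError("timestamps must strictly increase")

    def __len__(self) -> int:
        return len(self.values)

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"timestamp_ps": self.times_ps, "value": self.values}
                     ).to_csv(path, index=False)
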