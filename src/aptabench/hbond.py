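"""Geometric hydrogen-bond detection and reference-vs-prediction comparison.

Two criteria sets are supported. The *static* criteria follow the classic
HBPLUS defaults used on single structures: donor–acceptor distance at most
3.9 Å, hydrogen–acceptor distance at most 2.5 Å, and minimum angles of 90°
for donor–hydrogen–acceptor, hydrogen–acceptor–antecedent and
donor–acceptor–antecedent. The *md* criteria mirror trajectory tools:
donor–acceptor distance at most 0.35 nm with the hydrogen–donor–acceptor
angle (at the donor) at most 30°.

Experimental structures arrive dehydrogenated, so polar hydrogens with
geometrically determined positions (backbone amides, ring N–H, planar
amines) are rebuilt at idealized geometry; rotationally ambiguous donors
(hydroxyls, lysine ammonium, ribose O2') get no hydrogen and are evaluated
on the donor–acceptor criteria only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .seq_mapping import ResidueMap
from .structure import (AtomRecord, ResidueKey, Structure, TimeSeries,
                        Trajectory)

__all__ = [
    "HBondCriteria", "HBond", "HBondComparison", "DonorSpec", "AcceptorSpec",
    "donor_acceptor_tables", "infer_polar_hydrogens", "detect_hbonds_static",
    "detect_hbonds_md", "filter_interfacial", "compare_hbonds",
    "hbond_timeseries",
]

H_BOND_LENGTH = 1.01  # idealized N-H distance, Angstrom
H_COVALENT_CUTOFF = 1.25  # an H within this distance of a donor is "attached"


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric acceptance thresholds for hydrogen-bond detection."""

    mode: str  # "static" or "md"
    max_DA: float  # Angstrom
    max_HA: float | None = None  # Angstrom, static only
    min_angle_deg: float | None = None  # static: D-H-A, H-A-AA, D-A-AA floors
    max_angle_HDA_deg: float | None = None  # md: H-D-A ceiling at the donor

    def __post_init__(self) -> None:
        if self.max_DA <= 0 or (self.max_HA is not None and self.max_HA <= 0):
            raise ValueError("distances must be positive")
        for ang in (self.min_angle_deg, self.max_angle_HDA_deg):
            if ang is not None and not 0 < ang <= 180:
                raise ValueError("angles must lie in (0, 180]")

    @classmethod
    def static(cls, max_HA: float = 2.5, max_DA: float = 3.9,
               min_angle_deg: float = 90.0) -> "HBondCriteria":
        return cls("static", max_DA=max_DA, max_HA=max_HA,
                   min_angle_deg=min_angle_deg)

    @classmethod
    def md(cls, max_DA: float = 3.5, max_angle_HDA_deg: float = 30.0) -> "HBondCriteria":
        """MD criteria; note 0.35 nm donor–acceptor = 3.5 Å."""
        return cls("md", max_DA=max_DA, max_angle_HDA_deg=max_angle_HDA_deg)


@dataclass(frozen=True)
class DonorSpec:
    """A donor atom: how its hydrogen(s) can be placed.

    kind ``bisector``: one H on the external bisector of two heavy
    neighbors (backbone amide, ring N–H). kind ``amine2``: two in-plane H
    on a planar amine, built from the parent atom and one grandparent.
    kind ``ambiguous``: rotatable — no H is placed and the pair test falls
    back to donor–acceptor criteria.
    """

    atom: str
    kind: str
    neighbors: tuple[str, ...] = ()
    n_h: int = 1


@dataclass(frozen=True)
class AcceptorSpec:
    atom: str
    antecedent: str


def _protein_table() -> dict[str, tuple[list[DonorSpec], list[AcceptorSpec]]]:
    bb_donor = DonorSpec("N", "bisector", ("-C", "CA"))  # -C: C of previous residue
    bb_acc = [AcceptorSpec("O", "C"), AcceptorSpec("OXT", "C")]
    side: dict[str, tuple[list[DonorSpec], list[AcceptorSpec]]] = {
        "ALA": ([], []),
        "GLY": ([], []),
        "VAL": ([], []),
        "LEU": ([], []),
        "ILE": ([], []),
        "PHE": ([], []),
        "PRO": ([], []),  # backbone N has no H
        "MET": ([], [AcceptorSpec("SD", "CG")]),
        "CYS": ([DonorSpec("SG", "ambiguous")], [AcceptorSpec("SG", "CB")]),
        "SER": ([DonorSpec("OG", "ambiguous")], [AcceptorSpec("OG", "CB")]),
        "THR": ([DonorSpec("OG1", "ambiguous")], [AcceptorSpec("OG1", "CB")]),
        "TYR": ([DonorSpec("OH", "ambiguous")], [AcceptorSpec("OH", "CZ")]),
        "TRP": ([DonorSpec("NE1", "bisector", ("CD1", "CE2"))], []),
        "ASN": ([DonorSpec("ND2", "amine2", ("CG", "OD1"), n_h=2)],
                [AcceptorSpec("OD1", "CG")]),
        "GLN": ([DonorSpec("NE2", "amine2", ("CD", "OE1"), n_h=2)],
                [AcceptorSpec("OE1", "CD")]),
        "ASP": ([], [AcceptorSpec("OD1", "CG"), AcceptorSpec("OD2", "CG")]),
        "GLU": ([], [AcceptorSpec("OE1", "CD"), AcceptorSpec("OE2", "CD")]),
        "LYS": ([DonorSpec("NZ", "ambiguous")], []),
        "ARG": ([DonorSpec("NE", "bisector", ("CD", "CZ")),
                 DonorSpec("NH1", "amine2", ("CZ", "NE"), n_h=2),
                 DonorSpec("NH2", "amine2", ("CZ", "NE"), n_h=2)], []),
        "HIS": ([DonorSpec("ND1", "bisector", ("CG", "CE1")),
                 DonorSpec("NE2", "bisector", ("CD2", "CE1"))],
                [AcceptorSpec("ND1", "CG"), AcceptorSpec("NE2", "CE1")]),
    }
    table = {}
    for name, (donors, accs) in side.items():
        d = list(donors)
        if name != "PRO":
            d.insert(0, bb_donor)
        table[name] = (d, bb_acc + accs)
    return table


def _nucleotide_table() -> dict[str, tuple[list[DonorSpec], list[AcceptorSpec]]]:
    # sugar + phosphate, shared by every nucleotide (both OP1/OP2 and the
    # older O1P/O2P phosphate naming accepted)
    backbone_acc = [
        AcceptorSpec("OP1", "P"), AcceptorSpec("OP2", "P"),
        AcceptorSpec("O1P", "P"), AcceptorSpec("O2P", "P"),
        AcceptorSpec("O5'", "C5'"), AcceptorSpec("O4'", "C4'"),
        AcceptorSpec("O3'", "C3'"),
    ]
    ribose_acc = [AcceptorSpec("O2'", "C2'")]
    ribose_don = [DonorSpec("O2'", "ambiguous")]
    purine = {
        "A": ([DonorSpec("N6", "amine2", ("C6", "N1"), n_h=2)],
              [AcceptorSpec("N1", "C2"), AcceptorSpec("N3", "C2"),
               AcceptorSpec("N7", "C5")]),
        "G": ([DonorSpec("N1", "bisector", ("C2", "C6")),
               DonorSpec("N2", "amine2", ("C2", "N3"), n_h=2)],
              [AcceptorSpec("O6", "C6"), AcceptorSpec("N3", "C2"),
               AcceptorSpec("N7", "C5")]),
    }
    pyrimidine = {
        "C": ([DonorSpec("N4", "amine2", ("C4", "N3"), n_h=2)],
              [AcceptorSpec("O2", "C2"), AcceptorSpec("N3", "C2")]),
        "T": ([DonorSpec("N3", "bisector", ("C2", "C4"))],
              [AcceptorSpec("O2", "C2"), AcceptorSpec("O4", "C4")]),
        "U": ([DonorSpec("N3", "bisector", ("C2", "C4"))],
              [AcceptorSpec("O2", "C2"), AcceptorSpec("O4", "C4")]),
    }
    base = {**purine, **pyrimidine}
    table = {}
    for resname, letter, rna in [("DA", "A", False), ("DG", "G", False),
                                 ("DC", "C", False), ("DT", "T", False),
                                 ("A", "A", True), ("G", "G", True),
                                 ("C", "C", True), ("U", "U", True)]:
        donors, accs = base[letter]
        d = list(donors) + (list(ribose_don) if rna else [])
        a = list(accs) + backbone_acc + (list(ribose_acc) if rna else [])
        table[resname] = (d, a)
    return table


_TABLE_CACHE: dict[str, tuple[list[DonorSpec], list[AcceptorSpec]]] | None = None


def donor_acceptor_tables() -> dict[str, tuple[list[DonorSpec], list[AcceptorSpec]]]:
    """Donor and acceptor atoms for every standard residue name.

    Maps residue name → (donors, acceptors). Waters and nonstandard
    residues are absent (they are removed at sanitization); looking one up
    via :func:`lookup_residue` yields empty lists plus a warning.
    """
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        _TABLE_CACHE = {**_protein_table(), **_nucleotide_table()}
    return _TABLE_CACHE


def lookup_residue(resname: str) -> tuple[list[DonorSpec], list[AcceptorSpec]]:
    table = donor_acceptor_tables()
    if resname not in table:
        warnings.warn(f"no donor/acceptor chemistry for residue {resname!r}",
                      stacklevel=2)
        return [], []
    return table[resname]


# ---------------------------------------------------------------------------
# hydrogen inference

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("degenerate geometry (coincident atoms)")
    return v / n


def _bisector_h(d: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    direction = -_unit(_unit(n1 - d) + _unit(n2 - d))
    return d + H_BOND_LENGTH * direction


def _amine2_h(d: np.ndarray, parent: np.ndarray, grand: np.ndarray) -> list[np.ndarray]:
    e1 = _unit(d - parent)
    v = parent - grand
    p = v - np.dot(v, e1) * e1
    p = _unit(p)
    c, s = math.cos(math.radians(60.0)), math.sin(math.radians(60.0))
    return [d + H_BOND_LENGTH * (c * e1 + s * p),
            d + H_BOND_LENGTH * (c * e1 - s * p)]


def _h_names(donor_name: str, n: int) -> list[str]:
    suffix = donor_name[1:] if len(donor_name) > 1 else ""
    if n == 1:
        return [f"H{suffix}" if suffix else "H"]
    return [f"H{suffix}{i + 1}" for i in range(n)]


def infer_polar_hydrogens(s: Structure) -> Structure:
    """Place idealized hydrogens on geometrically determined donors.

    Backbone amides and other donors whose H position is fixed by the
    heavy-atom frame get hydrogens at ~1.0 Å; hydroxyls and other rotatable
    donors are left bare (detection then uses donor–acceptor criteria
    only). Donors that already carry a hydrogen are kept as-is. Donors with
    missing frame atoms are skipped with a warning.
    """
    residue_list = list(s.residues())
    by_key = {key: (resname, atoms) for key, resname, atoms in residue_list}
    # previous residue per chain, in atom order (for the backbone -C neighbor)
    prev_key: dict[ResidueKey, ResidueKey] = {}
    last_in_chain: dict[str, ResidueKey] = {}
    for key, _, _ in residue_list:
        if key[0] in last_in_chain:
            prev_key[key] = last_in_chain[key[0]]
        last_in_chain[key[0]] = key

    new_atoms: list[AtomRecord] = []
    for key, resname, atoms in residue_list:
        new_atoms.extend(atoms)
        donors, _ = lookup_residue(resname)
        coords = {a.atom_name: np.asarray(a.coords) for a in atoms}
        existing_h = [a for a in atoms if a.is_hydrogen]
        for spec in donors:
            if spec.kind == "ambiguous" or spec.atom not in coords:
                continue
            d = coords[spec.atom]
            if any(np.linalg.norm(np.asarray(h.coords) - d) <= H_COVALENT_CUTOFF
                   for h in existing_h):
                continue  # already protonated
            neighbor_xyz = []
            ok = True
            for nb in spec.neighbors:
                if nb == "-C":
                    pk = prev_key.get(key)
                    pc = by_key.get(pk) if pk else None
                    pos = None
                    if pc is not None:
                        for a in pc[1]:
                            if a.atom_name == "C":
                                pos = np.asarray(a.coords)
                    if pos is None:
                        ok = False  # chain start: no amide H frame
                        break
                    neighbor_xyz.append(pos)
                elif nb in coords:
                    neighbor_xyz.append(coords[nb])
                else:
                    warnings.warn(f"{key} {resname} donor {spec.atom}: missing "
                                  f"antecedent {nb}, skipped", stacklevel=2)
                    ok = False
                    break
            if not ok:
                continue
            if spec.kind == "bisector":
                positions = [_bisector_h(d, *neighbor_xyz)]
            else:  # amine2
                positions = _amine2_h(d, *neighbor_xyz)[:spec.n_h]
            for name, pos in zip(_h_names(spec.atom, len(positions)), positions):
                new_atoms.append(AtomRecord(key[0], key[1], key[2], resname,
                                            name, "H", tuple(float(x) for x in pos)))
    return Structure(new_atoms, dict(s.chain_entities), s.source_label)


# ---------------------------------------------------------------------------
# detection

@dataclass(frozen=True)
class HBond:
    """One detected hydrogen bond with its geometry."""

    donor: AtomRecord
    hydrogen: AtomRecord | None
    acceptor: AtomRecord
    acceptor_antecedent: AtomRecord
    d_DA: float
    d_HA: float | None
    angles: dict = field(default_factory=dict, compare=False, hash=False)
    interfacial: bool = False

    def key(self) -> tuple:
        return (self.donor.residue_key, self.donor.atom_name,
                self.acceptor.residue_key, self.acceptor.atom_name)


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, degrees."""
    u, v = _unit(a - b), _unit(c - b)
    return math.degrees(math.acos(np.clip(np.dot(u, v), -1.0, 1.0)))


def _collect_donors(s: Structure):
    out = []  # (donor AtomRecord, attached H AtomRecords)
    for key, resname, atoms in s.residues():
        donors, _ = lookup_residue(resname) if resname else ([], [])
        by_name = {a.atom_name: a for a in atoms}
        hs = [a for a in atoms if a.is_hydrogen]
        for spec in donors:
            donor = by_name.get(spec.atom)
            if donor is None:
                continue
            dpos = np.asarray(donor.coords)
            attached = [h for h in hs
                        if np.linalg.norm(np.asarray(h.coords) - dpos) <= H_COVALENT_CUTOFF]
            out.append((donor, attached))
    return out


def _collect_acceptors(s: Structure):
    out = []  # (acceptor AtomRecord, antecedent AtomRecord)
    for key, resname, atoms in s.residues():
        _, accs = lookup_residue(resname) if resname else ([], [])
        by_name = {a.atom_name: a for a in atoms}
        for spec in accs:
            acc = by_name.get(spec.atom)
            if acc is None:
                continue
            ant = by_name.get(spec.antecedent)
            if ant is None:
                warnings.warn(f"{key} {resname} acceptor {spec.atom}: missing "
                              f"antecedent {spec.antecedent}, skipped", stacklevel=2)
                continue
            out.append((acc, ant))
    return out


def detect_hbonds_static(s: Structure,
                         criteria: HBondCriteria | None = None) -> list[HBond]:
    """All hydrogen bonds in a structure under the static (HBPLUS) criteria.

    Donor/acceptor pairs in distinct residues with d(D,A) ≤ 3.9 Å are
    emitted when every applicable angle is ≥ 90° and, if the donor carries
    a hydrogen, some attached H has d(H,A) ≤ 2.5 Å with the D–H–A and
    H–A–AA angles also ≥ 90°. Bare (ambiguous) donors are judged on the
    D–A distance and the D–A–AA angle alone.
    """
    if criteria is None:
        criteria = HBondCriteria.static()
    if criteria.mode != "static":
        raise ValueError("detect_hbonds_static requires static-mode criteria")
    donors = _collect_donors(s)
    acceptors = _collect_acceptors(s)
    if not donors or not acceptors:
        return []
    acc_xyz = np.asarray([a.coords for a, _ in acceptors], dtype=float)
    tree = cKDTree(acc_xyz)
    bonds: list[HBond] = []
    for donor, hs in donors:
        dpos = np.asarray(donor.coords)
        for j in tree.query_ball_point(dpos, criteria.max_DA):
            acc, ant = acceptors[j]
            if acc.residue_key == donor.residue_key:
                continue
            apos, ntpos = np.asarray(acc.coords), np.asarray(ant.coords)
            d_da = float(np.linalg.norm(apos - dpos))
            ang_daa = _angle_deg(dpos, apos, ntpos)
            if ang_daa < criteria.min_angle_deg:
                continue
            best = None
            if hs:
                for h in hs:
                    hpos = np.asarray(h.coords)
                    d_ha = float(np.linalg.norm(apos - hpos))
                    if d_ha > criteria.max_HA:
                        continue
                    ang_dha = _angle_deg(dpos, hpos, apos)
                    ang_haa = _angle_deg(hpos, apos, ntpos)
                    if ang_dha < criteria.min_angle_deg or ang_haa < criteria.min_angle_deg:
                        continue
                    if best is None or d_ha < best[1]:
                        best = (h, d_ha, ang_dha, ang_haa)
                if best is None:
                    continue  # has H but no H satisfies the criteria
            if best is not None:
                h, d_ha, ang_dha, ang_haa = best
                angles = {"D-H-A": ang_dha, "H-A-AA": ang_haa, "D-A-AA": ang_daa}
                bonds.append(HBond(donor, h, acc, ant, d_da, d_ha, angles))
            else:
                bonds.append(HBond(donor, None, acc, ant, d_da, None,
                                   {"D-A-AA": ang_daa}))
    return bonds


def detect_hbonds_md(s: Structure,
                     criteria: HBondCriteria | None = None) -> list[HBond]:
    """Hydrogen bonds under the MD criteria (0.35 nm D–A, H–D–A ≤ 30°)."""
    if criteria is None:
        criteria = HBondCriteria.md()
    if criteria.mode != "md":
        raise ValueError("detect_hbonds_md requires md-mode criteria")
    donors = _collect_donors(s)
    acceptors = _collect_acceptors(s)
    if not donors or not acceptors:
        return []
    acc_xyz = np.asarray([a.coords for a, _ in acceptors], dtype=float)
    tree = cKDTree(acc_xyz)
    bonds: list[HBond] = []
    for donor, hs in donors:
        dpos = np.asarray(donor.coords)
        for j in tree.query_ball_point(dpos, criteria.max_DA):
            acc, ant = acceptors[j]
            if acc.residue_key == donor.residue_key:
                continue
            apos = np.asarray(acc.coords)
            d_da = float(np.linalg.norm(apos - dpos))
            best = None
            if hs:
                for h in hs:
                    ang_hda = _angle_deg(np.asarray(h.coords), dpos, apos)
                    if ang_hda > criteria.max_angle_HDA_deg:
                        continue
                    if best is None or ang_hda < best[1]:
                        best = (h, ang_hda)
                if best is None:
                    continue
            if best is not None:
                h, ang_hda = best
                bonds.append(HBond(donor, h, acc, ant, d_da,
                                   float(np.linalg.norm(apos - np.asarray(h.coords))),
                                   {"H-D-A": ang_hda}))
            else:
                bonds.append(HBond(donor, None, acc, ant, d_da, None, {}))
    return bonds


def filter_interfacial(bonds: list[HBond], protein_chains: list[str],
                       aptamer_chains: list[str]) -> list[HBond]:
    """Keep only protein↔aptamer bonds (either donation direction)."""
    prot, apt = set(protein_chains), set(aptamer_chains)
    out = []
    for b in bonds:
        dc, ac = b.donor.chain_id, b.acceptor.chain_id
        if (dc in prot and ac in apt) or (dc in apt and ac in prot):
            out.append(HBond(b.donor, b.hydrogen, b.acceptor,
                             b.acceptor_antecedent, b.d_DA, b.d_HA,
                             b.angles, interfacial=True))
    return out


# ---------------------------------------------------------------------------
# comparison

@dataclass
class HBondComparison:
    """Matched/unmatched decomposition of two bond sets with P/R/F1."""

    matched: list[tuple[HBond, HBond]]
    gt_only: list[HBond]
    pred_only: list[HBond]

    @property
    def precision(self) -> float:
        denom = len(self.matched) + len(self.pred_only)
        return len(self.matched) / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = len(self.matched) + len(self.gt_only)
        return len(self.matched) / denom if denom else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def _bond_match_key(b: HBond, lut: dict | None, level: str) -> frozenset | None:
    """Role-insensitive identity of a bond, in the prediction's keyspace."""
    sides = []
    for atom in (b.donor, b.acceptor):
        rk = atom.residue_key
        if lut is not None:
            rk = lut.get(rk)
            if rk is None:
                return None  # residue unmapped: bond cannot match
        sides.append((rk, atom.atom_name) if level == "atom" else rk)
    return frozenset(sides)  # donor/acceptor lie in distinct residues


def compare_hbonds(gt_bonds: list[HBond], pred_bonds: list[HBond],
                   m: ResidueMap, match_level: str = "atom") -> HBondComparison:
    """Match predicted against reference interfacial bonds.

    Identity is (residue, atom name) on each side, with donor/acceptor
    roles disregarded; reference residues are translated into the
    prediction's keyspace through ``m`` (which must cover both the protein
    and the aptamer chains — aptamer correspondence is positional since
    the sequences are identical by construction). ``match_level="residue"``
    coarsens identity to the residue pair, counting at most one bond per
    residue pair. Each bond matches at most once.
    """
    if match_level not in ("atom", "residue"):
        raise ValueError("match_level must be 'atom' or 'residue'")
    lut = m.as_dict()
    if match_level == "residue":
        gt_bonds = _dedupe_by_respair(gt_bonds)
        pred_bonds = _dedupe_by_respair(pred_bonds)
    pred_pool: dict[frozenset, list[HBond]] = {}
    for b in pred_bonds:
        k = _bond_match_key(b, None, match_level)
        pred_pool.setdefault(k, []).append(b)
    matched, gt_only = [], []
    for g in gt_bonds:
        k = _bond_match_key(g, lut, match_level)
        pool = pred_pool.get(k) if k is not None else None
        if pool:
            matched.append((g, pool.pop(0)))
        else:
            gt_only.append(g)
    pred_only = [b for pool in pred_pool.values() for b in pool]
    return HBondComparison(matched, gt_only, pred_only)


def _dedupe_by_respair(bonds: list[HBond]) -> list[HBond]:
    seen: set[frozenset] = set()
    out = []
    for b in bonds:
        k = frozenset((b.donor.residue_key, b.acceptor.residue_key))
        if k not in seen:
            seen.add(k)
            out.append(b)
    return out


# ---------------------------------------------------------------------------
# trajectories

def hbond_timeseries(traj: Trajectory, criteria: HBondCriteria | None = None,
                     protein_chains: list[str] | None = None,
                     aptamer_chains: list[str] | None = None) -> TimeSeries:
    """Interfacial hydrogen-bond count per frame under the MD criteria.

    Topologies that already carry explicit hydrogens are used as-is;
    otherwise polar hydrogens are rebuilt per frame from the frame's heavy
    atoms.
    """
    if criteria is None:
        criteria = HBondCriteria.md()
    topo = traj.topology
    if protein_chains is None:
        protein_chains = topo.protein_chains
    if aptamer_chains is None:
        aptamer_chains = topo.nucleic_chains
    has_h = any(a.is_hydrogen for a in topo.atoms)
    times, counts = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-frame inference repeats warnings
        for t, xyz in traj:
            frame = topo.with_coords(xyz)
            if not has_h:
                frame = infer_polar_hydrogens(frame)
            bonds = detect_hbonds_md(frame, criteria)
            bonds = filter_interfacial(bonds, protein_chains, aptamer_chains)
            times.append(t)
            counts.append(float(len(bonds)))
    if not any(counts) and not _collect_donors(topo):
        warnings.warn("no donors/acceptors in topology: H-bond series is all "
                      "zero", stacklevel=2)
    return TimeSeries("interfacial_hbonds", times, counts, "count")
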