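"""Toy protein–aptamer complexes and scripted trajectories with planted truth.

Fixtures are chemically plausible but idealized: a widely spaced poly-ALA
chain (so residue-level contacts stay independent) faces a poly-dT
"aptamer" whose nucleotides are rigid template copies. The generator plants
an exactly known pocket (which protein residues have an aptamer heavy atom
within the contact cutoff), an exactly known set of interfacial hydrogen
bonds with comfortable geometric margin, and — for trajectories — an
exactly known per-frame pocket occupancy. Every planted fact is re-derived
from the emitted coordinates by an independent brute-force check before
the fixture is returned; generation fails rather than emit unverified
truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hbond import (HBondCriteria, _bisector_h, detect_hbonds_static,
                    filter_interfacial)
from .structure import AtomRecord, ResidueKey, Structure, Trajectory

__all__ = ["ToyComplexSpec", "PlantedTruth", "make_toy_complex",
           "make_toy_trajectory", "GenerationError"]

RESIDUE_SPACING = 12.0  # A between protein residues: contacts stay local
POCKET_CUTOFF = 4.5
HBOND_DA = 2.9  # planted donor-acceptor distance, comfortably inside 3.9


class GenerationError(RuntimeError):
    """A fixture could not be built or failed its brute-force verification."""


@dataclass(frozen=True)
class ToyComplexSpec:
    """Parameters of a planted toy complex."""

    n_protein_res: int = 12
    n_apt_nt: int = 8
    n_contact_res: int = 4
    n_hbonds: int = 2
    perturbation: float = 0.0  # A of Gaussian noise for the derived "prediction"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contact_res > self.n_apt_nt:
            raise ValueError("each planted contact consumes one nucleotide: "
                             "n_contact_res must not exceed n_apt_nt")
        if self.n_contact_res > self.n_protein_res - 2:
            raise ValueError("need n_protein_res >= n_contact_res + 2 "
                             "(terminal residues are never contact sites)")
        if self.n_hbonds > self.n_contact_res:
            raise ValueError("every planted H-bond lives on a contact residue: "
                             "n_hbonds must not exceed n_contact_res")
        if self.perturbation < 0:
            raise ValueError("perturbation must be non-negative")


@dataclass
class PlantedTruth:
    """Ground truth recorded (and brute-force verified) at generation time."""

    pocket_keys: set[ResidueKey] = field(default_factory=set)
    hbond_keys: list[tuple] = field(default_factory=list)
    po_expected: list[float] = field(default_factory=list)
    rmsd_expected: list[float] | None = None


# -- rigid templates (local coordinates, Angstrom) ---------------------------

_ALA = {
    "N": (-1.458, 0.0, 0.0),
    "CA": (0.0, 0.0, 0.0),
    "C": (0.55, 1.42, 0.0),
    "O": (1.70, 1.86, 0.0),
    "CB": (-0.54, -0.77, 1.20),
}

# thymidine: planar base hexagon + approximate sugar/phosphate cluster
_DT = {
    "N1": (1.39, 0.0, 0.0), "C2": (0.695, 1.204, 0.0),
    "N3": (-0.695, 1.204, 0.0), "C4": (-1.39, 0.0, 0.0),
    "C5": (-0.695, -1.204, 0.0), "C6": (0.695, -1.204, 0.0),
    "O2": (1.31, 2.27, 0.0), "O4": (-2.62, 0.0, 0.0),
    "C7": (-1.31, -2.27, 0.0),
    "C1'": (2.86, 0.0, 0.0), "O4'": (3.6, 1.0, 0.8),
    "C2'": (3.5, -1.2, 0.4), "C3'": (4.9, -1.0, 0.6),
    "O3'": (5.5, -2.2, 1.0), "C4'": (5.0, 0.4, 1.0),
    "C5'": (5.9, 1.3, 0.2), "O5'": (6.3, 2.4, 1.0),
    "P": (7.6, 3.0, 0.6), "OP1": (8.6, 2.2, 0.0), "OP2": (7.9, 4.1, 1.5),
}

_DT_ELEMENTS = {name: name[0] for name in _DT}


def _rotation_between(u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix carrying unit vector u onto unit vector w."""
    u = u / np.linalg.norm(u)
    w = w / np.linalg.norm(w)
    v = np.cross(u, w)
    c = float(np.dot(u, w))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any axis orthogonal to u
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return _axis_rotation(axis, math.pi)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * K @ K


def _place_nucleotide(anchor_atom: str, anchor_pos: np.ndarray,
                      direction: np.ndarray, spin: float) -> dict[str, np.ndarray]:
    """Rigidly place the DT template.

    The template is rotated so the vector from ``anchor_atom`` toward the
    base centroid aligns with ``direction`` (pointing away from the
    protein), spun by ``spin`` radians about that axis, then translated so
    ``anchor_atom`` sits at ``anchor_pos``.
    """
    xyz = {k: np.asarray(v, dtype=float) for k, v in _DT.items()}
    centroid = np.mean([xyz[a] for a in ("N1", "C2", "N3", "C4", "C5", "C6")],
                       axis=0)
    u = centroid - xyz[anchor_atom]
    if np.linalg.norm(u) < 1e-9:
        u = np.array([1.0, 0.0, 0.0])
    R = _rotation_between(u, direction)
    R = _axis_rotation(direction, spin) @ R
    a0 = xyz[anchor_atom]
    return {k: R @ (v - a0) + anchor_pos for k, v in xyz.items()}


def _protein_chain(n_res: int) -> list[AtomRecord]:
    atoms = []
    for i in range(n_res):
        offset = np.array([RESIDUE_SPACING * i, 0.0, 0.0])
        for name in ("N", "CA", "C", "O", "CB"):
            pos = offset + np.asarray(_ALA[name])
            atoms.append(AtomRecord("A", i + 1, "", "ALA", name, name[0],
                                    tuple(pos)))
    return atoms


def _nucleotide_atoms(index: int, placed: dict[str, np.ndarray]) -> list[AtomRecord]:
    return [AtomRecord("B", index, "", "DT", name, _DT_ELEMENTS[name],
                       tuple(float(x) for x in placed[name]))
            for name in _DT]


def _brute_force_pocket(s: Structure, cutoff: float = POCKET_CUTOFF) -> set[ResidueKey]:
    """Independent O(N^2) contact pocket (no spatial index)."""
    apt = [(a.residue_key, np.asarray(a.coords)) for a in s.atoms
           if s.chain_entities.get(a.chain_id) == "nucleic" and not a.is_hydrogen]
    pocket = set()
    for a in s.atoms:
        if s.chain_entities.get(a.chain_id) != "protein" or a.is_hydrogen:
            continue
        p = np.asarray(a.coords)
        if any(np.linalg.norm(p - q) <= cutoff for _, q in apt):
            pocket.add(a.residue_key)
    return pocket


def _brute_force_po(s: Structure, xyz: np.ndarray, pocket: set[ResidueKey],
                    cutoff: float = POCKET_CUTOFF) -> float:
    apt_idx = [i for i, a in enumerate(s.atoms)
               if s.chain_entities.get(a.chain_id) == "nucleic" and not a.is_hydrogen]
    pocket_idx = [i for i, a in enumerate(s.atoms)
                  if a.residue_key in pocket and not a.is_hydrogen]
    if not apt_idx:
        raise GenerationError("no aptamer atoms")
    if not pocket_idx:
        return 0.0
    d = np.linalg.norm(xyz[apt_idx][:, None, :] - xyz[pocket_idx][None, :, :],
                       axis=2)
    return float(np.count_nonzero(d.min(axis=1) <= cutoff)) / len(apt_idx)


def make_toy_complex(spec: ToyComplexSpec) -> tuple[Structure, Structure, PlantedTruth]:
    """Build (reference, perturbed prediction, planted truth).

    Contact sites are interior protein residues; the first ``n_hbonds`` of
    them receive a nucleotide whose O4 acceptor sits 2.9 Å from the
    backbone amide nitrogen along the idealized N–H direction (near-linear
    bond, comfortably inside every static criterion); the remaining
    contact sites receive a nucleotide approaching through its apolar
    methyl carbon, close enough to count as a contact but with every polar
    pair out of hydrogen-bond range. Leftover nucleotides are parked far
    from the protein. The planted pocket and bond list are verified
    against brute-force re-detection before returning.
    """
    rng = np.random.default_rng(spec.seed)
    protein = _protein_chain(spec.n_protein_res)
    by_name = {(a.residue_index, a.atom_name): np.asarray(a.coords)
               for a in protein}

    # interior residues, spread evenly, as contact sites
    candidates = list(range(2, spec.n_protein_res))  # 1-based, skip termini
    if spec.n_contact_res:
        pick = np.linspace(0, len(candidates) - 1, spec.n_contact_res)
        sites = [candidates[int(round(p))] for p in pick]
    else:
        sites = []
    if len(set(sites)) != len(sites):
        raise GenerationError("could not choose distinct contact residues")

    truth = PlantedTruth()
    apt_atoms: list[AtomRecord] = []
    nt_index = 0
    for j, res_i in enumerate(sites):
        nt_index += 1
        if j < spec.n_hbonds:
            # plant a hydrogen bond: acceptor O4 along the amide N-H direction
            npos = by_name[(res_i, "N")]
            prev_c = by_name[(res_i - 1, "C")]
            ca = by_name[(res_i, "CA")]
            h = _bisector_h(npos, prev_c, ca)
            direction = (h - npos) / np.linalg.norm(h - npos)
            anchor, anchor_pos = "O4", npos + HBOND_DA * direction
            truth.hbond_keys.append((("A", res_i, ""), "N",
                                     ("B", nt_index, ""), "O4"))
        else:
            # contact through the apolar methyl: no hydrogen-bond geometry
            cb = by_name[(res_i, "CB")]
            direction = np.array([0.0, -0.94, -0.33])
            direction /= np.linalg.norm(direction)
            anchor, anchor_pos = "C7", cb + 3.5 * direction
        placed = None
        for spin_step in range(12):  # deterministic spins until clean placement
            trial = _place_nucleotide(anchor, anchor_pos, direction,
                                      spin=spin_step * math.pi / 6)
            if _placement_clean(trial, protein, res_i, planted_bond=j < spec.n_hbonds):
                placed = trial
                break
        if placed is None:
            raise GenerationError(f"could not place nucleotide {nt_index} at "
                                  f"residue {res_i} without side contacts")
        apt_atoms.extend(_nucleotide_atoms(nt_index, placed))
        truth.pocket_keys.add(("A", res_i, ""))

    for _ in range(spec.n_apt_nt - spec.n_contact_res):  # parked, far away
        nt_index += 1
        offset = np.array([RESIDUE_SPACING * nt_index, -40.0,
                           10.0 * (nt_index % 3)])
        placed = {k: np.asarray(v) + offset for k, v in _DT.items()}
        apt_atoms.extend(_nucleotide_atoms(nt_index, placed))

    gt = Structure(protein + apt_atoms, {}, source_label=f"toy-{spec.seed}")

    # brute-force verification of every planted fact
    pocket = _brute_force_pocket(gt)
    if pocket != truth.pocket_keys:
        raise GenerationError(f"pocket verification failed: planted "
                              f"{sorted(truth.pocket_keys)}, found {sorted(pocket)}")
    found = _verify_hbonds(gt)
    if found != set(map(tuple, truth.hbond_keys)):
        raise GenerationError(f"H-bond verification failed: planted "
                              f"{truth.hbond_keys}, found {sorted(found)}")

    if spec.perturbation > 0:
        noise = rng.normal(0.0, spec.perturbation, size=(len(gt.atoms), 3))
        pred = gt.with_coords(gt.coords + noise)
    else:
        pred = gt.with_coords(gt.coords)
    pred.source_label = f"toy-{spec.seed}-pred"
    return gt, pred, truth


def _placement_clean(placed: dict[str, np.ndarray], protein: list[AtomRecord],
                     contact_res: int, planted_bond: bool) -> bool:
    """No contacts outside the intended residue; no stray polar proximity."""
    polar = {k: v for k, v in placed.items() if k[0] in "NO"}
    for a in protein:
        p = np.asarray(a.coords)
        for name, q in placed.items():
            d = float(np.linalg.norm(p - q))
            if a.residue_index != contact_res and d <= POCKET_CUTOFF + 0.5:
                return False
            if a.atom_name[0] in "NO" and name in polar:
                if planted_bond and a.residue_index == contact_res \
                        and a.atom_name == "N" and name == "O4":
                    continue  # the planted pair itself
                if d <= 4.4:  # margin beyond the 3.9 A donor-acceptor limit
                    return False
    return True


def _verify_hbonds(gt: Structure) -> set[tuple]:
    """Interfacial static H-bonds found by the detector on the fixture."""
    import warnings as _w
    from .hbond import infer_polar_hydrogens
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        protonated = infer_polar_hydrogens(gt)
        bonds = detect_hbonds_static(protonated, HBondCriteria.static())
        bonds = filter_interfacial(bonds, gt.protein_chains, gt.nucleic_chains)
    return {(b.donor.residue_key, b.donor.atom_name,
             b.acceptor.residue_key, b.acceptor.atom_name) for b in bonds}


def make_toy_trajectory(s: Structure, mode: str = "stable", n_frames: int = 20,
                        dt_ps: float = 10.0, noise: float = 0.0,
                        seed: int = 0) -> tuple[Trajectory, PlantedTruth]:
    """Scripted trajectory over a toy complex, with per-frame planted truth.

    ``stable``: i.i.d. Gaussian jitter about the input coordinates.
    ``drift``: a growing whole-complex rigid motion plus jitter (protein-fit
    analysis must see through it).
    ``dissociate``: the aptamer translates away linearly, far enough that
    no aptamer atom remains within the contact cutoff by the final frame.

    Truth carries per-frame pocket occupancy recomputed by brute force on
    the emitted coordinates, and the expected analysis-group RMSD where it
    has a closed form (noise-free trajectories).
    """
    if mode not in ("stable", "drift", "dissociate"):
        raise ValueError(f"unknown trajectory mode {mode!r}")
    rng = np.random.default_rng(seed)
    base = s.coords
    apt_mask = np.array([s.chain_entities.get(a.chain_id) == "nucleic"
                         for a in s.atoms])
    if mode == "dissociate" and not apt_mask.any():
        raise ValueError("dissociation needs a nucleic chain")
    frames, rmsd_expected = [], []
    total_shift = 80.0  # final aptamer displacement, A; >> contact cutoff
    for k in range(n_frames):
        xyz = base.copy()
        if mode == "drift":
            angle = math.radians(2.0 * (k + 1))
            R = _axis_rotation(np.array([0.0, 0.0, 1.0]), angle)
            center = base.mean(axis=0)
            xyz = (xyz - center) @ R.T + center + (k + 1) * np.array([0.5, 0.3, 0.2])
            rmsd_expected.append(0.0)  # rigid motion is removed by fitting
        elif mode == "dissociate":
            shift = total_shift * (k / max(n_frames - 1, 1))
            xyz[apt_mask] += np.array([0.0, -shift, 0.0])
            rmsd_expected.append(shift)  # pure translation of the analysis group
        else:
            rmsd_expected.append(0.0)
        if noise > 0:
            xyz = xyz + rng.normal(0.0, noise, size=xyz.shape)
        frames.append(xyz)
    times = [dt_ps * (k + 1) for k in range(n_frames)]
    traj = Trajectory(s, times, frames)

    truth = PlantedTruth(rmsd_expected=(rmsd_expected if noise == 0 else None))
    pocket = _brute_force_pocket(s)
    truth.pocket_keys = pocket
    for xyz in frames:
        truth.po_expected.append(_brute_force_po(s, xyz, pocket))
    if mode == "dissociate" and truth.po_expected[-1] != 0.0:
        raise GenerationError("dissociation did not empty the pocket")
    return traj, truth
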