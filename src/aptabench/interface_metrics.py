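"""Binding-pocket definition, pocket occupancy, lDDT/iLDDT and thresholds.

The binding pocket is contact-defined: protein residues with at least one
heavy atom within 4.5 Å (inclusive) of any aptamer heavy atom in the
reference complex. Because predicted models rarely share the reference's
residue numbering, the pocket is carried to a prediction through a
sequence-derived :class:`~aptabench.seq_mapping.ResidueMap`, never by raw
residue numbers.

Pocket occupancy PO(t) = N_atom,t / N_atom,total — the fraction of aptamer
atoms within the cutoff of any pocket-residue atom at frame t — quantifies
whether the aptamer stays associated with the pocket along a trajectory.

lDDT is the local distance difference test: over all reference heavy-atom
pairs within the inclusion radius (same-residue pairs excluded), the mean
over the thresholds {0.5, 1, 2, 4} Å of the fraction of pairs whose model
distance reproduces the reference distance within the threshold, on a
0–100 scale. ``interface_only=True`` restricts the pairs to inter-chain
contacts (iLDDT); a complex whose chains never approach within the radius
has no qualifying pairs and gets no score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .seq_mapping import ResidueMap
from .structure import ResidueKey, Structure, TimeSeries, Trajectory

__all__ = [
    "PocketDefinition", "define_pocket", "map_pocket", "pocket_occupancy",
    "lddt_score", "classify_interface", "classify_iptm",
    "ILDDT_CORRECT", "ILDDT_VERY_HIGH", "IPTM_INCORRECT", "IPTM_HIGH",
]

#: iLDDT (%) boundaries matching the DockQ "correct" / "very high" categories.
ILDDT_CORRECT = 23.6
ILDDT_VERY_HIGH = 77.6

#: ipTM boundaries: below → incorrect assembly, above → high quality.
IPTM_INCORRECT = 0.6
IPTM_HIGH = 0.8

DEFAULT_POCKET_CUTOFF = 4.5
LDDT_INCLUSION_RADIUS = 15.0
LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)


@dataclass
class PocketDefinition:
    """Contact pocket on the reference plus its image in a prediction."""

    cutoff: float
    gt_pocket_residues: set[ResidueKey]
    mapped_pocket_residues: set[ResidueKey] = field(default_factory=set)
    unmapped: list[ResidueKey] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


def define_pocket(gt: Structure, cutoff: float = DEFAULT_POCKET_CUTOFF) -> PocketDefinition:
    """Protein residues with a heavy atom within ``cutoff`` of the aptamer.

    The boundary is inclusive (a heavy atom at exactly ``cutoff`` counts).
    Requires a sanitized complex with at least one protein and one nucleic
    chain.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    apt_mask = gt.select(entity="nucleic", heavy_only=True)
    if not apt_mask.any():
        raise ValueError("no aptamer component: structure has no nucleic chain")
    prot_mask = gt.select(entity="protein", heavy_only=True)
    if not prot_mask.any():
        raise ValueError("structure has no protein chain")
    coords = gt.coords
    tree = cKDTree(coords[apt_mask])
    dmin, _ = tree.query(coords[prot_mask], k=1)
    pocket: set[ResidueKey] = set()
    prot_atoms = [a for a, m in zip(gt.atoms, prot_mask) if m]
    for atom, d in zip(prot_atoms, dmin):
        if d <= cutoff:
            pocket.add(atom.residue_key)
    return PocketDefinition(cutoff, pocket)


def map_pocket(p: PocketDefinition, m: ResidueMap) -> PocketDefinition:
    """Carry a reference pocket into a prediction via a residue map.

    Pocket residues without a counterpart are recorded in ``unmapped`` and
    logged; an empty image is allowed (and flagged), not an error.
    """
    lut = m.as_dict()
    mapped: set[ResidueKey] = set()
    missing: list[ResidueKey] = []
    for key in sorted(p.gt_pocket_residues):
        if key in lut:
            mapped.add(lut[key])
        else:
            missing.append(key)
    if missing:
        warnings.warn(f"{len(missing)} pocket residue(s) have no counterpart "
                      "in the prediction", stacklevel=2)
    return PocketDefinition(p.cutoff, set(p.gt_pocket_residues), mapped, missing)


def pocket_occupancy(traj: Trajectory, pocket: set[ResidueKey],
                     aptamer_chains: list[str] | None = None,
                     cutoff: float = DEFAULT_POCKET_CUTOFF,
                     include_hydrogens: bool = False) -> TimeSeries:
    """Fraction of aptamer atoms inside the pocket, per frame.

    ``N_atom,total`` is the aptamer atom count of the topology (heavy atoms
    by default, for comparability with dehydrogenated references; set
    ``include_hydrogens=True`` to count all atoms, as a protonated MD system
    would).
    """
    topo = traj.topology
    if aptamer_chains is None:
        aptamer_chains = topo.nucleic_chains
    apt_mask = topo.select(chains=aptamer_chains, heavy_only=not include_hydrogens)
    n_total = int(apt_mask.sum())
    if n_total == 0:
        raise ValueError("zero aptamer atoms in topology")
    pocket_mask = np.array(
        [(a.residue_key in pocket) and not (a.is_hydrogen and not include_hydrogens)
         for a in topo.atoms], dtype=bool)
    times, values = [], []
    if not pocket_mask.any():
        warnings.warn("empty pocket selection: pocket occupancy is all zero",
                      stacklevel=2)
        return TimeSeries("pocket_occupancy", list(traj.times_ps),
                          [0.0] * len(traj), "fraction")
    for t, xyz in traj:
        tree = cKDTree(xyz[pocket_mask])
        dmin, _ = tree.query(xyz[apt_mask], k=1)
        times.append(t)
        values.append(float(np.count_nonzero(dmin <= cutoff)) / n_total)
    return TimeSeries("pocket_occupancy", times, values, "fraction")


def _paired_coords(ref: Structure, model: Structure, m: ResidueMap):
    """Heavy atoms of ref matched by residue map + atom name in model."""
    lut = m.as_dict()
    model_atoms = model.atom_lookup()
    ref_xyz, mod_xyz, chain_ids, res_ids = [], [], [], []
    res_index: dict[ResidueKey, int] = {}
    for a in ref.atoms:
        if a.is_hydrogen:
            continue
        target = lut.get(a.residue_key)
        if target is None:
            continue
        mate = model_atoms.get((target[0], target[1], target[2], a.atom_name))
        if mate is None or mate.is_hydrogen:
            continue
        ref_xyz.append(a.coords)
        mod_xyz.append(mate.coords)
        chain_ids.append(a.chain_id)
        res_ids.append(res_index.setdefault(a.residue_key, len(res_index)))
    return (np.asarray(ref_xyz, dtype=float), np.asarray(mod_xyz, dtype=float),
            np.asarray(chain_ids), np.asarray(res_ids))


def lddt_score(ref: Structure, model: Structure, m: ResidueMap,
               inclusion_radius: float = LDDT_INCLUSION_RADIUS,
               thresholds: tuple[float, ...] = LDDT_THRESHOLDS,
               interface_only: bool = False) -> float | None:
    """lDDT of ``model`` against ``ref`` over mapped heavy atoms, in percent.

    Returns ``None`` when no qualifying atom pair exists (for
    ``interface_only``, a complex without inter-chain contacts inside the
    inclusion radius).
    """
    ref_xyz, mod_xyz, chains, res_ids = _paired_coords(ref, model, m)
    if len(ref_xyz) == 0:
        raise ValueError("no mappable atoms between reference and model")
    tree = cKDTree(ref_xyz)
    pairs = np.asarray(sorted(tree.query_pairs(inclusion_radius)), dtype=int)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        keep = res_ids[i] != res_ids[j]
        if interface_only:
            keep &= chains[i] != chains[j]
        pairs = pairs[keep]
    if len(pairs) == 0:
        return None
    i, j = pairs[:, 0], pairs[:, 1]
    d_ref = np.linalg.norm(ref_xyz[i] - ref_xyz[j], axis=1)
    d_mod = np.linalg.norm(mod_xyz[i] - mod_xyz[j], axis=1)
    err = np.abs(d_mod - d_ref)
    fractions = [float(np.mean(err < t)) for t in thresholds]
    return 100.0 * float(np.mean(fractions))


def classify_interface(ilddt: float) -> str:
    """DockQ-aligned category for an iLDDT score on the 0–100 scale."""
    if not 0.0 <= ilddt <= 100.0:
        raise ValueError(f"iLDDT {ilddt} outside [0, 100]")
    if ilddt < ILDDT_CORRECT:
        return "incorrect"
    if ilddt < ILDDT_VERY_HIGH:
        return "correct"
    return "very_high"


def classify_iptm(iptm: float, scale_to_100: bool = False) -> str | tuple[str, float]:
    """Confidence category for an ipTM score in [0, 1].

    Below 0.6 the assembly is predicted incorrect; above 0.8 high quality;
    between, uncertain. With ``scale_to_100`` the rescaled value (×100, the
    reporting scale shared with iLDDT) is returned alongside the label.
    """
    if not 0.0 <= iptm <= 1.0:
        raise ValueError(f"ipTM {iptm} outside [0, 1]")
    if iptm < IPTM_INCORRECT:
        label = "incorrect"
    elif iptm <= IPTM_HIGH:
        label = "uncertain"
    else:
        label = "high"
    if scale_to_100:
        return label, iptm * 100.0
    return label
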