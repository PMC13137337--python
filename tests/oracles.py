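"""Independent brute-force evaluators used to cross-check the package.

These deliberately avoid the library's computational paths: no spatial
indexing, no dynamic programming, no vectorized shortcuts — plain
enumeration over all pairs / all alignments, slow but unarguable.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from aptabench.hbond import lookup_residue


def dist(p, q) -> float:
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def angle_deg(a, b, c) -> float:
    u = np.asarray(a) - np.asarray(b)
    v = np.asarray(c) - np.asarray(b)
    cosv = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


def brute_pocket(s, cutoff=4.5) -> set:
    """Protein residues with >=1 heavy atom within cutoff of any aptamer
    heavy atom; O(N^2) over explicit atom lists."""
    apt = [a for a in s.atoms
           if s.chain_entities.get(a.chain_id) == "nucleic" and not a.is_hydrogen]
    pocket = set()
    for a in s.atoms:
        if s.chain_entities.get(a.chain_id) != "protein" or a.is_hydrogen:
            continue
        if any(dist(a.coords, b.coords) <= cutoff for b in apt):
            pocket.add(a.residue_key)
    return pocket


def brute_po(s, xyz, pocket_keys, cutoff=4.5) -> float:
    """Fraction of aptamer heavy atoms within cutoff of pocket-residue
    heavy atoms in a coordinate frame."""
    apt_idx = [i for i, a in enumerate(s.atoms)
               if s.chain_entities.get(a.chain_id) == "nucleic" and not a.is_hydrogen]
    pocket_idx = [i for i, a in enumerate(s.atoms)
                  if a.residue_key in pocket_keys and not a.is_hydrogen]
    if not pocket_idx:
        return 0.0
    n_in = 0
    for i in apt_idx:
        if any(dist(xyz[i], xyz[j]) <= cutoff for j in pocket_idx):
            n_in += 1
    return n_in / len(apt_idx)


def brute_lddt(ref, model, inclusion_radius=15.0,
               thresholds=(0.5, 1.0, 2.0, 4.0), interface_only=False):
    """lDDT between two identically-keyed structures, all-pairs enumeration."""
    model_xyz = {a.atom_key: a.coords for a in model.atoms if not a.is_hydrogen}
    ref_atoms = [a for a in ref.atoms
                 if not a.is_hydrogen and a.atom_key in model_xyz]
    kept = []
    for a, b in itertools.combinations(ref_atoms, 2):
        if a.residue_key == b.residue_key:
            continue
        if interface_only and a.chain_id == b.chain_id:
            continue
        d_ref = dist(a.coords, b.coords)
        if d_ref > inclusion_radius:
            continue
        d_mod = dist(model_xyz[a.atom_key], model_xyz[b.atom_key])
        kept.append(abs(d_mod - d_ref))
    if not kept:
        return None
    fractions = [sum(e < t for e in kept) / len(kept) for t in thresholds]
    return 100.0 * sum(fractions) / len(fractions)


def brute_hbonds_static(s, max_HA=2.5, max_DA=3.9, min_angle=90.0) -> set:
    """Static-criteria hydrogen bonds by full donor x acceptor enumeration.

    Returns {(donor residue key, donor atom, acceptor residue key,
    acceptor atom)}. Uses the package's chemistry tables (shared data) but
    none of its detection code.
    """
    residues = list(s.residues())
    donors, acceptors, hydrogens = [], [], {}
    for key, resname, atoms in residues:
        dspecs, aspecs = lookup_residue(resname)
        names = {a.atom_name: a for a in atoms}
        hs = [a for a in atoms if a.is_hydrogen]
        for spec in dspecs:
            if spec.atom in names:
                donor = names[spec.atom]
                attached = [h for h in hs
                            if dist(h.coords, donor.coords) <= 1.25]
                donors.append(donor)
                hydrogens[donor.atom_key] = attached
        for spec in aspecs:
            if spec.atom in names and spec.antecedent in names:
                acceptors.append((names[spec.atom], names[spec.antecedent]))
    found = set()
    for donor in donors:
        for acc, ant in acceptors:
            if acc.residue_key == donor.residue_key:
                continue
            d_da = dist(donor.coords, acc.coords)
            if d_da > max_DA:
                continue
            if angle_deg(donor.coords, acc.coords, ant.coords) < min_angle:
                continue
            hs = hydrogens[donor.atom_key]
            if hs:
                ok = any(
                    dist(h.coords, acc.coords) <= max_HA
                    and angle_deg(donor.coords, h.coords, acc.coords) >= min_angle
                    and angle_deg(h.coords, acc.coords, ant.coords) >= min_angle
                    for h in hs)
                if not ok:
                    continue
            found.add((donor.residue_key, donor.atom_name,
                       acc.residue_key, acc.atom_name))
    return found


def brute_global_align_score(a: str, b: str, match=1.0, mismatch=-1.0,
                             gap_open=-2.0, gap_extend=-1.0) -> float:
    """Maximum global alignment score by exhaustive enumeration.

    Enumerates every monotone alignment (sequences of match/insert/delete
    moves); affine gaps cost gap_open for the first and gap_extend for each
    further gap in a run. Exponential — lengths <= 6 only.
    """
    best = -math.inf

    def rec(i, j, score, prev_move):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, "m")
        if i < len(a):
            cost = gap_extend if prev_move == "d" else gap_open
            rec(i + 1, j, score + cost, "d")
        if j < len(b):
            cost = gap_extend if prev_move == "i" else gap_open
            rec(i, j + 1, score + cost, "i")

    rec(0, 0, 0.0, "")
    return best


def brute_kabsch_rmsd(mobile, reference, n_grid=40) -> float:
    """Minimum RMSD over a dense grid of rotations (Euler angles) with
    optimal translation per rotation. Lower-bounds quality of the exact
    solver to within the grid resolution."""
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    best = math.inf
    angles = np.linspace(0, 2 * math.pi, n_grid, endpoint=False)
    half = np.linspace(0, math.pi, n_grid // 2 + 1)
    for alpha in angles:
        ca, sa = math.cos(alpha), math.sin(alpha)
        Rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        for beta in half:
            cb, sb = math.cos(beta), math.sin(beta)
            Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
            for gamma in angles:
                cg, sg = math.cos(gamma), math.sin(gamma)
                Rz2 = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
                R = Rz1 @ Ry @ Rz2
                rmsd = math.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1)))
                best = min(best, rmsd)
    return best
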