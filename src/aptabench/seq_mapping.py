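"""Chain sequences and reference↔prediction residue correspondences.

Residue numbering is rarely consistent between an experimental reference and
a predicted model, so pocket residues (and any other residue-level feature)
are carried across by *sequence position*: each chain sequence is extracted
in residue order, globally aligned (Needleman–Wunsch), and aligned non-gap
columns become residue pairs. Mapping is positional — a mismatched aligned
column still yields a pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .structure import ResidueKey, Structure

__all__ = [
    "SequenceRecord", "Alignment", "ResidueMap",
    "extract_sequence", "global_align", "build_residue_map",
    "identity_residue_map", "AA_THREE_TO_ONE", "NT_TO_ONE",
]

#: Standard amino-acid 3-letter → 1-letter table.
AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Nucleotide residue name → 1-letter table (DNA thymine reads as T).
NT_TO_ONE = {"DA": "A", "DC": "C", "DG": "G", "DT": "T",
             "A": "A", "C": "C", "G": "G", "U": "U"}


@dataclass
class SequenceRecord:
    """One chain's one-letter sequence plus the residue key per position."""

    chain_id: str
    sequence: str
    residue_keys: list[ResidueKey]
    nonstandard_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.residue_keys):
            raise ValueError("sequence and residue_keys lengths differ")


@dataclass
class Alignment:
    """A global pairwise alignment: gapped strings plus the score."""

    aligned_a: str
    aligned_b: str
    score: float

    @property
    def identity_fraction(self) -> float:
        """Fraction of columns aligned residue-to-residue that match."""
        cols = [(x, y) for x, y in zip(self.aligned_a, self.aligned_b)
                if x != "-" and y != "-"]
        if not cols:
            return 0.0
        return sum(x == y for x, y in cols) / len(cols)

    def __str__(self) -> str:  # plain-text pairwise dump
        marks = "".join("|" if x == y and x != "-" else " "
                        for x, y in zip(self.aligned_a, self.aligned_b))
        return f"{self.aligned_a}\n{marks}\n{self.aligned_b}"

    def column_pairs(self) -> list[tuple[int, int]]:
        """(index in a, index in b) for every non-gap/non-gap column."""
        out = []
        ia = ib = 0
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x != "-" and y != "-":
                out.append((ia, ib))
            if x != "-":
                ia += 1
            if y != "-":
                ib += 1
        return out


@dataclass
class ResidueMap:
    """One-to-one reference→prediction residue correspondence."""

    pairs: list[tuple[ResidueKey, ResidueKey]]
    identity_fraction: float
    unmapped_gt: list[ResidueKey] = field(default_factory=list)

    def __post_init__(self) -> None:
        gt_keys = [g for g, _ in self.pairs]
        pr_keys = [p for _, p in self.pairs]
        if len(set(gt_keys)) != len(gt_keys) or len(set(pr_keys)) != len(pr_keys):
            raise ValueError("residue map is not one-to-one")
        if not 0.0 <= self.identity_fraction <= 1.0:
            raise ValueError("identity_fraction outside [0, 1]")

    def as_dict(self) -> dict[ResidueKey, ResidueKey]:
        return dict(self.pairs)

    def inverted(self) -> "ResidueMap":
        return ResidueMap([(p, g) for g, p in self.pairs], self.identity_fraction)


def extract_sequence(s: Structure, chain_id: str) -> SequenceRecord:
    """One-letter sequence of a chain, in residue order.

    Unknown residue names become ``X`` and their positions are flagged.
    """
    keys: list[ResidueKey] = []
    letters: list[str] = []
    flagged: list[int] = []
    for key, resname, _ in s.residues():
        if key[0] != chain_id:
            continue
        keys.append(key)
        letter = AA_THREE_TO_ONE.get(resname) or NT_TO_ONE.get(resname)
        if letter is None:
            letter = "X"
            flagged.append(len(letters))
        letters.append(letter)
    if not keys:
        raise KeyError(f"chain {chain_id!r} not present")
    return SequenceRecord(chain_id, "".join(letters), keys, flagged)


def global_align(a: str, b: str, *, match: float = 1.0, mismatch: float = -1.0,
                 gap_open: float = -2.0, gap_extend: float = -1.0) -> Alignment:
    """Needleman–Wunsch global alignment with identity scoring.

    The default scheme (match +1, mismatch −1, first gap −2, each further
    gap −1) suits reference/prediction pairs that are near-identical by
    construction; all four parameters are configurable.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    best = aligner.align(a, b)[0]
    return Alignment(str(best[0]), str(best[1]), float(best.score))


def _greedy_chain_pairing(gt: Structure, pred: Structure,
                          entity: str) -> list[tuple[str, str]]:
    """Pair chains of one entity class by maximum alignment identity.

    Greedy: repeatedly take the highest-identity (gt, pred) chain pair among
    the unassigned; ties broken by chain-id order.
    """
    gt_chains = gt.chain_ids_of(entity)
    pred_chains = pred.chain_ids_of(entity)
    scored = []
    for g in gt_chains:
        sg = extract_sequence(gt, g)
        for p in pred_chains:
            sp = extract_sequence(pred, p)
            aln = global_align(sg.sequence, sp.sequence)
            scored.append((-aln.identity_fraction, g, p))
    scored.sort()
    used_g: set[str] = set()
    used_p: set[str] = set()
    pairs = []
    for _, g, p in scored:
        if g in used_g or p in used_p:
            continue
        pairs.append((g, p))
        used_g.add(g)
        used_p.add(p)
    return pairs


def build_residue_map(gt: Structure, pred: Structure,
                      chain_pairing: list[tuple[str, str]] | None = None) -> ResidueMap:
    """Residue correspondence between two structures via global alignment.

    Protein chains are paired with protein chains (and nucleic with nucleic)
    by greedy maximum sequence identity unless an explicit ``chain_pairing``
    is supplied. Aligned non-gap columns produce pairs; reference residues
    falling in gap columns are reported in ``unmapped_gt``.
    """
    if chain_pairing is None:
        chain_pairing = (_greedy_chain_pairing(gt, pred, "protein")
                         + _greedy_chain_pairing(gt, pred, "nucleic"))
    if not chain_pairing:
        raise ValueError("no chain pairing derivable between the two structures")
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    unmapped: list[ResidueKey] = []
    ident_num = ident_den = 0
    for g_chain, p_chain in chain_pairing:
        sg = extract_sequence(gt, g_chain)
        sp = extract_sequence(pred, p_chain)
        aln = global_align(sg.sequence, sp.sequence)
        mapped_gt_idx = set()
        for ia, ib in aln.column_pairs():
            pairs.append((sg.residue_keys[ia], sp.residue_keys[ib]))
            mapped_gt_idx.add(ia)
            ident_den += 1
            if sg.sequence[ia] == sp.sequence[ib]:
                ident_num += 1
        unmapped.extend(k for i, k in enumerate(sg.residue_keys)
                        if i not in mapped_gt_idx)
    identity = ident_num / ident_den if ident_den else 0.0
    return ResidueMap(pairs, identity, unmapped)


def identity_residue_map(s: Structure) -> ResidueMap:
    """The identity correspondence of a structure with itself."""
    keys = s.residue_keys()
    return ResidueMap([(k, k) for k in keys], 1.0, [])


def read_fasta(path) -> dict[str, str]:
    """Sequences from a FASTA file as {record id: sequence}."""
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    """Write {record id: sequence} as FASTA."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")
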