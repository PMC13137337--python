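"""Benchmark roster validation and specificity negative controls.

Two control strategies probe whether a structure predictor actually reads
aptamer identity rather than generic nucleic-acid shape:

* the *mismatched negative set* pairs every protein with the aptamer of the
  next complex in the roster (a cyclic derangement), under the constraint
  that aptamers raised against the same or a homologous protein are never
  reassigned within that family (the three anti-thrombin entries, for
  instance, must not be cross-paired);
* the *shuffled-sequence set* keeps each protein with a random permutation
  of its own aptamer sequence that preserves length and nucleotide
  composition while differing at ≥ 80% of positions, destroying any
  recognition motif. A fixed master seed makes both sets reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BenchmarkEntry", "NegativePairing", "validate_roster",
    "build_negative_set", "shuffle_sequence", "build_shuffle_set",
    "read_roster_csv", "BENCHMARK_ROSTER",
]

_ALPHABETS = {"DNA": set("ACGT"), "RNA": set("ACGU")}


@dataclass(frozen=True)
class BenchmarkEntry:
    """One benchmark complex: identifiers, aptamer sequence and groupings."""

    pdb_id: str
    aptamer_sequence: str
    nucleic_type: str  # "DNA" or "RNA"
    homology_group: str = ""  # entries sharing a target protein family
    study_group: str = ""  # entries deposited by the same study
    representative: bool = True
    seen: bool = False  # inside a model's training window
    protein_sequences: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.aptamer_sequence:
            raise ValueError(f"{self.pdb_id}: empty aptamer sequence")
        if self.nucleic_type not in _ALPHABETS:
            raise ValueError(f"{self.pdb_id}: nucleic_type must be DNA or RNA")


#: The 11-complex benchmark roster: ids, nucleic type, aptamer length (nt),
#: homology/study groupings and training-window (seen/unseen) status. The
#: aptamer sequence field here records only the published length; actual
#: sequences must be supplied by the user (or generated synthetically).
BENCHMARK_ROSTER: list[dict] = [
    {"pdb_id": "7LRI", "length": 35, "nucleic_type": "DNA",
     "homology_group": "hiv_rt", "seen": True},
    {"pdb_id": "7SZU", "length": 67, "nucleic_type": "RNA",
     "homology_group": "bl3_6_fab", "seen": True},
    {"pdb_id": "7V5N", "length": 24, "nucleic_type": "DNA",
     "homology_group": "bevacizumab_fab", "seen": True},
    {"pdb_id": "8D29", "length": 34, "nucleic_type": "RNA",
     "homology_group": "human_fab", "seen": True},
    {"pdb_id": "8TQS", "length": 30, "nucleic_type": "DNA",
     "homology_group": "thrombin", "seen": False},
    {"pdb_id": "7ZKO", "length": 15, "nucleic_type": "DNA",
     "homology_group": "thrombin", "seen": True},
    {"pdb_id": "8BW5", "length": 41, "nucleic_type": "DNA",
     "homology_group": "thrombin", "seen": False},
    {"pdb_id": "7ZQS", "length": 51, "nucleic_type": "DNA",
     "homology_group": "tfr1", "seen": True},
    {"pdb_id": "8TFD", "length": 20, "nucleic_type": "DNA",
     "homology_group": "sars2_ncap", "seen": False},
    {"pdb_id": "8ZBF", "length": 40, "nucleic_type": "DNA",
     "homology_group": "sars2_ncap", "seen": False},
    {"pdb_id": "9GXH", "length": 15, "nucleic_type": "DNA",
     "homology_group": "nanobody_tba", "seen": False},
]


@dataclass
class NegativePairing:
    """A constraint-satisfying perfect matching of proteins to aptamers."""

    pairs: list[tuple[str, str]]  # (protein entry id, aptamer entry id)
    ordering: list[str]
    constraint_log: list[str] = field(default_factory=list)


def validate_roster(entries: list[BenchmarkEntry]
                    ) -> tuple[list[BenchmarkEntry], list[tuple[BenchmarkEntry, str]]]:
    """Apply the curation rules; return (kept, excluded-with-reason).

    Entries whose aptamer contains a modified residue (letter ``X``) cannot
    be encoded by sequence-based predictors and are excluded. Within each
    study group only the designated representative survives (same-study
    depositions are closely related variants of one complex).
    """
    ids = [e.pdb_id for e in entries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate pdb_id(s): {', '.join(dupes)}")
    kept, excluded = [], []
    for e in entries:
        if "X" in e.aptamer_sequence.upper():
            excluded.append((e, "modified residue"))
        elif e.study_group and not e.representative:
            excluded.append((e, "same-study variant"))
        else:
            kept.append(e)
    return kept, excluded


def _violates(protein: BenchmarkEntry, aptamer: BenchmarkEntry) -> bool:
    if protein.pdb_id == aptamer.pdb_id:
        return True
    return bool(protein.homology_group) and \
        protein.homology_group == aptamer.homology_group


def build_negative_set(roster: list[BenchmarkEntry]) -> NegativePairing:
    """Cyclic mismatched pairing: protein_i gets the aptamer of entry i+1.

    When the base rule would keep an aptamer inside its own homology group,
    the assignment is repaired by swapping with the nearest forward
    position whose aptamer resolves both pairs (wrap-around), the smallest
    perturbation of the next-complex rule. Raises when no valid assignment
    exists (e.g. all entries in one group).
    """
    n = len(roster)
    if n < 3:
        raise ValueError("need at least 3 entries for a mismatched set")
    by_id = {e.pdb_id: e for e in roster}
    order = [e.pdb_id for e in roster]
    assign = order[1:] + order[:1]  # aptamer source per protein position
    log: list[str] = []
    for i in range(n):
        if not _violates(by_id[order[i]], by_id[assign[i]]):
            continue
        repaired = False
        for step in range(1, n):
            k = (i + step) % n
            if k == i:
                continue
            # swapping must leave pair i valid and not break pair k
            if _violates(by_id[order[i]], by_id[assign[k]]):
                continue
            if _violates(by_id[order[k]], by_id[assign[i]]):
                continue
            log.append(f"swap aptamers of positions {i} and {k} "
                       f"({assign[i]} <-> {assign[k]}) to satisfy homology "
                       f"constraint for {order[i]}")
            assign[i], assign[k] = assign[k], assign[i]
            repaired = True
            break
        if not repaired:
            raise ValueError(f"no valid mismatched assignment exists for "
                             f"{order[i]} (homology group "
                             f"{by_id[order[i]].homology_group!r})")
    pairs = list(zip(order, assign))
    for p, a in pairs:  # re-validate the emitted matching
        if _violates(by_id[p], by_id[a]):
            raise ValueError("internal error: emitted pairing violates constraints")
    if sorted(assign) != sorted(order):
        raise ValueError("internal error: pairing is not a perfect matching")
    return NegativePairing(pairs, order, log)


def shuffle_sequence(seq: str, min_diff_frac: float = 0.8,
                     seed: int = 0, max_attempts: int = 10000) -> str:
    """Composition-preserving permutation differing at ≥ ``min_diff_frac``
    of positions.

    Deterministic for a fixed seed. Raises when the difference criterion is
    unreachable within ``max_attempts`` (a near-homopolymer cannot differ at
    80% of positions), reporting the best fraction achieved.
    """
    if len(seq) < 2:
        raise ValueError("sequence too short to shuffle")
    rng = np.random.default_rng(seed)
    letters = np.array(list(seq))
    best = 0.0
    for _ in range(max_attempts):
        perm = rng.permutation(letters)
        diff = float(np.mean(perm != letters))
        if diff >= min_diff_frac:
            return "".join(perm)
        best = max(best, diff)
    raise ValueError(f"could not reach {min_diff_frac:.0%} positional "
                     f"difference in {max_attempts} attempts (best "
                     f"{best:.0%}); sequence composition too uniform")


def _entry_seed(master_seed: int, pdb_id: str) -> int:
    """Per-entry sub-seed: SHA-256 of "seed:pdb_id", truncated to 31 bits.

    Hash-derived so the result never depends on roster order.
    """
    digest = hashlib.sha256(f"{master_seed}:{pdb_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def build_shuffle_set(roster: list[BenchmarkEntry], seed: int = 0,
                      min_diff_frac: float = 0.8
                      ) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """One shuffled-sequence control per roster entry.

    Returns (controls, failures): controls are (pdb_id, shuffled sequence);
    entries whose sequence cannot satisfy the difference criterion are
    reported in failures as (pdb_id, reason) and do not abort the rest.
    """
    controls, failures = [], []
    for e in roster:
        try:
            shuffled = shuffle_sequence(e.aptamer_sequence, min_diff_frac,
                                        seed=_entry_seed(seed, e.pdb_id))
            controls.append((e.pdb_id, shuffled))
        except ValueError as exc:
            failures.append((e.pdb_id, str(exc)))
    return controls, failures


def read_roster_csv(path) -> list[BenchmarkEntry]:
    """Read a roster CSV with columns pdb_id, aptamer_sequence, nucleic_type
    and optional homology_group, study_group, representative_flag, seen."""
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"pdb_id", "aptamer_sequence", "nucleic_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"roster missing column(s): {', '.join(sorted(missing))}")
    entries = []
    for _, row in df.iterrows():
        entries.append(BenchmarkEntry(
            pdb_id=row["pdb_id"],
            aptamer_sequence=row["aptamer_sequence"].upper(),
            nucleic_type=row["nucleic_type"].upper(),
            homology_group=row.get("homology_group", ""),
            study_group=row.get("study_group", ""),
            representative=str(row.get("representative_flag", "1")).lower()
            in ("1", "true", "yes", ""),
            seen=str(row.get("seen", "0")).lower() in ("1", "true", "yes"),
        ))
    return entries
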