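# Methods

This note records the models, conventions and design choices behind
`aptabench`, in the order a user meets them.

## Structures and sanitization

Structures are flat atom lists keyed by (chain, author residue number,
insertion code, atom name, alt-loc). Coordinates are Angstrom everywhere
internally; the Rg CLI can report nanometres because trajectory tooling
conventionally does. Author numbering is never rewritten — numbering
disagreements between a reference and a prediction are resolved by
sequence alignment (below), which is robust to renumbering, truncation
and expression tags.

Multi-model files are disambiguated by intent: read as a *structure*, only
MODEL 1 survives (PDB convention; experimental references are single
assemblies); read as a *trajectory*, every MODEL is a frame. Trajectory
timestamps come from a declared frame spacing (default 10 ps, the usual
compressed-output interval), with frame 1 at t = dt.

Sanitization reduces a deposited complex to protein and nucleic heavy
atoms: hydrogens/deuteriums, waters (HOH/WAT/H2O/DOD), and any residue
outside the standard amino-acid and nucleotide dictionaries (ions,
ligands, modified residues) are removed — deliberately without a chemical
component dictionary, since the standard dictionaries decide membership.
Alternate locations collapse to the highest-occupancy conformer, ties
broken by alt-loc letter. Chains are typed by residue majority; a
structure left without a protein or nucleic component is legal
(aptamer-only analyses) and carries a warning instead of failing.

## Residue correspondence

Chain sequences are extracted in residue order (unknown residues become
`X` and are flagged). Reference and prediction chains of the same entity
class are paired greedily by global-alignment identity (ties by chain-id
order — deposition order is the only stable convention when two chains
are identical, e.g. antibody light/heavy pairs). Needleman–Wunsch uses
identity scoring (match +1, mismatch −1, first gap −2, further gaps −1):
the two sequences are near-identical by construction, so a substitution
matrix would add parameters without information. Aligned non-gap columns
become residue pairs even when the letters differ — the mapping is
positional, because a point mutation does not move the binding site.

## Pocket and pocket occupancy

The binding pocket is contact-defined on the reference: protein residues
with ≥ 1 heavy atom within 4.5 Å (inclusive — the boundary must be
deterministic) of any aptamer heavy atom. Pocket occupancy over a
trajectory is the fraction of aptamer atoms within the same cutoff of any
pocket-residue atom. Both counts use heavy atoms by default: references
are dehydrogenated, and comparability between reference-derived and
MD-derived numbers matters more than counting protons; a toggle
(`include_hydrogens`) restores all-atom counting for protonated MD
topologies. Neighbor searches use a k-d tree and are tested for exact
agreement with brute-force all-pairs enumeration. An empty (fully
unmapped) pocket yields an all-zero series plus a warning rather than an
error, so batch runs complete.

## lDDT / iLDDT

The local distance difference test follows the standard definition:
reference heavy-atom pairs within a 15 Å inclusion radius, same-residue
pairs excluded, each unordered pair counted once; the score is the mean
over thresholds {0.5, 1, 2, 4} Å of the fraction of pairs whose model
distance errs by strictly less than the threshold, × 100. Stereochemistry
penalties are omitted (a geometric benchmark, not a validation tool).
`interface_only` keeps only inter-chain pairs; a complex whose chains
never approach within the radius has no qualifying pairs and scores
`None` — reported as missing, never as zero. Atom pairing between
reference and model goes through the residue map plus identical atom
names.

## Hydrogen bonds

Chemistry tables enumerate, per standard residue, donor atoms (with how
their hydrogens are geometrically determined) and acceptor atoms (with the
covalent antecedent used in angle tests): protein backbone N/O, side-chain
N/O/S sites, nucleotide base N/O sites, sugar O2'/O3'/O4'/O5' and
phosphate OP1/OP2 (O1P/O2P also accepted).

Dehydrogenated inputs get polar hydrogens rebuilt at idealized geometry
(1.01 Å) where the heavy-atom frame fixes them: external bisector for
amides and ring N–H, in-plane pair for planar amines. Rotatable donors
(hydroxyls, lysine ammonium, ribose O2') get no hydrogen; for them the
bond test falls back to donor–acceptor distance and D–A–AA angle only —
the same compromise HBPLUS makes when it cannot place a proton. Inputs
that already carry hydrogens are used as-is.

Static criteria: d(D,A) ≤ 3.9 Å, d(H,A) ≤ 2.5 Å, and D–H–A, H–A–AA,
D–A–AA all ≥ 90°. MD criteria: d(D,A) ≤ 0.35 nm with the
hydrogen–donor–acceptor angle at the donor ≤ 30°, the convention of
trajectory H-bond tools. Duplicate geometric solutions between one atom
pair collapse to a single bond.

Reference-vs-prediction matching is the one genuinely open design point:
bond identity here is (residue, atom name) on each side with
donor/acceptor roles disregarded (role assignment flips easily for
bare-donor bonds), reference residues translated into the prediction's
keyspace via the residue map; aptamer correspondence is positional, since
control aptamer sequences are identical by construction. A
`match_level="residue"` switch coarsens identity to the residue pair,
counting at most one bond per pair. Each bond matches at most once;
precision = matched/predicted, recall = matched/reference, F1 the
harmonic mean, all zero-by-convention on empty denominators.

## Geometry and window statistics

Superposition is the Kabsch algorithm (SVD with reflection correction;
degenerate point sets rejected). Trajectory RMSD fits each frame on the
protein backbone (N, CA, C, O) against the reference — the initial frame
unless an external structure is given — then reports the unweighted RMSD
over the analysis group, by default the full aptamer chain; aptamer-only
mode uses the aptamer for both. Rg is mass-weighted with standard atomic
masses (unknown elements are an error, not a silent default).

Window summaries report mean ± *population* SD (a trajectory window is the
whole object of interest, not a sample from it; switchable). The default
summary start of 1 ns excludes the equilibration phase. Frame-window
selection is inclusive at both ends: at 10 ps spacing over 20 ns, the
10.01–20.00 ns production window selects exactly frames 1001–2000 (1000
frames). Subwindow segmentation splits a window into k consecutive
equal-as-possible parts (earlier parts take the remainder), so the
size-weighted mean of the k parts reproduces the full-window mean to
machine precision — the identity the tests enforce.

## Negative controls

Roster validation drops entries whose aptamer contains a modified residue
(`X`, which sequence predictors cannot encode) and collapses same-study
variant groups to their designated representative. The mismatched set is
the cyclic rule — protein *i* receives the aptamer of entry *i*+1,
wrap-around — repaired where it would pair within a homology group: the
violating position swaps aptamers with the nearest forward position for
which both touched pairs become valid, cascading with wrap-around and
failing only when no assignment exists (e.g. one group holding more than
half the roster). The emitted matching is re-validated: a derangement with
zero intra-group assignments, or an exception. The bundled 11-entry
roster metadata carries the benchmark ids, nucleic types, published
aptamer lengths, homology groups (three anti-thrombin entries, two
SARS-CoV-2 nucleocapsid entries) and training-window flags; actual
aptamer sequences are not bundled and must be supplied (the examples
generate synthetic ones of the published lengths).

Shuffled controls are uniform random permutations accepted only when ≥ 80%
of positions differ from the native sequence (Hamming, no realignment —
permutations preserve length), retried up to a bound and rejected with
the best fraction achieved when the composition makes the criterion
unreachable (near-homopolymers). Per-entry seeds derive from
SHA-256(master seed : entry id), so roster order cannot change any
control.

## Statistics

Pearson r requires n ≥ 3 and nonzero variance. Bootstrap CIs are
percentile intervals over resampled pairs (10,000 iterations, 95% by
default), chosen over BCa for transparency at benchmark-scale n;
resamples where a variable's variance collapses are skipped and counted,
and more than 50% degenerate resamples voids the interval. Leave-one-out
recomputes r with each complex excluded; an exclusion that collapses
variance yields NaN rather than aborting the sweep. Representative
predictions are chosen by ranking on model confidence, taking the top
two, and keeping the one with the lower (more favorable) ΔG_bind — energy
ties keep the higher-confidence candidate. Energies are kcal/mol
throughout.

## Synthetic fixtures

The generator emulates exactly what the metrics measure and nothing else:
a poly-ALA chain spaced at 12 Å (so each contact involves one residue and
stays independent of its neighbors) faces rigid thymidine templates.
Hydrogen-bond sites place the nucleotide's O4 acceptor 2.9 Å along the
idealized backbone N–H direction (near-linear geometry, ≥ 0.2 Å / 10°
margin inside every static criterion); contact-only sites approach
through the apolar methyl carbon with all polar pairs held beyond
donor–acceptor range; spare nucleotides park ≥ 25 Å away. Placements are
screened against stray contacts, spun deterministically about the
approach axis until clean, and every planted fact (pocket membership,
bond list, per-frame occupancy) is re-derived by brute force from the
emitted coordinates — generation raises rather than emit unverified
truth. Scripted trajectories cover stable binding (i.i.d. jitter), rigid
whole-complex drift (which backbone fitting must cancel exactly) and
linear aptamer dissociation (occupancy monotone to zero).

What the fixtures do *not* emulate: real backbone connectivity at the
12 Å spacing, sugar puckers, base pairing, G-quadruplex folds, force-field
plausibility, or MD thermal motion. Passing tests therefore certify the
*metrics* — their geometry, conventions and equivalence to brute force —
not any claim about predictor behavior on real complexes.

## Problem sizes and determinism

Default test fixtures run 8–16 protein residues and 4–10 nucleotides
(≤ ~500 atoms), 50 randomized fixtures for oracle equivalence, 1000
randomized rosters for control contracts, and 100 Monte-Carlo replicates
for bootstrap coverage — sizes chosen so brute-force oracles stay exact
and the whole suite runs in seconds to minutes. All randomness flows
through explicit seeds (NumPy `default_rng`); fixtures, controls and
bootstrap intervals are bit-reproducible per seed.

## Known limitations

- No binary trajectory formats (XTC/DCD); trajectories are multi-model
  PDB. No symmetry-mate assembly generation.
- Hydrogen inference covers geometrically determined donors only; no
  rotamer optimization of hydroxyl protons, so bonds donated by hydroxyls
  are judged on distance and heavy-atom angle alone.
- No DockQ, solvent accessibility, electrostatics, salt-bridge or
  π-stacking metrics; MM/GBSA energies are consumed as tables, never
  computed.
- Homology groups are user-supplied labels; no sequence-based homology
  detection.
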