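"""Rigid superposition, RMSD/Rg trajectory analysis and window statistics.

The trajectory conventions follow standard MD practice for complex
stability analysis: frames are least-squares superposed on the protein
backbone (N, CA, C, O) against a reference — the initial structure unless
an external one is given — and the RMSD is then reported over an analysis
group, by default the full aptamer chain. Summaries over a time window
drop the first nanosecond by default to exclude the equilibration phase,
and report mean ± population standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gemmi
import numpy as np

from .structure import Structure, TimeSeries, Trajectory

__all__ = [
    "RigidTransform", "kabsch_superpose", "rmsd_timeseries",
    "radius_of_gyration", "rg_timeseries", "summarize_timeseries",
    "select_frames_window", "subwindow_means", "PROTEIN_BACKBONE_ATOMS",
]

PROTEIN_BACKBONE_ATOMS = ("N", "CA", "C", "O")
EQUILIBRATION_CUTOFF_PS = 1000.0  # summaries start at 1 ns by default


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation: x ↦ R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation determinant is not +1 (reflection?)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ np.asarray(self.rotation).T \
            + np.asarray(self.translation)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None
                     ) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Classic Kabsch algorithm: the returned transform minimizes the
    (weighted) RMSD, with the reflection case corrected so the rotation is
    always proper. Returns (transform, rmsd after superposition).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must share an (n, 3) shape")
    n = P.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("invalid weights")
    w = w / w.sum()
    cp = w @ P
    cq = w @ Q
    P0, Q0 = P - cp, Q - cq
    H = (P0 * w[:, None]).T @ Q0
    if np.linalg.matrix_rank(H) < 2:
        raise ValueError("degenerate (collinear or coincident) point set")
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    transform = RigidTransform(R, t)
    moved = transform.apply(P)
    rmsd = float(np.sqrt(np.sum(w * np.sum((moved - Q) ** 2, axis=1))))
    return transform, rmsd


def _selection_mask(topo: Structure, selection) -> np.ndarray:
    """Resolve a selection spec into a boolean atom mask.

    Accepts a boolean mask, or the names ``"protein-backbone"``,
    ``"aptamer"`` (all nucleic-chain atoms), ``"protein"`` and
    ``"complex"`` (protein + nucleic).
    """
    if isinstance(selection, np.ndarray):
        return selection.astype(bool)
    if selection == "protein-backbone":
        return topo.select(entity="protein", atom_names=PROTEIN_BACKBONE_ATOMS)
    if selection == "aptamer":
        return topo.select(entity="nucleic")
    if selection == "protein":
        return topo.select(entity="protein")
    if selection == "complex":
        return topo.select(entity="protein") | topo.select(entity="nucleic")
    raise ValueError(f"unknown selection {selection!r}")


def rmsd_timeseries(traj: Trajectory, fit_selection="protein-backbone",
                    analysis_selection="aptamer",
                    reference: Structure | None = None) -> TimeSeries:
    """Per-frame RMSD of an analysis group after fitting on another group.

    Each frame is superposed on ``fit_selection`` against the reference
    (frame 0 of the trajectory unless an external structure is supplied),
    and the unweighted RMSD is reported over ``analysis_selection``.
    Aptamer-only analysis passes ``"aptamer"`` for both selections.
    """
    topo = traj.topology
    fit_mask = _selection_mask(topo, fit_selection)
    ana_mask = _selection_mask(topo, analysis_selection)
    if not fit_mask.any():
        raise ValueError(f"empty fit selection {fit_selection!r}")
    if not ana_mask.any():
        raise ValueError(f"empty analysis selection {analysis_selection!r}")
    ref_xyz = traj.frames[0] if reference is None else reference.coords
    if ref_xyz.shape != (len(topo.atoms), 3):
        raise ValueError("reference atom count does not match topology")
    times, values = [], []
    for t, xyz in traj:
        transform, _ = kabsch_superpose(xyz[fit_mask], ref_xyz[fit_mask])
        moved = transform.apply(xyz[ana_mask])
        rmsd = float(np.sqrt(np.mean(np.sum((moved - ref_xyz[ana_mask]) ** 2,
                                            axis=1))))
        times.append(t)
        values.append(rmsd)
    return TimeSeries("rmsd", times, values, "A")


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration, in the units of ``coords``."""
    xyz = np.asarray(coords, dtype=float).reshape(-1, 3)
    m = np.asarray(masses, dtype=float)
    if xyz.shape[0] == 0:
        raise ValueError("need at least one atom")
    if m.shape != (xyz.shape[0],) or np.any(m <= 0):
        raise ValueError("masses must be positive, one per atom")
    total = m.sum()
    center = (m[:, None] * xyz).sum(axis=0) / total
    return float(np.sqrt((m * np.sum((xyz - center) ** 2, axis=1)).sum() / total))


def element_masses(s: Structure, mask: np.ndarray | None = None) -> np.ndarray:
    """Standard atomic masses for the (selected) atoms of a structure."""
    atoms = s.atoms if mask is None else [a for a, k in zip(s.atoms, mask) if k]
    out = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        el = gemmi.Element(a.element)
        if el.name in ("X", "") or el.weight <= 0:
            raise ValueError(f"unknown element {a.element!r} for atom {a.atom_key}")
        out[i] = el.weight
    return out


def rg_timeseries(traj: Trajectory, selection="aptamer",
                  units: str = "A") -> TimeSeries:
    """Per-frame radius of gyration of a selection (``"aptamer"`` or
    ``"complex"``), in Angstrom by default or nanometres with
    ``units="nm"``."""
    topo = traj.topology
    mask = _selection_mask(topo, selection)
    if not mask.any():
        raise ValueError(f"empty selection {selection!r}")
    masses = element_masses(topo, mask)
    scale = 0.1 if units == "nm" else 1.0
    times, values = [], []
    for t, xyz in traj:
        times.append(t)
        values.append(scale * radius_of_gyration(xyz[mask], masses))
    return TimeSeries(f"rg_{selection}", times, values, units)


def summarize_timeseries(ts: TimeSeries, t_start: float = EQUILIBRATION_CUTOFF_PS,
                         t_end: float | None = None) -> tuple[float, float, int]:
    """Mean, population SD and sample count over [t_start, t_end].

    Both bounds are inclusive; ``t_end`` defaults to the last timestamp.
    """
    if t_end is None:
        t_end = float(ts.times_ps[-1]) if len(ts) else t_start
    keep = (ts.times_ps >= t_start) & (ts.times_ps <= t_end)
    if not keep.any():
        raise ValueError(f"no samples in [{t_start}, {t_end}] ps")
    vals = ts.values[keep]
    return float(vals.mean()), float(vals.std(ddof=0)), int(keep.sum())


def select_frames_window(frame_times_ps, t0: float, t1: float) -> list[int]:
    """Indices of frames with t0 ≤ t ≤ t1 (both ends inclusive)."""
    if t0 >= t1:
        raise ValueError("window start must precede its end")
    t = np.asarray(frame_times_ps, dtype=float)
    idx = np.nonzero((t >= t0) & (t <= t1))[0].tolist()
    if not idx:
        warnings.warn(f"window [{t0}, {t1}] ps selects no frames", stacklevel=2)
    return idx


def subwindow_means(values, k: int = 4) -> list[float]:
    """Means of k consecutive, equal-as-possible segments.

    With a remainder r, the first r segments take one extra sample (for a
    10-sample series and k = 4 the segment sizes are 3, 3, 2, 2).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    vals = np.asarray(values, dtype=float)
    if len(vals) < k:
        raise ValueError(f"need at least {k} values for {k} segments")
    base, rem = divmod(len(vals), k)
    means, start = [], 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        means.append(float(vals[start:start + size].mean()))
        start += size
    return means
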