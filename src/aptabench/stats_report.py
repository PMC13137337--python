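"""Correlation and robustness statistics over per-complex metric tables.

Binding-energy tables (MM/GBSA ΔG_bind in kcal/mol, computed upstream) and
other per-complex metrics are compared between reference and predicted
structures with Pearson correlation. Because the benchmark is small
(eleven complexes), every correlation is accompanied by a percentile
bootstrap confidence interval (10,000 resamples by default) and a
leave-one-out sweep that recomputes r with each complex excluded in turn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult", "pearson", "bootstrap_ci", "loo_correlations",
    "correlate", "select_representative", "split_cohort", "write_report",
]


@dataclass
class CorrelationResult:
    """Pearson r with bootstrap CI and leave-one-out values."""

    r: float
    n: int
    ci_low: float
    ci_high: float
    loo: list[tuple[str, float]] = field(default_factory=list)
    degenerate_resamples: int = 0

    def __post_init__(self) -> None:
        for v in (self.r, self.ci_low, self.ci_high):
            if not np.isnan(v) and not -1.0 <= v <= 1.0 + 1e-12:
                raise ValueError("correlation values must lie in [-1, 1]")
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low exceeds ci_high")


def _as_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    return x, y


def pearson(x, y) -> float:
    """Product–moment correlation coefficient (n ≥ 3, nonzero variance)."""
    x, y = _as_xy(x, y)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: a variable has zero variance")
    return float(sps.pearsonr(x, y).statistic)


def bootstrap_ci(x, y, iters: int = 10000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float, int]:
    """Percentile bootstrap interval for Pearson r.

    Pairs are resampled with replacement; resamples in which either
    variable collapses to zero variance are skipped and counted (more than
    50% degenerate resamples raises). Deterministic per seed. Returns
    (ci_low, ci_high, n_degenerate).
    """
    x, y = _as_xy(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(iters, n))
    xs, ys = x[idx], y[idx]
    sx = xs.std(axis=1)
    sy = ys.std(axis=1)
    valid = (sx > 0) & (sy > 0)
    degenerate = int(iters - valid.sum())
    if degenerate > iters / 2:
        raise ValueError(f"{degenerate}/{iters} bootstrap resamples were "
                         "degenerate; interval unreliable")
    xs, ys = xs[valid], ys[valid]
    cov = ((xs - xs.mean(axis=1, keepdims=True))
           * (ys - ys.mean(axis=1, keepdims=True))).mean(axis=1)
    r = np.clip(cov / (xs.std(axis=1) * ys.std(axis=1)), -1.0, 1.0)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(r, [alpha, 1.0 - alpha])
    return float(lo), float(hi), degenerate


def loo_correlations(ids, x, y) -> list[tuple[str, float]]:
    """Pearson r with each observation excluded in turn.

    Exclusions that collapse a variable's variance yield NaN (flagged by
    the caller), not an exception, so the sweep always completes.
    """
    x, y = _as_xy(x, y)
    ids = list(ids)
    if len(ids) != len(x):
        raise ValueError("ids length must match data length")
    if len(x) < 4:
        raise ValueError("leave-one-out needs at least 4 observations")
    out = []
    for i, label in enumerate(ids):
        keep = np.arange(len(x)) != i
        xi, yi = x[keep], y[keep]
        if np.std(xi) == 0 or np.std(yi) == 0:
            out.append((label, float("nan")))
        else:
            out.append((label, float(sps.pearsonr(xi, yi).statistic)))
    return out


def correlate(ids, x, y, iters: int = 10000, level: float = 0.95,
              seed: int = 0, loo: bool = True) -> CorrelationResult:
    """Full correlation analysis: r, bootstrap CI, optional LOO sweep."""
    r = pearson(x, y)
    lo, hi, degenerate = bootstrap_ci(x, y, iters=iters, level=level, seed=seed)
    loo_values = loo_correlations(ids, x, y) if loo else []
    return CorrelationResult(r, len(list(ids)), lo, hi, loo_values, degenerate)


def select_representative(candidates: list[tuple[str, float, float | None]]) -> str:
    """Representative prediction: best ΔG_bind among the top-2 by confidence.

    ``candidates`` are (id, confidence, dG_bind) with dG possibly missing
    outside the top 2. Candidates are ranked by confidence (descending,
    ties by input order); of the top two, the one with the lower (more
    favorable) ΔG_bind wins; a ΔG tie keeps the higher-confidence one.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidates")
    ranked = sorted(enumerate(candidates), key=lambda t: (-t[1][1], t[0]))
    top2 = [c for _, c in ranked[:2]]
    for cid, _, dg in top2:
        if dg is None:
            raise ValueError(f"candidate {cid!r} is in the top 2 by confidence "
                             "but has no binding free energy")
    return top2[1][0] if top2[1][2] < top2[0][2] else top2[0][0]


def split_cohort(roster_ids: list[str], seen_ids) -> tuple[list[str], list[str]]:
    """Partition complexes into seen (D1) and unseen (D2) subsets."""
    seen = set(seen_ids)
    unknown = seen - set(roster_ids)
    if unknown:
        raise ValueError(f"unknown id(s) in seen set: {', '.join(sorted(unknown))}")
    d1 = [i for i in roster_ids if i in seen]
    d2 = [i for i in roster_ids if i not in seen]
    return d1, d2


def write_report(results: dict, out_dir) -> list[Path]:
    """Write a results bundle: JSON plus CSV tables for tabular sections.

    Any value in ``results`` that is a pandas DataFrame is written as
    ``<key>.csv`` (and serialized as records in the JSON); everything else
    must be JSON-representable. Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    serializable = {}
    for key, value in results.items():
        if isinstance(value, pd.DataFrame):
            csv_path = out_dir / f"{key}.csv"
            value.to_csv(csv_path, index=False)
            written.append(csv_path)
            serializable[key] = value.to_dict(orient="records")
        elif isinstance(value, CorrelationResult):
            serializable[key] = {
                "r": value.r, "n": value.n,
                "ci_low": value.ci_low, "ci_high": value.ci_high,
                "loo": [[i, r] for i, r in value.loo],
                "degenerate_resamples": value.degenerate_resamples,
            }
        else:
            serializable[key] = value
    json_path = out_dir / "report.json"
    with open(json_path, "w") as fh:
        json.dump(serializable, fh, indent=2, sort_keys=True)
    written.append(json_path)
    return written
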