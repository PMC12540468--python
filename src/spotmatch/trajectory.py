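"""Metabolite dynamics along pseudotime branches.

Trophoblast differentiation starts in villous cytotrophoblasts
(prebranch) and bifurcates into a syncytiotrophoblast branch (branch 1)
and an extravillous-trophoblast branch (branch 2).  Spot-level
metabolite intensities from registration are projected onto the two
root-to-tip paths (prebranch spots are prepended to both), and each
metabolite's dynamic is classified per path by Spearman rank correlation
with pseudotime: increasing / decreasing when |rho| clears a threshold
at significance, otherwise unchanged.  Rank-based, so the call is
invariant to any monotone re-parameterisation of pseudotime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .integration import SpotMetaboliteMatrix

__all__ = [
    "BranchAssignment",
    "BranchSeries",
    "MetaboliteTrend",
    "project_branches",
    "classify_trend",
    "trend_table",
]

BRANCH_LABELS = ("prebranch", "branch1", "branch2")
PATHS = ("prebranch->branch1", "prebranch->branch2")


@dataclass
class BranchAssignment:
    """Per-spot branch label and pseudotime (external trajectory output)."""

    barcodes: np.ndarray
    branch: np.ndarray
    pseudotime: np.ndarray

    def __post_init__(self) -> None:
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.branch = np.asarray(self.branch, dtype=object)
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        unknown = set(self.branch.tolist()) - set(BRANCH_LABELS)
        if unknown:
            raise ValueError(f"unknown branch labels: {sorted(map(str, unknown))}")
        if not np.all(np.isfinite(self.pseudotime)) or np.any(self.pseudotime < 0):
            raise ValueError("pseudotime must be finite and non-negative")
        for b in BRANCH_LABELS:
            if not np.any(self.branch == b):
                raise ValueError(f"branch {b!r} is empty")


@dataclass
class BranchSeries:
    """Spots of one root-to-tip path, ordered by pseudotime."""

    path: str
    barcodes: np.ndarray
    pseudotime: np.ndarray
    intensity: np.ndarray  # spots x mz, pseudotime order
    mz_values: np.ndarray
    n_dropped: int


@dataclass
class MetaboliteTrend:
    mz: float
    path: str
    direction: str  # increasing | decreasing | unchanged
    rho: float
    p_value: float
    profile: np.ndarray
    note: str = ""


def project_branches(
    matrix: SpotMetaboliteMatrix, assignment: BranchAssignment
) -> dict[str, BranchSeries]:
    """Order spots along each differentiation path with intensities attached.

    Prebranch spots open both paths; spots in the assignment but missing
    from the matrix are dropped and counted.  Ties in pseudotime are
    ordered by barcode for determinism.
    """
    idx = {b: i for i, b in enumerate(matrix.barcodes)}
    out: dict[str, BranchSeries] = {}
    for path, tip in zip(PATHS, ("branch1", "branch2")):
        on_path = (assignment.branch == "prebranch") | (assignment.branch == tip)
        bars = assignment.barcodes[on_path]
        pt = assignment.pseudotime[on_path]
        present = np.array([b in idx for b in bars])
        n_dropped = int((~present).sum())
        bars, pt = bars[present], pt[present]
        if bars.size == 0:
            raise ValueError(
                f"no spot of path {path!r} is present in the metabolite matrix"
            )
        order = sorted(range(len(bars)), key=lambda i: (pt[i], str(bars[i])))
        order = np.array(order)
        rows = np.array([idx[b] for b in bars[order]])
        out[path] = BranchSeries(
            path=path,
            barcodes=bars[order],
            pseudotime=pt[order],
            intensity=matrix.intensity[rows],
            mz_values=matrix.mz_values,
            n_dropped=n_dropped,
        )
    return out


def _binned_profile(values: np.ndarray, bins: int) -> np.ndarray:
    """Sliding mean over equal-count pseudotime bins (values pre-ordered)."""
    n = len(values)
    bins = min(bins, n)
    edges = np.linspace(0, n, bins + 1).astype(int)
    return np.array([values[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])


def classify_trend(
    series: BranchSeries,
    rho_threshold: float = 0.3,
    alpha: float = 0.05,
    bins: int = 20,
    min_spots: int = 10,
) -> list[MetaboliteTrend]:
    """Classify every metabolite's dynamic along one path.

    rho is the Spearman correlation of intensity with pseudotime;
    direction is ``increasing`` when rho >= threshold at p < alpha,
    ``decreasing`` when rho <= -threshold at p < alpha, else
    ``unchanged``.  A constant intensity series is ``unchanged`` with a
    note.  The smoothed profile is the mean within ``bins`` equal-count
    pseudotime bins.
    """
    n = len(series.pseudotime)
    if n < min_spots:
        raise ValueError(f"path {series.path!r} has {n} spots; need >= {min_spots}")
    trends = []
    for j, mz in enumerate(series.mz_values):
        v = series.intensity[:, j]
        profile = _binned_profile(v, bins)
        if np.all(v == v[0]):
            trends.append(
                MetaboliteTrend(float(mz), series.path, "unchanged", 0.0, 1.0,
                                profile, note="constant")
            )
            continue
        rho, p = stats.spearmanr(series.pseudotime, v)
        if p < alpha and rho >= rho_threshold:
            direction = "increasing"
        elif p < alpha and rho <= -rho_threshold:
            direction = "decreasing"
        else:
            direction = "unchanged"
        trends.append(
            MetaboliteTrend(float(mz), series.path, direction, float(rho), float(p),
                            profile)
        )
    return trends


def trend_table(trends: list[MetaboliteTrend]) -> pd.DataFrame:
    """Flatten trend calls to a tidy mz/path/direction/rho/p table."""
    return pd.DataFrame(
        {
            "mz": [t.mz for t in trends],
            "path": [t.path for t in trends],
            "direction": [t.direction for t in trends],
            "rho": [t.rho for t in trends],
            "p_value": [t.p_value for t in trends],
        }
    )
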