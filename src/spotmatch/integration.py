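"""Pixel-to-spot integration and spot-level annotation.

After registration every MSI pixel has coordinates in the ST frame.
Pixels are assigned to their nearest spot within a matching radius
(default: half the 100 um spot pitch, so the raster partitions cleanly
into spot cells), TIC-normalised intensities are averaged per spot, and
spots are optionally given a cell-type label from externally supplied
deconvolution proportions.

The designation rule is applied literally: a cell type whose proportion
strictly exceeds 70% names the spot; otherwise the *second* most
prevalent type is used.  A conventional argmax mode is available because
the literal else-branch is surprising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import MSIRaster

__all__ = [
    "SpotMetaboliteMatrix",
    "PixelSpotMapping",
    "tic_normalize",
    "match_pixels_to_spots",
    "aggregate_spot_metabolites",
    "assign_spot_celltype",
]


@dataclass
class SpotMetaboliteMatrix:
    """Spot x metabolite intensity matrix with assignment bookkeeping."""

    barcodes: np.ndarray
    mz_values: np.ndarray
    intensity: np.ndarray
    n_pixels_per_spot: np.ndarray
    unassigned_pixels: int = 0

    def __post_init__(self) -> None:
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.mz_values = np.asarray(self.mz_values, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.n_pixels_per_spot = np.asarray(self.n_pixels_per_spot, dtype=np.int64)
        if self.intensity.shape != (len(self.barcodes), len(self.mz_values)):
            raise ValueError("intensity shape does not match barcodes x mz")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if np.any(self.n_pixels_per_spot < 1):
            raise ValueError("every retained spot must have >= 1 matched pixel")

    def __len__(self) -> int:
        return len(self.barcodes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intensity, index=self.barcodes, columns=self.mz_values
        )


@dataclass
class PixelSpotMapping:
    """Result of nearest-spot assignment: pixel index -> spot index (-1 unassigned)."""

    spot_index: np.ndarray
    distances_um: np.ndarray

    @property
    def assigned(self) -> np.ndarray:
        return self.spot_index >= 0

    @property
    def n_unassigned(self) -> int:
        return int((~self.assigned).sum())


def tic_normalize(
    raster: MSIRaster, on_zero_tic: str = "exclude"
) -> tuple[MSIRaster, int]:
    """Divide each pixel's spectrum by its total ion count.

    Returns the normalised raster and the number of zero-TIC pixels that
    were excluded (``on_zero_tic="exclude"``, the default) or raises on
    them (``"error"``).  Per-pixel intensity sums equal 1 afterwards.
    """
    tic = raster.intensity.sum(axis=1)
    zero = tic == 0
    n_zero = int(zero.sum())
    if n_zero:
        if on_zero_tic == "error":
            raise ValueError(f"{n_zero} pixels have zero total ion count")
        warnings.warn(
            f"excluding {n_zero} zero-TIC pixels from the raster", stacklevel=2
        )
    keep = ~zero
    normalized = raster.intensity[keep] / tic[keep, None]
    out = MSIRaster(
        meta_x=raster.meta_x[keep],
        meta_y=raster.meta_y[keep],
        mz_values=raster.mz_values,
        intensity=normalized,
        metaresolution=raster.metaresolution,
        pixel_ids=raster.pixel_ids[keep],
        mz_range=raster.mz_range,
    )
    return out, n_zero


def match_pixels_to_spots(
    spot_points: np.ndarray,
    spot_barcodes: np.ndarray,
    pixel_points: np.ndarray,
    radius_um: float = 50.0,
    tie_decimals: int = 6,
) -> PixelSpotMapping:
    """Assign each transformed pixel to its nearest spot within ``radius_um``.

    Both point sets must already be in the ST unified frame.  The default
    radius of 50 um is half the spot pitch, so a 100 um-step raster maps
    one pixel into essentially every covered spot cell.  Distance ties
    (after rounding to ``tie_decimals`` um decimals) are broken by the
    lexicographically smallest barcode.
    """
    spot_points = np.asarray(spot_points, dtype=float)
    pixel_points = np.atleast_2d(np.asarray(pixel_points, dtype=float))
    if len(spot_points) == 0:
        raise ValueError("empty spot set")
    spot_barcodes = np.asarray(spot_barcodes, dtype=object)

    tree = cKDTree(spot_points)
    dist, idx = tree.query(pixel_points)
    assigned = np.where(dist <= radius_um, idx, -1)

    # resolve exact-distance ties deterministically by barcode order
    tol = 10.0 ** (-tie_decimals)
    for i in np.nonzero(assigned >= 0)[0]:
        cand = tree.query_ball_point(pixel_points[i], dist[i] + tol)
        if len(cand) > 1:
            d = np.linalg.norm(spot_points[cand] - pixel_points[i], axis=1)
            tied = [c for c, dd in zip(cand, d) if abs(dd - dist[i]) <= tol]
            if len(tied) > 1:
                assigned[i] = min(tied, key=lambda c: str(spot_barcodes[c]))
    return PixelSpotMapping(spot_index=assigned, distances_um=dist)


def aggregate_spot_metabolites(
    mapping: PixelSpotMapping,
    raster: MSIRaster,
    spot_barcodes: np.ndarray,
    statistic: str = "mean",
) -> SpotMetaboliteMatrix:
    """Aggregate assigned pixel intensities per spot.

    Default statistic is the per-spot mean over assigned pixels; median
    is available.  Spots with no assigned pixel are dropped (their count
    is implicit in the output length); unassigned pixels are counted.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown aggregation statistic {statistic!r}")
    spot_barcodes = np.asarray(spot_barcodes, dtype=object)
    assigned = mapping.assigned
    if not assigned.any():
        raise ValueError("no pixel was assigned to any spot")
    spot_idx = mapping.spot_index[assigned]
    values = raster.intensity[assigned]

    hit_spots = np.unique(spot_idx)
    inten = np.empty((hit_spots.size, len(raster.mz_values)))
    counts = np.empty(hit_spots.size, dtype=np.int64)
    agg = np.mean if statistic == "mean" else np.median
    for row, s in enumerate(hit_spots):
        block = values[spot_idx == s]
        inten[row] = agg(block, axis=0)
        counts[row] = len(block)
    return SpotMetaboliteMatrix(
        barcodes=spot_barcodes[hit_spots],
        mz_values=raster.mz_values,
        intensity=inten,
        n_pixels_per_spot=counts,
        unassigned_pixels=mapping.n_unassigned,
    )


def assign_spot_celltype(
    proportions: pd.DataFrame,
    threshold: float = 0.70,
    mode: str = "second_if_below",
) -> pd.DataFrame:
    """Designate one cell type per spot from deconvolution proportions.

    ``proportions`` is spots x cell types, each row summing to 1.  In the
    default ``"second_if_below"`` mode the rule is literal: if the top
    proportion strictly exceeds ``threshold`` the top label is used
    (``rule_used="dominant_over_70"``), otherwise the second-largest
    label is chosen (``rule_used="second_most_prevalent"``).  Mode
    ``"dominant"`` always takes the argmax.

    Returns a DataFrame indexed by spot with columns ``cell_type`` and
    ``rule_used``.  The outcome does not depend on column order: within-
    row ties are broken by proportion first, label name second.
    """
    if mode not in ("second_if_below", "dominant"):
        raise ValueError(f"unknown designation mode {mode!r}")
    sums = proportions.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        bad = proportions.index[np.argmax(np.abs(sums - 1.0))]
        raise ValueError(f"proportions for spot {bad!r} do not sum to 1")

    labels = np.asarray(proportions.columns, dtype=object)
    out_label, out_rule = [], []
    for _, row in proportions.iterrows():
        # stable ranking: descending proportion, ascending label on ties
        order = sorted(range(len(labels)), key=lambda j: (-row.iloc[j], str(labels[j])))
        if mode == "dominant" or row.iloc[order[0]] > threshold:
            out_label.append(labels[order[0]])
            out_rule.append("dominant_over_70" if mode != "dominant" else "dominant")
        else:
            if len(labels) < 2:
                raise ValueError(
                    "need at least two cell types to pick the second most "
                    f"prevalent for spot {_!r}"
                )
            out_label.append(labels[order[1]])
            out_rule.append("second_most_prevalent")
    return pd.DataFrame(
        {"cell_type": out_label, "rule_used": out_rule}, index=proportions.index
    )
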