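"""Coordinate geometry for spot arrays and MSI rasters.

Both modalities are converted into a common physical frame in micrometres
before registration.  Spatial-transcriptomics spots sit on a hexagonal
offset grid (odd rows shifted half a pitch); mass-spectrometry-imaging
pixels sit on a square raster.  The conversions are

    x_spot = (col / 2 + 0.5) * pitch          y_spot = row * sqrt(3/4) * pitch
    x_pix  = col_pix * step                   y_pix  = row_pix * step

where ``pitch`` (``transresolution``) is the micrometre value of one grid
unit and ``step`` (``metaresolution``) is the raster step.  With the Visium
parity-offset column encoding (columns within a row differ by 2) these
formulas give an exact 100 um centre-to-centre distance between hex
neighbours at the default 100 um pitch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from math import sqrt

import numpy as np
import pandas as pd

__all__ = [
    "Frame",
    "SpotGrid",
    "MSIRaster",
    "hex_to_physical",
    "msi_to_physical",
    "DEFAULT_PITCH_UM",
    "DEFAULT_MSI_STEP_UM",
    "DEFAULT_SPOT_DIAMETER_UM",
    "DEFAULT_MZ_RANGE",
]

#: Centre-to-centre spot distance of the assay, micrometres.
DEFAULT_PITCH_UM = 100.0
#: Raster step of the DESI acquisition, micrometres.
DEFAULT_MSI_STEP_UM = 100.0
#: Capture-spot diameter, micrometres (metadata; parameterises matching radius).
DEFAULT_SPOT_DIAMETER_UM = 55.0
#: Instrument mass range, Da.
DEFAULT_MZ_RANGE = (70.0, 1200.0)

ROW_FACTOR = sqrt(0.75)


class Frame(str, Enum):
    """Which unified physical frame a set of points lives in."""

    ST_UNIFIED = "ST_unified"
    MSI_UNIFIED = "MSI_unified"


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class SpotGrid:
    """Hexagonal spot array.

    Parameters
    ----------
    barcodes
        Unique spot identifiers, one per spot.
    trans_x, trans_y
        Integer array column / row indices in the parity-offset hex
        encoding (within one row, columns share parity and neighbours
        differ by 2).
    in_tissue
        Boolean mask of spots overlapping tissue.
    transresolution
        Micrometres per grid unit (the spot pitch).
    spot_diameter
        Physical spot diameter in micrometres, carried as metadata.
    """

    barcodes: np.ndarray
    trans_x: np.ndarray
    trans_y: np.ndarray
    in_tissue: np.ndarray
    transresolution: float = DEFAULT_PITCH_UM
    spot_diameter: float = DEFAULT_SPOT_DIAMETER_UM

    def __post_init__(self) -> None:
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.trans_x = np.asarray(self.trans_x)
        self.trans_y = np.asarray(self.trans_y)
        self.in_tissue = np.asarray(self.in_tissue, dtype=bool)
        if self.transresolution <= 0:
            raise ValidationError("transresolution must be positive")
        n = len(self.barcodes)
        if not (len(self.trans_x) == len(self.trans_y) == len(self.in_tissue) == n):
            raise ValidationError("spot table columns have unequal lengths")
        if len(set(self.barcodes.tolist())) != n:
            raise ValidationError("spot barcodes are not unique")
        for name, col in (("TransX", self.trans_x), ("TransY", self.trans_y)):
            frac = np.mod(np.asarray(col, dtype=float), 1.0)
            bad = np.nonzero(frac != 0)[0]
            if bad.size:
                raise ValidationError(
                    f"non-integer {name} for barcode {self.barcodes[bad[0]]!r}"
                )
            neg = np.nonzero(np.asarray(col, dtype=float) < 0)[0]
            if neg.size:
                raise ValidationError(
                    f"negative {name} for barcode {self.barcodes[neg[0]]!r}"
                )
        self.trans_x = self.trans_x.astype(np.int64)
        self.trans_y = self.trans_y.astype(np.int64)
        # hex offset encoding: columns within one row share parity
        for row in np.unique(self.trans_y):
            cols = self.trans_x[self.trans_y == row]
            if np.unique(cols % 2).size > 1:
                raise ValidationError(
                    f"TransX parity mixed within row {int(row)}; "
                    "not a valid hex offset encoding"
                )

    def __len__(self) -> int:
        return len(self.barcodes)

    def subset(self, mask: np.ndarray) -> "SpotGrid":
        return SpotGrid(
            self.barcodes[mask],
            self.trans_x[mask],
            self.trans_y[mask],
            self.in_tissue[mask],
            self.transresolution,
            self.spot_diameter,
        )

    def tissue_only(self) -> "SpotGrid":
        return self.subset(self.in_tissue)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.barcodes,
                "in_tissue": self.in_tissue.astype(int),
                "array_row": self.trans_y,
                "array_col": self.trans_x,
            }
        )


@dataclass
class MSIRaster:
    """Square-raster ion-image stack: pixels x m/z intensities.

    ``intensity[i, j]`` is the intensity of ``mz_values[j]`` at the pixel
    with indices ``(meta_x[i], meta_y[i])``.
    """

    meta_x: np.ndarray
    meta_y: np.ndarray
    mz_values: np.ndarray
    intensity: np.ndarray
    metaresolution: float = DEFAULT_MSI_STEP_UM
    pixel_ids: np.ndarray | None = None
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE

    def __post_init__(self) -> None:
        self.meta_x = np.asarray(self.meta_x, dtype=np.int64)
        self.meta_y = np.asarray(self.meta_y, dtype=np.int64)
        self.mz_values = np.asarray(self.mz_values, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.metaresolution <= 0:
            raise ValidationError("metaresolution must be positive")
        n = len(self.meta_x)
        if len(self.meta_y) != n:
            raise ValidationError("MetaX and MetaY have unequal lengths")
        if self.intensity.shape != (n, len(self.mz_values)):
            raise ValidationError(
                f"intensity shape {self.intensity.shape} does not match "
                f"{n} pixels x {len(self.mz_values)} m/z values"
            )
        pairs = set(zip(self.meta_x.tolist(), self.meta_y.tolist()))
        if len(pairs) != n:
            raise ValidationError("duplicate (MetaX, MetaY) pixel indices")
        if np.any(np.diff(self.mz_values) <= 0):
            raise ValidationError("mz_values must be strictly increasing")
        lo, hi = self.mz_range
        if self.mz_values.size and (
            self.mz_values[0] < lo or self.mz_values[-1] > hi
        ):
            raise ValidationError(
                f"m/z values outside instrument range {lo}-{hi} Da"
            )
        if np.any(self.intensity < 0):
            raise ValidationError("intensities must be non-negative")
        if self.pixel_ids is None:
            self.pixel_ids = np.array(
                [f"px_{x}_{y}" for x, y in zip(self.meta_x, self.meta_y)],
                dtype=object,
            )
        else:
            self.pixel_ids = np.asarray(self.pixel_ids, dtype=object)

    def __len__(self) -> int:
        return len(self.meta_x)


def hex_to_physical(grid: SpotGrid) -> np.ndarray:
    """Convert hex array indices to physical micrometre coordinates.

    Returns an ``(n, 2)`` array of ``(x, y)`` points in the ST unified
    frame, in input order.  x = (col/2 + 0.5) * pitch compresses the
    parity-doubled column index back to half-pitch steps; y scales row
    index by sqrt(3)/2 of the pitch, the row spacing of a regular
    hexagonal lattice.
    """
    res = grid.transresolution
    x = (grid.trans_x / 2.0 + 0.5) * res
    y = grid.trans_y * ROW_FACTOR * res
    return np.column_stack([x, y])


def msi_to_physical(raster: MSIRaster) -> np.ndarray:
    """Convert raster pixel indices to micrometre coordinates.

    Returns an ``(n, 2)`` array of ``(x, y)`` points in the MSI unified
    frame: index times step in each axis.
    """
    res = raster.metaresolution
    return np.column_stack([raster.meta_x * res, raster.meta_y * res])
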