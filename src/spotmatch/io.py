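"""Readers and writers for the standard file dialects.

Spot tables use the Visium ``tissue_positions.csv`` dialect (5- or
6-column, header auto-detected); ion images come from imzML (via
pyimzml, continuous or processed mode) or a long-format CSV
``x,y,mz,intensity``; landmarks, designs and branch assignments are
plain CSV.  Output matrices go to TSV or MatrixMarket.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    DEFAULT_MSI_STEP_UM,
    DEFAULT_PITCH_UM,
    MSIRaster,
    SpotGrid,
    ValidationError,
)
from .integration import SpotMetaboliteMatrix
from .registration import SimilarityTransform
from .trajectory import BranchAssignment

__all__ = [
    "read_tissue_positions",
    "write_tissue_positions",
    "read_msi_csv",
    "write_msi_csv",
    "read_imzml",
    "read_landmarks",
    "write_landmarks",
    "read_design",
    "read_branch_assignment",
    "read_cell_proportions",
    "write_transform_json",
    "read_transform_json",
    "write_matrix_tsv",
    "write_matrix_mtx",
]

_TP_COLUMNS_6 = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]
_TP_COLUMNS_5 = _TP_COLUMNS_6[:4] + ["pxl_in_fullres"]


def read_tissue_positions(
    path: str | Path, transresolution: float = DEFAULT_PITCH_UM
) -> SpotGrid:
    """Read a Visium-style ``tissue_positions.csv`` into a :class:`SpotGrid`.

    Handles both the headered 6-column dialect and the older headerless
    list; pixel columns, when present, are ignored (registration works in
    array space).  ``array_col`` maps to TransX and ``array_row`` to
    TransY.
    """
    first = pd.read_csv(path, nrows=1, header=None)
    has_header = str(first.iloc[0, 0]).strip().lower() == "barcode"
    if has_header:
        df = pd.read_csv(path)
        df.columns = [c.strip().lower() for c in df.columns]
    else:
        raw = pd.read_csv(path, header=None)
        ncol = raw.shape[1]
        if ncol == 6:
            raw.columns = _TP_COLUMNS_6
        elif ncol == 5:
            raw.columns = _TP_COLUMNS_5
        elif ncol == 4:
            raw.columns = _TP_COLUMNS_6[:4]
        else:
            raise ValidationError(
                f"unrecognised tissue_positions layout with {ncol} columns"
            )
        df = raw
    required = {"barcode", "in_tissue", "array_row", "array_col"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"tissue_positions missing columns: {sorted(missing)}")
    return SpotGrid(
        barcodes=df["barcode"].to_numpy(dtype=object),
        trans_x=df["array_col"].to_numpy(),
        trans_y=df["array_row"].to_numpy(),
        in_tissue=df["in_tissue"].to_numpy().astype(bool),
        transresolution=transresolution,
    )


def write_tissue_positions(grid: SpotGrid, path: str | Path) -> None:
    grid.to_frame().to_csv(path, index=False)


def read_msi_csv(
    path: str | Path,
    metaresolution: float = DEFAULT_MSI_STEP_UM,
    mz_range: tuple[float, float] | None = None,
) -> MSIRaster:
    """Read long-format ``x,y,mz,intensity`` CSV into an :class:`MSIRaster`.

    Missing (pixel, m/z) combinations are filled with zero intensity.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"x", "y", "mz", "intensity"}
    if not required <= set(df.columns):
        raise ValidationError(f"MSI CSV needs columns {sorted(required)}")
    wide = df.pivot_table(
        index=["x", "y"], columns="mz", values="intensity", aggfunc="sum", fill_value=0.0
    )
    xy = wide.index.to_frame(index=False)
    kwargs = {} if mz_range is None else {"mz_range": mz_range}
    return MSIRaster(
        meta_x=xy["x"].to_numpy(),
        meta_y=xy["y"].to_numpy(),
        mz_values=wide.columns.to_numpy(dtype=float),
        intensity=wide.to_numpy(dtype=float),
        metaresolution=metaresolution,
        **kwargs,
    )


def write_msi_csv(raster: MSIRaster, path: str | Path) -> None:
    """Write an :class:`MSIRaster` as long-format CSV (zeros omitted)."""
    rows = []
    for i in range(len(raster)):
        nz = np.nonzero(raster.intensity[i])[0]
        cols = nz if nz.size else np.arange(len(raster.mz_values))
        for j in cols:
            rows.append(
                (raster.meta_x[i], raster.meta_y[i], raster.mz_values[j],
                 raster.intensity[i, j])
            )
    pd.DataFrame(rows, columns=["x", "y", "mz", "intensity"]).to_csv(path, index=False)


def read_imzml(
    path: str | Path,
    metaresolution: float = DEFAULT_MSI_STEP_UM,
    mz_decimals: int = 4,
    mz_range: tuple[float, float] | None = None,
) -> MSIRaster:
    """Read an imzML ion-image file (continuous or processed mode).

    Spectra are binned onto a common m/z axis by rounding to
    ``mz_decimals`` decimals, which is exact for centroided synthetic
    data and a coarse union for processed-mode files.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    coords = []
    spectra = []
    mz_union: set[float] = set()
    for i, (x, y, *_z) in enumerate(parser.coordinates):
        mzs, ints = parser.getspectrum(i)
        mzs = np.round(np.asarray(mzs, dtype=float), mz_decimals)
        coords.append((int(x), int(y)))
        spectra.append((mzs, np.asarray(ints, dtype=float)))
        mz_union.update(mzs.tolist())
    mz_values = np.array(sorted(mz_union))
    lookup = {mz: j for j, mz in enumerate(mz_values)}
    intensity = np.zeros((len(coords), mz_values.size))
    for i, (mzs, ints) in enumerate(spectra):
        for mz, v in zip(mzs, ints):
            intensity[i, lookup[mz]] += v
    coords_arr = np.asarray(coords)
    kwargs = {} if mz_range is None else {"mz_range": mz_range}
    return MSIRaster(
        meta_x=coords_arr[:, 0],
        meta_y=coords_arr[:, 1],
        mz_values=mz_values,
        intensity=intensity,
        metaresolution=metaresolution,
        **kwargs,
    )


def read_landmarks(path: str | Path) -> pd.DataFrame:
    """Landmark CSV ``spot_barcode,pixel_x,pixel_y`` (MSI pixel indices)."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"spot_barcode", "pixel_x", "pixel_y"}
    if not required <= set(df.columns):
        raise ValidationError(f"landmark CSV needs columns {sorted(required)}")
    return df


def write_landmarks(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    """Design CSV ``barcode,group`` for the two-group contrast."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"barcode", "group"} <= set(df.columns):
        raise ValidationError("design CSV needs columns ['barcode', 'group']")
    return df


def read_branch_assignment(path: str | Path) -> BranchAssignment:
    """Branch CSV ``barcode,branch,pseudotime`` from an external trajectory."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"barcode", "branch", "pseudotime"} <= set(df.columns):
        raise ValidationError(
            "branch CSV needs columns ['barcode', 'branch', 'pseudotime']"
        )
    return BranchAssignment(
        barcodes=df["barcode"].to_numpy(dtype=object),
        branch=df["branch"].to_numpy(dtype=object),
        pseudotime=df["pseudotime"].to_numpy(dtype=float),
    )


def read_cell_proportions(path: str | Path) -> pd.DataFrame:
    """Per-spot cell-type proportion CSV: ``barcode`` column + one per type."""
    df = pd.read_csv(path)
    if "barcode" not in df.columns:
        raise ValidationError("proportion CSV needs a 'barcode' column")
    return df.set_index("barcode")


def write_transform_json(
    transform: SimilarityTransform, path: str | Path, diagnostics: dict | None = None
) -> None:
    payload = transform.to_dict()
    if diagnostics:
        payload["diagnostics"] = diagnostics
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_transform_json(path: str | Path) -> SimilarityTransform:
    return SimilarityTransform.from_dict(json.loads(Path(path).read_text()))


def write_matrix_tsv(matrix: SpotMetaboliteMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "barcode"
    df.to_csv(path, sep="\t")


def write_matrix_mtx(matrix: SpotMetaboliteMatrix, prefix: str | Path) -> None:
    """MatrixMarket triple: ``<prefix>.mtx``, ``<prefix>.barcodes.txt``,
    ``<prefix>.mz.txt``."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), csr_matrix(matrix.intensity))
    prefix.with_suffix(".barcodes.txt").write_text(
        "\n".join(map(str, matrix.barcodes)) + "\n"
    )
    prefix.with_suffix(".mz.txt").write_text(
        "\n".join(f"{v:.6f}" for v in matrix.mz_values) + "\n"
    )
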