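"""Synthetic paired-section generator with known ground truth.

Every downstream module is exercised on data this generator produces: a
hexagonal spot array at the assay's 100 um pitch, a square MSI raster at
the instrument's 100 um step, a known similarity transform between the
two frames, region-structured log-normal metabolite intensities, planted
two-group effects, and planted per-branch monotone pseudotime trends.

The defaults are the study conditions the rest of the package is
validated under: 55 um spots on a 100 um hex pitch, m/z values inside
70-1200 Da, a 5-of-50 informative-metabolite group contrast at a 2 SD
log-scale effect with 30 spots per group, and branch paths of >= 50
spots with planted rank correlations of at least 0.5 in magnitude.
Intensities are log-normal because MSI ion counts are positive and
right-skewed; group and branch effects are additive on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    DEFAULT_MSI_STEP_UM,
    DEFAULT_PITCH_UM,
    DEFAULT_SPOT_DIAMETER_UM,
    MSIRaster,
    SpotGrid,
    hex_to_physical,
)
from .integration import SpotMetaboliteMatrix
from .registration import LandmarkSet, SimilarityTransform
from .trajectory import BranchAssignment

__all__ = [
    "SyntheticScenario",
    "SectionPair",
    "generate_section_pair",
    "generate_group_study",
    "generate_branch_study",
]

REGION_LABELS = ("villous", "basal_plate")


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic paired section (seed mandatory)."""

    seed: int
    n_rows: int = 20
    n_cols: int = 20
    transresolution: float = DEFAULT_PITCH_UM
    metaresolution: float = DEFAULT_MSI_STEP_UM
    scale: float = 1.0
    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    n_landmarks: int = 8
    landmark_jitter_um: float = 0.0
    outlier_fraction: float = 0.0
    outlier_displacement_um: float = 500.0
    n_metabolites: int = 20
    mz_min: float = 70.0
    mz_max: float = 1200.0
    region_log_mean_shift: float = 1.0   # log-scale separation between regions
    log_sd: float = 0.3                  # within-region log-intensity SD
    # group study
    n_per_group: int = 30
    n_group_metabolites: int = 50
    n_informative: int = 5
    effect_sd_units: float = 2.0
    # branch study
    n_prebranch: int = 30
    n_per_branch: int = 40
    branch_effect_sd_units: float = 2.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")
        if not 0 <= self.outlier_fraction < 0.5:
            raise ValueError("outlier_fraction must be in [0, 0.5)")


@dataclass
class SectionPair:
    """A paired synthetic section plus its generating truth."""

    grid: SpotGrid
    raster: MSIRaster
    landmarks: LandmarkSet
    true_transform: SimilarityTransform
    spot_regions: np.ndarray
    region_log_means: np.ndarray  # regions x metabolites
    outlier_landmarks: np.ndarray  # boolean per landmark


def _hex_grid(scenario: SyntheticScenario) -> SpotGrid:
    rows, cols = np.meshgrid(
        np.arange(scenario.n_rows), np.arange(scenario.n_cols), indexing="ij"
    )
    trans_y = rows.ravel()
    trans_x = 2 * cols.ravel() + (trans_y % 2)  # parity-offset column encoding
    barcodes = np.array(
        [f"SPOT-{r:03d}-{c:03d}" for r, c in zip(trans_y, trans_x)], dtype=object
    )
    return SpotGrid(
        barcodes=barcodes,
        trans_x=trans_x,
        trans_y=trans_y,
        in_tissue=np.ones(trans_y.size, dtype=bool),
        transresolution=scenario.transresolution,
        spot_diameter=DEFAULT_SPOT_DIAMETER_UM,
    )


def _true_transform(scenario: SyntheticScenario) -> SimilarityTransform:
    return SimilarityTransform(
        scale=scenario.scale,
        rotation_deg=scenario.rotation_deg,
        centroid_msi=np.zeros(2),
        centroid_st=np.asarray(scenario.translation, dtype=float),
    )


def _spread_indices(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy farthest-point sampling for evenly distributed landmarks."""
    n = len(points)
    start = int(rng.integers(n))
    chosen = [start]
    d = np.linalg.norm(points - points[start], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return np.array(chosen)


def generate_section_pair(scenario: SyntheticScenario) -> SectionPair:
    """Build a hex spot grid, a matching MSI raster, and landmark pairs.

    MSI pixel coordinates are the ST-frame tissue pushed through the
    *inverse* of the true transform, snapped to the raster; landmarks are
    evenly spread spots whose MSI-side points get the configured jitter,
    with a configured fraction grossly displaced as outliers.
    """
    rng = np.random.default_rng(scenario.seed)
    grid = _hex_grid(scenario)
    st_points = hex_to_physical(grid)
    truth = _true_transform(scenario)
    inverse = truth.inverse()

    # raster covering the tissue in the MSI frame
    corners_msi = inverse.apply(
        np.array(
            [
                [st_points[:, 0].min(), st_points[:, 1].min()],
                [st_points[:, 0].min(), st_points[:, 1].max()],
                [st_points[:, 0].max(), st_points[:, 1].min()],
                [st_points[:, 0].max(), st_points[:, 1].max()],
            ]
        )
    )
    step = scenario.metaresolution
    ix_min = int(np.floor(corners_msi[:, 0].min() / step))
    ix_max = int(np.ceil(corners_msi[:, 0].max() / step))
    iy_min = int(np.floor(corners_msi[:, 1].min() / step))
    iy_max = int(np.ceil(corners_msi[:, 1].max() / step))
    if ix_min < 0 or iy_min < 0:
        shift_x, shift_y = max(0, -ix_min), max(0, -iy_min)
    else:
        shift_x = shift_y = 0
    gx, gy = np.meshgrid(
        np.arange(ix_min + shift_x, ix_max + shift_x + 1),
        np.arange(iy_min + shift_y, iy_max + shift_y + 1),
        indexing="ij",
    )
    meta_x, meta_y = gx.ravel(), gy.ravel()
    if meta_x.size < 4:
        raise ValueError("raster too small to cover the tissue")
    # the index shift is a pure MSI-frame translation; fold it into the truth
    offset = np.array([shift_x * step, shift_y * step])
    truth = SimilarityTransform(
        scale=truth.scale,
        rotation_deg=truth.rotation_deg,
        centroid_msi=truth.centroid_msi + offset,
        centroid_st=truth.centroid_st,
    )
    inverse = truth.inverse()

    pixel_msi = np.column_stack([meta_x * step, meta_y * step])
    pixel_st = truth.apply(pixel_msi)

    # two-territory region map split along x in the ST frame
    x_split = np.median(st_points[:, 0])
    spot_regions = np.where(st_points[:, 0] <= x_split, REGION_LABELS[0], REGION_LABELS[1])
    pixel_regions = (pixel_st[:, 0] > x_split).astype(int)

    mz = np.sort(
        rng.uniform(scenario.mz_min, scenario.mz_max, scenario.n_metabolites)
    )
    base = rng.normal(2.0, 0.5, scenario.n_metabolites)
    shift = rng.choice([-1.0, 1.0], scenario.n_metabolites) * scenario.region_log_mean_shift
    region_log_means = np.vstack([base, base + shift])
    log_int = region_log_means[pixel_regions] + rng.normal(
        0.0, scenario.log_sd, (meta_x.size, scenario.n_metabolites)
    )
    raster = MSIRaster(
        meta_x=meta_x,
        meta_y=meta_y,
        mz_values=mz,
        intensity=np.exp(log_int),
        metaresolution=step,
        mz_range=(scenario.mz_min, scenario.mz_max),
    )

    lm_idx = _spread_indices(st_points, scenario.n_landmarks, rng)
    lm_st = st_points[lm_idx]
    lm_msi = inverse.apply(lm_st)
    if scenario.landmark_jitter_um > 0:
        lm_msi = lm_msi + rng.normal(0, scenario.landmark_jitter_um, lm_msi.shape)
    n_out = int(round(scenario.outlier_fraction * scenario.n_landmarks))
    outliers = np.zeros(scenario.n_landmarks, dtype=bool)
    if n_out:
        which = rng.choice(scenario.n_landmarks, n_out, replace=False)
        outliers[which] = True
        theta = rng.uniform(0, 2 * np.pi, n_out)
        lm_msi[which] += scenario.outlier_displacement_um * np.column_stack(
            [np.cos(theta), np.sin(theta)]
        )
    landmarks = LandmarkSet(
        spot_barcodes=grid.barcodes[lm_idx],
        st_points=lm_st,
        pixel_ids=np.array([f"lm_px_{i}" for i in range(scenario.n_landmarks)], dtype=object),
        msi_points=lm_msi,
    )
    return SectionPair(
        grid=grid,
        raster=raster,
        landmarks=landmarks,
        true_transform=truth,
        spot_regions=spot_regions,
        region_log_means=region_log_means,
        outlier_landmarks=outliers,
    )


def generate_group_study(
    scenario: SyntheticScenario,
) -> tuple[SpotMetaboliteMatrix, SpotMetaboliteMatrix, dict]:
    """Case and control spot-metabolite matrices with planted effects.

    Log intensities are Gaussian with per-metabolite baselines; the first
    ``n_informative`` (after a seeded shuffle) receive an additive case
    effect of ``effect_sd_units`` standard deviations on the log scale.
    Returns (case, control, truth) where truth lists the informative
    metabolite indices and m/z values.
    """
    rng = np.random.default_rng(scenario.seed)
    m = scenario.n_group_metabolites
    n = scenario.n_per_group
    mz = np.sort(rng.uniform(scenario.mz_min, scenario.mz_max, m))
    base = rng.normal(2.0, 0.5, m)
    informative = rng.choice(m, scenario.n_informative, replace=False)
    effect = np.zeros(m)
    effect[informative] = scenario.effect_sd_units * scenario.log_sd

    def matrix(group: str, shift: np.ndarray) -> SpotMetaboliteMatrix:
        log_int = base + shift + rng.normal(0, scenario.log_sd, (n, m))
        return SpotMetaboliteMatrix(
            barcodes=np.array([f"{group}-{i:03d}" for i in range(n)], dtype=object),
            mz_values=mz,
            intensity=np.exp(log_int),
            n_pixels_per_spot=np.ones(n, dtype=np.int64),
        )

    case = matrix("CASE", effect)
    control = matrix("CTRL", np.zeros(m))
    truth = {
        "informative_indices": np.sort(informative),
        "informative_mz": mz[np.sort(informative)],
        "effect_sd_units": scenario.effect_sd_units,
    }
    return case, control, truth


def generate_branch_study(
    scenario: SyntheticScenario,
) -> tuple[SpotMetaboliteMatrix, BranchAssignment, dict]:
    """Spot matrix plus branch/pseudotime assignment with planted trends.

    Each metabolite gets a (branch1, branch2) trend pattern drawn from
    {increasing, decreasing, unchanged}^2, including the class that falls
    along the syncytiotrophoblast path and rises along the
    extravillous path.  Trend slopes are sized so the planted rank
    correlation magnitude along a full path is at least 0.5.
    """
    rng = np.random.default_rng(scenario.seed)
    n_pre, n_b = scenario.n_prebranch, scenario.n_per_branch
    barcodes = np.array(
        [f"TRAJ-{i:03d}" for i in range(n_pre + 2 * n_b)], dtype=object
    )
    branch = np.array(
        ["prebranch"] * n_pre + ["branch1"] * n_b + ["branch2"] * n_b, dtype=object
    )
    pt = np.concatenate(
        [
            rng.uniform(0.0, 0.4, n_pre),
            rng.uniform(0.4, 1.0, n_b),
            rng.uniform(0.4, 1.0, n_b),
        ]
    )
    assignment = BranchAssignment(barcodes=barcodes, branch=branch, pseudotime=pt)

    patterns = [
        ("decreasing", "increasing"),  # falls to SCT, rises to EVT
        ("increasing", "decreasing"),
        ("decreasing", "decreasing"),
        ("unchanged", "increasing"),
        ("unchanged", "unchanged"),
    ]
    m = scenario.n_metabolites
    mz = np.sort(rng.uniform(scenario.mz_min, scenario.mz_max, m))
    chosen = [patterns[i % len(patterns)] for i in range(m)]
    slope_mag = scenario.branch_effect_sd_units * scenario.log_sd / 0.6
    sign = {"increasing": 1.0, "decreasing": -1.0, "unchanged": 0.0}

    log_int = np.empty((len(barcodes), m))
    base = rng.normal(2.0, 0.5, m)
    for j, (d1, d2) in enumerate(chosen):
        # prebranch spots are shared by both paths, so they stay at the
        # common baseline; each branch departs monotonically from it
        mu = np.full(len(barcodes), base[j])
        b1, b2 = branch == "branch1", branch == "branch2"
        mu[b1] += sign[d1] * slope_mag * (pt[b1] - 0.4)
        mu[b2] += sign[d2] * slope_mag * (pt[b2] - 0.4)
        log_int[:, j] = mu + rng.normal(0, scenario.log_sd, len(barcodes))
    matrix = SpotMetaboliteMatrix(
        barcodes=barcodes,
        mz_values=mz,
        intensity=np.exp(log_int),
        n_pixels_per_spot=np.ones(len(barcodes), dtype=np.int64),
    )
    truth = {"patterns": chosen, "mz": mz}
    return matrix, assignment, truth
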