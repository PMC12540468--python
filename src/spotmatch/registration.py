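"""Landmark-based similarity registration of the MSI frame onto the ST frame.

The method estimates scale, rotation and translation from >= 6 manually
paired landmarks (spot barcode <-> MSI pixel), following the spot-match
recipe: per-pair distance ratios give the scale after robust outlier
filtering; per-pair orientation differences give the rotation via a
circular mean; the translation aligns the landmark centroids ("central
coordinates").  A closed-form least-squares Procrustes fit is provided
as an independent oracle for validation only.

Sign convention: the stored rotation angle rotates MSI coordinates into
the ST frame, counter-clockwise positive.  Per-pair angles as printed
(MSI orientation minus ST orientation) are therefore negated when the
transform is assembled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LandmarkSet",
    "SimilarityTransform",
    "RegistrationDiagnostics",
    "RegistrationError",
    "pairwise_scale_ratios",
    "estimate_scale",
    "pairwise_rotation_angles",
    "estimate_rotation",
    "fit_transform",
    "apply_transform",
    "procrustes_oracle",
]

MIN_LANDMARKS = 6
ROTATION_FLAG_DEG = 5.0


class RegistrationError(ValueError):
    """Raised when landmarks cannot support a similarity fit."""


@dataclass
class LandmarkSet:
    """Paired landmark points: ST spots vs MSI pixels, in micrometres.

    ``st_points[i]`` and ``msi_points[i]`` are corresponding physical
    locations in the ST_unified and MSI_unified frames respectively.
    """

    spot_barcodes: np.ndarray
    st_points: np.ndarray
    pixel_ids: np.ndarray
    msi_points: np.ndarray

    def __post_init__(self) -> None:
        self.spot_barcodes = np.asarray(self.spot_barcodes, dtype=object)
        self.pixel_ids = np.asarray(self.pixel_ids, dtype=object)
        self.st_points = np.asarray(self.st_points, dtype=float)
        self.msi_points = np.asarray(self.msi_points, dtype=float)
        n = len(self.spot_barcodes)
        if self.st_points.shape != (n, 2) or self.msi_points.shape != (n, 2):
            raise RegistrationError("landmark point arrays must be (n, 2)")
        if n < MIN_LANDMARKS:
            raise RegistrationError(
                f"{n} landmark pairs supplied; at least {MIN_LANDMARKS} "
                "evenly distributed spots are required"
            )
        if len(set(self.spot_barcodes.tolist())) != n:
            raise RegistrationError("duplicate spot barcodes in landmark set")
        if len(set(map(tuple, np.round(self.msi_points, 9)))) != n:
            raise RegistrationError("duplicate MSI landmark points")
        for name, pts in (("ST", self.st_points), ("MSI", self.msi_points)):
            if not np.all(np.isfinite(pts)):
                raise RegistrationError(f"non-finite {name} landmark coordinates")
            spread = pts - pts.mean(axis=0)
            if np.linalg.matrix_rank(spread, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
                raise RegistrationError(
                    f"{name} landmarks are collinear; rotation is not identifiable"
                )

    def __len__(self) -> int:
        return len(self.spot_barcodes)


@dataclass
class SimilarityTransform:
    """Scale + rotation + translation mapping MSI_unified -> ST_unified.

    Applied as ``p' = s * R(theta) @ (p - centroid_msi) + centroid_st``,
    which is the centred form used throughout; ``translation`` caches the
    equivalent offset of the uncentred form ``p' = s R p + t``.
    """

    scale: float
    rotation_deg: float
    centroid_msi: np.ndarray
    centroid_st: np.ndarray
    reflection: bool = False

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise RegistrationError("scale must be positive")
        self.rotation_deg = wrap_angle_deg(self.rotation_deg)
        self.centroid_msi = np.asarray(self.centroid_msi, dtype=float)
        self.centroid_st = np.asarray(self.centroid_st, dtype=float)

    @property
    def rotation_matrix(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        r = np.array([[c, -s], [s, c]])
        if self.reflection:
            r = r @ np.diag([1.0, -1.0])
        return r

    @property
    def translation(self) -> np.ndarray:
        """Offset of the uncentred form p' = s R p + t."""
        return self.centroid_st - self.scale * self.rotation_matrix @ self.centroid_msi

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (
            self.scale * (pts - self.centroid_msi) @ self.rotation_matrix.T
            + self.centroid_st
        )
        return out

    def inverse(self) -> "SimilarityTransform":
        if self.reflection:
            # reflected transforms invert to reflected transforms with the
            # same axis convention; compose matrices explicitly
            raise NotImplementedError("inverse of reflected transform")
        return SimilarityTransform(
            scale=1.0 / self.scale,
            rotation_deg=-self.rotation_deg,
            centroid_msi=self.centroid_st,
            centroid_st=self.centroid_msi,
        )

    def to_dict(self) -> dict:
        return {
            "scale": float(self.scale),
            "rotation_deg": float(self.rotation_deg),
            "tx": float(self.translation[0]),
            "ty": float(self.translation[1]),
            "centroid_msi": [float(v) for v in self.centroid_msi],
            "centroid_st": [float(v) for v in self.centroid_st],
            "reflection": bool(self.reflection),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(
            scale=d["scale"],
            rotation_deg=d["rotation_deg"],
            centroid_msi=np.asarray(d["centroid_msi"], dtype=float),
            centroid_st=np.asarray(d["centroid_st"], dtype=float),
            reflection=d.get("reflection", False),
        )


@dataclass
class RegistrationDiagnostics:
    pairwise_ratios: np.ndarray
    kept_ratio_mask: np.ndarray
    pairwise_angles_deg: np.ndarray
    angle_spread_deg: float
    exceeds_5deg: bool
    landmark_rmse_um: float


def wrap_angle_deg(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap angle(s) to the half-open interval (-180, 180]."""
    wrapped = -np.mod(-np.asarray(angle, dtype=float) + 180.0, 360.0) + 180.0
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def pairwise_scale_ratios(landmarks: LandmarkSet) -> np.ndarray:
    """Distance ratio ST/MSI for every unordered landmark pair.

    C(n, 2) values, each the Euclidean landmark distance in the ST frame
    divided by the corresponding distance in the MSI frame.
    """
    ia, ib = _pair_indices(len(landmarks))
    d_st = np.linalg.norm(landmarks.st_points[ia] - landmarks.st_points[ib], axis=1)
    d_msi = np.linalg.norm(landmarks.msi_points[ia] - landmarks.msi_points[ib], axis=1)
    zero = np.nonzero(d_msi == 0)[0]
    if zero.size:
        k = zero[0]
        raise RegistrationError(
            "coincident MSI landmark points for pair "
            f"({landmarks.pixel_ids[ia[k]]!r}, {landmarks.pixel_ids[ib[k]]!r})"
        )
    return d_st / d_msi


def mad_outlier_mask(values: np.ndarray, n_mads: float = 3.0) -> np.ndarray:
    """True for values within median +/- n_mads * MAD.

    With MAD == 0 (at least half the values identical) only exact ties
    with the median survive.
    """
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    return np.abs(values - med) <= n_mads * mad


def iqr_outlier_mask(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Tukey fence: True within [Q1 - k*IQR, Q3 + k*IQR]."""
    values = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values >= q1 - k * iqr) & (values <= q3 + k * iqr)


_OUTLIER_RULES = {"mad": mad_outlier_mask, "iqr": iqr_outlier_mask, "none": None}


def estimate_scale(
    ratios: np.ndarray, outlier_rule: str = "mad"
) -> tuple[float, np.ndarray]:
    """Mean of the pairwise ratios surviving the outlier filter.

    Returns ``(scale, kept_mask)``.  ``outlier_rule`` is one of ``"mad"``
    (median +/- 3 MAD, default), ``"iqr"`` (1.5 IQR fences) or ``"none"``.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size < 3:
        raise RegistrationError("need at least 3 pairwise ratios")
    if outlier_rule not in _OUTLIER_RULES:
        raise RegistrationError(f"unknown outlier rule {outlier_rule!r}")
    rule = _OUTLIER_RULES[outlier_rule]
    kept = np.ones(ratios.size, dtype=bool) if rule is None else rule(ratios)
    if kept.sum() < 2:
        raise RegistrationError(
            "outlier filter rejected nearly all ratios; supply more or "
            "better-distributed landmarks"
        )
    return float(ratios[kept].mean()), kept


def pairwise_rotation_angles(landmarks: LandmarkSet) -> np.ndarray:
    """Signed orientation difference (MSI minus ST) per landmark pair, degrees.

    Each pair's segment orientation is measured with the two-argument
    arctangent (full-quadrant), the difference wrapped to (-180, 180].
    The one-argument ratio form cannot distinguish opposite quadrants and
    would alias rotations beyond +/-90 degrees.
    """
    ia, ib = _pair_indices(len(landmarks))
    d_st = landmarks.st_points[ia] - landmarks.st_points[ib]
    d_msi = landmarks.msi_points[ia] - landmarks.msi_points[ib]
    deg_st = np.linalg.norm(d_st, axis=1)
    deg_msi = np.linalg.norm(d_msi, axis=1)
    for dist, ids in ((deg_st, landmarks.spot_barcodes), (deg_msi, landmarks.pixel_ids)):
        zero = np.nonzero(dist == 0)[0]
        if zero.size:
            k = zero[0]
            raise RegistrationError(
                f"coincident landmark points for pair ({ids[ia[k]]!r}, {ids[ib[k]]!r})"
            )
    ang_msi = np.arctan2(d_msi[:, 1], d_msi[:, 0])
    ang_st = np.arctan2(d_st[:, 1], d_st[:, 0])
    return wrap_angle_deg(np.rad2deg(ang_msi - ang_st))


def circular_mean_deg(
    angles_deg: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """(Weighted) mean direction of angles on the circle, in (-180, 180]."""
    th = np.deg2rad(np.asarray(angles_deg, dtype=float))
    w = np.ones_like(th) if weights is None else np.asarray(weights, float)
    mean = np.arctan2(np.average(np.sin(th), weights=w),
                      np.average(np.cos(th), weights=w))
    return wrap_angle_deg(np.rad2deg(mean))


def circular_std_deg(
    angles_deg: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """(Weighted) circular standard deviation sqrt(-2 ln R), in degrees."""
    th = np.deg2rad(np.asarray(angles_deg, dtype=float))
    w = np.ones_like(th) if weights is None else np.asarray(weights, float)
    r = np.hypot(np.average(np.sin(th), weights=w),
                 np.average(np.cos(th), weights=w))
    r = min(r, 1.0)
    if r == 0.0:
        return float("inf")
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(r))))


def estimate_rotation(
    angles_deg: np.ndarray,
    spread_ceiling_deg: float = 15.0,
    weights: np.ndarray | None = None,
) -> tuple[float, float, bool]:
    """Circular mean and spread of pairwise angles; flag rotations > 5 deg.

    Returns ``(rotation_deg, angle_spread_deg, exceeds_5deg)``.  Angles
    are averaged as unit vectors so estimates straddling the +/-180 wrap
    are handled correctly.  Optional ``weights`` downweight noisy angles:
    the orientation error of a jittered pair scales inversely with its
    baseline length, so pair distances are the natural choice.
    ``exceeds_5deg`` is True only for strict exceedance (|rotation| > 5).
    """
    angles_deg = np.asarray(angles_deg, dtype=float)
    if angles_deg.size < 3:
        raise RegistrationError("need at least 3 pairwise angles")
    rot = circular_mean_deg(angles_deg, weights)
    spread = circular_std_deg(angles_deg, weights)
    if spread > spread_ceiling_deg:
        raise RegistrationError(
            f"pairwise rotation spread {spread:.1f} deg exceeds "
            f"{spread_ceiling_deg} deg; landmarks are inconsistent with a "
            "rigid rotation (check pairing)"
        )
    return rot, spread, abs(rot) > ROTATION_FLAG_DEG


def _detect_reflection(landmarks: LandmarkSet) -> bool:
    """Majority sign of cross-product consistency over landmark triples."""
    n = len(landmarks)
    signs = []
    for i in range(n - 2):
        for j in range(i + 1, n - 1):
            for k in range(j + 1, n):
                def cross(pts):
                    v1 = pts[j] - pts[i]
                    v2 = pts[k] - pts[i]
                    return v1[0] * v2[1] - v1[1] * v2[0]

                c_st = cross(landmarks.st_points)
                c_msi = cross(landmarks.msi_points)
                if c_st != 0 and c_msi != 0:
                    signs.append(np.sign(c_st) != np.sign(c_msi))
    return bool(signs) and (np.mean(signs) > 0.5)


def fit_transform(
    landmarks: LandmarkSet,
    outlier_rule: str = "mad",
    rotation_mode: str = "always",
    allow_reflection: bool = False,
    spread_ceiling_deg: float = 15.0,
) -> tuple[SimilarityTransform, RegistrationDiagnostics]:
    """Estimate the MSI->ST similarity transform from paired landmarks.

    Scale is the robust mean of pairwise distance ratios; rotation the
    (negated) circular mean of pairwise orientation differences;
    translation aligns the scaled-and-rotated MSI landmark centroid with
    the ST landmark centroid.

    ``rotation_mode``:
        ``"always"``   apply the estimated rotation (default);
        ``"threshold"`` apply it only when |rotation| exceeds 5 degrees,
        the deviation level at which the protocol mandates an adjustment.
    """
    if rotation_mode not in ("always", "threshold"):
        raise RegistrationError(f"unknown rotation mode {rotation_mode!r}")
    original = landmarks
    reflected = _detect_reflection(landmarks)
    if reflected:
        if not allow_reflection:
            raise RegistrationError(
                "landmark orientation is mirrored between frames (flipped "
                "section?); pass allow_reflection=True to proceed"
            )
        warnings.warn("mirrored landmark configuration detected", stacklevel=2)
        # estimate on y-flipped MSI points; the stored transform replays the
        # flip via its reflection flag (R @ diag(1, -1) with the original
        # MSI centroid, which equals fitting on the flipped cloud)
        landmarks = LandmarkSet(
            landmarks.spot_barcodes,
            landmarks.st_points,
            landmarks.pixel_ids,
            landmarks.msi_points * np.array([1.0, -1.0]),
        )

    ratios = pairwise_scale_ratios(landmarks)
    scale, kept = estimate_scale(ratios, outlier_rule)
    angles = pairwise_rotation_angles(landmarks)
    ia, ib = _pair_indices(len(landmarks))
    pair_lengths = np.linalg.norm(
        landmarks.msi_points[ia] - landmarks.msi_points[ib], axis=1
    )
    mean_pair_angle, spread, exceeds = estimate_rotation(
        angles, spread_ceiling_deg, weights=pair_lengths
    )
    # per-pair angles are MSI minus ST; rotating MSI into ST needs the negative
    rotation = -mean_pair_angle
    if rotation_mode == "threshold" and not exceeds:
        rotation = 0.0

    transform = SimilarityTransform(
        scale=scale,
        rotation_deg=rotation,
        centroid_msi=original.msi_points.mean(axis=0),
        centroid_st=original.st_points.mean(axis=0),
        reflection=reflected,
    )
    resid = transform.apply(original.msi_points) - original.st_points
    rmse = float(np.sqrt((resid**2).sum(axis=1).mean()))
    diag = RegistrationDiagnostics(
        pairwise_ratios=ratios,
        kept_ratio_mask=kept,
        pairwise_angles_deg=angles,
        angle_spread_deg=spread,
        exceeds_5deg=exceeds,
        landmark_rmse_um=rmse,
    )
    return transform, diag


def apply_transform(points: np.ndarray, transform: SimilarityTransform) -> np.ndarray:
    """Map MSI_unified points into the ST_unified frame."""
    pts = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise RegistrationError("non-finite input points")
    return transform.apply(pts)


def procrustes_oracle(landmarks: LandmarkSet) -> SimilarityTransform:
    """Closed-form least-squares similarity fit (validation oracle).

    Umeyama/Kabsch estimator: SVD of the cross-covariance of centred
    landmark clouds gives the optimal rotation, the trace of the singular
    values over the MSI variance gives the optimal scale.  Used only to
    validate the pairwise-ratio method; reflection solutions are rejected.
    """
    src = landmarks.msi_points
    dst = landmarks.st_points
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    cov = xd.T @ xs / len(src)
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    if d < 0:
        raise RegistrationError(
            "least-squares solution is a reflection; landmark pairing is mirrored"
        )
    r = u @ vt
    var_s = (xs**2).sum() / len(src)
    if var_s == 0:
        raise RegistrationError("degenerate (coincident) MSI landmarks")
    scale = float(s.sum() / var_s)
    rotation = float(np.rad2deg(np.arctan2(r[1, 0], r[0, 0])))
    return SimilarityTransform(
        scale=scale,
        rotation_deg=rotation,
        centroid_msi=mu_s,
        centroid_st=mu_d,
    )
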