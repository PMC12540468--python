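"""Similarity-transform estimation from paired landmarks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spotmatch.registration import (
    LandmarkSet,
    RegistrationError,
    SimilarityTransform,
    apply_transform,
    circular_mean_deg,
    circular_std_deg,
    estimate_rotation,
    estimate_scale,
    fit_transform,
    pairwise_rotation_angles,
    pairwise_scale_ratios,
    procrustes_oracle,
    wrap_angle_deg,
)

from conftest import make_landmarks


class TestPairwiseRatios:
    def test_uniform_scale_gives_constant_ratios(self):
        lm, _ = make_landmarks(scale=2.0, seed=1)
        np.testing.assert_allclose(pairwise_scale_ratios(lm), 2.0, rtol=1e-12)

    def test_identity_gives_unit_ratios(self):
        lm, _ = make_landmarks(seed=2)
        np.testing.assert_allclose(pairwise_scale_ratios(lm), 1.0, rtol=1e-12)

    def test_one_displaced_landmark_contaminates_exactly_its_pairs(self):
        lm, _ = make_landmarks(n=6, seed=3)
        msi = lm.msi_points.copy()
        msi[2] += [700.0, -400.0]
        bad = LandmarkSet(lm.spot_barcodes, lm.st_points, lm.pixel_ids, msi)
        ratios = pairwise_scale_ratios(bad)
        # brute-force: the 5 pairs containing landmark 2 are contaminated
        ia, ib = np.triu_indices(6, k=1)
        contaminated = (ia == 2) | (ib == 2)
        assert contaminated.sum() == 5 and ratios.size == 15
        assert np.allclose(ratios[~contaminated], 1.0, rtol=1e-12)
        assert not np.allclose(ratios[contaminated], 1.0, rtol=1e-3)

    def test_coincident_msi_points_raise(self):
        lm, _ = make_landmarks(seed=4)
        msi = lm.msi_points.copy()
        msi[1] = msi[0]
        with pytest.raises(RegistrationError, match="duplicate|coincident"):
            bad = LandmarkSet(lm.spot_barcodes, lm.st_points, lm.pixel_ids, msi)
            pairwise_scale_ratios(bad)


class TestEstimateScale:
    def test_constant_ratios(self):
        scale, kept = estimate_scale(np.full(10, 1.5))
        assert scale == 1.5 and kept.all()

    def test_mad_rejects_gross_outlier(self):
        scale, kept = estimate_scale(np.array([1.0, 1.0, 1.0, 10.0]))
        assert scale == 1.0
        np.testing.assert_array_equal(kept, [True, True, True, False])

    def test_contaminated_pairs_filtered_to_clean_mean(self):
        lm, _ = make_landmarks(n=6, scale=1.2, seed=5, jitter=2.0)
        msi = lm.msi_points.copy()
        msi[0] += [900.0, 900.0]
        bad = LandmarkSet(lm.spot_barcodes, lm.st_points, lm.pixel_ids, msi)
        ratios = pairwise_scale_ratios(bad)
        ia, ib = np.triu_indices(6, k=1)
        clean = ~((ia == 0) | (ib == 0))
        scale, kept = estimate_scale(ratios)
        assert scale == pytest.approx(ratios[clean].mean(), rel=1e-6)

    def test_too_few_ratios(self):
        with pytest.raises(RegistrationError):
            estimate_scale(np.array([1.0, 1.0]))


class TestRotation:
    def test_identity_angles_zero(self):
        lm, _ = make_landmarks(seed=6)
        np.testing.assert_allclose(pairwise_rotation_angles(lm), 0.0, atol=1e-10)

    def test_rotated_point_set_gives_constant_pairwise_angle(self):
        # MSI->ST rotation of +30 deg means MSI-minus-ST orientations of -30
        lm, _ = make_landmarks(rotation_deg=30.0, seed=7)
        np.testing.assert_allclose(pairwise_rotation_angles(lm), -30.0, atol=1e-9)

    def test_circular_mean_across_wrap(self):
        # unit-vector oracle: mean of 179 and -179 is 180, not 0
        assert circular_mean_deg(np.array([179.0, -179.0])) == pytest.approx(180.0)

    def test_estimate_rotation_small_sample(self):
        rot, spread, exceeds = estimate_rotation(np.array([4.0, 5.0, 6.0]))
        assert rot == pytest.approx(5.0, abs=1e-9)
        # circular SD oracle: sqrt(-2 ln R) of three unit vectors
        th = np.deg2rad([4.0, 5.0, 6.0])
        r = np.hypot(np.sin(th).mean(), np.cos(th).mean())
        assert spread == pytest.approx(np.rad2deg(np.sqrt(-2 * np.log(r))))
        assert spread == pytest.approx(0.8165, abs=2e-3)
        assert not exceeds  # 5 is not strictly greater than 5

    def test_constant_30_flags_rotation(self):
        rot, _, exceeds = estimate_rotation(np.full(5, 30.0))
        assert rot == pytest.approx(30.0) and exceeds

    def test_inconsistent_angles_raise(self):
        with pytest.raises(RegistrationError, match="inconsistent"):
            estimate_rotation(np.array([0.0, 60.0, -60.0, 90.0]))


@pytest.mark.parametrize("scale", [0.5, 1.0, 1.3, 2.0])
@pytest.mark.parametrize("rotation", [-170.0, -30.0, 0.0, 5.0, 90.0, 179.0])
def test_exact_recovery_noise_free(scale, rotation):
    lm, truth = make_landmarks(
        scale=scale, rotation_deg=rotation, translation=(831.0, -212.0), seed=11
    )
    t, diag = fit_transform(lm)
    assert t.scale == pytest.approx(truth.scale, rel=1e-9)
    assert wrap_angle_deg(t.rotation_deg - truth.rotation_deg) == pytest.approx(0, abs=1e-9)
    np.testing.assert_allclose(t.translation, truth.translation, rtol=1e-9, atol=1e-6)
    assert diag.landmark_rmse_um <= 1e-6


def test_identity_landmarks_give_identity_transform():
    lm, _ = make_landmarks(seed=12)
    t, diag = fit_transform(lm)
    assert t.scale == pytest.approx(1.0, rel=1e-12)
    assert t.rotation_deg == pytest.approx(0.0, abs=1e-9)
    assert diag.landmark_rmse_um < 1e-9


def test_jittered_fit_rmse_near_noise_level():
    sigma = 10.0
    rmses = []
    for seed in range(100):
        lm, truth = make_landmarks(
            scale=1.3, rotation_deg=25.0, translation=(400, -150),
            seed=seed, jitter=sigma,
        )
        t, diag = fit_transform(lm)
        rmses.append(diag.landmark_rmse_um)
        assert t.scale == pytest.approx(truth.scale, rel=0.05)
        assert abs(wrap_angle_deg(t.rotation_deg - truth.rotation_deg)) < 3.0
    assert sigma / 2 < np.mean(rmses) < 2 * sigma


def test_threshold_mode_drops_small_rotation_only():
    lm, _ = make_landmarks(rotation_deg=3.0, seed=13)
    t_thresh, diag = fit_transform(lm, rotation_mode="threshold")
    assert not diag.exceeds_5deg and t_thresh.rotation_deg == 0.0
    t_always, _ = fit_transform(lm, rotation_mode="always")
    assert t_always.rotation_deg == pytest.approx(3.0, abs=1e-9)
    lm2, _ = make_landmarks(rotation_deg=12.0, seed=13)
    t2, diag2 = fit_transform(lm2, rotation_mode="threshold")
    assert diag2.exceeds_5deg and t2.rotation_deg == pytest.approx(12.0, abs=1e-9)


def test_estimators_invariant_to_landmark_order():
    lm, _ = make_landmarks(scale=1.4, rotation_deg=40.0, seed=14, jitter=5.0)
    perm = np.random.default_rng(0).permutation(len(lm))
    lm_perm = LandmarkSet(
        lm.spot_barcodes[perm], lm.st_points[perm],
        lm.pixel_ids[perm], lm.msi_points[perm],
    )
    t1, _ = fit_transform(lm)
    t2, _ = fit_transform(lm_perm)
    assert t1.scale == pytest.approx(t2.scale, rel=1e-12)
    assert t1.rotation_deg == pytest.approx(t2.rotation_deg, abs=1e-9)


def test_apply_transform_round_trip():
    lm, truth = make_landmarks(scale=1.3, rotation_deg=25.0,
                               translation=(400, -150), seed=15)
    t, _ = fit_transform(lm)
    held_out = np.random.default_rng(1).uniform(-500, 3500, (50, 2))
    mapped = apply_transform(held_out, t)
    np.testing.assert_allclose(mapped, truth.apply(held_out), atol=1e-6)
    back = t.inverse().apply(mapped)
    np.testing.assert_allclose(back, held_out, atol=1e-9)


def test_pure_scale_about_centroid_doubles_offsets():
    t = SimilarityTransform(2.0, 0.0, np.zeros(2), np.zeros(2))
    pts = np.array([[1.0, 2.0], [-3.0, 4.0]])
    np.testing.assert_allclose(t.apply(pts), 2 * pts)


class TestProcrustesOracle:
    def test_noise_free_equivalence_with_method(self):
        lm, truth = make_landmarks(scale=1.3, rotation_deg=25.0,
                                   translation=(400, -150), seed=16)
        t_m, _ = fit_transform(lm)
        t_o = procrustes_oracle(lm)
        assert t_o.scale == pytest.approx(t_m.scale, rel=1e-9)
        assert t_o.rotation_deg == pytest.approx(t_m.rotation_deg, abs=1e-9)
        np.testing.assert_allclose(t_o.translation, t_m.translation, rtol=1e-9)

    def test_identity(self):
        lm, _ = make_landmarks(seed=17)
        t = procrustes_oracle(lm)
        assert t.scale == pytest.approx(1.0) and t.rotation_deg == pytest.approx(0.0, abs=1e-9)

    def test_oracle_never_beaten_on_jittered_data(self):
        for seed in range(100):
            lm, _ = make_landmarks(scale=1.2, rotation_deg=-40.0, seed=seed, jitter=8.0)
            _, diag = fit_transform(lm)
            t_o = procrustes_oracle(lm)
            rmse_o = np.sqrt(
                ((t_o.apply(lm.msi_points) - lm.st_points) ** 2).sum(axis=1).mean()
            )
            assert rmse_o <= diag.landmark_rmse_um + 1e-9

    def test_matches_independent_library_estimator(self):
        pytest.importorskip("skimage")
        from skimage.transform import estimate_transform

        lm, _ = make_landmarks(scale=1.7, rotation_deg=65.0,
                               translation=(100, 900), seed=18, jitter=6.0)
        t_o = procrustes_oracle(lm)
        t_sk = estimate_transform("similarity", lm.msi_points, lm.st_points)
        assert t_o.scale == pytest.approx(t_sk.scale, rel=1e-9)
        assert np.deg2rad(t_o.rotation_deg) == pytest.approx(t_sk.rotation, abs=1e-9)


def test_robust_scale_recovery_with_corrupted_landmarks():
    hits = 0
    for seed in range(100):
        lm, truth = make_landmarks(n=10, scale=1.3, rotation_deg=20.0,
                                   seed=seed, jitter=5.0)
        rng = np.random.default_rng(seed + 10_000)
        msi = lm.msi_points.copy()
        which = rng.choice(10, 2, replace=False)
        theta = rng.uniform(0, 2 * np.pi, 2)
        msi[which] += 600.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        bad = LandmarkSet(lm.spot_barcodes, lm.st_points, lm.pixel_ids, msi)
        scale, _ = estimate_scale(pairwise_scale_ratios(bad))
        if abs(scale - truth.scale) / truth.scale < 0.01:
            hits += 1
    assert hits >= 95


def test_reflection_detected_and_rejected_by_default():
    lm, _ = make_landmarks(seed=19)
    mirrored = LandmarkSet(
        lm.spot_barcodes, lm.st_points, lm.pixel_ids,
        lm.msi_points * np.array([1.0, -1.0]),
    )
    with pytest.raises(RegistrationError, match="mirror"):
        fit_transform(mirrored)
    with pytest.warns(UserWarning):
        t, diag = fit_transform(mirrored, allow_reflection=True)
    assert t.reflection and diag.landmark_rmse_um < 1e-6


def test_fewer_than_six_landmarks_rejected():
    with pytest.raises(RegistrationError, match="at least 6"):
        make_landmarks(n=5)


@settings(max_examples=30, deadline=None)
@given(
    scale=st.floats(0.3, 3.0),
    rotation=st.floats(-179.0, 180.0),
    tx=st.floats(-2000, 2000),
    ty=st.floats(-2000, 2000),
)
def test_recovery_property_over_transform_space(scale, rotation, tx, ty):
    """Noise-free fits invert any similarity transform, including wraps."""
    lm, truth = make_landmarks(scale=scale, rotation_deg=rotation,
                               translation=(tx, ty), seed=20)
    t, diag = fit_transform(lm)
    assert t.scale == pytest.approx(truth.scale, rel=1e-8)
    assert wrap_angle_deg(t.rotation_deg - truth.rotation_deg) == pytest.approx(0, abs=1e-7)
    assert diag.landmark_rmse_um < 1e-5
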