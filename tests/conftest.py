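import numpy as np
import pytest

from spotmatch import (
    LandmarkSet,
    SimilarityTransform,
    SyntheticScenario,
    generate_section_pair,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_pair():
    """Noise-free synthetic section with a known nontrivial transform."""
    scenario = SyntheticScenario(
        seed=7, scale=1.3, rotation_deg=25.0, translation=(400.0, -150.0)
    )
    return generate_section_pair(scenario)


def make_landmarks(n=8, scale=1.0, rotation_deg=0.0, translation=(0.0, 0.0),
                   seed=0, jitter=0.0):
    """Random well-spread ST landmarks and their exact (or jittered) MSI
    counterparts under a known MSI->ST similarity transform."""
    rng = np.random.default_rng(seed)
    st = rng.uniform(0, 3000, (n, 2))
    truth = SimilarityTransform(
        scale=scale,
        rotation_deg=rotation_deg,
        centroid_msi=np.zeros(2),
        centroid_st=np.asarray(translation, float),
    )
    msi = truth.inverse().apply(st)
    if jitter:
        msi = msi + rng.normal(0, jitter, msi.shape)
    lm = LandmarkSet(
        spot_barcodes=np.array([f"bc{i}" for i in range(n)], dtype=object),
        st_points=st,
        pixel_ids=np.array([f"px{i}" for i in range(n)], dtype=object),
        msi_points=msi,
    )
    return lm, truth
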