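"""Register a synthetic MSI raster onto a spot array and recover the
planted similarity transform.

Builds a paired section whose MSI frame is scaled 1.3x, rotated 25
degrees and translated relative to the spot frame, then estimates the
transform from 8 landmark pairs via pairwise distance ratios (robust
mean) and pairwise orientation differences (circular mean).
"""

import numpy as np

from spotmatch import (
    SyntheticScenario,
    fit_transform,
    generate_section_pair,
    procrustes_oracle,
)

scenario = SyntheticScenario(
    seed=1, scale=1.3, rotation_deg=25.0, translation=(400.0, -150.0),
    n_landmarks=8,
)
pair = generate_section_pair(scenario)

transform, diag = fit_transform(pair.landmarks)
oracle = procrustes_oracle(pair.landmarks)

print(f"planted   : scale={pair.true_transform.scale:.6f} "
      f"rotation={pair.true_transform.rotation_deg:.4f} deg")
print(f"recovered : scale={transform.scale:.6f} "
      f"rotation={transform.rotation_deg:.4f} deg")
print(f"oracle    : scale={oracle.scale:.6f} "
      f"rotation={oracle.rotation_deg:.4f} deg")
print(f"landmark RMSE: {diag.landmark_rmse_um:.2e} um "
      f"(ratios kept {diag.kept_ratio_mask.sum()}/{diag.kept_ratio_mask.size}, "
      f"rotation-over-5deg flag: {diag.exceeds_5deg})")

# held-out check: every MSI pixel lands where the planted transform says
from spotmatch.geometry import msi_to_physical

pix = msi_to_physical(pair.raster)
err = np.abs(transform.apply(pix) - pair.true_transform.apply(pix)).max()
print(f"max pixel mapping error vs truth: {err:.2e} um")
# With noise-free landmarks both estimators recover the planted transform
# to machine precision; the RMSE is the residual of landmarks after mapping.
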