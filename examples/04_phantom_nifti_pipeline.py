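"""NIfTI path end to end: phantom -> files -> ROI reduction -> fit.

Builds a 4D DWI phantom with an ellipsoidal tumor, writes NIfTI + bval
files, reads them back, reduces the ROI to a mean-signal decay and
refits the tumor parameters.
"""

import tempfile
from pathlib import Path

from gammadwi import (
    EllipsoidSpec,
    GammaParams,
    NoiseSpec,
    fit_gamma_model,
    reduce_roi,
    simulate_phantom,
)
from gammadwi.io import read_dwi, write_bvals, write_dwi
from gammadwi.simulate import DEFAULT_B_VALUES

tumor = EllipsoidSpec(
    center=(16.0, 16.0, 8.0), semiaxes=(6.0, 5.0, 4.0),
    params=GammaParams.from_display(0.0623, 74.55), s0=1000.0,
)
vol, mask = simulate_phantom((33, 33, 17), tumor, noise=NoiseSpec("rician", 80.0), seed=5)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    write_dwi(tmp / "dwi.nii.gz", vol)
    write_bvals(tmp / "dwi.bval", DEFAULT_B_VALUES)
    loaded, bvals = read_dwi(tmp / "dwi.nii.gz", tmp / "dwi.bval")
    print(f"volume {loaded.shape}, b-values {bvals}")

decay = reduce_roi(loaded, mask, bvals, roi_id="tumor", subject_id="phantom")
print(f"ROI holds {decay.n_voxels} voxels; mean signal per b: "
      + ", ".join(f"{s:.1f}" for s in decay.signals))

fit = fit_gamma_model(decay, theta_fixed=tumor.params.theta)
print(f"\nrefit kappa = {fit.params.kappa:.4f} (truth {tumor.params.kappa})")
print("Averaging hundreds of voxels suppresses the Rician noise, so the")
print("ROI-level fit lands close to the generating parameters.")
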