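"""Decompose a tumor ROI with the dual-tree complex wavelet transform.

Takes one 60x60 tumor ROI from a simulated day-15 projection, runs the
2-level dual-tree transform, and prints the subband geometry, the
reconstruction error (the transform is perfectly invertible), and the
fraction of signal energy captured by each of the four derived images
(HF1/HF2 = RMS of the six oriented complex magnitudes per level,
LF1/LF2 = scaling images).
"""

import numpy as np

from ilpci import DetectorModel, build_liver_phantom
from ilpci.dtcwt import dtcwt_forward, dtcwt_inverse, subband_images
from ilpci.optics import default_geometry, default_optics
from ilpci.pipeline import sample_stage_rois
from ilpci.simulate import simulate_projection

GRID = (512, 512)
scene = build_liver_phantom("15d", GRID, seed=3)
image = simulate_projection(scene, default_optics(), default_geometry(GRID),
                            DetectorModel(seed=3))
roi = sample_stage_rois(image, scene.region_mask, "15d", n=1, size=60, seed=3)[-1]
print(f"ROI at {roi.origin} in the {roi.region_label} region")

x = roi.pixels.astype(float)
pyramid = dtcwt_forward(x, levels=2)
err = np.abs(dtcwt_inverse(pyramid) - x).max()
print(f"perfect reconstruction: max abs error {err:.2e} on 16-bit data")

sub = subband_images(pyramid)
for name, img in sub.as_dict().items():
    print(f"{name}: shape {img.shape}, energy {np.sum(img.astype(float)**2):.3e}")
print("LF images carry the bulk of the energy (tissue structure); HF images "
      "hold the oriented fine detail that is stable under small shifts")
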