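"""Simulate one phase-contrast liver projection and quantify edge enhancement.

Builds a day-12 phantom (necrotic lumps + vessels), projects it at 15 keV,
propagates the exit wave 0.5 m with the Fresnel transfer function, and applies
the detector model.  Printed numbers: the phantom's ground-truth lump census,
and the image contrast with and without free-space propagation — the contrast
gain is the phase-contrast edge enhancement that makes lump boundaries visible.
"""

import numpy as np

from ilpci import DetectorModel, build_liver_phantom, detect, project_scene
from ilpci.optics import default_geometry, default_optics
from ilpci.projection import fresnel_intensity, tie_intensity

GRID = (512, 512)

scene = build_liver_phantom("12d", GRID, seed=42)
print(f"phantom: stage {scene.stage}, {scene.lump_count()} necrotic lumps, "
      f"mean radius {scene.mean_lump_radius():.1f} px, "
      f"{len(scene.vessel_paths)} vessels")

optics = default_optics()
geometry = default_geometry(GRID)
projection = project_scene(scene, optics)

contact = projection.contact_intensity
propagated = fresnel_intensity(projection, geometry, optics)
linearized = tie_intensity(projection, geometry, optics)

inside = scene.region_mask > 0
def contrast(img):
    return (img[inside].max() - img[inside].min()) / img[inside].mean()

print(f"contact-image contrast (absorption only): {contrast(contact):.4f}")
print(f"propagated contrast (phase + absorption): {contrast(propagated):.4f}")
# the linearization clips to 0 at the strongest lump edges; compare elsewhere
ok = linearized > 0.1
print(f"linearized (TIE) vs full Fresnel, RMS rel. diff: "
      f"{np.sqrt(np.mean(((propagated[ok] - linearized[ok]) / linearized[ok]) ** 2)):.4f}")

image = detect(propagated, DetectorModel(seed=0), geometry.pixel_size_m)
print(f"detected image: {image.pixels.dtype}, range "
      f"[{image.pixels.min()}, {image.pixels.max()}]")
print("the contrast gain under propagation is the edge enhancement produced "
      "by the Laplacian of the X-ray phase at material boundaries")
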