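"""Batch simulation: phantoms -> propagated projections -> TIFF dataset."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detector import DetectorModel, ProjectionImage, detect
from .optics import OpticalConstants, PropagationGeometry, default_geometry, default_optics
from .phantom import STAGES, PhantomParams, PhantomScene, build_liver_phantom
from .projection import fresnel_intensity, project_scene
from .roi import write_image


def derive_seed(master_seed: int, *parts) -> int:
    """Stable per-item seed below 2^31 from (master seed, labels, indices),
    so adding images never perturbs earlier ones."""
    key = ":".join([str(master_seed), *map(str, parts)]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


@dataclass
class SimulationConfig:
    stages: tuple[str, ...] = STAGES
    images_per_stage: int = 6
    grid_shape: tuple[int, int] = (1024, 1024)
    master_seed: int = 0
    optics: OpticalConstants = field(default_factory=default_optics)
    geometry: PropagationGeometry | None = None
    detector: DetectorModel = field(default_factory=DetectorModel)
    phantom_params: PhantomParams = field(default_factory=PhantomParams)

    def resolved_geometry(self) -> PropagationGeometry:
        return self.geometry or default_geometry(self.grid_shape)


def simulate_projection(
    scene: PhantomScene,
    optics: OpticalConstants,
    geometry: PropagationGeometry,
    detector: DetectorModel,
    rng: np.random.Generator | None = None,
) -> ProjectionImage:
    """One phantom through the full chain: project, propagate, detect."""
    projection = project_scene(scene, optics)
    intensity = fresnel_intensity(projection, geometry, optics)
    image = detect(intensity, detector, geometry.pixel_size_m, rng=rng)
    image.meta.update({"stage": scene.stage, "seed": scene.seed})
    return image


def simulate_dataset(config: SimulationConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write one image TIFF + one mask TIFF per phantom plus a manifest CSV.

    Deterministic under a fixed master seed: per-image seeds are derived by
    hashing (master seed, stage, index).  Returns the manifest with columns
    ``file, mask, stage, seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geometry = config.resolved_geometry()
    rows = []
    for stage in config.stages:
        for i in range(config.images_per_stage):
            seed = derive_seed(config.master_seed, stage, i)
            scene = build_liver_phantom(
                stage, config.grid_shape, geometry.pixel_size_m, seed,
                config.phantom_params,
            )
            rng = np.random.default_rng(derive_seed(config.master_seed, stage, i, "detector"))
            image = simulate_projection(scene, config.optics, geometry, config.detector, rng)
            img_name = f"{stage}_{i:02d}.tif"
            mask_name = f"{stage}_{i:02d}_mask.tif"
            write_image(image, out_dir / img_name)
            write_image(scene.region_mask.astype(np.uint8), out_dir / mask_name)
            rows.append({"file": img_name, "mask": mask_name, "stage": stage, "seed": seed})
    manifest = pd.DataFrame(rows, columns=["file", "mask", "stage", "seed"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
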