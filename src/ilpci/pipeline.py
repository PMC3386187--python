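"""End-to-end orchestration: simulate -> ROIs -> texture -> PCA -> SVM.

`run_pipeline` drives the whole study design from one config and one master
seed, writing images, masks, feature tables (CSV), the per-stage
discriminant report and the SVM staging report (JSON), plus a run log.
The intermediate helpers are the library surface used by scripts and
notebooks; the CLI wraps them thinly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detector import DetectorModel, ProjectionImage
from .dtcwt import dtcwt_forward, subband_images, subband_texture
from .glcm import TEXTURE_FEATURE_NAMES, orientation_average
from .optics import default_geometry, default_optics
from .pca import FeatureMatrix, fit_discriminant, stage_monotonicity
from .phantom import STAGES, PhantomParams, build_liver_phantom
from .roi import ROIPatch, quantize, sample_rois
from .simulate import SimulationConfig, derive_seed, simulate_dataset, simulate_projection
from .svm import ClassifierConfig, build_stage_features, crossval_svm

logger = logging.getLogger(__name__)

SUBBANDS = ("HF1", "HF2", "LF1", "LF2")


@dataclass
class PipelineConfig:
    stages: tuple[str, ...] = STAGES
    images_per_stage: int = 1
    rois_per_region: int = 20
    roi_size: int = 60
    n_gray_levels: int = 16
    dtcwt_levels: int = 2
    cr_threshold: float = 0.80
    disjoint_rois: bool = False
    grid_shape: tuple[int, int] = (1024, 1024)
    master_seed: int = 0
    svm: ClassifierConfig = field(default_factory=ClassifierConfig)
    detector: DetectorModel = field(default_factory=DetectorModel)
    phantom_params: PhantomParams = field(default_factory=PhantomParams)

    def validate(self) -> None:
        if not self.stages:
            raise ValueError("config is missing 'stages'")
        if self.images_per_stage < 1 or self.rois_per_region < 1:
            raise ValueError("images_per_stage and rois_per_region must be >= 1")
        if self.roi_size < 8:
            raise ValueError("roi_size must be >= 8")
        if not 0 < self.cr_threshold <= 1:
            raise ValueError("cr_threshold must lie in (0, 1]")


def glcm_feature_rows(
    patches: list[ROIPatch], n_gray_levels: int = 16, distance: int = 1
) -> pd.DataFrame:
    """Orientation-averaged co-occurrence features, one row per ROI."""
    rows = []
    for p in patches:
        vec = orientation_average(quantize(p, n_gray_levels), distance)
        rows.append(
            {"source_id": p.source_id, "region_label": p.region_label, "stage": p.stage}
            | dict(zip(TEXTURE_FEATURE_NAMES, vec.as_array()))
        )
    return pd.DataFrame(rows)


def dtcwt_feature_rows(
    patches: list[ROIPatch],
    n_gray_levels: int = 16,
    levels: int = 2,
    distance: int = 1,
) -> pd.DataFrame:
    """Subband texture features (HF1/HF2/LF1/LF2), four rows per ROI."""
    rows = []
    for p in patches:
        pyramid = dtcwt_forward(p.pixels.astype(np.float64), levels)
        vectors = subband_texture(subband_images(pyramid), n_gray_levels, distance)
        for subband, vec in vectors.items():
            rows.append(
                {
                    "source_id": p.source_id,
                    "region_label": p.region_label,
                    "stage": p.stage,
                    "subband": subband,
                }
                | dict(zip(TEXTURE_FEATURE_NAMES, vec.as_array()))
            )
    return pd.DataFrame(rows)


def feature_matrix_from_frame(df: pd.DataFrame) -> FeatureMatrix:
    return FeatureMatrix(
        values=df[list(TEXTURE_FEATURE_NAMES)].to_numpy(),
        region_labels=df["region_label"].to_numpy() if "region_label" in df else None,
        stages=df["stage"].to_numpy() if "stage" in df else None,
    )


def sample_stage_rois(
    image: ProjectionImage,
    mask: np.ndarray,
    stage: str,
    n: int,
    size: int,
    seed: int,
    disjoint: bool = False,
    source_id: str | None = None,
) -> list[ROIPatch]:
    """n normal + n tumor ROIs from one projection image."""
    patches = []
    for label in ("normal", "tumor"):
        patches.extend(
            sample_rois(
                image, mask, label, n=n, size=size,
                seed=derive_seed(seed, stage, label), disjoint=disjoint,
                stage=stage, source_id=source_id,
            )
        )
    return patches


def simulate_stage_patches(config: PipelineConfig) -> list[ROIPatch]:
    """Simulate every (stage, image) of the config and sample its ROIs,
    without writing anything to disk."""
    config.validate()
    geometry = default_geometry(config.grid_shape)
    optics = default_optics()
    patches: list[ROIPatch] = []
    for stage in config.stages:
        for i in range(config.images_per_stage):
            seed = derive_seed(config.master_seed, stage, i)
            scene = build_liver_phantom(
                stage, config.grid_shape, geometry.pixel_size_m, seed, config.phantom_params
            )
            rng = np.random.default_rng(derive_seed(config.master_seed, stage, i, "detector"))
            image = simulate_projection(scene, optics, geometry, config.detector, rng)
            patches.extend(
                sample_stage_rois(
                    image, scene.region_mask, stage,
                    n=config.rois_per_region, size=config.roi_size,
                    seed=derive_seed(config.master_seed, stage, i, "roi"),
                    disjoint=config.disjoint_rois, source_id=f"{stage}_{i:02d}",
                )
            )
    return patches


def discriminant_by_stage(features: pd.DataFrame, cr_threshold: float = 0.80) -> dict:
    """Per-stage correlation PCA + F1 sign rule (one fit per stage, the
    protocol behind a per-stage mean +- sd table)."""
    report: dict = {}
    for stage, group in features.groupby("stage", sort=False):
        fm = feature_matrix_from_frame(group)
        _, _, disc, selected = fit_discriminant(fm, cr_threshold)
        report[str(stage)] = {
            "normal": disc.group_mean_sd.get("normal"),
            "tumor": disc.group_mean_sd.get("tumor"),
            "cr1": disc.cr1,
            "n_components": len(selected),
            "agreement": disc.agreement,
        }
    return report


def lf1_stage_trend(
    dtcwt_features: pd.DataFrame, cr_threshold: float = 0.80, subband: str = "LF1"
) -> tuple[dict[str, float], float]:
    """Pooled tumor-ROI PCA of one subband's texture; per-stage F1 means and
    their Spearman rank correlation with stage order."""
    sel = dtcwt_features[
        (dtcwt_features["subband"] == subband)
        & (dtcwt_features["region_label"] == "tumor")
    ]
    fm = feature_matrix_from_frame(sel)
    dataset = build_stage_features(fm, cr_threshold)
    f1 = dataset.features[:, 0]
    order = sorted(set(dataset.stages), key=lambda s: float(str(s).rstrip("d")))
    means = {str(s): float(f1[dataset.stages == s].mean()) for s in order}
    return means, stage_monotonicity(means)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run the full study and write all artifacts under ``out_dir``.

    Writes images+masks+manifest, ``features.csv``, ``features_dtcwt.csv``,
    ``discriminant_report.json``, ``svm_report.json`` and ``run_log.json``.
    Deterministic under a fixed master seed.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_name = "simulate"
    try:
        sim = SimulationConfig(
            stages=config.stages,
            images_per_stage=config.images_per_stage,
            grid_shape=config.grid_shape,
            master_seed=config.master_seed,
            detector=config.detector,
            phantom_params=config.phantom_params,
        )
        simulate_dataset(sim, out_dir / "images")

        stage_name = "extract+texture"
        patches = simulate_stage_patches(config)
        features = glcm_feature_rows(patches, config.n_gray_levels)
        features.to_csv(out_dir / "features.csv", index=False)
        dt_features = dtcwt_feature_rows(patches, config.n_gray_levels, config.dtcwt_levels)
        dt_features.to_csv(out_dir / "features_dtcwt.csv", index=False)

        stage_name = "discriminate"
        disc = discriminant_by_stage(features, config.cr_threshold)
        if len(config.stages) >= 3:
            lf1_means, rho = lf1_stage_trend(dt_features, config.cr_threshold)
        else:  # a rank trend needs >= 3 stages
            lf1_means, rho = None, None
        with open(out_dir / "discriminant_report.json", "w") as fh:
            json.dump(
                {"per_stage": disc, "lf1_stage_means": lf1_means, "lf1_spearman_rho": rho},
                fh, indent=2,
            )

        stage_name = "stage-classify"
        tumor_lf1 = dt_features[
            (dt_features["subband"] == "LF1") & (dt_features["region_label"] == "tumor")
        ]
        dataset = build_stage_features(feature_matrix_from_frame(tumor_lf1), config.cr_threshold)
        svm_report = crossval_svm(dataset, config.svm)
        with open(out_dir / "svm_report.json", "w") as fh:
            json.dump(
                {
                    "accuracy": svm_report.accuracy,
                    "fold_accuracies": svm_report.fold_accuracies.tolist(),
                    "best_params": svm_report.best_params,
                    "confusion": svm_report.confusion.tolist(),
                    "class_order": [str(c) for c in svm_report.class_order],
                    "permutation_accuracy": svm_report.permutation_accuracy,
                    "lf1_cr1": dataset.cr1,
                    "n_pc_features": dataset.features.shape[1],
                },
                fh, indent=2,
            )
    except Exception as exc:
        with open(out_dir / "run_log.json", "w") as fh:
            json.dump({"status": "failed", "failed_stage": stage_name, "error": str(exc)}, fh)
        raise RuntimeError(f"pipeline failed during stage {stage_name!r}: {exc}") from exc

    cfg_text = json.dumps(_config_dict(config), sort_keys=True, default=str)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(
            {
                "status": "ok",
                "python": platform.python_version(),
                "numpy": np.__version__,
                "master_seed": config.master_seed,
                "config": json.loads(cfg_text),
                "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
            },
            fh, indent=2,
        )
    return out_dir


def _config_dict(config: PipelineConfig) -> dict:
    return asdict(config)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a flat TOML config; unknown or missing keys raise a config error
    naming the key."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {
        "stages", "images_per_stage", "rois_per_region", "roi_size",
        "n_gray_levels", "dtcwt_levels", "cr_threshold", "disjoint_rois",
        "grid_shape", "master_seed", "svm_folds", "svm_seed",
        "psf_sigma", "photons_per_pixel", "bit_depth", "noise",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "stages" not in raw:
        raise ValueError("config is missing 'stages'")
    kwargs: dict = {"stages": tuple(raw["stages"])}
    for key in ("images_per_stage", "rois_per_region", "roi_size", "n_gray_levels",
                "dtcwt_levels", "cr_threshold", "disjoint_rois", "master_seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "grid_shape" in raw:
        kwargs["grid_shape"] = tuple(raw["grid_shape"])
    svm_kwargs = {}
    if "svm_folds" in raw:
        svm_kwargs["n_folds"] = raw["svm_folds"]
    if "svm_seed" in raw:
        svm_kwargs["seed"] = raw["svm_seed"]
    if svm_kwargs:
        kwargs["svm"] = ClassifierConfig(**svm_kwargs)
    det_kwargs = {
        k: raw[k] for k in ("psf_sigma", "photons_per_pixel", "bit_depth", "noise") if k in raw
    }
    if det_kwargs:
        kwargs["detector"] = DetectorModel(**det_kwargs)
    config = PipelineConfig(**kwargs)
    config.validate()
    return config
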