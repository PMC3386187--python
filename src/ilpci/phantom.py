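"""Synthetic liver phantoms with staged tumors and ground-truth masks.

A phantom is a set of projected-thickness maps (meters) for four materials —
normal parenchyma, viable tumor, necrotic lumps, vessels — plus a per-pixel
region label.  The stage model follows the qualitative morphology of
implanted hepatocellular tumors observed in propagation-based imaging:

* day 6: diffuse, fine-grained tumor texture, no necrotic lumps;
* days 9/12/15: necrotic lumps (dense disk-like blobs with sharp,
  edge-enhancing boundaries) whose number density and mean radius grow with
  stage, with curvilinear vessels adjacent to the tumor.

Everything is generated from one integer seed; identical (stage, grid, seed,
params) reproduce the scene bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

BACKGROUND, NORMAL, TUMOR = 0, 1, 2

STAGES = ("6d", "9d", "12d", "15d")


@dataclass(frozen=True)
class StageParams:
    """Stage-dependent tumor morphology parameters (lengths in pixels)."""

    #: expected necrotic lumps per squared pixel of tumor area
    lump_density_per_px2: float
    #: mean lump radius in pixels
    lump_radius_px: float
    #: standard deviation of lump radius
    lump_radius_sd_px: float
    #: number of vessel paths adjacent to the tumor
    n_vessels: int


#: Default stage table.  Lump density and radius grow with stage so necrotic
#: coverage of the tumor rises from 0 (day 6) to roughly 40% (day 15).
DEFAULT_STAGE_TABLE: dict[str, StageParams] = {
    "6d": StageParams(0.0, 0.0, 0.0, 0),
    "9d": StageParams(8.0e-4, 4.0, 0.8, 1),
    "12d": StageParams(1.2e-3, 6.0, 1.2, 2),
    "15d": StageParams(1.6e-3, 9.0, 1.8, 2),
}


@dataclass(frozen=True)
class PhantomParams:
    """Geometry- and texture-model parameters of the liver phantom.

    Thicknesses are in meters, correlation lengths in pixels.  Defaults are
    chosen so that, at 15 keV with a 0.5 m propagation distance and 9 um
    pixels, parenchymal texture contrast sits a few times above shot noise
    while the fine tumor grain is an order of magnitude stronger — the
    regime in which tumor tissue is conspicuous in real projections.
    """

    liver_thickness_m: float = 2.0e-3
    liver_semiaxes_frac: tuple[float, float] = (0.40, 0.45)
    tumor_semiaxes_frac: tuple[float, float] = (0.20, 0.26)
    tumor_center_frac: tuple[float, float] = (0.52, 0.50)
    tumor_boundary_irregularity: float = 0.10
    tumor_base_thickness_m: float = 2.0e-4
    normal_texture_sigma_px: float = 4.0
    normal_texture_amp_m: float = 1.0e-5
    tumor_grain_sigma_px: float = 1.2
    tumor_grain_amp_m: float = 1.2e-5
    lump_thickness_scale: float = 2.0
    vessel_width_px: float = 1.8
    vessel_thickness_m: float = 6.0e-5
    tumor_fraction_check: float = 0.05  # sanity bound on tumor area fraction
    stage_table: dict[str, StageParams] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_TABLE)
    )


@dataclass
class PhantomScene:
    """Ground-truthed synthetic liver: thickness maps, labels, truth records."""

    thickness_maps: dict[str, np.ndarray]
    region_mask: np.ndarray
    stage: str
    seed: int
    pixel_size_m: float
    #: list of (row, col, radius_px) for every necrotic lump
    lumps: list[tuple[float, float, float]]
    #: list of (n_points, 2) vessel centerline arrays
    vessel_paths: list[np.ndarray]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.region_mask.shape

    def lump_count(self) -> int:
        return len(self.lumps)

    def mean_lump_radius(self) -> float:
        if not self.lumps:
            return 0.0
        return float(np.mean([r for _, _, r in self.lumps]))


def _correlated_field(rng: np.random.Generator, shape, sigma_px: float) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length sigma_px."""
    white = rng.standard_normal(shape)
    f = gaussian_filter(white, sigma=sigma_px, mode="wrap")
    return (f - f.mean()) / f.std()


def _irregular_ellipse_mask(
    shape, center, semiaxes, irregularity: float, rng: np.random.Generator
) -> np.ndarray:
    """Ellipse whose radius is perturbed by a low-order Fourier series."""
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    dy = (rr - center[0]) / semiaxes[0]
    dx = (cc - center[1]) / semiaxes[1]
    radius = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    perturb = np.zeros_like(theta)
    for order in range(2, 6):
        amp = irregularity * rng.uniform(0.3, 1.0) / 2.0
        phase = rng.uniform(0, 2 * np.pi)
        perturb += amp * np.cos(order * theta + phase)
    return radius <= 1.0 + perturb


def _place_lumps(
    rng: np.random.Generator,
    tumor_mask: np.ndarray,
    stage_params: StageParams,
) -> list[tuple[float, float, float]]:
    area = int(tumor_mask.sum())
    n_lumps = int(round(stage_params.lump_density_per_px2 * area))
    if n_lumps == 0:
        return []
    rows, cols = np.nonzero(tumor_mask)
    idx = rng.integers(0, len(rows), size=n_lumps)
    radii = rng.normal(stage_params.lump_radius_px, stage_params.lump_radius_sd_px, n_lumps)
    radii = np.clip(radii, 0.3 * stage_params.lump_radius_px, None)
    return [(float(rows[i]), float(cols[i]), float(r)) for i, r in zip(idx, radii)]


def _lump_thickness(
    shape, lumps, pixel_size_m: float, scale: float
) -> np.ndarray:
    """Spherical-cap thickness profile per lump: t = scale * 2*sqrt(r^2-d^2)*px."""
    t = np.zeros(shape)
    for r0, c0, rad in lumps:
        r_lo, r_hi = int(max(0, r0 - rad - 1)), int(min(shape[0], r0 + rad + 2))
        c_lo, c_hi = int(max(0, c0 - rad - 1)), int(min(shape[1], c0 + rad + 2))
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        cap = np.sqrt(np.clip(rad**2 - d2, 0.0, None))
        t[r_lo:r_hi, c_lo:c_hi] += scale * 2.0 * cap * pixel_size_m
    return t


def _vessel_paths(
    rng: np.random.Generator,
    tumor_mask: np.ndarray,
    n_vessels: int,
    shape,
) -> list[np.ndarray]:
    """Random smooth walks starting at the tumor boundary, heading outward."""
    paths = []
    boundary = tumor_mask & ~np.roll(tumor_mask, 1, axis=0)
    rows, cols = np.nonzero(boundary)
    if len(rows) == 0:
        rows, cols = np.nonzero(tumor_mask)
    for _ in range(n_vessels):
        i = rng.integers(0, len(rows))
        pos = np.array([float(rows[i]), float(cols[i])])
        heading = rng.uniform(0, 2 * np.pi)
        pts = [pos.copy()]
        n_steps = int(0.35 * min(shape))
        for _ in range(n_steps):
            heading += rng.normal(0.0, 0.18)
            pos = pos + np.array([np.sin(heading), np.cos(heading)])
            if not (0 <= pos[0] < shape[0] - 1 and 0 <= pos[1] < shape[1] - 1):
                break
            pts.append(pos.copy())
        paths.append(np.array(pts))
    return paths


def _vessel_thickness(
    shape, paths, width_px: float, thickness_m: float
) -> np.ndarray:
    canvas = np.zeros(shape)
    for path in paths:
        ij = np.round(path).astype(int)
        canvas[ij[:, 0], ij[:, 1]] = 1.0
    tube = gaussian_filter(canvas, sigma=width_px / 2.0, mode="constant")
    if tube.max() > 0:
        tube = tube / tube.max()
    return thickness_m * tube


def build_liver_phantom(
    stage: str,
    grid_shape: tuple[int, int] = (1024, 1024),
    pixel_size_m: float = 9e-6,
    seed: int = 0,
    params: PhantomParams | None = None,
) -> PhantomScene:
    """Generate one staged liver phantom.

    Parameters
    ----------
    stage : one of ``"6d"``, ``"9d"``, ``"12d"``, ``"15d"``.
    grid_shape : even-sized grid, at least 256 per side.
    pixel_size_m : detector pixel pitch (meters).
    seed : RNG seed; scenes are bit-for-bit reproducible.
    params : texture/morphology parameters (defaults emulate the study
        conditions; see :class:`PhantomParams`).
    """
    params = params or PhantomParams()
    if stage not in params.stage_table:
        raise ValueError(f"unknown stage {stage!r}; expected one of {sorted(params.stage_table)}")
    rows, cols = grid_shape
    if rows % 2 or cols % 2 or rows < 256 or cols < 256:
        raise ValueError(f"grid must be even-sized and >= 256x256, got {grid_shape}")
    for frac in (*params.liver_semiaxes_frac, *params.tumor_semiaxes_frac):
        if not 0 < frac < 1:
            raise ValueError("semiaxis fractions must lie in (0,1)")

    rng = np.random.default_rng(seed)
    sp = params.stage_table[stage]

    center = (rows / 2.0, cols / 2.0)
    liver_semi = (params.liver_semiaxes_frac[0] * rows, params.liver_semiaxes_frac[1] * cols)
    liver_mask = _irregular_ellipse_mask(grid_shape, center, liver_semi, 0.05, rng)

    t_center = (params.tumor_center_frac[0] * rows, params.tumor_center_frac[1] * cols)
    t_semi = (params.tumor_semiaxes_frac[0] * rows, params.tumor_semiaxes_frac[1] * cols)
    tumor_mask = _irregular_ellipse_mask(
        grid_shape, t_center, t_semi, params.tumor_boundary_irregularity, rng
    )
    tumor_mask &= liver_mask
    if not tumor_mask.any():
        raise ValueError("degenerate configuration: empty tumor mask")
    tumor_frac = tumor_mask.sum() / liver_mask.sum()
    if not params.tumor_fraction_check < tumor_frac < 1.0:
        raise ValueError(
            f"tumor area fraction {tumor_frac:.3f} outside "
            f"({params.tumor_fraction_check}, 1)"
        )

    # parenchyma: elliptical-cap dome plus a smooth correlated texture
    rr, cc = np.mgrid[0:rows, 0:cols]
    dome = 1.0 - ((rr - center[0]) / liver_semi[0]) ** 2 - ((cc - center[1]) / liver_semi[1]) ** 2
    dome = np.sqrt(np.clip(dome, 0.0, None))
    parenchyma = params.liver_thickness_m * dome
    parenchyma += (
        params.normal_texture_amp_m
        * _correlated_field(rng, grid_shape, params.normal_texture_sigma_px)
    )
    parenchyma = np.clip(parenchyma, 0.0, None) * liver_mask

    # viable tumor: base plate plus fine-grained correlated field
    grain = _correlated_field(rng, grid_shape, params.tumor_grain_sigma_px)
    tumor = (params.tumor_base_thickness_m + params.tumor_grain_amp_m * grain) * tumor_mask
    tumor = np.clip(tumor, 0.0, None)

    lumps = _place_lumps(rng, tumor_mask, sp)
    necrosis = _lump_thickness(grid_shape, lumps, pixel_size_m, params.lump_thickness_scale)
    necrosis *= tumor_mask

    paths = _vessel_paths(rng, tumor_mask, sp.n_vessels, grid_shape)
    vessel = _vessel_thickness(grid_shape, paths, params.vessel_width_px, params.vessel_thickness_m)
    vessel *= liver_mask

    region_mask = np.full(grid_shape, BACKGROUND, dtype=np.uint8)
    region_mask[liver_mask] = NORMAL
    region_mask[tumor_mask] = TUMOR

    return PhantomScene(
        thickness_maps={
            "parenchyma": parenchyma,
            "tumor": tumor,
            "necrosis": necrosis,
            "vessel": vessel,
        },
        region_mask=region_mask,
        stage=stage,
        seed=seed,
        pixel_size_m=pixel_size_m,
        lumps=lumps,
        vessel_paths=paths,
    )
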