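"""Image I/O, ROI sampling inside labeled regions, gray-level quantization.

ROIs follow the study protocol: square patches (60x60 pixels by default)
placed uniformly at random over all admissible origins inside a labeled
region, 20 per region.  Quantization is per-ROI min-max to Ng levels so the
co-occurrence features are invariant to local illumination scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .detector import ProjectionImage
from .phantom import NORMAL, TUMOR

REGION_LABELS = {"normal": NORMAL, "tumor": TUMOR}


@dataclass
class ROIPatch:
    """A square patch cut from a labeled region of a projection image."""

    pixels: np.ndarray
    origin: tuple[int, int]  # (row, col), 0-based
    region_label: str
    stage: str | None = None
    source_id: str | None = None

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class QuantizedPatch:
    """Integer levels in [0, Ng-1]."""

    levels: np.ndarray
    n_levels: int

    def __post_init__(self) -> None:
        if self.levels.size and (self.levels.min() < 0 or self.levels.max() > self.n_levels - 1):
            raise ValueError("levels out of [0, Ng-1]")


def read_image(path: str | Path) -> ProjectionImage:
    """Read an 8/16-bit grayscale TIFF; pixel size taken from resolution tags
    when present (else left at 0)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        pixel_size = 0.0
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is not None and unit is not None:
            num, den = res.value
            if num > 0:
                per_unit = num / den
                scale = {2: 0.0254, 3: 0.01}.get(int(unit.value))
                if scale:
                    pixel_size = scale / per_unit
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected single-channel grayscale, got shape {arr.shape}; "
            "convert RGB/multi-channel input to grayscale first"
        )
    return ProjectionImage(pixels=arr, pixel_size_m=pixel_size, meta={"path": str(path)})


def write_image(image: ProjectionImage | np.ndarray, path: str | Path) -> None:
    """Write a grayscale array losslessly as TIFF, carrying pixel size as
    resolution metadata when known."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(image, np.ndarray):
        tifffile.imwrite(path, image)
        return
    kwargs = {}
    if image.pixel_size_m and image.pixel_size_m > 0:
        per_cm = 0.01 / image.pixel_size_m
        kwargs = {"resolution": (per_cm, per_cm), "resolutionunit": 3}
    tifffile.imwrite(path, image.pixels, **kwargs)


def _admissible_origins(mask: np.ndarray, size: int) -> np.ndarray:
    """Origins (r, c) whose size x size window lies fully inside the mask."""
    rows, cols = mask.shape
    if rows < size or cols < size:
        return np.empty((0, 2), dtype=int)
    # integral image: window sum == size^2 <=> fully inside
    ii = np.zeros((rows + 1, cols + 1), dtype=np.int64)
    ii[1:, 1:] = np.cumsum(np.cumsum(mask.astype(np.int64), axis=0), axis=1)
    win = (
        ii[size:, size:]
        - ii[:-size, size:]
        - ii[size:, :-size]
        + ii[:-size, :-size]
    )
    rr, cc = np.nonzero(win == size * size)
    return np.stack([rr, cc], axis=1)


class CapacityError(ValueError):
    """Region cannot host the requested number of ROIs."""


def sample_rois(
    image: ProjectionImage | np.ndarray,
    mask: np.ndarray,
    region_label: str,
    n: int = 20,
    size: int = 60,
    seed: int = 0,
    disjoint: bool = False,
    stage: str | None = None,
    source_id: str | None = None,
    max_tries: int = 10_000,
) -> list[ROIPatch]:
    """Sample ``n`` size x size patches fully contained in the labeled region.

    Placement is uniform over all admissible origins.  With
    ``disjoint=True`` placement is by rejection (retry cap ``max_tries``)
    and patches are pairwise non-overlapping.  Raises
    :class:`CapacityError` when the region cannot host the request, stating
    the feasible count reached.
    """
    pixels = image.pixels if isinstance(image, ProjectionImage) else image
    if mask.shape != pixels.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {pixels.shape}")
    if n < 1 or size < 2:
        raise ValueError("need n >= 1 and size >= 2")
    if region_label not in REGION_LABELS:
        raise ValueError(f"region_label must be one of {sorted(REGION_LABELS)}")
    region = mask == REGION_LABELS[region_label]
    origins = _admissible_origins(region, size)
    if len(origins) == 0:
        raise CapacityError(
            f"no admissible {size}x{size} origin inside region {region_label!r} "
            "(maximum feasible n is 0)"
        )
    rng = np.random.default_rng(seed)
    if not disjoint:
        chosen = origins[rng.integers(0, len(origins), size=n)]
    else:
        chosen_list: list[np.ndarray] = []
        tries = 0
        while len(chosen_list) < n:
            tries += 1
            if tries > max_tries:
                raise CapacityError(
                    f"could not place {n} disjoint {size}x{size} ROIs in region "
                    f"{region_label!r} within {max_tries} tries; "
                    f"maximum feasible n is at least {len(chosen_list)}"
                )
            cand = origins[rng.integers(0, len(origins))]
            overlap = any(
                abs(cand[0] - prev[0]) < size and abs(cand[1] - prev[1]) < size
                for prev in chosen_list
            )
            if not overlap:
                chosen_list.append(cand)
        chosen = np.array(chosen_list)
    patches = []
    for r, c in chosen:
        patches.append(
            ROIPatch(
                pixels=np.array(pixels[r : r + size, c : c + size]),
                origin=(int(r), int(c)),
                region_label=region_label,
                stage=stage,
                source_id=source_id,
            )
        )
    return patches


def quantize(patch: ROIPatch | np.ndarray, n_levels: int = 16) -> QuantizedPatch:
    """Affine min-max quantization to {0..Ng-1}.

    level = floor((v - min)/(max - min) * Ng), with v = max mapped to Ng-1;
    a constant patch maps to all zeros.  Order-preserving by construction.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 gray levels")
    values = patch.pixels if isinstance(patch, ROIPatch) else patch
    values = np.asarray(values, dtype=np.float64)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return QuantizedPatch(np.zeros(values.shape, dtype=np.int64), n_levels)
    levels = np.floor((values - lo) / (hi - lo) * n_levels).astype(np.int64)
    np.clip(levels, 0, n_levels - 1, out=levels)
    return QuantizedPatch(levels, n_levels)
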