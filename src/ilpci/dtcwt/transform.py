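"""Two-dimensional dual-tree complex wavelet transform.

Four parallel separable real DWTs are run — one per (row-tree, column-tree)
combination in {A, B} x {A, B} — with tree B delayed by one sample at level
1 and using the time-reversed quarter-shift filter at levels >= 2.  For
each detail type (LH, HL, HH) the four real subbands are combined unitarily
into two complex, approximately analytic, oriented subbands:

    z1 = (d_AA - d_BB)/sqrt(2) + i (d_AB + d_BA)/sqrt(2)
    z2 = (d_AA + d_BB)/sqrt(2) + i (d_AB - d_BA)/sqrt(2)

giving six orientations per level (nominally +-15, +-45, +-75 degrees).
Because the combination is unitary and each tree is individually a
perfect-reconstruction filter bank, the inverse transform is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from ..glcm import TextureVector, orientation_average
from ..roi import quantize
from .filters import level1_wavelet, qshift_wavelets

_TREES = (("a", "a"), ("a", "b"), ("b", "a"), ("b", "b"))
_SQRT2 = np.sqrt(2.0)

#: nominal orientation (degrees) of each complex subband slice
ORIENTATIONS = (15, -15, 75, -75, 45, -45)


@dataclass
class DTCWTPyramid:
    """Dual-tree pyramid: complex oriented subbands plus per-tree lowpasses.

    highpasses[l] has shape (rows_l, cols_l, 6), complex, for level l+1.
    lowpass_levels[l] maps tree pair -> real lowpass image at level l+1
    (the final level's entries are the coefficients needed for inversion;
    earlier levels are retained so LF1 is available from a 2-level run).
    """

    highpasses: list[np.ndarray]
    lowpass_levels: list[dict[tuple[str, str], np.ndarray]]
    input_shape: tuple[int, int]
    pads: list[tuple[int, int]]

    @property
    def levels(self) -> int:
        return len(self.highpasses)


def _combine(details: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]]) -> np.ndarray:
    """Unitary 4-tree -> 6-complex-subband combination."""
    out = []
    for t in range(3):
        d_aa = details[("a", "a")][t]
        d_ab = details[("a", "b")][t]
        d_ba = details[("b", "a")][t]
        d_bb = details[("b", "b")][t]
        p = (d_aa - d_bb) / _SQRT2
        q = (d_ab + d_ba) / _SQRT2
        r = (d_aa + d_bb) / _SQRT2
        s = (d_ab - d_ba) / _SQRT2
        out.append(p + 1j * q)
        out.append(r + 1j * s)
    return np.stack(out, axis=-1)


def _split(z: np.ndarray) -> dict[tuple[str, str], tuple]:
    """Inverse of :func:`_combine`."""
    per_tree: dict[tuple[str, str], list[np.ndarray]] = {t: [] for t in _TREES}
    for t in range(3):
        z1, z2 = z[..., 2 * t], z[..., 2 * t + 1]
        p, q = z1.real, z1.imag
        r, s = z2.real, z2.imag
        per_tree[("a", "a")].append((p + r) / _SQRT2)
        per_tree[("b", "b")].append((r - p) / _SQRT2)
        per_tree[("a", "b")].append((q + s) / _SQRT2)
        per_tree[("b", "a")].append((q - s) / _SQRT2)
    return {k: tuple(v) for k, v in per_tree.items()}


def _pad_to_even(x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    pr = x.shape[0] % 2
    pc = x.shape[1] % 2
    if pr or pc:
        x = np.pad(x, ((0, pr), (0, pc)), mode="symmetric")
    return x, (pr, pc)


def dtcwt_forward(patch: np.ndarray, levels: int = 2) -> DTCWTPyramid:
    """Forward dual-tree transform of a real 2-D patch.

    Odd-sized inputs (at any level) are padded to even size by symmetric
    reflection; the padding is recorded and stripped by the inverse.
    """
    x = np.asarray(patch, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("patch must be 2-D")
    if levels < 1:
        raise ValueError("need at least 1 level")
    wav1 = level1_wavelet()
    wav_qa, wav_qb = qshift_wavelets()

    highpasses: list[np.ndarray] = []
    lowpass_levels: list[dict] = []
    pads: list[tuple[int, int]] = []
    input_shape = x.shape

    # level 1: same biorthogonal pair in both trees, tree B delayed 1 sample
    x, pad = _pad_to_even(x)
    pads.append(pad)
    if min(x.shape) < wav1.dec_len:
        raise ValueError(
            f"patch of shape {input_shape} smaller than the level-1 filter "
            f"support ({wav1.dec_len})"
        )
    low: dict[tuple[str, str], np.ndarray] = {}
    det: dict[tuple[str, str], tuple] = {}
    for tr, tc in _TREES:
        xi = np.roll(x, 1, axis=0) if tr == "b" else x
        xi = np.roll(xi, 1, axis=1) if tc == "b" else xi
        cA, (cH, cV, cD) = pywt.dwt2(xi, wav1, mode="periodization")
        low[(tr, tc)] = cA
        det[(tr, tc)] = (cH, cV, cD)
    highpasses.append(_combine(det))
    lowpass_levels.append(low)

    # levels >= 2: quarter-shift tree A, time-reversed tree B
    for _ in range(1, levels):
        ref = low[("a", "a")]
        _, pad = _pad_to_even(ref)
        pads.append(pad)
        new_low: dict[tuple[str, str], np.ndarray] = {}
        det = {}
        for tr, tc in _TREES:
            xi, _ = _pad_to_even(low[(tr, tc)])
            if min(xi.shape) < wav_qa.dec_len:
                raise ValueError(
                    f"level input of shape {low[(tr, tc)].shape} smaller than "
                    f"the quarter-shift filter support ({wav_qa.dec_len})"
                )
            wav_r = wav_qa if tr == "a" else wav_qb
            wav_c = wav_qa if tc == "a" else wav_qb
            cA, (cH, cV, cD) = pywt.dwt2(xi, (wav_r, wav_c), mode="periodization")
            new_low[(tr, tc)] = cA
            det[(tr, tc)] = (cH, cV, cD)
        highpasses.append(_combine(det))
        lowpass_levels.append(new_low)
        low = new_low

    return DTCWTPyramid(
        highpasses=highpasses,
        lowpass_levels=lowpass_levels,
        input_shape=input_shape,
        pads=pads,
    )


def dtcwt_inverse(pyramid: DTCWTPyramid) -> np.ndarray:
    """Exact inverse: invert each of the four per-tree DWTs and average."""
    wav1 = level1_wavelet()
    wav_qa, wav_qb = qshift_wavelets()
    levels = pyramid.levels
    low = {t: pyramid.lowpass_levels[-1][t].copy() for t in _TREES}

    for lvl in range(levels - 1, 0, -1):
        det = _split(pyramid.highpasses[lvl])
        pad = pyramid.pads[lvl]
        target = pyramid.lowpass_levels[lvl - 1]
        for tr, tc in _TREES:
            wav_r = wav_qa if tr == "a" else wav_qb
            wav_c = wav_qa if tc == "a" else wav_qb
            rec = pywt.idwt2((low[(tr, tc)], det[(tr, tc)]), (wav_r, wav_c),
                             mode="periodization")
            r, c = target[(tr, tc)].shape
            low[(tr, tc)] = rec[:r, :c] if (pad[0] or pad[1]) else rec

    det = _split(pyramid.highpasses[0])
    pad = pyramid.pads[0]
    recons = []
    for tr, tc in _TREES:
        rec = pywt.idwt2((low[(tr, tc)], det[(tr, tc)]), wav1, mode="periodization")
        rec = np.roll(rec, -1, axis=0) if tr == "b" else rec
        rec = np.roll(rec, -1, axis=1) if tc == "b" else rec
        recons.append(rec)
    out = np.mean(recons, axis=0)
    r, c = pyramid.input_shape
    return out[:r, :c]


@dataclass
class SubbandImageSet:
    """The four real subband images of a 2-level decomposition."""

    HF1: np.ndarray
    HF2: np.ndarray
    LF1: np.ndarray
    LF2: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"HF1": self.HF1, "HF2": self.HF2, "LF1": self.LF1, "LF2": self.LF2}


def subband_images(pyramid: DTCWTPyramid) -> SubbandImageSet:
    """Collapse the pyramid to two lowpass and two highpass images.

    LFl is the mean of the four tree lowpasses at level l; HFl aggregates
    the six oriented complex magnitudes by root-mean-square, which is
    orientation-fair and non-negative.
    """
    if pyramid.levels < 2:
        raise ValueError("need a 2-level pyramid")

    def hf(level: int) -> np.ndarray:
        z = pyramid.highpasses[level]
        return np.sqrt(np.mean(np.abs(z) ** 2, axis=-1))

    def lf(level: int) -> np.ndarray:
        return np.mean([pyramid.lowpass_levels[level][t] for t in _TREES], axis=0)

    return SubbandImageSet(HF1=hf(0), HF2=hf(1), LF1=lf(0), LF2=lf(1))


def subband_texture(
    sub: SubbandImageSet, n_levels: int = 16, distance: int = 1
) -> dict[str, TextureVector]:
    """Quantize each subband image (per-image min-max) and compute the
    orientation-averaged co-occurrence texture vector."""
    out = {}
    for name, img in sub.as_dict().items():
        if min(img.shape) < 8:
            raise ValueError(f"subband {name} smaller than 8x8: {img.shape}")
        out[name] = orientation_average(quantize(img, n_levels), distance)
    return out
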