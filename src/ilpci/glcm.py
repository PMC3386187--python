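"""Gray-level co-occurrence matrices and the nine Haralick-type features.

The co-occurrence matrix C_ij is the joint probability of observing the
quantized level pair (i, j) at a fixed pixel offset.  From it the nine
texture parameters used for tumor discrimination are computed:

    angular second moment   sum C_ij^2
    inertia (contrast)      sum (i-j)^2 C_ij
    inverse diff. moment    sum C_ij / (1 + (i-j)^2)
    entropy                 -sum C_ij ln C_ij
    correlation             (sum i*j*C_ij - mu_x mu_y) / (sigma_x sigma_y)
    sum average             sum_k k p_{x+y}(k)
    difference average      sum_k k p_{|x-y|}(k)
    sum entropy             -sum p_{x+y} ln p_{x+y}
    difference entropy      -sum p_{|x-y|} ln p_{|x-y|}

Entropies use the natural log (the base only rescales features and is
absorbed by the downstream standardization); 0*ln 0 := 0.  The degenerate
correlation (sigma_x sigma_y = 0, e.g. a constant patch) is defined as 0 so
constant ROIs cannot poison the PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roi import QuantizedPatch

TEXTURE_FEATURE_NAMES = (
    "asm",
    "inertia",
    "idm",
    "entropy",
    "correlation",
    "sum_average",
    "difference_average",
    "sum_entropy",
    "difference_entropy",
)

#: distance-d offsets at 0, 45, 90, 135 degrees, (drow, dcol) convention
def orientation_offsets(distance: int = 1) -> tuple[tuple[int, int], ...]:
    d = distance
    return ((0, d), (-d, d), (-d, 0), (-d, -d))


@dataclass
class GLCM:
    """Normalized co-occurrence distribution for one offset."""

    C: np.ndarray
    offset: tuple[int, int]
    symmetric: bool

    @property
    def n_levels(self) -> int:
        return self.C.shape[0]

    def validate(self) -> None:
        if abs(self.C.sum() - 1.0) > 1e-12:
            raise ValueError("GLCM does not sum to 1")
        if np.any(self.C < 0):
            raise ValueError("GLCM has negative entries")
        if self.symmetric and not np.array_equal(self.C, self.C.T):
            raise ValueError("symmetric GLCM is not equal to its transpose")


@dataclass
class MarginalStats:
    px: np.ndarray
    py: np.ndarray
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    p_sum: np.ndarray   # distribution of i+j over 0..2Ng-2
    p_diff: np.ndarray  # distribution of |i-j| over 0..Ng-1


@dataclass
class TextureVector:
    asm: float
    inertia: float
    idm: float
    entropy: float
    correlation: float
    sum_average: float
    difference_average: float
    sum_entropy: float
    difference_entropy: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in TEXTURE_FEATURE_NAMES])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "TextureVector":
        return cls(**{n: float(v) for n, v in zip(TEXTURE_FEATURE_NAMES, arr)})


def compute_glcm(
    q: QuantizedPatch, offset: tuple[int, int], symmetric: bool = True
) -> GLCM:
    """Count all in-bounds ordered level pairs (p, p+offset) and normalize.

    With ``symmetric=True`` the transposed counts are added first, making
    C exactly symmetric (the unordered-pair convention).
    """
    dr, dc = offset
    if dr == 0 and dc == 0:
        raise ValueError("offset must be nonzero")
    levels = q.levels
    rows, cols = levels.shape
    r0, r1 = max(0, -dr), min(rows, rows - dr)
    c0, c1 = max(0, -dc), min(cols, cols - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(
            f"patch of shape {levels.shape} has no pixel pairs at offset {offset}"
        )
    a = levels[r0:r1, c0:c1].ravel()
    b = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    ng = q.n_levels
    counts = np.zeros((ng, ng), dtype=np.float64)
    np.add.at(counts, (a, b), 1.0)
    if symmetric:
        counts = counts + counts.T
    return GLCM(C=counts / counts.sum(), offset=offset, symmetric=symmetric)


def marginal_stats(glcm: GLCM) -> MarginalStats:
    """Row/column marginals, their index moments, and the sum/difference
    distributions needed by the correlation and sum/difference features."""
    C = glcm.C
    ng = glcm.n_levels
    idx = np.arange(ng, dtype=np.float64)
    px = C.sum(axis=1)
    py = C.sum(axis=0)
    mu_x = float(idx @ px)
    mu_y = float(idx @ py)
    sigma_x = float(np.sqrt(((idx - mu_x) ** 2) @ px))
    sigma_y = float(np.sqrt(((idx - mu_y) ** 2) @ py))
    i = idx[:, None] + idx[None, :]
    j = np.abs(idx[:, None] - idx[None, :])
    p_sum = np.bincount(i.astype(int).ravel(), weights=C.ravel(), minlength=2 * ng - 1)
    p_diff = np.bincount(j.astype(int).ravel(), weights=C.ravel(), minlength=ng)
    return MarginalStats(px, py, mu_x, mu_y, sigma_x, sigma_y, p_sum, p_diff)


def _nats(p: np.ndarray) -> float:
    """-sum p ln p with 0 ln 0 := 0."""
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def texture_vector(glcm: GLCM) -> TextureVector:
    """The nine co-occurrence texture features of one GLCM."""
    C = glcm.C
    ng = glcm.n_levels
    idx = np.arange(ng, dtype=np.float64)
    diff2 = (idx[:, None] - idx[None, :]) ** 2
    st = marginal_stats(glcm)
    asm = float((C**2).sum())
    inertia = float((diff2 * C).sum())
    idm = float((C / (1.0 + diff2)).sum())
    entropy = _nats(C.ravel())
    denom = st.sigma_x * st.sigma_y
    if denom == 0.0:
        correlation = 0.0
    else:
        cross = float((idx[:, None] * idx[None, :] * C).sum())
        correlation = (cross - st.mu_x * st.mu_y) / denom
    k_sum = np.arange(len(st.p_sum), dtype=np.float64)
    k_diff = np.arange(len(st.p_diff), dtype=np.float64)
    return TextureVector(
        asm=asm,
        inertia=inertia,
        idm=idm,
        entropy=entropy,
        correlation=correlation,
        sum_average=float(k_sum @ st.p_sum),
        difference_average=float(k_diff @ st.p_diff),
        sum_entropy=_nats(st.p_sum),
        difference_entropy=_nats(st.p_diff),
    )


def orientation_average(q: QuantizedPatch, distance: int = 1) -> TextureVector:
    """Mean of the nine features over the four symmetric offsets at 0, 45,
    90 and 135 degrees (the paper states no offset protocol; averaging the
    four canonical orientations at distance 1 is rotation-fair)."""
    vecs = [
        texture_vector(compute_glcm(q, off, symmetric=True)).as_array()
        for off in orientation_offsets(distance)
    ]
    return TextureVector.from_array(np.mean(vecs, axis=0))
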