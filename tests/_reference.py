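"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain double loops over pixels / matrix
entries, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def glcm_brute_force(levels: np.ndarray, ng: int, offset: tuple[int, int], symmetric: bool) -> np.ndarray:
    """Co-occurrence matrix by explicit pair enumeration."""
    dr, dc = offset
    rows, cols = levels.shape
    counts = np.zeros((ng, ng))
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                counts[levels[r, c], levels[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def texture_features_brute_force(C: np.ndarray) -> dict[str, float]:
    """The nine co-occurrence features by explicit summation."""
    ng = C.shape[0]
    asm = inertia = idm = entropy = cross = 0.0
    px = [0.0] * ng
    py = [0.0] * ng
    p_sum = [0.0] * (2 * ng - 1)
    p_diff = [0.0] * ng
    for i in range(ng):
        for j in range(ng):
            c = C[i, j]
            asm += c * c
            inertia += (i - j) ** 2 * c
            idm += c / (1.0 + (i - j) ** 2)
            if c > 0:
                entropy -= c * math.log(c)
            cross += i * j * c
            px[i] += c
            py[j] += c
            p_sum[i + j] += c
            p_diff[abs(i - j)] += c
    mu_x = sum(i * px[i] for i in range(ng))
    mu_y = sum(j * py[j] for j in range(ng))
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(ng)))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(ng)))
    corr = 0.0 if sd_x * sd_y == 0 else (cross - mu_x * mu_y) / (sd_x * sd_y)
    sum_avg = sum(k * p for k, p in enumerate(p_sum))
    diff_avg = sum(k * p for k, p in enumerate(p_diff))
    sum_ent = -sum(p * math.log(p) for p in p_sum if p > 0)
    diff_ent = -sum(p * math.log(p) for p in p_diff if p > 0)
    return {
        "asm": asm,
        "inertia": inertia,
        "idm": idm,
        "entropy": entropy,
        "correlation": corr,
        "sum_average": sum_avg,
        "difference_average": diff_avg,
        "sum_entropy": sum_ent,
        "difference_entropy": diff_ent,
    }


def eig_sym3_brute_force(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of a symmetric 3x3 matrix via the characteristic
    polynomial's roots and null-space solves (no numpy.linalg.eigh)."""
    a, b, c = A[0, 0], A[1, 1], A[2, 2]
    d, e, f = A[0, 1], A[0, 2], A[1, 2]
    # det(A - x I) = -x^3 + tr x^2 - m2 x + det
    tr = a + b + c
    m2 = a * b + a * c + b * c - d * d - e * e - f * f
    det = a * (b * c - f * f) - d * (d * c - f * e) + e * (d * f - b * e)
    roots = np.roots([-1.0, tr, -m2, det])
    roots = np.sort(np.real(roots))[::-1]
    vecs = []
    for lam in roots:
        M = A - lam * np.eye(3)
        # null vector via cross products of rows (most stable pair)
        candidates = [
            np.cross(M[0], M[1]),
            np.cross(M[0], M[2]),
            np.cross(M[1], M[2]),
        ]
        v = max(candidates, key=lambda u: np.linalg.norm(u))
        n = np.linalg.norm(v)
        if n < 1e-12:  # repeated eigenvalue; fall back to any unit null vector
            _, _, Vt = np.linalg.svd(M)
            v, n = Vt[-1], 1.0
        vecs.append(v / np.linalg.norm(v))
    return roots, np.array(vecs).T
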