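"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own linear-algebra paths: the
rotation search scans an Euler-angle grid, the hull area is assembled
from point triples, and the permutation p-value is an exhaustive
enumeration over group assignments.
"""

import itertools

import numpy as np


def euler_rotation(a: float, b: float, c: float) -> np.ndarray:
    """Z(a) Y(b) Z(c) rotation matrix from Euler angles in radians."""
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return rz1 @ ry @ rz2


def grid_min_residual(source: np.ndarray, target: np.ndarray, step_deg: float = 1.0) -> float:
    """Min over a ZYZ Euler grid of ``||source @ R - target||``.

    Uses ``||sR - t||^2 = ||s||^2 + ||t||^2 - 2 tr(R^T s^T t)`` so only the
    trace term is evaluated on the grid.
    """
    m = source.T @ target  # 3x3
    step = np.deg2rad(step_deg)
    a = np.arange(0.0, 2 * np.pi, step)
    b = np.arange(0.0, np.pi + step, step)
    c = np.arange(0.0, 2 * np.pi, step)

    def rz_stack(angles):
        ca, sa = np.cos(angles), np.sin(angles)
        out = np.zeros((angles.size, 3, 3))
        out[:, 0, 0], out[:, 0, 1] = ca, -sa
        out[:, 1, 0], out[:, 1, 1] = sa, ca
        out[:, 2, 2] = 1.0
        return out

    cb, sb = np.cos(b), np.sin(b)
    ry = np.zeros((b.size, 3, 3))
    ry[:, 0, 0], ry[:, 0, 2] = cb, sb
    ry[:, 1, 1] = 1.0
    ry[:, 2, 0], ry[:, 2, 2] = -sb, cb

    ab = np.einsum("aij,bjk->abik", rz_stack(a), ry)
    # trace(M^T R) with R = AB @ C, contracted without forming R explicitly
    p = np.einsum("abik,il->abkl", ab, m)
    traces = np.einsum("abkl,ckl->abc", p, rz_stack(c))
    best = traces.max()
    ss = float(np.sum(source**2) + np.sum(target**2))
    return float(np.sqrt(max(ss - 2.0 * best, 0.0)))


def hull_area_bruteforce(points: np.ndarray) -> float:
    """2D convex hull area assembled from point triples.

    A point is interior when it lies strictly inside some triangle of
    other points; the remaining boundary points, ordered by angle around
    their centroid, form the hull polygon (shoelace area).
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]

    def in_triangle(p, a, b, c):
        def cross(o, u, v):
            return (u[0] - o[0]) * (v[1] - o[1]) - (u[1] - o[1]) * (v[0] - o[0])

        d1, d2, d3 = cross(a, b, p), cross(b, c, p), cross(c, a, p)
        has_neg = (d1 < 0) or (d2 < 0) or (d3 < 0)
        has_pos = (d1 > 0) or (d2 > 0) or (d3 > 0)
        return not (has_neg and has_pos)

    boundary = []
    for i in range(n):
        interior = False
        for a, b, c in itertools.combinations([j for j in range(n) if j != i], 3):
            if in_triangle(points[i], points[a], points[b], points[c]):
                interior = True
                break
        if not interior:
            boundary.append(i)
    pts = points[boundary]
    centroid = pts.mean(axis=0)
    order = np.argsort(np.arctan2(pts[:, 1] - centroid[1], pts[:, 0] - centroid[0]))
    pts = pts[order]
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def exhaustive_permutation_p(d_a: np.ndarray, d_b: np.ndarray) -> float:
    """Exact two-sided permutation p over all assignments of pooled distances."""
    pooled = np.concatenate([d_a, d_b])
    n = pooled.size
    n_a = d_a.size
    obs = np.sum(d_b**2) / (d_b.size - 1) - np.sum(d_a**2) / (n_a - 1)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        delta = np.sum(pooled[~mask] ** 2) / (n - n_a - 1) - np.sum(pooled[mask] ** 2) / (n_a - 1)
        count += abs(delta) >= abs(obs) - 1e-12
        total += 1
    return count / total
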