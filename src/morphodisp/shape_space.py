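"""Principal components of aligned shapes and allometric size correction.

The size correction regresses every retained PC-score column on log
centroid size (ordinary least squares with intercept) and re-decomposes
the residual score matrix with a second PCA, yielding scores that are
uncorrelated with size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .exceptions import ContractError
from .superimposition import AlignedSample

__all__ = ["ShapeSpace", "pca", "remove_allometry", "morphospace_hull_area"]

# Degrees of freedom removed from a 3D configuration by translation (3),
# rotation (3) and scaling (1).
_SIMILARITY_DOF = 7


@dataclass(frozen=True)
class ShapeSpace:
    """Principal-component decomposition of a shape sample.

    Attributes
    ----------
    scores : (n, m) ndarray
        Specimen scores on the m retained components.
    eigenvalues : (m,) ndarray
        Component variances, descending.
    loadings : (m, p) ndarray
        Component directions in the flattened coordinate space.
    percent_variance : (m,) ndarray
        Percent of total variance per component.
    stage : str
        ``"raw"`` or ``"size_corrected"``.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray
    percent_variance: np.ndarray
    stage: str = "raw"
    mean: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # sign convention: each loading's largest-magnitude entry is positive,
    # so scores are reproducible across runs and BLAS builds
    flips = np.sign(loadings[np.arange(loadings.shape[0]), np.abs(loadings).argmax(axis=1)])
    flips[flips == 0] = 1.0
    return loadings * flips[:, None], scores * flips[None, :]


def _decompose(x: np.ndarray, max_components: int, stage: str) -> ShapeSpace:
    n = x.shape[0]
    mean = x.mean(axis=0)
    centered = x - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    total = eigenvalues.sum()
    m = min(max_components, len(eigenvalues))
    scores = u[:, :m] * s[:m]
    loadings, scores = _fix_signs(vt[:m], scores)
    percent = (
        100.0 * eigenvalues[:m] / total if total > 0 else np.zeros(m)
    )
    return ShapeSpace(
        scores=scores,
        eigenvalues=eigenvalues[:m],
        loadings=loadings,
        percent_variance=percent,
        stage=stage,
        mean=mean,
    )


def pca(aligned: AlignedSample | np.ndarray) -> ShapeSpace:
    """PCA of superimposed coordinates (stage ``"raw"``).

    Retains at most ``min(n - 1, 3k - 7)`` components: superimposition
    removes the seven similarity degrees of freedom, so later components
    carry only round-off.
    """
    if isinstance(aligned, AlignedSample):
        x = aligned.flat()
        cap = min(aligned.n - 1, 3 * aligned.k - _SIMILARITY_DOF)
    else:
        x = np.asarray(aligned, dtype=float)
        cap = min(x.shape[0] - 1, x.shape[1])
    if x.shape[0] < 3:
        raise ContractError("PCA requires at least 3 specimens")
    return _decompose(x, cap, stage="raw")


def remove_allometry(space: ShapeSpace, log_cs: np.ndarray) -> ShapeSpace:
    """Regress out log centroid size from PC scores and re-decompose.

    Every retained score column is regressed on ``log_cs`` (OLS with
    intercept); the residual matrix goes through a second PCA whose
    loadings are composed back into coordinate space.  If ``log_cs`` has
    zero variance the correction is a warned no-op.
    """
    if space.stage != "raw":
        raise ContractError(f"remove_allometry expects a raw ShapeSpace, got {space.stage!r}")
    log_cs = np.asarray(log_cs, dtype=float)
    if log_cs.shape != (space.n,):
        raise ContractError(
            f"log_cs has shape {log_cs.shape}, expected ({space.n},)"
        )
    if not np.all(np.isfinite(log_cs)):
        raise ContractError("log_cs contains non-finite values")
    x = log_cs - log_cs.mean()
    xtx = float(x @ x)
    if xtx < 1e-300:
        warnings.warn("log centroid size has zero variance; allometry correction is a no-op")
        residuals = space.scores - space.scores.mean(axis=0)
    else:
        slopes = (x @ space.scores) / xtx  # per-column OLS slope
        centered = space.scores - space.scores.mean(axis=0)
        residuals = centered - np.outer(x, slopes)
    second = _decompose(residuals, residuals.shape[1], stage="size_corrected")
    return ShapeSpace(
        scores=second.scores,
        eigenvalues=second.eigenvalues,
        loadings=second.loadings @ space.loadings,
        percent_variance=second.percent_variance,
        stage="size_corrected",
        mean=space.mean,
    )


def morphospace_hull_area(
    space: ShapeSpace, members: np.ndarray | list[int] | None = None, axes: tuple[int, int] = (0, 1)
) -> float:
    """Area of the 2D convex hull of member scores on a pair of component axes.

    Fewer than 3 members or collinear points give area 0 with a warning.
    """
    pts = space.scores[:, list(axes)]
    if members is not None:
        pts = pts[np.asarray(members)]
    if pts.shape[0] < 3:
        warnings.warn(f"hull of {pts.shape[0]} points is degenerate; area 0")
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        warnings.warn("collinear points; hull area 0")
        return 0.0
    return float(hull.volume)  # 2D ConvexHull.volume is the enclosed area
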