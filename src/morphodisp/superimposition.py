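"""Centroid size, Kabsch rotation, generalized Procrustes analysis, and
partial Procrustes distances.

Scaling follows the unit-centroid-size (partial Procrustes) convention:
with ``scale=True`` every configuration is translated to the origin and
scaled to centroid size 1 before iterative rotation to the consensus, and
distances between aligned shapes are partial Procrustes distances.
Reflections are never permitted (rotations have determinant +1), so
left/right anatomy cannot mirror during alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ContractError, DegenerateConfigurationError, ZeroSizeError
from .landmark_io import LandmarkDataset

__all__ = [
    "AlignedSample",
    "centroid_size",
    "optimal_rotation",
    "gpa",
    "procrustes_distance",
    "tangent_project",
]

_EPS = 1e-12


def centroid_size(config: np.ndarray) -> float:
    """Centroid size: root summed squared deviation of landmarks from their centroid.

    Accepts a (k, 3) array or a :class:`~morphodisp.landmark_io.LandmarkConfiguration`.
    """
    coords = np.asarray(getattr(config, "coords", config), dtype=float)
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs < _EPS:
        raise ZeroSizeError("all landmarks coincide; centroid size is zero")
    return cs


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (3x3, det +1) minimizing ``||source @ R - target||``.

    Both inputs must be centered (k, 3) arrays with the same k.  This is
    the Kabsch solution with the reflection branch excluded.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape:
        raise ContractError(f"shape mismatch {source.shape} vs {target.shape}")
    for name, arr in (("source", source), ("target", target)):
        if np.linalg.norm(arr.mean(axis=0)) > 1e-6 * max(1.0, np.abs(arr).max()):
            raise ContractError(f"{name} configuration is not centered")
    if min(np.linalg.matrix_rank(source), np.linalg.matrix_rank(target)) < 2:
        raise DegenerateConfigurationError(
            "rank < 2 configuration: rotation is ill-conditioned"
        )
    return _kabsch(source, target)


def _kabsch(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    # R maximizes tr(R^T M) with M = source^T target; det(+1) enforced by
    # flipping the smallest singular direction if needed.
    m = source.T @ target
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def _principal_axes(config: np.ndarray) -> np.ndarray:
    """Proper rotation taking a centered configuration to its principal axes,
    with the largest-magnitude coordinate on each of the first two axes
    positive (third axis sign fixed by det +1)."""
    w, v = np.linalg.eigh(config.T @ config)
    v = v[:, ::-1]  # descending spread
    for j in range(2):
        col = config @ v[:, j]
        if col[np.abs(col).argmax()] < 0:
            v[:, j] = -v[:, j]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return v


def _kabsch_batch(sources: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Batched Kabsch: rotations (n,3,3) aligning each (n,k,3) source onto target."""
    m = np.einsum("nki,kj->nij", sources, target)
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(np.einsum("nij,njk->nik", u, vt)))
    u = u.copy()
    u[:, :, 2] *= d[:, None]
    return np.einsum("nij,njk->nik", u, vt)


@dataclass(frozen=True)
class AlignedSample:
    """Result of a generalized Procrustes superimposition.

    Attributes
    ----------
    coords : (n, k, 3) ndarray
        Superimposed configurations (centered; unit centroid size when
        ``scaled`` is true).
    centroid_sizes : (n,) ndarray
        Original-unit centroid sizes, recorded before any scaling.
    consensus : (k, 3) ndarray
        Arithmetic mean of the aligned coordinates.
    specimen_ids, species : tuple of str
        Identity carried over from the dataset, in row order.
    """

    coords: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    specimen_ids: tuple[str, ...] = ()
    species: tuple[str, ...] = ()
    scaled: bool = True
    iterations: int = 0
    converged: bool = True

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def log_centroid_sizes(self) -> np.ndarray:
        return np.log(self.centroid_sizes)

    def flat(self) -> np.ndarray:
        """Aligned coordinates flattened to an (n, 3k) matrix."""
        return self.coords.reshape(self.n, -1)


def gpa(
    dataset: LandmarkDataset | np.ndarray,
    scale: bool = True,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> AlignedSample:
    """Generalized Procrustes analysis of a dataset (or a raw (n, k, 3) array).

    Iterates rotate-to-consensus / update-consensus until the change in the
    total residual sum of squares drops below ``tol`` or ``max_iter`` is
    reached; non-convergence warns and sets ``converged=False``.  Centroid
    sizes are recorded before scaling.
    """
    if isinstance(dataset, LandmarkDataset):
        coords = dataset.coords_array().astype(float)
        specimen_ids = tuple(dataset.specimen_ids())
        species = tuple(c.species for c in dataset.configurations)
    else:
        coords = np.asarray(dataset, dtype=float).copy()
        specimen_ids = tuple(f"s{i}" for i in range(coords.shape[0]))
        species = specimen_ids
    n, k, _ = coords.shape
    if n < 2:
        raise ContractError("GPA requires at least 2 configurations")
    if k < 3:
        raise ContractError("GPA requires at least 3 landmarks")

    coords = coords - coords.mean(axis=1, keepdims=True)
    sizes = np.sqrt(np.sum(coords**2, axis=(1, 2)))
    for i in range(n):
        if sizes[i] < _EPS:
            raise DegenerateConfigurationError(
                f"specimen {specimen_ids[i]!r}: all landmarks coincide"
            )
        if np.linalg.matrix_rank(coords[i]) < 2:
            raise DegenerateConfigurationError(
                f"specimen {specimen_ids[i]!r}: rank < 2 configuration"
            )
    if scale:
        coords = coords / sizes[:, None, None]

    consensus = coords[0].copy()
    prev_rss = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        rotations = _kabsch_batch(coords, consensus)
        coords = np.einsum("nki,nij->nkj", coords, rotations)
        consensus = coords.mean(axis=0)
        if scale:
            # keep the consensus on the unit-size sphere so rotations are
            # computed against a shape, not a shrunken average
            consensus = consensus / np.sqrt(np.sum(consensus**2))
        rss = float(np.sum((coords - consensus) ** 2))
        if abs(prev_rss - rss) <= tol:
            converged = True
            break
        prev_rss = rss
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations (last RSS change "
            f"{abs(prev_rss - rss):.3g})",
            stacklevel=2,
        )
    # canonical orientation: consensus principal axes with deterministic
    # signs, so the output does not depend on the input orientations
    v = _principal_axes(coords.mean(axis=0))
    coords = coords @ v
    consensus = consensus @ v
    return AlignedSample(
        coords=coords,
        centroid_sizes=sizes,
        consensus=coords.mean(axis=0),
        specimen_ids=specimen_ids,
        species=species,
        scaled=scale,
        iterations=iterations,
        converged=converged,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray, check: bool = True) -> float:
    """Partial Procrustes distance: ``||a @ R - b||`` at the optimal rotation R.

    Both configurations must be centered with unit centroid size.  Pass
    ``check=False`` to skip the (cheap) precondition checks in inner loops.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if check:
        for name, arr in (("a", a), ("b", b)):
            if np.linalg.norm(arr.mean(axis=0)) > 1e-6:
                raise ContractError(f"configuration {name} is not centered")
            if abs(np.sqrt(np.sum(arr**2)) - 1.0) > 1e-6:
                raise ContractError(f"configuration {name} does not have unit centroid size")
    r = _kabsch(a, b)
    return float(np.linalg.norm(a @ r - b))


def residual_distances(coords: np.ndarray, mean_shape: np.ndarray) -> np.ndarray:
    """Rotation-optimal residual distances of each (n,k,3) configuration
    from a common mean shape (the mean is used as-is, not re-normalized)."""
    coords = np.asarray(coords, dtype=float)
    rotations = _kabsch_batch(coords, mean_shape)
    fitted = np.einsum("nki,nij->nkj", coords, rotations)
    return np.sqrt(np.sum((fitted - mean_shape) ** 2, axis=(1, 2)))


def tangent_project(aligned: AlignedSample) -> AlignedSample:
    """Orthogonally project aligned shapes onto the tangent plane at the consensus.

    Optional: analyses operate on superimposed coordinates by default."""
    c = aligned.consensus.ravel()
    c = c / np.linalg.norm(c)
    x = aligned.flat()
    proj = x - np.outer(x @ c, c) + c  # keep the consensus offset
    coords = proj.reshape(aligned.coords.shape)
    return AlignedSample(
        coords=coords,
        centroid_sizes=aligned.centroid_sizes,
        consensus=coords.mean(axis=0),
        specimen_ids=aligned.specimen_ids,
        species=aligned.species,
        scaled=aligned.scaled,
        iterations=aligned.iterations,
        converged=aligned.converged,
    )
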