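"""Synthetic landmark studies with known ground truth.

Specimens are generated as a mean configuration plus a zero-mean
perturbation drawn in the tangent space at the mean (orthogonal to the
translation, rotation and scaling directions of the mean), with expected
squared norm equal to the planted variance.  Because the perturbations
are tangent to the similarity group, the planted variance maps directly
onto the Procrustes variance recovered by the pipeline.  An optional
allometric component shifts shape along a fixed unit tangent direction in
proportion to (log centroid size - mean log centroid size).  Each
specimen is then randomly rotated and translated and scaled to a
log-normally distributed centroid size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import DatasetError, MorphodispError
from .landmark_io import (
    LandmarkConfiguration,
    LandmarkDataset,
    LandmarkScheme,
    TaxonMetadata,
)

__all__ = [
    "GroupSpec",
    "SyntheticSpec",
    "make_mean_shape",
    "tangent_basis",
    "simulate_group",
    "simulate_study",
]


@dataclass(frozen=True)
class GroupSpec:
    """One synthetic group: label, clade, size, and planted shape variance."""

    label: str
    clade: str
    n_specimens: int
    planted_variance: float
    allometric_slope: float = 0.0
    mean_shape: object = "shared"  # "shared" or a (k, 3) array

    def __post_init__(self):
        if self.planted_variance < 0:
            raise ValueError("planted_variance must be >= 0")
        if self.n_specimens < 2:
            raise ValueError("n_specimens must be >= 2")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full study specification: scheme, groups, sizes, ecology, seed."""

    scheme: LandmarkScheme
    groups: tuple[GroupSpec, ...]
    size_distribution: tuple[float, float] = (2.0, 0.3)  # (mean, sd) of log CS
    sex_ratio: float = 0.5
    ecology_assignment: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    region_effects: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        labels = [g.label for g in self.groups]
        if len(labels) != len(set(labels)):
            raise DatasetError(f"group labels collide: {labels}")
        if self.region_effects is not None and any(
            m <= 0 for m in self.region_effects.values()
        ):
            raise ValueError("region variance multipliers must be positive")


def make_mean_shape(
    k: int, seed: int, min_separation: float = 0.02, max_retries: int = 200
) -> np.ndarray:
    """Reproducible rank-3 mean configuration, unit centroid size, centered.

    Pairwise landmark separations are at least ``min_separation`` (in
    unit-centroid-size scale); generation retries with fresh draws until
    the separation constraint holds.
    """
    if k < 4:
        raise ValueError("mean shape needs k >= 4 landmarks")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x6D65616E)))
    for _ in range(max_retries):
        coords = rng.standard_normal((k, 3))
        coords -= coords.mean(axis=0)
        coords /= np.sqrt(np.sum(coords**2))
        diffs = coords[:, None, :] - coords[None, :, :]
        dists = np.sqrt(np.sum(diffs**2, axis=2))
        np.fill_diagonal(dists, np.inf)
        if dists.min() >= min_separation and np.linalg.matrix_rank(coords) == 3:
            return coords
    raise MorphodispError(
        f"could not draw a k={k} mean shape with min separation {min_separation} "
        f"in {max_retries} attempts"
    )


def tangent_basis(mean_shape: np.ndarray) -> np.ndarray:
    """Orthonormal basis Q (3k x 7) of the similarity directions at the mean.

    Columns span translations (3), infinitesimal rotations (3) and scaling
    (1); the shape tangent space is the orthogonal complement.
    """
    mean_shape = np.asarray(mean_shape, dtype=float)
    k = mean_shape.shape[0]
    p = 3 * k
    cols = []
    for axis in range(3):
        t = np.zeros((k, 3))
        t[:, axis] = 1.0
        cols.append(t.ravel())
    gens = [
        np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], dtype=float),
        np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0]], dtype=float),
        np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float),
    ]
    cols.extend((mean_shape @ g.T).ravel() for g in gens)
    cols.append(mean_shape.ravel())
    q, _ = np.linalg.qr(np.column_stack(cols))
    assert q.shape == (p, 7)
    return q


def _project_tangent(vectors: np.ndarray, q: np.ndarray) -> np.ndarray:
    return vectors - (vectors @ q) @ q.T


def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """n uniform proper rotations via normalized random quaternions."""
    quat = rng.standard_normal((n, 4))
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    w, x, y, z = quat.T
    return np.stack(
        [
            np.stack([1 - 2 * (y**2 + z**2), 2 * (x * y - w * z), 2 * (x * z + w * y)], -1),
            np.stack([2 * (x * y + w * z), 1 - 2 * (x**2 + z**2), 2 * (y * z - w * x)], -1),
            np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x**2 + y**2)], -1),
        ],
        axis=1,
    )


def simulate_group(
    mean_shape: np.ndarray,
    planted_variance: float,
    n: int,
    allometric_slope: float = 0.0,
    size_distribution: tuple[float, float] = (2.0, 0.3),
    region_effects: np.ndarray | None = None,
    seed: int = 0,
    label: str = "group",
) -> list[LandmarkConfiguration]:
    """Draw n specimens around a mean shape with planted tangent variance.

    ``region_effects`` is an optional per-landmark variance multiplier
    array (length k); the perturbation is rescaled so its total expected
    squared norm still equals ``planted_variance``.
    """
    mean_shape = np.asarray(mean_shape, dtype=float)
    k = mean_shape.shape[0]
    p = 3 * k
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x73696D)))
    q = tangent_basis(mean_shape)

    # per-coordinate standard deviations implementing region multipliers
    if region_effects is not None:
        scale = np.repeat(np.sqrt(np.asarray(region_effects, dtype=float)), 3)
    else:
        scale = np.ones(p)
    # expected squared norm of the projected scaled draw: tr(P D) with
    # P = I - QQ^T and D = diag(scale^2)
    trace_pd = float(scale @ scale) - float(np.sum((q * scale[:, None]) ** 2))
    raw = rng.standard_normal((n, p)) * scale
    tangent = _project_tangent(raw, q)
    if planted_variance > 0:
        tangent *= np.sqrt(planted_variance / trace_pd)
    else:
        tangent[:] = 0.0

    mu_log, sd_log = size_distribution
    log_cs = mu_log + sd_log * rng.standard_normal(n)
    if allometric_slope != 0.0:
        direction = _project_tangent(rng.standard_normal(p), q)
        direction /= np.linalg.norm(direction)
        tangent += allometric_slope * (log_cs - mu_log)[:, None] * direction

    shapes = mean_shape.ravel()[None, :] + tangent
    shapes = shapes.reshape(n, k, 3)

    rotations = _random_rotations(rng, n)
    translations = rng.standard_normal((n, 3)) * np.exp(mu_log)
    sizes = np.exp(log_cs)
    configs = []
    for i in range(n):
        cs = np.sqrt(np.sum((shapes[i] - shapes[i].mean(0)) ** 2))
        coords = (shapes[i] / cs * sizes[i]) @ rotations[i].T + translations[i]
        configs.append(
            LandmarkConfiguration(
                specimen_id=f"{label}_{i:03d}",
                species=f"{label}_sp{i:03d}",
                coords=coords,
            )
        )
    return configs


def simulate_study(spec: SyntheticSpec) -> LandmarkDataset:
    """Generate a pooled multi-group dataset with metadata, from a spec + seed."""
    scheme = spec.scheme
    k = scheme.k
    root = np.random.SeedSequence(spec.seed)
    mean_seed, *group_seeds = [
        int(s.generate_state(1)[0]) for s in root.spawn(1 + len(spec.groups))
    ]
    shared_mean = make_mean_shape(k, seed=mean_seed)

    if spec.region_effects is not None:
        landmark_mult = np.array(
            [spec.region_effects.get(scheme.regions[lid], 1.0) for lid in scheme.landmark_ids]
        )
    else:
        landmark_mult = None

    configurations: list[LandmarkConfiguration] = []
    metadata: dict[str, TaxonMetadata] = {}
    for group, gseed in zip(spec.groups, group_seeds):
        mean = (
            shared_mean
            if isinstance(group.mean_shape, str) and group.mean_shape == "shared"
            else np.asarray(group.mean_shape, dtype=float)
        )
        configs = simulate_group(
            mean,
            group.planted_variance,
            group.n_specimens,
            allometric_slope=group.allometric_slope,
            size_distribution=spec.size_distribution,
            region_effects=landmark_mult,
            seed=gseed,
            label=group.label,
        )
        configurations.extend(configs)
        ecology = dict(spec.ecology_assignment.get(group.label, {}))
        fixed_sex = ecology.pop("sex", None)
        n_female = round(group.n_specimens * spec.sex_ratio)
        for i, cfg in enumerate(configs):
            sex = fixed_sex if fixed_sex is not None else ("female" if i < n_female else "male")
            metadata[cfg.species] = TaxonMetadata(
                species=cfg.species, clade=group.clade, sex=sex, **ecology
            )
    return LandmarkDataset(scheme, tuple(configurations), metadata)
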