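"""Procrustes-variance disparity, bootstrap sample-size equalization, and
the delta-variance permutation test.

The disparity of a group is its Procrustes variance: the sum of squared
residual Procrustes distances of members from the group mean shape,
divided by (n - 1).  The test statistic comparing two groups is the delta
variance ``variance_b - variance_a``.  Its null distribution is built by
pooling the per-specimen residual distances from their own group means,
shuffling them, reassigning the first n_a to group a and the rest to
group b, and recomputing the delta — i.e. distances are permuted without
recomputing group means.  An alternative mode that permutes specimen
labels and recomputes means is available but not the default.

Unequal group sizes are handled by stratified bootstrap equalization:
each (group, sex) stratum is resampled with replacement to the size of
the smallest stratum, the observed variances are averaged over the
bootstrap replicates, and the permutation null is built from the residual
distances of the first (reference) replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ContractError, DatasetError
from .landmark_io import LandmarkDataset, region_subset_ids, subset_dataset
from .shape_space import pca, remove_allometry
from .superimposition import AlignedSample, _kabsch_batch, gpa

__all__ = [
    "ResamplingPlan",
    "DisparityResult",
    "Grouping",
    "BatteryResult",
    "group_variance",
    "delta_variance",
    "bootstrap_equalize",
    "permutation_test",
    "bonferroni_threshold",
    "run_disparity_battery",
    "results_to_frame",
]


@dataclass(frozen=True)
class ResamplingPlan:
    """Resampling settings for disparity tests.

    ``n_bootstrap = 0`` disables sample-size equalization (groups are used
    as-is); otherwise each stratum is resampled with replacement to
    ``n_target`` (default: the smallest stratum size) in every replicate.
    """

    n_target: int | None = None
    n_bootstrap: int = 1000
    n_permutations: int = 1000
    seed: int = 0
    tail: str = "two_sided"
    strata: tuple | None = None  # explicit (clade, sex) cells; None = derive

    def __post_init__(self):
        if self.tail not in ("two_sided", "greater"):
            raise ValueError(f"unknown tail {self.tail!r}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.n_bootstrap < 0:
            raise ValueError("n_bootstrap must be >= 0")


@dataclass(frozen=True)
class DisparityResult:
    """One delta-variance test: per-group variances, delta, permutation p."""

    dataset_label: str
    region: str
    group_a: str
    group_b: str
    variance_a: float
    variance_b: float
    delta: float
    p_value: float
    n_a: int
    n_b: int
    n_permutations: int
    n_bootstrap: int
    n_equalized: int
    seed: int
    alpha_adjusted: float = 0.01
    tail: str = "two_sided"

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_adjusted


@dataclass(frozen=True)
class Grouping:
    """A labelled pair of metadata filters defining the two compared groups.

    Filter values may be single tokens or sets of tokens (union semantics),
    e.g. ``{"clade": {"marsupial", "fossil_metatherian"}}``.
    """

    label: str
    filter_a: Mapping[str, object]
    filter_b: Mapping[str, object]
    label_a: str = "group_a"
    label_b: str = "group_b"


@dataclass(frozen=True)
class BatteryResult:
    """Outcome of a test battery: rows, Bonferroni divisor, skipped cells."""

    results: tuple[DisparityResult, ...]
    alpha: float
    skipped: tuple[str, ...] = ()

    @property
    def m(self) -> int:
        """Number of emitted tests — the Bonferroni divisor."""
        return len(self.results)

    @property
    def alpha_adjusted(self) -> float:
        return bonferroni_threshold(self.alpha, max(self.m, 1))


# ---------------------------------------------------------------------------
# Variances and distances
# ---------------------------------------------------------------------------

def _points_and_metric(sample):
    """Normalize input to (points, metric): (n,k,3) rotation-optimal coords
    or an (n,p) matrix with plain Euclidean distances."""
    if isinstance(sample, AlignedSample):
        return sample.coords, "procrustes"
    arr = np.asarray(sample, dtype=float)
    if arr.ndim == 3:
        return arr, "procrustes"
    if arr.ndim == 2:
        return arr, "euclidean"
    raise ContractError(f"expected AlignedSample, (n,k,3) or (n,p) array, got ndim {arr.ndim}")


def _residuals(points: np.ndarray, metric: str, members: np.ndarray) -> np.ndarray:
    """Residual distances of members from the members' mean."""
    sub = points[members]
    mean = sub.mean(axis=0)
    if metric == "procrustes":
        rot = _kabsch_batch(sub, mean)
        fitted = np.einsum("nki,nij->nkj", sub, rot)
        return np.sqrt(np.sum((fitted - mean) ** 2, axis=(1, 2)))
    return np.sqrt(np.sum((sub - mean) ** 2, axis=1))


def group_variance(sample, members: Sequence[int] | np.ndarray) -> float:
    """Procrustes variance of a group of specimens.

    Sum of squared residual Procrustes distances of the members from the
    members' mean shape, divided by (n - 1).  ``sample`` may be an
    :class:`AlignedSample`, an (n, k, 3) coordinate stack, or an (n, p)
    score matrix (Euclidean residuals).
    """
    members = np.asarray(members, dtype=int)
    if members.size < 2:
        raise ContractError(f"group variance requires >= 2 members, got {members.size}")
    points, metric = _points_and_metric(sample)
    d = _residuals(points, metric, members)
    return float(np.sum(d**2) / (members.size - 1))


def delta_variance(variance_a: float, variance_b: float) -> float:
    """Delta variance: ``variance_b - variance_a``."""
    return variance_b - variance_a


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Adjusted significance threshold ``alpha / m`` for m tests."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return alpha / m


# ---------------------------------------------------------------------------
# Bootstrap equalization
# ---------------------------------------------------------------------------

def _derive_clade_sex_strata(dataset: LandmarkDataset) -> dict[tuple[str, str], np.ndarray]:
    cells: dict[tuple[str, str], list[int]] = {}
    for i, cfg in enumerate(dataset.configurations):
        meta = dataset.metadata[cfg.species]
        cells.setdefault((meta.clade, meta.sex), []).append(i)
    return {cell: np.asarray(idx) for cell, idx in cells.items()}


def bootstrap_equalize(
    dataset: LandmarkDataset, plan: ResamplingPlan
) -> list[dict[str, np.ndarray]]:
    """Stratified bootstrap equalization over (clade, sex) cells.

    Returns, for each of ``plan.n_bootstrap`` replicates, a mapping
    ``clade -> member indices`` where every (clade, sex) stratum has been
    resampled with replacement to ``n_target`` and strata are pooled by
    clade.  The replicate sequence is a pure function of ``plan.seed``.
    """
    cells = _derive_clade_sex_strata(dataset)
    if plan.strata is not None:
        for cell in plan.strata:
            if cell not in cells or cells[tuple(cell)].size == 0:
                raise DatasetError(f"empty stratum {tuple(cell)!r}")
        cells = {tuple(c): cells[tuple(c)] for c in plan.strata}
    n_target = plan.n_target or min(idx.size for idx in cells.values())
    if n_target < 2:
        raise ContractError(f"n_target must be >= 2, got {n_target}")
    if any(idx.size == 0 for idx in cells.values()):
        empty = next(c for c, idx in cells.items() if idx.size == 0)
        raise DatasetError(f"empty stratum {empty!r}")
    rng = np.random.default_rng(plan.seed)
    replicates = []
    for _ in range(plan.n_bootstrap):
        by_clade: dict[str, list[np.ndarray]] = {}
        for (clade, _sex), idx in sorted(cells.items()):
            draw = idx[rng.integers(0, idx.size, size=n_target)]
            by_clade.setdefault(clade, []).append(draw)
        replicates.append({clade: np.concatenate(parts) for clade, parts in by_clade.items()})
    return replicates


def _bootstrap_members(
    strata: list[np.ndarray], n_target: int, n_bootstrap: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_bootstrap, n_target * n_strata) member index matrix."""
    draws = [
        s[rng.integers(0, s.size, size=(n_bootstrap, n_target))] for s in strata
    ]
    return np.concatenate(draws, axis=1)


def _replicate_variances(points: np.ndarray, metric: str, members: np.ndarray) -> np.ndarray:
    """Group variance for each row of a (B, m) member index matrix."""
    b, m = members.shape
    sub = points[members]  # (B, m, ...) gather
    if metric == "procrustes":
        mean = sub.mean(axis=1)  # (B, k, 3)
        flat_sub = sub.reshape(b * m, *points.shape[1:])
        flat_mean = np.repeat(mean, m, axis=0)
        mm = np.einsum("nki,nkj->nij", flat_sub, flat_mean)
        u, _, vt = np.linalg.svd(mm)
        dsign = np.sign(np.linalg.det(np.einsum("nij,njk->nik", u, vt)))
        u[:, :, 2] *= dsign[:, None]
        rot = np.einsum("nij,njk->nik", u, vt)
        fitted = np.einsum("nki,nij->nkj", flat_sub, rot)
        d2 = np.sum((fitted - flat_mean) ** 2, axis=(1, 2)).reshape(b, m)
    else:
        mean = sub.mean(axis=1, keepdims=True)
        d2 = np.sum((sub - mean) ** 2, axis=2)
    return d2.sum(axis=1) / (m - 1)


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def permutation_test(
    sample,
    members_a: Sequence[int] | np.ndarray,
    members_b: Sequence[int] | np.ndarray,
    plan: ResamplingPlan,
    labels: tuple[str, str] = ("group_a", "group_b"),
    strata_a: list[np.ndarray] | None = None,
    strata_b: list[np.ndarray] | None = None,
    dataset_label: str = "dataset",
    region: str = "whole_skull",
    permute_labels: bool = False,
) -> DisparityResult:
    """Delta-variance permutation test between two specimen groups.

    Observed group variances are (bootstrap-averaged, when equalization is
    enabled) Procrustes variances; the null shuffles the pooled residual
    distances between the two groups without recomputing the group means
    (set ``permute_labels=True`` to instead permute specimen labels and
    recompute means).  The p-value estimator is ``(b + 1) / (B + 1)``.
    """
    members_a = np.asarray(members_a, dtype=int)
    members_b = np.asarray(members_b, dtype=int)
    if np.intersect1d(members_a, members_b).size:
        raise ContractError("groups overlap; membership must be disjoint")
    if members_a.size < 2 or members_b.size < 2:
        raise ContractError("both groups need >= 2 members")
    if plan.n_permutations < 99:
        warnings.warn(
            f"{plan.n_permutations} permutations give coarse p resolution "
            f"(minimum p = {1 / (plan.n_permutations + 1):.3g})",
            stacklevel=2,
        )
    points, metric = _points_and_metric(sample)
    ss = np.random.SeedSequence(plan.seed)
    rng_boot, rng_perm = (np.random.default_rng(s) for s in ss.spawn(2))

    if plan.n_bootstrap > 0:
        sa = strata_a if strata_a is not None else [members_a]
        sb = strata_b if strata_b is not None else [members_b]
        n_target = plan.n_target or min(s.size for s in sa + sb)
        if n_target < 2:
            raise ContractError(f"equalization target {n_target} is too small")
        boot_a = _bootstrap_members(sa, n_target, plan.n_bootstrap, rng_boot)
        boot_b = _bootstrap_members(sb, n_target, plan.n_bootstrap, rng_boot)
        variance_a = float(_replicate_variances(points, metric, boot_a).mean())
        variance_b = float(_replicate_variances(points, metric, boot_b).mean())
        ref_a, ref_b = boot_a[0], boot_b[0]
        n_equalized = n_target
    else:
        variance_a = group_variance(points, members_a)
        variance_b = group_variance(points, members_b)
        ref_a, ref_b = members_a, members_b
        n_equalized = 0

    delta_obs = delta_variance(variance_a, variance_b)
    n_a, n_b = ref_a.size, ref_b.size
    b_count = plan.n_permutations

    if permute_labels:
        pooled_members = np.concatenate([ref_a, ref_b])
        deltas = np.empty(b_count)
        for i in range(b_count):
            perm = rng_perm.permutation(pooled_members)
            deltas[i] = delta_variance(
                group_variance(points, perm[:n_a]), group_variance(points, perm[n_a:])
            )
    else:
        d_a = _residuals(points, metric, ref_a)
        d_b = _residuals(points, metric, ref_b)
        # sorted pooling is label-order independent, so equal-sized groups
        # get an exactly label-symmetric null
        pooled = np.sort(np.concatenate([d_a, d_b]))
        perms = rng_perm.permuted(np.tile(pooled, (b_count, 1)), axis=1)
        var_a_perm = (perms[:, :n_a] ** 2).sum(axis=1) / (n_a - 1)
        var_b_perm = (perms[:, n_a:] ** 2).sum(axis=1) / (n_b - 1)
        deltas = var_b_perm - var_a_perm

    eps = 1e-12
    if plan.tail == "two_sided":
        exceed = int(np.sum(np.abs(deltas) >= abs(delta_obs) - eps))
    else:
        exceed = int(np.sum(deltas >= delta_obs - eps))
    p_value = (exceed + 1) / (b_count + 1)

    return DisparityResult(
        dataset_label=dataset_label,
        region=region,
        group_a=labels[0],
        group_b=labels[1],
        variance_a=variance_a,
        variance_b=variance_b,
        delta=delta_obs,
        p_value=p_value,
        n_a=members_a.size,
        n_b=members_b.size,
        n_permutations=b_count,
        n_bootstrap=plan.n_bootstrap,
        n_equalized=n_equalized,
        seed=plan.seed,
        tail=plan.tail,
    )


# ---------------------------------------------------------------------------
# Battery runner
# ---------------------------------------------------------------------------

def _matches(meta, filt: Mapping[str, object]) -> bool:
    for fname, value in filt.items():
        allowed = {value} if isinstance(value, str) else set(value)
        if getattr(meta, fname) not in allowed:
            return False
    return True


def _sex_strata(dataset: LandmarkDataset, members: np.ndarray) -> list[np.ndarray]:
    by_sex: dict[str, list[int]] = {}
    for i in members:
        meta = dataset.metadata[dataset.configurations[i].species]
        by_sex.setdefault(meta.sex, []).append(int(i))
    return [np.asarray(v) for _, v in sorted(by_sex.items())]


def _average_species(dataset: LandmarkDataset) -> LandmarkDataset:
    from .landmark_io import LandmarkConfiguration

    seen: dict[str, list[np.ndarray]] = {}
    for cfg in dataset.configurations:
        seen.setdefault(cfg.species, []).append(cfg.coords)
    configs = tuple(
        LandmarkConfiguration(sp, sp, np.mean(stack, axis=0)) for sp, stack in seen.items()
    )
    return LandmarkDataset(dataset.scheme, configs, dict(dataset.metadata))


def run_disparity_battery(
    dataset: LandmarkDataset,
    regions: Sequence[str],
    groupings: Sequence[Grouping],
    plan: ResamplingPlan,
    size_correction: bool = True,
    alpha: float = 0.01,
    average_species: bool = False,
) -> BatteryResult:
    """Run the full grouping x region battery of delta-variance tests.

    For each (grouping, region) pair: subset the landmarks, re-superimpose
    the subset for the specimens in the two groups, optionally remove
    allometry (PC scores residual to log centroid size), stratify each
    group by sex, equalize by bootstrap, and run the permutation test.
    Cells with fewer than 2 specimens in either group are skipped with a
    logged reason.  The number of emitted rows is the Bonferroni divisor;
    each row's ``alpha_adjusted`` is ``alpha / m``.
    """
    if not dataset.metadata:
        raise DatasetError("battery requires specimen metadata")
    if average_species:
        dataset = _average_species(dataset)
    ss = np.random.SeedSequence(plan.seed)
    seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(len(groupings) * len(regions))]
    results: list[DisparityResult] = []
    skipped: list[str] = []
    test_idx = 0
    for grouping in groupings:
        for region in regions:
            cell = f"{grouping.label}/{region}"
            cell_seed = seeds[test_idx]
            test_idx += 1
            ids = region_subset_ids(dataset.scheme, region)
            sub = subset_dataset(dataset, ids)
            sel_a = [
                i
                for i, cfg in enumerate(sub.configurations)
                if _matches(sub.metadata[cfg.species], grouping.filter_a)
            ]
            # overlapping selections (e.g. extant-only vs extant-plus-fossil)
            # are handled by duplicating the shared specimens in the union,
            # keeping membership index sets disjoint
            sel_b = [
                i
                for i, cfg in enumerate(sub.configurations)
                if _matches(sub.metadata[cfg.species], grouping.filter_b)
            ]
            if len(sel_a) < 2 or len(sel_b) < 2:
                skipped.append(
                    f"{cell}: group sizes {len(sel_a)}/{len(sel_b)} below minimum 2"
                )
                warnings.warn(skipped[-1], stacklevel=2)
                continue
            union = sel_a + sel_b
            union_configs = tuple(sub.configurations[i] for i in union)
            union_ds = LandmarkDataset(sub.scheme, union_configs, dict(sub.metadata))
            aligned = gpa(union_ds)
            members_a = np.arange(len(sel_a))
            members_b = np.arange(len(sel_a), len(union))
            if size_correction:
                corrected = remove_allometry(pca(aligned), aligned.log_centroid_sizes())
                sample = corrected.scores
            else:
                sample = aligned
            result = permutation_test(
                sample,
                members_a,
                members_b,
                replace(plan, seed=cell_seed),
                labels=(grouping.label_a, grouping.label_b),
                strata_a=_sex_strata(union_ds, members_a),
                strata_b=_sex_strata(union_ds, members_b),
                dataset_label=grouping.label,
                region=region,
            )
            results.append(result)
    m = max(len(results), 1)
    adjusted = bonferroni_threshold(alpha, m)
    results = [replace(r, alpha_adjusted=adjusted) for r in results]
    return BatteryResult(results=tuple(results), alpha=alpha, skipped=tuple(skipped))


def results_to_frame(battery: BatteryResult):
    """Battery rows as a pandas DataFrame mirroring the report columns."""
    import pandas as pd

    rows = [
        {
            "dataset": r.dataset_label,
            "skull_region": r.region,
            "group_a": r.group_a,
            "group_b": r.group_b,
            "variance_a": r.variance_a,
            "variance_b": r.variance_b,
            "delta_variance": r.delta,
            "p_value": r.p_value,
            "n_a": r.n_a,
            "n_b": r.n_b,
            "alpha_adjusted": r.alpha_adjusted,
            "significant": r.significant,
        }
        for r in battery.results
    ]
    return pd.DataFrame(rows)
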