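import numpy as np
import pytest

import morphodisp as md
from morphodisp.exceptions import ContractError, DatasetError
from morphodisp.superimposition import residual_distances
from conftest import make_two_clade_study
from oracles import exhaustive_permutation_p


def aligned_sample(scheme, **kwargs):
    return md.gpa(make_two_clade_study(scheme, **kwargs))


# ---------------------------------------------------------------------------
# group_variance / delta_variance / bonferroni
# ---------------------------------------------------------------------------

class TestGroupVariance:
    def test_identical_shapes_zero(self, rng):
        base = rng.standard_normal((6, 3))
        base -= base.mean(0)
        base /= np.sqrt((base**2).sum())
        coords = np.stack([base] * 5)
        assert md.group_variance(coords, range(5)) == pytest.approx(0.0, abs=1e-20)

    def test_two_shapes_half_squared_distance(self, small_scheme):
        aligned = aligned_sample(small_scheme, n_per_group=2, seed=5)
        coords = aligned.coords / np.sqrt(np.sum(aligned.coords**2, axis=(1, 2), keepdims=True))
        d = md.procrustes_distance(coords[0], coords[1])
        # with the n-1 denominator, var of a pair at distance d is d^2/2
        assert md.group_variance(aligned.coords[:2], [0, 1]) == pytest.approx(
            d**2 / 2, rel=1e-4
        )

    def test_matches_direct_summation(self, small_scheme):
        aligned = aligned_sample(small_scheme, n_per_group=5, seed=9)
        members = np.arange(10)
        mean = aligned.coords[members].mean(axis=0)
        d = residual_distances(aligned.coords[members], mean)
        expected = np.sum(d**2) / (len(members) - 1)
        assert md.group_variance(aligned, members) == pytest.approx(expected, rel=1e-12)

    def test_score_matrix_backend(self, rng):
        pts = rng.standard_normal((12, 4))
        members = np.arange(12)
        mean = pts.mean(axis=0)
        expected = np.sum((pts - mean) ** 2) / 11
        assert md.group_variance(pts, members) == pytest.approx(expected, rel=1e-12)

    def test_too_few_members(self, rng):
        with pytest.raises(ContractError):
            md.group_variance(rng.standard_normal((5, 4)), [0])


def test_delta_variance_table_arithmetic():
    assert md.delta_variance(0.0258, 0.0681) == pytest.approx(0.0423)
    assert md.delta_variance(0.0314, 0.0310) == pytest.approx(-0.0004)
    assert md.delta_variance(0.7, 0.7) == 0.0


def test_bonferroni_threshold():
    assert md.bonferroni_threshold(0.01, 5) == pytest.approx(0.002)
    assert md.bonferroni_threshold(0.01, 36) == pytest.approx(0.01 / 36)
    assert md.bonferroni_threshold(0.05, 1) == 0.05
    with pytest.raises(ValueError):
        md.bonferroni_threshold(1.5, 3)
    with pytest.raises(ValueError):
        md.bonferroni_threshold(0.01, 0)


# ---------------------------------------------------------------------------
# bootstrap_equalize
# ---------------------------------------------------------------------------

class TestBootstrapEqualize:
    def make_unbalanced(self, scheme, seed=0):
        spec = md.SyntheticSpec(
            scheme=scheme,
            groups=(
                md.GroupSpec("mars", "marsupial", 24, 0.02),
                md.GroupSpec("plac", "placental", 10, 0.02),
            ),
            sex_ratio=0.5,
            seed=seed,
        )
        return md.simulate_study(spec)

    def test_every_stratum_resampled_to_target(self, small_scheme):
        ds = self.make_unbalanced(small_scheme)
        plan = md.ResamplingPlan(n_target=4, n_bootstrap=20, seed=1)
        reps = md.bootstrap_equalize(ds, plan)
        assert len(reps) == 20
        for rep in reps:
            # two sexes per clade, 4 each
            assert {clade: idx.size for clade, idx in rep.items()} == {
                "marsupial": 8,
                "placental": 8,
            }

    def test_default_target_is_smallest_stratum(self, small_scheme):
        ds = self.make_unbalanced(small_scheme)
        plan = md.ResamplingPlan(n_bootstrap=5, seed=1)
        reps = md.bootstrap_equalize(ds, plan)
        assert reps[0]["placental"].size == 2 * 5  # smallest (clade, sex) cell is 5

    def test_determinism(self, small_scheme):
        ds = self.make_unbalanced(small_scheme)
        plan = md.ResamplingPlan(n_target=4, n_bootstrap=10, seed=42)
        r1 = md.bootstrap_equalize(ds, plan)
        r2 = md.bootstrap_equalize(ds, plan)
        for a, b in zip(r1, r2):
            for clade in a:
                np.testing.assert_array_equal(a[clade], b[clade])

    def test_empty_stratum_named(self, small_scheme):
        ds = self.make_unbalanced(small_scheme)
        plan = md.ResamplingPlan(
            n_target=4, n_bootstrap=5, seed=1, strata=(("marsupial", "unknown"),)
        )
        with pytest.raises(DatasetError, match="unknown"):
            md.bootstrap_equalize(ds, plan)

    def test_resampling_consistency(self, small_scheme):
        """Mean bootstrap variance approaches the full-group variance as the
        target approaches the stratum size."""
        ds = self.make_unbalanced(small_scheme, seed=3)
        aligned = md.gpa(ds)
        mars = np.arange(24)
        full_var = md.group_variance(aligned, mars)
        plan = md.ResamplingPlan(n_target=12, n_bootstrap=1000, seed=7)
        reps = md.bootstrap_equalize(ds, plan)
        boot_vars = [md.group_variance(aligned, rep["marsupial"]) for rep in reps]
        # bootstrap variance is biased slightly low; allow a loose band
        assert np.mean(boot_vars) == pytest.approx(full_var, rel=0.15)


# ---------------------------------------------------------------------------
# permutation_test
# ---------------------------------------------------------------------------

class TestPermutationTest:
    def test_duplicated_sample_gives_zero_delta_p_one(self, small_scheme):
        ds = make_two_clade_study(small_scheme, n_per_group=8, seed=13)
        coords = md.gpa(ds).coords
        doubled = np.concatenate([coords[:8], coords[:8]])
        plan = md.ResamplingPlan(n_bootstrap=0, n_permutations=199, seed=5)
        res = md.permutation_test(doubled, np.arange(8), np.arange(8, 16), plan)
        assert res.delta == pytest.approx(0.0, abs=1e-15)
        assert res.p_value == 1.0

    def test_overlapping_groups_rejected(self, small_scheme):
        aligned = aligned_sample(small_scheme, n_per_group=5)
        plan = md.ResamplingPlan(n_bootstrap=0, n_permutations=199)
        with pytest.raises(ContractError, match="overlap"):
            md.permutation_test(aligned, [0, 1, 2], [2, 3, 4], plan)

    def test_matches_exhaustive_enumeration(self, small_scheme):
        aligned = aligned_sample(small_scheme, n_per_group=3, var_a=0.01, var_b=0.05, seed=2)
        members_a, members_b = np.arange(3), np.arange(3, 6)
        mean_a = aligned.coords[members_a].mean(axis=0)
        mean_b = aligned.coords[members_b].mean(axis=0)
        d_a = residual_distances(aligned.coords[members_a], mean_a)
        d_b = residual_distances(aligned.coords[members_b], mean_b)
        exact = exhaustive_permutation_p(d_a, d_b)
        plan = md.ResamplingPlan(n_bootstrap=0, n_permutations=20000, seed=3)
        res = md.permutation_test(aligned, members_a, members_b, plan)
        # (b+1)/(B+1) estimator vs exact proportion: binomial Monte-Carlo error
        se = np.sqrt(exact * (1 - exact) / 20000)
        assert abs(res.p_value - exact) < 4 * se + 2 / 20001

    def test_detects_large_variance_ratio(self, small_scheme):
        aligned = aligned_sample(
            small_scheme, n_per_group=30, var_a=0.0005, var_b=0.05, seed=17
        )
        plan = md.ResamplingPlan(n_bootstrap=0, n_permutations=999, seed=1)
        res = md.permutation_test(aligned, np.arange(30), np.arange(30, 60), plan)
        assert res.delta > 0
        assert res.p_value <= 0.01

    def test_antisymmetry_equal_sizes(self, small_scheme):
        aligned = aligned_sample(small_scheme, n_per_group=12, var_a=0.01, var_b=0.03, seed=23)
        a, b = np.arange(12), np.arange(12, 24)
        plan = md.ResamplingPlan(n_bootstrap=0, n_permutations=499, seed=11)
        fwd = md.permutation_test(aligned, a, b, plan)
        rev = md.permutation_test(aligned, b, a, plan)
        assert rev.delta == pytest.approx(-fwd.delta, rel=1e-12)
        assert rev.p_value == fwd.p_value

    def test_bit_reproducible(self, small_scheme):
        aligned = aligned_sample(small_scheme, n_per_group=10, var_a=0.01, var_b=0.02)
        plan = md.ResamplingPlan(n_bootstrap=50, n_permutations=199, seed=99)
        a, b = np.arange(10), np.arange(10, 20)
        r1 = md.permutation_test(aligned, a, b, plan)
        r2 = md.permutation_test(aligned, a, b, plan)
        assert r1 == r2

    def test_p_value_floor(self, small_scheme):
        aligned = aligned_sample(small_scheme, n_per_group=25, var_a=0.0001, var_b=0.05)
        plan = md.ResamplingPlan(n_bootstrap=0, n_permutations=199, seed=1)
        res = md.permutation_test(aligned, np.arange(25), np.arange(25, 50), plan)
        assert res.p_value >= 1 / (plan.n_permutations + 1)

    def test_few_permutations_warn(self, small_scheme):
        aligned = aligned_sample(small_scheme, n_per_group=5)
        plan = md.ResamplingPlan(n_bootstrap=0, n_permutations=50, seed=1)
        with pytest.warns(UserWarning, match="coarse"):
            md.permutation_test(aligned, np.arange(5), np.arange(5, 10), plan)

    def test_permute_labels_mode(self, small_scheme):
        aligned = aligned_sample(small_scheme, n_per_group=10, var_a=0.001, var_b=0.05, seed=31)
        plan = md.ResamplingPlan(n_bootstrap=0, n_permutations=199, seed=1)
        res = md.permutation_test(
            aligned, np.arange(10), np.arange(10, 20), plan, permute_labels=True
        )
        assert res.p_value <= 0.05

    def test_bootstrap_equalization_recorded(self, small_scheme):
        spec = md.SyntheticSpec(
            scheme=small_scheme,
            groups=(
                md.GroupSpec("mars", "marsupial", 20, 0.02),
                md.GroupSpec("plac", "placental", 8, 0.02),
            ),
            seed=4,
        )
        aligned = md.gpa(md.simulate_study(spec))
        plan = md.ResamplingPlan(n_bootstrap=100, n_permutations=199, seed=6)
        res = md.permutation_test(aligned, np.arange(20), np.arange(20, 28), plan)
        assert res.n_bootstrap == 100
        assert res.n_equalized == 8  # smallest group drives the target
        assert res.n_a == 20 and res.n_b == 8


# ---------------------------------------------------------------------------
# battery
# ---------------------------------------------------------------------------

def clade_grouping(label="all", extra=None):
    extra = extra or {}
    return md.Grouping(
        label=label,
        filter_a={"clade": "marsupial", **extra},
        filter_b={"clade": "placental", **extra},
        label_a="marsupial",
        label_b="placental",
    )


class TestBattery:
    @pytest.fixture()
    def study(self, small_scheme):
        return make_two_clade_study(
            small_scheme,
            n_per_group=12,
            var_a=0.01,
            var_b=0.04,
            seed=19,
            ecology={
                "mars": {"diet": "omnivore", "habitat": "terrestrial"},
                "plac": {"diet": "omnivore", "habitat": "terrestrial"},
            },
        )

    def test_five_region_battery_m5(self, study):
        plan = md.ResamplingPlan(n_bootstrap=10, n_permutations=99, seed=1)
        battery = md.run_disparity_battery(
            study,
            regions=list(md.REGION_QUERIES),
            groupings=[clade_grouping()],
            plan=plan,
        )
        assert battery.m == 5
        assert battery.alpha_adjusted == pytest.approx(0.002)
        assert all(r.alpha_adjusted == pytest.approx(0.002) for r in battery.results)

    def test_row_per_grouping_region(self, study):
        plan = md.ResamplingPlan(n_bootstrap=0, n_permutations=99, seed=1)
        battery = md.run_disparity_battery(
            study,
            regions=["whole_skull", "neurocranium"],
            groupings=[clade_grouping(), clade_grouping("omnivores", {"diet": "omnivore"})],
            plan=plan,
        )
        assert battery.m == 4
        assert [(r.dataset_label, r.region) for r in battery.results] == [
            ("all", "whole_skull"),
            ("all", "neurocranium"),
            ("omnivores", "whole_skull"),
            ("omnivores", "neurocranium"),
        ]

    def test_underfilled_cell_skipped(self, study):
        plan = md.ResamplingPlan(n_bootstrap=0, n_permutations=99, seed=1)
        groupings = [clade_grouping("folivores", {"diet": "folivore"}), clade_grouping()]
        with pytest.warns(UserWarning):
            battery = md.run_disparity_battery(
                study, regions=["whole_skull"], groupings=groupings, plan=plan
            )
        assert battery.m == 1
        assert len(battery.skipped) == 1
        assert "folivores" in battery.skipped[0]

    def test_overlapping_groups_duplicate_specimens(self, small_scheme):
        """Extant-vs-extant-plus-fossil style comparison runs as one row."""
        spec = md.SyntheticSpec(
            scheme=small_scheme,
            groups=(
                md.GroupSpec("mars", "marsupial", 10, 0.02),
                md.GroupSpec("foss", "fossil_metatherian", 4, 0.02),
            ),
            ecology_assignment={"foss": {"sex": "unknown"}},
            seed=8,
        )
        ds = md.simulate_study(spec)
        grouping = md.Grouping(
            label="extant_vs_with_fossils",
            filter_a={"clade": "marsupial"},
            filter_b={"clade": {"marsupial", "fossil_metatherian"}},
            label_a="marsupials",
            label_b="marsupials_and_fossils",
        )
        plan = md.ResamplingPlan(n_bootstrap=0, n_permutations=199, seed=2)
        battery = md.run_disparity_battery(
            ds, regions=["whole_skull"], groupings=[grouping], plan=plan,
            size_correction=False,
        )
        assert battery.m == 1
        row = battery.results[0]
        assert row.n_a == 10 and row.n_b == 14
        assert row.delta == pytest.approx(row.variance_b - row.variance_a)

    def test_determinism(self, study):
        plan = md.ResamplingPlan(n_bootstrap=20, n_permutations=99, seed=3)
        kwargs = dict(regions=["whole_skull"], groupings=[clade_grouping()], plan=plan)
        b1 = md.run_disparity_battery(study, **kwargs)
        b2 = md.run_disparity_battery(study, **kwargs)
        assert b1.results == b2.results

    def test_size_correction_switch(self, study):
        plan = md.ResamplingPlan(n_bootstrap=0, n_permutations=99, seed=3)
        with_corr = md.run_disparity_battery(
            study, regions=["whole_skull"], groupings=[clade_grouping()], plan=plan
        )
        without = md.run_disparity_battery(
            study,
            regions=["whole_skull"],
            groupings=[clade_grouping()],
            plan=plan,
            size_correction=False,
        )
        assert with_corr.results[0].variance_a != without.results[0].variance_a

    def test_species_averaging_switch(self, small_scheme):
        ds = make_two_clade_study(small_scheme, n_per_group=8, seed=29)
        plan = md.ResamplingPlan(n_bootstrap=0, n_permutations=99, seed=3)
        battery = md.run_disparity_battery(
            ds,
            regions=["whole_skull"],
            groupings=[clade_grouping()],
            plan=plan,
            average_species=True,
        )
        # every synthetic specimen is its own species here, so counts match
        assert battery.results[0].n_a == 8


def test_results_frame_columns(small_scheme):
    ds = make_two_clade_study(small_scheme, n_per_group=6, var_b=0.05, seed=37)
    plan = md.ResamplingPlan(n_bootstrap=0, n_permutations=99, seed=1)
    battery = md.run_disparity_battery(
        ds, regions=["whole_skull"], groupings=[clade_grouping()], plan=plan
    )
    frame = md.results_to_frame(battery)
    assert list(frame.columns) == [
        "dataset",
        "skull_region",
        "group_a",
        "group_b",
        "variance_a",
        "variance_b",
        "delta_variance",
        "p_value",
        "n_a",
        "n_b",
        "alpha_adjusted",
        "significant",
    ]
    assert len(frame) == 1
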