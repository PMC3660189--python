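import numpy as np
import pytest

import morphodisp as md


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def table3():
    return md.load_scheme("table3")


@pytest.fixture
def small_scheme():
    """9-landmark scheme with at least 3 landmarks per region query."""
    ids = tuple(range(1, 10))
    regions = {
        1: "oral",
        2: "oral",
        3: "oral",
        4: "viscerocranium_both",
        5: "viscerocranium_non_oral",
        6: "viscerocranium_non_oral",
        7: "neurocranium",
        8: "neurocranium",
        9: "neurocranium",
    }
    return md.LandmarkScheme(name="small9", landmark_ids=ids, regions=regions)


def make_two_clade_study(
    scheme,
    n_per_group=20,
    var_a=0.02,
    var_b=0.02,
    seed=0,
    slope_a=0.0,
    slope_b=0.0,
    ecology=None,
):
    spec = md.SyntheticSpec(
        scheme=scheme,
        groups=(
            md.GroupSpec("mars", "marsupial", n_per_group, var_a, allometric_slope=slope_a),
            md.GroupSpec("plac", "placental", n_per_group, var_b, allometric_slope=slope_b),
        ),
        ecology_assignment=ecology or {},
        seed=seed,
    )
    return md.simulate_study(spec)


@pytest.fixture
def two_clade_dataset(small_scheme):
    return make_two_clade_study(small_scheme, n_per_group=15, seed=7)


@pytest.fixture
def tiny_dataset(small_scheme):
    """4-specimen dataset for structural tests."""
    return make_two_clade_study(small_scheme, n_per_group=2, seed=11)
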