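import numpy as np
import pytest

from growthdesign import (
    AbilityGrid,
    CriterionSpec,
    GrowthDesign,
    Item,
    asymptotic_var_growth,
    asymptotic_var_percentile,
    build_case_objective,
    crit_growth,
    crit_mean,
    crit_percentile,
    make_normal_grid,
    make_percentile_grid,
)
from growthdesign.criteria import WeightedVarianceObjective
from growthdesign.irt import test_information as tif
from growthdesign.weights import WeightedPoints

POINT0 = AbilityGrid([0.0], [1.0])


def naive_criterion(design: GrowthDesign, grid1, grid2) -> float:
    """Independent double-loop oracle for the growth criterion."""
    total = 0.0
    for pts, w, form in ((grid1.points, grid1.weights, design.form1),
                         (grid2.points, grid2.weights, design.form2)):
        for theta, wj in zip(pts, w):
            tif = 0.0
            for it in form:
                p = 1.0 / (1.0 + np.exp(-it.a * (theta - it.b)))
                tif += it.a**2 * p * (1 - p)
            total += wj / tif
    return total


class TestCritMean:
    def test_single_item_point_grid(self):
        assert crit_mean([Item(1, 0)], POINT0) == pytest.approx(4.0, abs=1e-12)

    def test_weight_splitting_invariance(self):
        split = WeightedPoints([0.0, 0.0], [0.5, 0.5])
        assert crit_mean([Item(1, 0)], split) == pytest.approx(4.0, abs=1e-12)

    def test_doubling_information_halves_criterion(self):
        assert crit_mean([Item(1, 0), Item(1, 0)], POINT0) == pytest.approx(2.0)

    def test_decreases_when_item_added(self):
        grid = make_normal_grid(0, 1, 21, 4)
        items = [Item(1.0, -0.3), Item(0.8, 0.6)]
        assert crit_mean(items + [Item(0.5, 1.0)], grid) < crit_mean(items, grid)


class TestCritGrowth:
    def test_hand_value(self, simple_design):
        g1 = AbilityGrid([-0.5], [1.0])
        g2 = AbilityGrid([0.5], [1.0])
        assert crit_growth(simple_design, g1, g2) == pytest.approx(
            4.123679, abs=1e-5
        )
        assert crit_growth(simple_design, g1, g2) == pytest.approx(
            2.0 / 0.4850037122015945, rel=1e-12
        )

    def test_reflection_symmetry(self, simple_design):
        g1 = make_normal_grid(-0.5, 1, 11, 4)
        g2 = make_normal_grid(0.5, 1, 11, 4)
        val = crit_growth(simple_design, g1, g2)
        reflected = GrowthDesign(
            tuple(Item(i.a, -i.b) for i in simple_design.unique2),
            tuple(Item(i.a, -i.b) for i in simple_design.common),
            tuple(Item(i.a, -i.b) for i in simple_design.unique1),
        )
        rg1 = AbilityGrid(-g2.points[::-1], g2.weights[::-1])
        rg2 = AbilityGrid(-g1.points[::-1], g1.weights[::-1])
        assert crit_growth(reflected, rg1, rg2) == pytest.approx(val, abs=1e-12)

    def test_extra_common_item_strictly_decreases(self, simple_design):
        g1 = AbilityGrid([-0.5], [1.0])
        g2 = AbilityGrid([0.5], [1.0])
        bigger = GrowthDesign(
            simple_design.unique1,
            simple_design.common + (Item(1, 0),),
            simple_design.unique2,
        )
        assert crit_growth(bigger, g1, g2) < crit_growth(simple_design, g1, g2)

    def test_matches_naive_double_loop_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n1, nc, n2 = rng.integers(1, 5, size=3)
            design = GrowthDesign(
                tuple(Item(rng.uniform(0.5, 2), rng.uniform(-2, 2)) for _ in range(n1)),
                tuple(Item(rng.uniform(0.5, 2), rng.uniform(-2, 2)) for _ in range(nc)),
                tuple(Item(rng.uniform(0.5, 2), rng.uniform(-2, 2)) for _ in range(n2)),
            )
            g1 = make_normal_grid(rng.uniform(-1, 0), 1, 7, 3)
            g2 = make_normal_grid(rng.uniform(0, 1), 1, 7, 3)
            assert crit_growth(design, g1, g2) == pytest.approx(
                naive_criterion(design, g1, g2), abs=1e-12
            )


class TestCritPercentile:
    def test_median_only_single_items(self):
        design = GrowthDesign((Item(1, 0),), (), (Item(1, 0),))
        g = make_percentile_grid([50], 0, 1)
        assert crit_percentile(design, g, g) == pytest.approx(4.0, abs=1e-12)

    def test_higher_discrimination_scales(self):
        design = GrowthDesign((Item(2, 0),), (), (Item(2, 0),))
        g = make_percentile_grid([50], 0, 1)
        assert crit_percentile(design, g, g) == pytest.approx(1.0, abs=1e-12)

    def test_coincides_with_growth_on_degenerate_grids(self):
        design = GrowthDesign((Item(1, 0),), (), (Item(1, 0),))
        g = make_percentile_grid([50], 0, 1)
        half = WeightedPoints([0.0], [1.0])
        expected = 0.5 * crit_growth(design, half, half)
        assert crit_percentile(design, g, g) == pytest.approx(expected, abs=1e-12)


class TestCaseObjectives:
    def test_case1_equals_crit_growth_on_unpacked_design(self):
        spec = CriterionSpec(d=1.0, a_level=1.0, n1=2, nc=1, n2=2, l=11)
        obj = build_case_objective(1, spec)
        b = np.array([-0.8, -0.2, 0.0, 0.3, 0.9])
        design = obj.unpack(b)
        g1 = make_normal_grid(-0.5, 1, 11, 4)
        g2 = make_normal_grid(0.5, 1, 11, 4)
        assert obj(b) == pytest.approx(crit_growth(design, g1, g2), rel=1e-12)

    def test_case4_zero_shift_equals_case1(self):
        spec = CriterionSpec(d=1.0, a_level=1.0, n1=2, nc=1, n2=2, l=11, group_shift=0.0)
        obj1 = build_case_objective(1, spec)
        obj4 = build_case_objective(4, spec)
        b = np.array([-0.8, -0.2, 0.0, 0.3, 0.9])
        assert obj4(b) == pytest.approx(obj1(b), rel=1e-12)

    def test_case3_hand_summed_six_terms(self):
        """Case 3 at d=0 is the six-term percentile weighted sum."""
        spec = CriterionSpec(d=0.0, a_level=1.0, n1=1, nc=1, n2=1)
        obj = build_case_objective(3, spec)
        b = np.array([-0.4, 0.0, 0.4])
        design = obj.unpack(b)
        q = make_percentile_grid([25, 50, 75], 0, 1)
        expected = sum(
            0.5 * wj / tif(design.form1, th)
            for th, wj in zip(q.points, q.weights)
        ) + sum(
            0.5 * wj / tif(design.form2, th)
            for th, wj in zip(q.points, q.weights)
        )
        assert obj(b) == pytest.approx(expected, rel=1e-12)

    def test_case2_is_equal_mass_average(self):
        spec = CriterionSpec(d=1.0, a_level=1.0, n1=2, nc=1, n2=2, l=11)
        obj2 = build_case_objective(2, spec)
        b = np.array([-0.8, -0.2, 0.0, 0.3, 0.9])
        design = obj2.unpack(b)
        g1 = make_normal_grid(-0.5, 1, 11, 4)
        g2 = make_normal_grid(0.5, 1, 11, 4)
        q1 = make_percentile_grid([25, 75], -0.5, 1)
        q2 = make_percentile_grid([25, 75], 0.5, 1)
        expected = 0.5 * crit_growth(design, g1, g2) + 0.5 * crit_percentile(
            design, q1, q2
        )
        assert obj2(b) == pytest.approx(expected, rel=1e-12)

    def test_batch_and_scalar_paths_agree(self):
        spec = CriterionSpec(d=1.5, a_level=0.8, n1=3, nc=2, n2=3, l=15)
        obj = build_case_objective(1, spec)
        rng = np.random.default_rng(5)
        batch = rng.uniform(-3, 3, size=(6, 8))
        vals = obj(batch)
        for k in range(6):
            assert vals[k] == pytest.approx(obj(batch[k]), rel=1e-14)

    def test_wrong_vector_length_rejected(self):
        obj = build_case_objective(1, CriterionSpec(n1=2, nc=1, n2=2, l=5))
        with pytest.raises(ValueError):
            obj(np.zeros(4))

    def test_invalid_case_id(self):
        with pytest.raises(ValueError):
            build_case_objective(5, CriterionSpec())

    def test_criterion_strictly_positive(self):
        spec = CriterionSpec(d=2.0, a_level=2.0, n1=2, nc=2, n2=2, l=21)
        obj = build_case_objective(2, spec)
        rng = np.random.default_rng(8)
        assert np.all(obj(rng.uniform(-6, 6, size=(20, 6))) > 0)


class TestAsymptoticVariance:
    def test_unit_samples_match_growth_criterion(self, simple_design):
        v = asymptotic_var_growth(simple_design, [-0.5], [0.5], 1, 1)
        assert v == pytest.approx(4.123679, abs=1e-5)

    def test_doubling_samples_halves_variance(self, simple_design):
        th1, th2 = [-0.5, 0.3], [0.2, 0.8]
        v1 = asymptotic_var_growth(simple_design, th1, th2, 2, 2)
        v2 = asymptotic_var_growth(simple_design, th1 * 2, th2 * 2, 4, 4)
        assert v2 == pytest.approx(v1 / 2, rel=1e-12)

    def test_single_form_degenerate_case(self, simple_design):
        v = asymptotic_var_growth(simple_design, [-0.5, 0.1], [], 2, 0)
        expected = sum(
            1.0 / tif(simple_design.form1, t) for t in (-0.5, 0.1)
        ) / 4
        assert v == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_rejected(self, simple_design):
        with pytest.raises(ValueError):
            asymptotic_var_growth(simple_design, [0.0], [0.0], 2, 1)

    def test_percentile_variance_values(self):
        d1 = GrowthDesign((Item(1, 0),), (), (Item(1, 0),))
        assert asymptotic_var_percentile(d1, 0, 0) == pytest.approx(8.0, abs=1e-12)
        d2 = GrowthDesign((Item(2, 0),), (), (Item(2, 0),))
        assert asymptotic_var_percentile(d2, 0, 0) == pytest.approx(2.0, abs=1e-12)

    def test_scale_link_between_criterion_and_variance(self, simple_design):
        """Point grids at the sampled abilities with unit weights make the
        criterion equal N times the asymptotic variance (N1 = N2 = N)."""
        th1, th2 = [-0.4], [0.6]
        g1 = AbilityGrid(th1, [1.0])
        g2 = AbilityGrid(th2, [1.0])
        N = 7
        crit = crit_growth(simple_design, g1, g2)
        var = asymptotic_var_growth(simple_design, th1 * N, th2 * N, N, N)
        assert crit == pytest.approx(N * var, rel=1e-12)


def test_objective_requires_components():
    with pytest.raises(ValueError):
        WeightedVarianceObjective(1.0, 1, 1, 1, [])


def test_design_requires_nonempty_forms():
    with pytest.raises(ValueError):
        GrowthDesign((), (), (Item(1, 0),))
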