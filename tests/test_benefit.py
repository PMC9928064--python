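"""Zone combination, weighted benefit triples, and lexicographic comparison."""

import random
from fractions import Fraction

import pytest

from aedcorridor import (
    BenefitTriple,
    Deployment,
    Ordering,
    ZoneLabel,
    compare_benefit,
    deployment_benefit,
    fixed_at,
    make_corridor,
    patrol,
    summonable_at,
    weighted_sizes,
    zone_profile,
)


def triple(h, c, w):
    return BenefitTriple(hot=Fraction(h), cold=Fraction(c), warm=Fraction(w))


class TestZoneProfile:
    def test_single_center_unit_counts(self, fig_fixture):
        corridor, deps = fig_fixture
        profile = zone_profile(deps["center"], corridor)
        assert profile.count(ZoneLabel.HOT) == 3
        assert profile.count(ZoneLabel.WARM) == 14
        assert profile.count(ZoneLabel.COLD) == 5

    def test_two_units_leave_no_cold_zone(self, fig_fixture):
        corridor, deps = fig_fixture
        profile = zone_profile(deps["pair"], corridor)
        assert profile.count(ZoneLabel.HOT) == 6
        assert profile.count(ZoneLabel.COLD) == 0

    def test_empty_deployment_is_all_cold(self, corridor22):
        profile = zone_profile(Deployment(), corridor22)
        assert profile.count(ZoneLabel.COLD) == 22
        assert all(t is None for t in profile.times)

    def test_patrol_unit_rejected(self, corridor22):
        with pytest.raises(ValueError, match="patrol"):
            zone_profile(Deployment((patrol(),)), corridor22)

    def test_label_partition(self, fig_fixture):
        corridor, deps = fig_fixture
        profile = zone_profile(deps["pair_improved"], corridor)
        counts = [profile.count(lab) for lab in ZoneLabel]
        assert sum(counts) == corridor.n_cells


class TestWeightedSizes:
    def test_single_center_unit_exact_triple(self, fig_fixture):
        corridor, deps = fig_fixture
        result = weighted_sizes(zone_profile(deps["center"], corridor), corridor)
        assert result == triple(3, 5, Fraction(481, 140))

    def test_shifted_unit_same_triple(self, fig_fixture):
        corridor, deps = fig_fixture
        center = weighted_sizes(zone_profile(deps["center"], corridor), corridor)
        shifted = weighted_sizes(zone_profile(deps["shifted"], corridor), corridor)
        assert center == shifted

    def test_two_unit_exact_triple(self, fig_fixture):
        corridor, deps = fig_fixture
        result = weighted_sizes(zone_profile(deps["pair"], corridor), corridor)
        assert result == triple(6, 0, Fraction(4131, 840))

    def test_empty_profile_all_mass_cold(self, corridor22):
        result = weighted_sizes(zone_profile(Deployment(), corridor22), corridor22)
        assert result == triple(0, 22, 0)

    def test_density_and_area_scale_the_triple(self):
        c = make_corridor(22, density=[2] * 22, cell_area="1/2")
        result = weighted_sizes(
            zone_profile(Deployment((fixed_at(11),)), c), c
        )
        # density 2 times dA 1/2 restores the uniform unit weights
        assert result == triple(3, 5, Fraction(481, 140))


class TestDeploymentBenefit:
    def test_patrol_is_average_of_summonable_positions(self, corridor22):
        patrol_triple = deployment_benefit(
            Deployment((patrol(8, 11),)), corridor22
        )
        sums = [Fraction(0)] * 3
        for cell in range(8, 12):
            t = deployment_benefit(Deployment((summonable_at(cell),)), corridor22)
            for i, x in enumerate(t.as_tuple()):
                sums[i] += x
        assert patrol_triple.as_tuple() == tuple(s / 4 for s in sums)

    def test_single_cell_patrol_equals_summonable(self, corridor22):
        p = deployment_benefit(Deployment((patrol(6, 6),)), corridor22)
        s = deployment_benefit(Deployment((summonable_at(6),)), corridor22)
        assert p == s

    def test_whole_space_patrol_within_summonable_envelope(self, corridor22):
        """Each component of the patrol triple sits between the best and the
        worst of that component over all summonable placements."""
        p = deployment_benefit(Deployment((patrol(),)), corridor22)
        singles = [
            deployment_benefit(Deployment((summonable_at(c),)), corridor22)
            for c in range(1, 23)
        ]
        for i in range(3):
            values = [s.as_tuple()[i] for s in singles]
            assert min(values) <= p.as_tuple()[i] <= max(values)

    def test_static_deployment_matches_weighted_sizes(self, fig_fixture):
        corridor, deps = fig_fixture
        direct = weighted_sizes(zone_profile(deps["pair"], corridor), corridor)
        assert deployment_benefit(deps["pair"], corridor) == direct

    def test_budget_overrun_warns_but_computes(self):
        c = make_corridor(5)
        dep = Deployment((patrol(), patrol()))
        with pytest.warns(RuntimeWarning, match="budget"):
            result = deployment_benefit(dep, c, patrol_budget=10)
        assert result.hot > 0


class TestCompareBenefit:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (triple(6, 0, 0), triple(5, 0, 100), Ordering.A_BETTER),
            (triple(6, 2, 1), triple(6, 1, 1), Ordering.B_BETTER),
            (triple(6, 0, 2), triple(6, 0, 1), Ordering.A_BETTER),
            (triple(3, 5, Fraction(481, 140)), triple(3, 5, Fraction(481, 140)),
             Ordering.EQUAL),
        ],
    )
    def test_lexicographic_rules(self, a, b, expected):
        assert compare_benefit(a, b) is expected

    def test_moving_left_unit_out_improves_pair(self, fig_fixture):
        """Spreading the two units further apart strictly improves A_W."""
        corridor, deps = fig_fixture
        improved = deployment_benefit(deps["pair_improved"], corridor)
        original = deployment_benefit(deps["pair"], corridor)
        assert compare_benefit(improved, original) is Ordering.A_BETTER

    def test_tolerance_mode_treats_near_ties_as_equal(self):
        a = triple(3, 5, Fraction(481, 140))
        b = BenefitTriple(
            hot=a.hot + Fraction(1, 10**12), cold=a.cold, warm=a.warm
        )
        assert compare_benefit(a, b) is Ordering.B_BETTER
        assert compare_benefit(a, b, tolerance=Fraction(1, 10**9)) is Ordering.EQUAL


class TestInvariants:
    def _random_static(self, rng, n):
        units = []
        for _ in range(rng.randint(1, 3)):
            maker = rng.choice([fixed_at, summonable_at])
            units.append(maker(rng.randint(1, n)))
        return Deployment(tuple(units))

    def test_conservation_of_weighted_mass(self):
        """Hot + cold + (unweighted) warm mass always equals the total mass."""
        rng = random.Random(20260924)
        for _ in range(50):
            n = rng.randint(3, 25)
            density = [Fraction(rng.randint(0, 10), 10) for _ in range(n)]
            if all(d == 0 for d in density):
                density[0] = Fraction(1)
            c = make_corridor(n, density=density)
            dep = self._random_static(rng, n)
            profile = zone_profile(dep, c)
            t = weighted_sizes(profile, c)
            warm_mass = sum(
                (
                    c.density[i] * c.cell_area
                    for i in range(n)
                    if profile.labels[i] is ZoneLabel.WARM
                ),
                Fraction(0),
            )
            assert t.hot + t.cold + warm_mass == c.total_mass

    def test_mirror_symmetry_under_uniform_conditions(self):
        rng = random.Random(4)
        for _ in range(30):
            n = rng.randint(3, 25)
            c = make_corridor(n)
            dep = self._random_static(rng, n)
            mirrored = Deployment(
                tuple(
                    type(u)(u.kind, cell=n + 1 - u.cell) for u in dep.units
                )
            )
            assert deployment_benefit(dep, c) == deployment_benefit(mirrored, c)

    def test_adding_a_unit_never_hurts_hot_or_cold(self):
        rng = random.Random(9)
        for _ in range(30):
            n = rng.randint(3, 20)
            c = make_corridor(n)
            dep = self._random_static(rng, n)
            extra = rng.choice([fixed_at, summonable_at])(rng.randint(1, n))
            bigger = Deployment(dep.units + (extra,))
            a = deployment_benefit(dep, c)
            b = deployment_benefit(bigger, c)
            assert b.hot >= a.hot
            assert b.cold <= a.cold

    def test_summonable_dominates_fixed_at_same_cell(self, corridor22):
        for cell in range(1, 23):
            s = deployment_benefit(Deployment((summonable_at(cell),)), corridor22)
            f = deployment_benefit(Deployment((fixed_at(cell),)), corridor22)
            assert compare_benefit(s, f) is not Ordering.B_BETTER

    @pytest.mark.parametrize("n", [17, 18, 21, 25, 34])
    def test_summonable_at_end_equals_fixed_at_center(self, n):
        """Halved acquisition time exactly offsets the halved coverage of an
        end position, for corridors long enough to hold the warm reach."""
        c = make_corridor(n)
        s_end = deployment_benefit(Deployment((summonable_at(1),)), c)
        f_center = deployment_benefit(
            Deployment((fixed_at((n + 1) // 2),)), c
        )
        assert s_end == f_center
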