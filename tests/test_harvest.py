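import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from standsim import (
    HarvestParams,
    Intensity,
    OwnerType,
    RestrictionZone,
    age_adjusted_probability,
    application_probability,
    clearcut_cluster_area,
    cumulative_cut_probability,
    draw_willingness,
    execute_clearcut,
    permit_clearcut,
    run_scenario,
    run_year,
    split_two_step,
    state_forest_harvest,
    stand_age,
    unit_application_probability,
)
from standsim.core import CadastralUnit, RegenerationMode
from standsim.harvest import _attempt_cut
from standsim.scenario import build_scenario

from conftest import make_stand, make_state


class TestAgeAdjustedProbability:
    @pytest.mark.parametrize("base,ypm,expected", [
        (0.385, 20, 0.77),     # doubling at the 20-year horizon
        (0.385, -3, 0.0),      # maturity not reached
        (0.6, 40, 1.0),        # capped at 1
        (0.2, 0, 0.2),
    ])
    def test_examples(self, base, ypm, expected):
        assert age_adjusted_probability(base, ypm) == pytest.approx(expected)

    @given(st.floats(0, 1), st.floats(-50, 200))
    def test_is_probability_and_monotone(self, base, ypm):
        p = age_adjusted_probability(base, ypm)
        assert 0.0 <= p <= 1.0
        assert age_adjusted_probability(base, ypm + 5) >= p


class TestUnitApplicationProbability:
    def test_worked_example_mean_over_nonzero(self):
        """Strict and immature stands carry zero weight: the unit probability
        from adjusted values {0, 0.3, 0, 0.77} is (0.3 + 0.77) / 2."""
        assert application_probability([0.0, 0.3, 0.0, 0.77]) == pytest.approx(0.535)

    def test_worked_example_through_the_engine(self, worked_example):
        """The four-stand example unit, with the class-A age adjustment run
        at its slower horizon so the class-A stand lands at 0.3."""
        params = HarvestParams(restricted_doubling_horizon=60.0)
        unit = worked_example.units[0]
        p = unit_application_probability(unit, worked_example, params)
        assert p == pytest.approx(0.535)

    def test_default_rule_doubles_class_a_too(self, worked_example):
        p = unit_application_probability(worked_example.units[0],
                                         worked_example, HarvestParams())
        # class-A stand adjusts to min(1, 0.2·(1+30/20)) = 0.5
        assert p == pytest.approx((0.5 + 0.77) / 2)

    def test_all_immature_gives_zero(self):
        state = make_state([make_stand(1, age=50.0), make_stand(2, age=60.0)])
        assert unit_application_probability(state.units[0], state,
                                            HarvestParams()) == 0.0

    def test_single_eligible_stand(self):
        state = make_state([make_stand(1, age=90.0)])  # exactly at maturity
        assert unit_application_probability(state.units[0], state,
                                            HarvestParams()) == pytest.approx(0.385)

    def test_state_unit_rejected(self):
        state = make_state([make_stand(1)],
                           units=[CadastralUnit(0, OwnerType.STATE,
                                                Intensity.NOT_APPLICABLE, [1])])
        with pytest.raises(ValueError, match="state"):
            unit_application_probability(state.units[0], state, HarvestParams())

    def test_nonint_cap_on_class_a(self):
        """Class A/B base probabilities never exceed the unit's unrestricted
        base probability."""
        state = make_state([make_stand(1, zone=RestrictionZone.CLASS_A, age=90.0)])
        state.units[0].intensity = Intensity.NONINT
        p = unit_application_probability(state.units[0], state, HarvestParams())
        assert p == pytest.approx(0.055)   # min(0.2, 0.055)


class TestDrawWillingness:
    def test_zero_probability_never_applies(self, rng):
        state = make_state([make_stand(1, age=50.0)])
        for _ in range(50):
            assert draw_willingness(state, HarvestParams(), rng).applications == {}

    def test_certain_unit_applies_with_all_eligible_stands(self, rng):
        # stand 1 is 110 y past maturity, so its adjusted probability caps at 1
        state = make_state([make_stand(1, age=200.0), make_stand(2, age=50.0)])
        will = draw_willingness(state, HarvestParams(), rng)
        assert will.applications == {0: [1]}   # immature stand 2 not listed

    def test_empirical_rate_matches_unit_probability(self, worked_example):
        params = HarvestParams(restricted_doubling_horizon=60.0)
        rng = np.random.default_rng(7)
        hits = sum(bool(draw_willingness(worked_example, params, rng).applications)
                   for _ in range(100_000))
        assert hits / 100_000 == pytest.approx(0.535, abs=0.005)


class TestClusterArea:
    def test_singleton(self):
        state = make_state([make_stand(1, area=30_000.0, age=100.0)])
        assert clearcut_cluster_area(state.stands[1], state) == 30_000.0

    def test_chain_through_young_neighbors(self):
        """3 ha candidate – 3 ha clear-cut – 2 ha clear-cut chain sums to 8 ha,
        matching a brute-force component walk."""
        stands = [
            make_stand(1, area=30_000.0, age=100.0, neighbors={2}),
            make_stand(2, area=30_000.0, age=2.0, neighbors={1, 3}),
            make_stand(3, area=20_000.0, age=4.0, neighbors={2}),
        ]
        state = make_state(stands)
        assert clearcut_cluster_area(state.stands[1], state) == 80_000.0

    def test_mature_neighbors_do_not_count(self):
        stands = [
            make_stand(1, area=30_000.0, age=100.0, neighbors={2}),
            make_stand(2, area=20_000.0, age=100.0, neighbors={1}),
        ]
        state = make_state(stands)
        assert clearcut_cluster_area(state.stands[1], state) == 30_000.0


class TestPermit:
    def test_worked_example_both_stands_within_limit(self):
        """3 ha + 2 ha applied stands: total 5 ha stays below the 7 ha
        general-management cutover limit."""
        stands = [
            make_stand(2, area=30_000.0, age=120.0, neighbors={4}),
            make_stand(4, area=20_000.0, age=110.0, neighbors={2}),
        ]
        state = make_state(stands)
        assert permit_clearcut(state.stands[2], state, HarvestParams()).allowed

    def test_young_neighbors_push_cluster_over_limit(self):
        stands = [
            make_stand(1, area=30_000.0, age=100.0, neighbors={2}),
            make_stand(2, area=30_000.0, age=2.0, neighbors={1, 3},
                       years_since_clearcut=2),
            make_stand(3, area=20_000.0, age=4.0, neighbors={2},
                       years_since_clearcut=4),
        ]
        state = make_state(stands)
        decision = permit_clearcut(state.stands[1], state, HarvestParams())
        assert decision.status == "denied"
        assert decision.cluster_area == 80_000.0

    def test_limited_management_quiet_period(self):
        stands = [
            make_stand(1, area=10_000.0, age=120.0, zone=RestrictionZone.CLASS_A,
                       neighbors={2}),
            make_stand(2, area=10_000.0, age=3.0, neighbors={1},
                       years_since_clearcut=3),
        ]
        state = make_state(stands)
        assert permit_clearcut(state.stands[1], state,
                               HarvestParams()).status == "denied"
        # after the quiet period the neighbor no longer blocks
        state.stands[2].years_since_clearcut = 5
        assert permit_clearcut(state.stands[1], state, HarvestParams()).allowed

    def test_single_large_stand_exemption(self):
        state = make_state([make_stand(1, area=90_000.0, age=120.0)])
        assert permit_clearcut(state.stands[1], state, HarvestParams()).allowed

    def test_exemption_void_with_attached_young_area(self):
        stands = [
            make_stand(1, area=90_000.0, age=120.0, neighbors={2}),
            make_stand(2, area=10_000.0, age=2.0, neighbors={1},
                       years_since_clearcut=2),
        ]
        state = make_state(stands)
        assert permit_clearcut(state.stands[1], state,
                               HarvestParams()).status == "denied"

    def test_strict_zone_is_unreachable(self):
        state = make_state([make_stand(1, zone=RestrictionZone.STRICT)])
        with pytest.raises(RuntimeError, match="strictly protected"):
            permit_clearcut(state.stands[1], state, HarvestParams())

    def test_riparian_over_limit_goes_two_step(self):
        state = make_state([make_stand(1, area=30_000.0, age=120.0,
                                       zone=RestrictionZone.WATERBODY)])
        assert permit_clearcut(state.stands[1], state,
                               HarvestParams()).status == "allowed_two_step"


class TestSplitTwoStep:
    def test_equal_split_conserves_area_and_adjacency(self):
        stands = [make_stand(1, area=30_000.0, age=120.0,
                             zone=RestrictionZone.WATERBODY, neighbors={2}),
                  make_stand(2, area=10_000.0, age=50.0, neighbors={1})]
        state = make_state(stands)
        first, rest = split_two_step(state.stands[1], state, 20_000.0)
        assert first.area == pytest.approx(15_000.0)
        assert rest.area == pytest.approx(15_000.0)
        assert rest.id in first.neighbor_ids and first.id in rest.neighbor_ids
        assert {first.id, rest.id} <= state.stands[2].neighbor_ids
        assert 1 not in state.stands
        assert sorted(state.units[0].stand_ids) == sorted([2, first.id, rest.id])

    def test_at_limit_not_split(self):
        state = make_state([make_stand(1, area=20_000.0, age=120.0,
                                       zone=RestrictionZone.WATERBODY)])
        assert permit_clearcut(state.stands[1], state, HarvestParams()).allowed
        with pytest.raises(ValueError):
            split_two_step(state.stands[1], state, 20_000.0)

    def test_residual_blocked_until_first_child_matures(self, rng):
        """After the first step of a two-step cut, the residual half stays
        denied until the cut half is 6 years old."""
        state = make_state([make_stand(1, area=30_000.0, age=120.0,
                                       zone=RestrictionZone.WATERBODY)])
        params = HarvestParams(regen_transition_prob=0.0)
        area = _attempt_cut(state.stands[1], state, params, rng)
        assert area == pytest.approx(15_000.0)
        first_id = min(i for i in state.stands if i != 1 and
                       state.stands[i].years_since_clearcut == 0)
        rest_id = next(i for i in state.stands if i not in (first_id,))
        for _ in range(6):
            decision = permit_clearcut(state.stands[rest_id], state, params)
            assert decision.status == "denied"
            from standsim import advance_ages
            advance_ages(state)
        assert stand_age(state.stands[first_id]) == 6.0
        assert permit_clearcut(state.stands[rest_id], state, params).allowed


class TestExecuteClearcut:
    def test_no_transition_keeps_composition(self, rng):
        state = make_state([make_stand(1, age=100.0)])
        execute_clearcut(state.stands[1], state,
                         HarvestParams(regen_transition_prob=0.0), rng)
        stand = state.stands[1]
        assert [c.species for c in stand.upper_layer] == ["pine"]
        assert stand_age(stand) == 0.0
        assert stand.years_since_clearcut == 0
        assert [e.event for e in state.events] == ["clearcut"]

    def test_transition_fraction_matches_probability(self):
        rng = np.random.default_rng(11)
        flips = 0
        n = 10_000
        for _ in range(n):
            state = make_state([make_stand(1, age=100.0,
                                           regeneration_mode=RegenerationMode.NATURAL)])
            execute_clearcut(state.stands[1], state, HarvestParams(), rng)
            flips += state.stands[1].regeneration_mode is RegenerationMode.PLANTED
        assert flips / n == pytest.approx(0.05, abs=0.007)

    def test_transition_copies_similar_stand_composition(self):
        target = make_stand(1, age=100.0,
                            regeneration_mode=RegenerationMode.NATURAL)
        ref = make_stand(2, age=60.0, species="spruce",
                         regeneration_mode=RegenerationMode.PLANTED)
        target.similar_stand_ids = (None, 2)
        state = make_state([target, ref])
        rng = np.random.default_rng(0)
        execute_clearcut(target, state, HarvestParams(regen_transition_prob=1.0), rng)
        assert target.regeneration_mode is RegenerationMode.PLANTED
        assert [c.species for c in target.upper_layer] == ["spruce"]
        assert stand_age(target) == 0.0

    def test_strict_zone_guarded(self, rng):
        state = make_state([make_stand(1, zone=RestrictionZone.STRICT)])
        with pytest.raises(RuntimeError):
            execute_clearcut(state.stands[1], state, HarvestParams(), rng)


def _state_landscape(cluster_specs):
    """Single-owner state landscape; cluster_specs = list of lists of
    (area, centroid) placed far apart."""
    stands = []
    sid = 0
    for spec in cluster_specs:
        for area, centroid in spec:
            stands.append(make_stand(sid, area=area, centroid=centroid,
                                     age=110.0))  # 20 y past maturity
            sid += 1
    units = [CadastralUnit(0, OwnerType.STATE, Intensity.NOT_APPLICABLE,
                           [s.id for s in stands])]
    for s in stands:
        s.unit_id = 0
    return make_state(stands, units=units)


class TestStateForestHarvest:
    def test_zero_quota_cuts_nothing(self, rng):
        state = _state_landscape([[(20_000.0, (0.0, 0.0))]])
        state_forest_harvest(state, HarvestParams(state_quota=0.0), rng)
        assert state.events == []

    def test_single_eligible_stand_cut(self, rng):
        state = _state_landscape([[(20_000.0, (0.0, 0.0))]])
        state_forest_harvest(state, HarvestParams(), rng)
        assert [e.stand_id for e in state.events] == [0]

    def test_largest_cluster_processed_first(self, rng):
        """Two clusters of summed areas 9 ha vs 4 ha: the 9 ha cluster goes
        first; a quota of 9 ha leaves the small cluster standing."""
        big = [(30_000.0, (0.0, 0.0)), (30_000.0, (500.0, 0.0)),
               (30_000.0, (0.0, 500.0))]
        small = [(20_000.0, (50_000.0, 0.0)), (20_000.0, (50_500.0, 0.0))]
        state = _state_landscape([big, small])
        params = HarvestParams(state_quota=90_000.0)
        state_forest_harvest(state, params, rng)
        cut = {e.stand_id for e in state.events}
        assert cut == {0, 1, 2}

    def test_hpi_needs_twenty_years_past_maturity(self, rng):
        state = _state_landscape([[(20_000.0, (0.0, 0.0))]])
        state.stands[0].hpi = True     # 20 y past maturity: exactly eligible
        state_forest_harvest(state, HarvestParams(), rng)
        assert len(state.events) == 1
        state2 = _state_landscape([[(20_000.0, (0.0, 0.0))]])
        state2.stands[0].hpi = True
        state2.stands[0].upper_layer[0].age = 105.0   # only 15 y past
        state_forest_harvest(state2, HarvestParams(), rng)
        assert state2.events == []


class TestRunYear:
    def test_zero_willingness_only_ages(self):
        state = make_state([make_stand(1, age=50.0), make_stand(2, age=40.0)])
        config = build_scenario("REAL")
        run_year(state, config, np.random.default_rng(0))
        assert [stand_age(state.stands[i]) for i in (1, 2)] == [51.0, 41.0]
        assert not [e for e in state.events if e.event == "clearcut"]

    def test_sequential_permitting_cuts_only_one_of_two_adjacent(self):
        """Two adjacent applying 4 ha stands under the 7 ha limit: cutting the
        first makes the second's 8 ha cluster illegal this year."""
        stands = [make_stand(1, area=40_000.0, age=200.0, neighbors={2}),
                  make_stand(2, area=40_000.0, age=200.0, neighbors={1})]
        state = make_state(stands)
        config = build_scenario("REAL", state_quota=0.0, regen_transition_prob=0.0)
        run_year(state, config, np.random.default_rng(1))
        cuts = [e for e in state.events if e.event == "clearcut"]
        assert len(cuts) == 1

    def test_same_seed_is_bit_identical(self):
        from standsim.synthgen import SynthParams, generate_landscape
        from standsim import apply_second_layer_rules, save_landscape_csv
        from standsim.core import stands_to_frame
        initial = generate_landscape(SynthParams(n_stands=300, seed=9))
        apply_second_layer_rules(initial)
        config = build_scenario("REAL")
        results = []
        for _ in range(2):
            res = run_scenario(initial, config, n_years=5, seeds=[4])
            results.append(res)
        a, b = results
        assert a.trajectories[4].equals(b.trajectories[4])
        assert stands_to_frame(a.final_states[4]).equals(
            stands_to_frame(b.final_states[4]))
        import dataclasses
        assert [dataclasses.astuple(e) for e in a.final_states[4].events] == \
            [dataclasses.astuple(e) for e in b.final_states[4].events]


class TestRunScenario:
    def test_one_year_equals_one_run_year(self):
        from standsim.synthgen import SynthParams, generate_landscape
        initial = generate_landscape(SynthParams(n_stands=120, seed=5))
        config = build_scenario("DEFa")
        res = run_scenario(initial, config, n_years=1, seeds=[3])
        assert len(res.trajectories[3]) == 1
        assert res.final_states[3].year == config.start_year + 1

    def test_distinct_seeds_distinct_valid_trajectories(self):
        from standsim import validate_landscape
        from standsim.synthgen import SynthParams, generate_landscape
        initial = generate_landscape(SynthParams(n_stands=200, seed=6))
        config = build_scenario("REAL")
        res = run_scenario(initial, config, n_years=4, seeds=[1, 2, 3])
        assert len(res.trajectories) == 3
        for st in res.final_states.values():
            assert validate_landscape(st) == []

    def test_unconstrained_time_to_cut_matches_analytic_cdf(self):
        """Single-stand intensive units with no neighbors and no state quota:
        the empirical 3-year cumulative cut fraction matches
        1 − Π(1 − min(1, p(1+t/20)))."""
        n = 2000
        stands = [make_stand(i, area=10_000.0, unit_id=i, age=90.0,
                             centroid=(100.0 * i, 0.0)) for i in range(n)]
        state = make_state(stands)
        config = build_scenario("REAL", state_quota=0.0,
                                simulated_extra_clearcuts=False)
        # intensity is re-drawn per replicate from the physical-owner prior;
        # force all-intensive via the prior
        config.p_int_physical = 1.0
        res = run_scenario(state, config, n_years=3, seeds=[8])
        events = res.final_states[8].events
        cut_fraction = len({e.stand_id for e in events
                            if e.event == "clearcut"}) / n
        analytic = cumulative_cut_probability(0.385, 3)
        assert cut_fraction == pytest.approx(analytic, abs=0.03)


class TestCumulativeCutProbability:
    def test_matches_explicit_product(self):
        p = 0.385
        explicit = 1.0 - (1 - p) * (1 - p * 1.05) * (1 - p * 1.10)
        assert cumulative_cut_probability(p, 3) == pytest.approx(explicit)

    def test_monotone_in_years(self):
        vals = [cumulative_cut_probability(0.055, n) for n in range(1, 40)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
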