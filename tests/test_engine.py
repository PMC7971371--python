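import math

import pytest

from chwplan import (
    Cadre,
    ConfigurationError,
    InfeasibilityError,
    Intervention,
    PopulationProfile,
    TargetSpec,
    TimePolicy,
    annual_demand_hours,
    available_service_hours,
    chws_needed,
    expected_coverage,
    rank_time_consumers,
    synthetic_scenario,
)
from chwplan.scenario import SetHeadcount, edit

from conftest import scenario_with_demands, single_demand_scenario


class TestAnnualDemandHours:
    def _profile(self, n=1000):
        return PopulationProfile(
            name="p", total_population=n, group_fractions={"g": 1.0}
        )

    def test_home_visit_arithmetic(self):
        iv = Intervention(
            name="v", cadre="c", mode="home-visit",
            target=TargetSpec(kind="stock-group", key="g"),
            contacts_per_year=4, minutes_per_contact=30, coverage_goal=0.9,
        )
        # 1000 x 0.9 x 4 x 0.5 h
        assert annual_demand_hours(iv, self._profile()) == pytest.approx(1800.0)

    def test_zero_coverage_goal_demands_nothing(self):
        iv = Intervention(
            name="v", cadre="c", mode="home-visit",
            target=TargetSpec(kind="stock-group", key="g"),
            contacts_per_year=4, minutes_per_contact=30, coverage_goal=0.0,
        )
        assert annual_demand_hours(iv, self._profile()) == 0.0

    def test_group_sessions_divide_by_group_size(self):
        iv = Intervention(
            name="club", cadre="c", mode="group-session",
            target=TargetSpec(kind="stock-group", key="g"),
            contacts_per_year=12, minutes_per_contact=60, group_size=20,
        )
        # (100 / 20) sessions x 12 rounds x 1 h
        assert annual_demand_hours(iv, self._profile(100)) == pytest.approx(60.0)

    def test_group_ceiling_rounds_sessions_up(self):
        iv = Intervention(
            name="club", cadre="c", mode="group-session",
            target=TargetSpec(kind="stock-group", key="g"),
            contacts_per_year=1, minutes_per_contact=60, group_size=30,
        )
        exact = annual_demand_hours(iv, self._profile(100))
        ceiled = annual_demand_hours(iv, self._profile(100), group_ceiling=True)
        assert exact == pytest.approx(100 / 30)
        assert ceiled == pytest.approx(4.0)

    def test_travel_surcharge_adds_to_contact_minutes(self):
        base = Intervention(
            name="v", cadre="c", mode="home-visit",
            target=TargetSpec(kind="stock-group", key="g"),
            contacts_per_year=1, minutes_per_contact=30,
        )
        tariffed = base.model_copy(update={"travel_minutes_per_contact": 30.0})
        assert annual_demand_hours(tariffed, self._profile()) == pytest.approx(
            2 * annual_demand_hours(base, self._profile())
        )

    def test_linearity_in_dose_parameters(self):
        p = self._profile()
        iv = Intervention(
            name="v", cadre="c", mode="home-visit",
            target=TargetSpec(kind="stock-group", key="g"),
            contacts_per_year=3, minutes_per_contact=20, coverage_goal=0.8,
        )
        base = annual_demand_hours(iv, p)
        for field in ("contacts_per_year", "minutes_per_contact"):
            doubled = iv.model_copy(update={field: getattr(iv, field) * 2})
            assert annual_demand_hours(doubled, p) == pytest.approx(2 * base)
        halved_goal = iv.model_copy(update={"coverage_goal": 0.4})
        assert annual_demand_hours(halved_goal, p) == pytest.approx(0.5 * base)


class TestAvailableServiceHours:
    def test_travel_share_scales_gross_time(self):
        # 18 h/week x 52 weeks, one third lost to travel
        policy = TimePolicy(
            hours_per_week=18, weeks_per_year=52, travel_share=1 / 3
        )
        assert available_service_hours(policy) == pytest.approx(624.0)

    def test_no_overheads_is_identity(self):
        policy = TimePolicy(hours_per_week=20, weeks_per_year=40)
        assert available_service_hours(policy) == pytest.approx(800.0)

    def test_training_consuming_gross_leaves_zero(self):
        policy = TimePolicy(
            hours_per_week=10, weeks_per_year=40, training_hours_per_year=400
        )
        assert available_service_hours(policy) == 0.0

    def test_campaign_block_subtracted_before_shares(self):
        policy = TimePolicy(
            hours_per_week=10, weeks_per_year=40,
            campaign_hours_per_year=100, travel_share=0.5,
        )
        assert available_service_hours(policy) == pytest.approx((400 - 100) * 0.5)

    def test_never_exceeds_gross_or_goes_negative(self):
        policy = TimePolicy(
            hours_per_week=10, weeks_per_year=10,
            training_hours_per_year=90, campaign_hours_per_year=90,
        )
        assert available_service_hours(policy) == 0.0


class TestChwsNeeded:
    def test_ceiling_of_demand_over_supply(self):
        s = scenario_with_demands({"a": 1000.0}, available_hours=624.0)
        assert chws_needed(s).per_cadre["chw"].required_chws == 2

    def test_zero_demand_needs_nobody(self):
        s = scenario_with_demands({"a": 0.0}, available_hours=624.0)
        assert chws_needed(s).per_cadre["chw"].required_chws == 0

    @pytest.mark.parametrize("k", [1, 2, 3, 7, 50])
    def test_exact_multiple_has_no_spurious_extra_worker(self, k):
        s = single_demand_scenario(600 * k, available_hours=600.0)
        assert chws_needed(s).per_cadre["chw"].required_chws == k

    def test_zero_available_hours_is_infeasible(self):
        s = scenario_with_demands({"a": 100.0}, available_hours=0.0)
        with pytest.raises(InfeasibilityError, match="chw"):
            chws_needed(s)

    def test_missing_time_policy_is_a_configuration_error(self):
        s = scenario_with_demands({"a": 100.0}, available_hours=1.0)
        bare = s.model_copy(
            update={"cadres": [Cadre(name="chw", headcount=5)]}
        )
        with pytest.raises(ConfigurationError, match="time policy"):
            chws_needed(bare)


class TestExpectedCoverage:
    def test_overloaded_cadre_achieves_supply_over_demand(self):
        # reported-aggregate shape: 1,300 h assigned vs 632 h available
        s = single_demand_scenario(1300, available_hours=632.0, headcount=1)
        cov = expected_coverage(s)
        share = cov.per_cadre["chw"].aggregate_achievable_share
        assert share == pytest.approx(632 / 1300, rel=1e-12)
        assert share < 0.5

    def test_slack_capacity_achieves_all_goals(self):
        s = scenario_with_demands({"a": 100.0, "b": 50.0}, 300.0, headcount=1)
        cov = expected_coverage(s)
        assert all(
            c.achievable_coverage == 1.0 for c in cov.per_intervention.values()
        )
        assert cov.per_cadre["chw"].aggregate_achievable_share == 1.0

    def test_proportional_allocation_equalizes_shares(self):
        s = scenario_with_demands({"a": 300.0, "b": 100.0}, 200.0, headcount=1)
        cov = expected_coverage(s)
        assert cov.per_intervention["a"].achievable_coverage == pytest.approx(0.5)
        assert cov.per_intervention["b"].achievable_coverage == pytest.approx(0.5)

    def test_priority_fill_serves_highest_priority_first(self):
        s = scenario_with_demands(
            {"a": 300.0, "b": 100.0}, 200.0, headcount=1,
            allocation="priority-fill", priorities={"b": 1, "a": 2},
        )
        cov = expected_coverage(s)
        assert cov.per_intervention["b"].achievable_coverage == pytest.approx(1.0)
        assert cov.per_intervention["a"].achievable_coverage == pytest.approx(100 / 300)

    def test_unset_headcount_with_demand_is_an_error(self):
        s = scenario_with_demands({"a": 100.0}, 200.0, headcount=None)
        with pytest.raises(ConfigurationError, match="headcount"):
            expected_coverage(s)

    def test_load_ratio_is_demand_over_supply(self):
        s = scenario_with_demands({"a": 300.0}, 100.0, headcount=2)
        cov = expected_coverage(s)
        assert cov.per_cadre["chw"].load_ratio == pytest.approx(1.5)


class TestRankTimeConsumers:
    def test_ties_broken_alphabetically(self):
        s = scenario_with_demands({"A": 10.0, "C": 30.0, "B": 30.0}, 100.0)
        order = [r.intervention for r in rank_time_consumers(s)]
        assert order == ["B", "C", "A"]

    def test_single_intervention_owns_all_cadre_time(self):
        s = scenario_with_demands({"only": 42.0}, 100.0)
        (row,) = rank_time_consumers(s)
        assert row.share_of_cadre_demand == pytest.approx(1.0)

    def test_matches_independent_sort_of_recomputed_demands(self):
        s = synthetic_scenario(13, 3, 20)
        expected = sorted(
            (
                (
                    -annual_demand_hours(iv, s.profile),
                    iv.name,
                )
                for iv in s.interventions
            )
        )
        got = [(-r.annual_hours, r.intervention) for r in rank_time_consumers(s)]
        assert [n for _, n in got] == [n for _, n in expected]

    def test_shares_sum_to_one_per_cadre(self):
        s = synthetic_scenario(29, 4, 25)
        by_cadre: dict[str, float] = {}
        for r in rank_time_consumers(s):
            by_cadre[r.cadre] = by_cadre.get(r.cadre, 0.0) + r.share_of_cadre_demand
        for total in by_cadre.values():
            assert total == pytest.approx(1.0, abs=1e-9)


class TestEngineProperties:
    """Structural properties on seeded synthetic scenarios."""

    SEEDS = range(25)

    def test_duality_of_staffing_and_coverage(self):
        """Staffing the workforce the staffing answer asks for achieves
        every goal; one fewer worker in any binding cadre breaks it."""
        for seed in self.SEEDS:
            s = synthetic_scenario(seed, n_cadres=3, n_interventions=9)
            need = chws_needed(s)
            staffed = edit(
                s,
                [SetHeadcount(c, r.required_chws) for c, r in need.per_cadre.items()],
            )
            cov = expected_coverage(staffed)
            assert all(
                c.aggregate_achievable_share == pytest.approx(1.0)
                for c in cov.per_cadre.values()
            )
            for cadre, r in need.per_cadre.items():
                if r.required_chws == 0:
                    continue
                reduced = edit(staffed, [SetHeadcount(cadre, r.required_chws - 1)])
                short = expected_coverage(reduced)
                assert short.per_cadre[cadre].aggregate_achievable_share < 1.0

    def test_share_monotone_in_headcount(self):
        for seed in (2, 9, 17):
            s = synthetic_scenario(seed, 2, 8)
            shares = []
            for h in (10, 100, 1000, 10_000):
                cov = expected_coverage(edit(s, [SetHeadcount("cadre-1", h)]))
                shares.append(cov.per_cadre["cadre-1"].aggregate_achievable_share)
            assert shares == sorted(shares)

    def test_share_antitone_in_demand(self):
        s = scenario_with_demands({"a": 100.0, "b": 50.0}, 60.0, headcount=1)
        base = expected_coverage(s).per_cadre["chw"].aggregate_achievable_share
        from chwplan.scenario import ScaleField

        heavier = edit(s, [ScaleField("intervention", "a", "contacts_per_year", 2.0)])
        assert (
            expected_coverage(heavier).per_cadre["chw"].aggregate_achievable_share
            <= base
        )

    @pytest.mark.parametrize("mode", ["proportional", "priority-fill"])
    def test_allocation_conserves_hours(self, mode):
        for seed in self.SEEDS:
            s = synthetic_scenario(seed, 3, 9, allocation_mode=mode)
            cov = expected_coverage(s)
            for cadre, load in cov.per_cadre.items():
                allocated = sum(
                    c.allocated_hours
                    for c in cov.per_intervention.values()
                    if c.cadre == cadre
                )
                expected_total = min(load.supply_hours, load.demand_hours)
                assert allocated == pytest.approx(expected_total, rel=1e-9, abs=1e-6)
            for c in cov.per_intervention.values():
                assert c.allocated_hours <= c.demand_hours * (1 + 1e-12)
                assert 0.0 <= c.achievable_coverage <= 1.0
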