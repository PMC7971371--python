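import math
import warnings

import pytest

from chwplan import (
    Cadre,
    ConfigurationWarning,
    Intervention,
    PopulationProfile,
    Scenario,
    TargetSpec,
    TimePolicy,
)


def scenario_with_demands(
    demands: dict[str, float],
    available_hours: float,
    headcount: int | None = None,
    allocation: str = "proportional",
    cadre: str = "chw",
    priorities: dict[str, int] | None = None,
) -> Scenario:
    """One-cadre scenario whose interventions demand the given annual
    hours (1 contact/year at 60 min => hours == target persons)."""
    total = max(1, int(math.ceil(sum(demands.values()))) + 1)
    profile = PopulationProfile(
        name="test",
        total_population=total,
        group_fractions={k: d / total for k, d in demands.items()},
    )
    ivs = [
        Intervention(
            name=k,
            cadre=cadre,
            mode="home-visit",
            target=TargetSpec(kind="stock-group", key=k),
            contacts_per_year=1.0,
            minutes_per_contact=60.0,
            priority=(priorities or {}).get(k),
        )
        for k in demands
    ]
    c = Cadre(
        name=cadre,
        headcount=headcount,
        time_policy=TimePolicy(hours_per_week=available_hours, weeks_per_year=1.0),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConfigurationWarning)
        return Scenario(
            name="test",
            profile=profile,
            cadres=[c],
            interventions=ivs,
            allocation_mode=allocation,
        )


def single_demand_scenario(
    demand_hours: int, available_hours: float, headcount: int | None = None
) -> Scenario:
    """Exact-arithmetic variant: integral demand enters as a whole
    population at fraction 1.0, so demand hours carry no float error."""
    assert demand_hours == int(demand_hours)
    profile = PopulationProfile(
        name="test",
        total_population=int(demand_hours),
        group_fractions={"g": 1.0},
    )
    iv = Intervention(
        name="iv",
        cadre="chw",
        mode="home-visit",
        target=TargetSpec(kind="stock-group", key="g"),
        contacts_per_year=1.0,
        minutes_per_contact=60.0,
    )
    c = Cadre(
        name="chw",
        headcount=headcount,
        time_policy=TimePolicy(hours_per_week=available_hours, weeks_per_year=1.0),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConfigurationWarning)
        return Scenario(name="test", profile=profile, cadres=[c], interventions=[iv])


@pytest.fixture
def simple_profile() -> PopulationProfile:
    return PopulationProfile(
        name="district",
        total_population=10_000,
        group_fractions={"under-5": 0.15, "women-15-49": 0.24},
        annual_event_rates={"live-births": 0.03},
    )
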