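"""Core time-use arithmetic.

Three quantities drive every answer the tool gives:

* **demand** — annual service hours an intervention requires at its
  coverage goal: ``target_population x coverage_goal x contacts_per_year
  x minutes_per_contact / 60`` (group sessions divide the contact count
  by the session size);
* **supply** — annual direct-service hours one CHW offers: gross annual
  hours, minus training and campaign block time, scaled by
  ``(1 - travel_share - admin_share)``;
* their ratio per cadre, which answers the two staffing questions —
  how many CHWs are needed (ceiling of demand over per-CHW supply), and
  what share of the assigned workload a fixed workforce can actually
  deliver (capped at 1).

When a cadre is overloaded, its supply is allocated across interventions
either *proportionally* (every intervention achieves the same fraction of
its goal) or by *priority-fill* (full demand in priority order until the
hours run out).  Both rules conserve hours: the sum of allocated hours
equals min(supply, demand).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from .catalog import Cadre, Intervention
from .demography import PopulationProfile, target_population
from .errors import ConfigurationError, InfeasibilityError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .scenario import Scenario

__all__ = [
    "TimeDemand",
    "CadreStaffing",
    "StaffingResult",
    "InterventionCoverage",
    "CadreLoad",
    "CoverageResult",
    "RankedActivity",
    "annual_demand_hours",
    "available_service_hours",
    "cadre_demand_hours",
    "time_demands",
    "chws_needed",
    "expected_coverage",
    "rank_time_consumers",
]

# Relative slack when taking the ceiling of demand/supply, so that a
# demand of exactly k CHW-years never rounds up to k+1 through float
# noise accumulated while summing intervention demands.
_CEIL_RTOL = 1e-9


# ---------------------------------------------------------------------------
# elementary quantities


def annual_demand_hours(
    intervention: Intervention,
    profile: PopulationProfile,
    *,
    group_ceiling: bool = False,
) -> float:
    """Annual service hours one intervention demands at its coverage goal.

    For individual-contact modes this is ``target x goal x contacts x
    minutes / 60``; minutes include any per-visit travel surcharge.  For
    group sessions the number of sessions is ``target x goal /
    group_size`` per contact round — exact division by default, or
    rounded up per round when ``group_ceiling`` is set (the correction is
    negligible at national scale but available for small catchments).
    """
    n = target_population(profile, intervention.target) * intervention.coverage_goal
    minutes = intervention.minutes_per_contact + intervention.travel_minutes_per_contact
    if intervention.mode == "group-session":
        sessions_per_round = n / intervention.group_size
        if group_ceiling:
            sessions_per_round = math.ceil(sessions_per_round - _CEIL_RTOL)
        return sessions_per_round * intervention.contacts_per_year * minutes / 60.0
    return n * intervention.contacts_per_year * minutes / 60.0


def available_service_hours(policy) -> float:
    """Annual direct-service hours one CHW offers under a time policy.

    ``(gross - training - campaign block) x (1 - travel_share -
    admin_share)``, floored at zero.  Validation on the policy already
    guarantees the shares sum below 1 and training fits in the gross
    budget.
    """
    if policy.travel_share + policy.admin_share >= 1.0:
        raise ConfigurationError(
            "travel and administration shares consume the entire working time"
        )
    gross = policy.hours_per_week * policy.weeks_per_year
    net = gross - policy.training_hours_per_year - policy.campaign_hours_per_year
    return max(0.0, net) * (1.0 - policy.travel_share - policy.admin_share)


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class TimeDemand:
    """Annual hours one intervention demands, whole-catchment and per CHW."""

    intervention: str
    cadre: str
    annual_hours: float
    hours_per_chw: float | None  # None when the cadre headcount is unset


@dataclass(frozen=True)
class CadreStaffing:
    """Staffing answer for one cadre."""

    required_chws: int
    available_hours_per_chw: float
    total_demand_hours: float


@dataclass(frozen=True)
class StaffingResult:
    """Per-cadre workforce required to meet every coverage goal."""

    per_cadre: dict[str, CadreStaffing]

    @property
    def total_required(self) -> int:
        return sum(c.required_chws for c in self.per_cadre.values())


@dataclass(frozen=True)
class InterventionCoverage:
    """Achievable share of one intervention's coverage goal."""

    cadre: str
    demand_hours: float
    allocated_hours: float
    achievable_coverage: float  # fraction of the goal-scaled target, in [0, 1]


@dataclass(frozen=True)
class CadreLoad:
    """Demand/supply balance of one cadre with a fixed headcount."""

    supply_hours: float
    demand_hours: float
    load_ratio: float  # demand / supply; inf when supply is 0 and demand > 0
    aggregate_achievable_share: float  # min(1, supply / demand)


@dataclass(frozen=True)
class CoverageResult:
    """Expected-coverage answer for a fixed workforce."""

    per_intervention: dict[str, InterventionCoverage]
    per_cadre: dict[str, CadreLoad]
    allocation_mode: str


@dataclass(frozen=True)
class RankedActivity:
    """One row of the time-consumption ranking."""

    intervention: str
    cadre: str
    annual_hours: float
    share_of_cadre_demand: float


# ---------------------------------------------------------------------------
# scenario-level operations


def _demand_by_intervention(scenario: "Scenario") -> dict[str, float]:
    return {
        iv.name: annual_demand_hours(
            iv, scenario.profile, group_ceiling=scenario.group_ceiling
        )
        for iv in scenario.interventions
    }


def cadre_demand_hours(scenario: "Scenario") -> dict[str, float]:
    """Total annual demand hours per cadre (cadres with no interventions
    report 0)."""
    totals = {c.name: 0.0 for c in scenario.cadres}
    for iv in scenario.interventions:
        totals[iv.cadre] += annual_demand_hours(
            iv, scenario.profile, group_ceiling=scenario.group_ceiling
        )
    return totals


def _policy_hours(cadre: Cadre, *, needed_for: str) -> float:
    if cadre.time_policy is None:
        raise ConfigurationError(
            f"cadre {cadre.name!r} carries service demand but has no time policy; "
            f"one is required to compute {needed_for}"
        )
    return available_service_hours(cadre.time_policy)


def time_demands(scenario: "Scenario") -> list[TimeDemand]:
    """Per-intervention demand hours, with per-CHW hours where the
    assigned cadre's headcount is set and positive."""
    heads = {c.name: c.headcount for c in scenario.cadres}
    out = []
    for iv in scenario.interventions:
        hours = annual_demand_hours(
            iv, scenario.profile, group_ceiling=scenario.group_ceiling
        )
        h = heads.get(iv.cadre)
        out.append(
            TimeDemand(
                intervention=iv.name,
                cadre=iv.cadre,
                annual_hours=hours,
                hours_per_chw=hours / h if h else None,
            )
        )
    return out


def _ceil_with_slack(ratio: float) -> int:
    return math.ceil(ratio - _CEIL_RTOL * max(1.0, abs(ratio)))


def chws_needed(scenario: "Scenario") -> StaffingResult:
    """Workforce needed per cadre to achieve every coverage goal.

    Per cadre: ``ceil(total demand hours / available hours per CHW)``;
    zero when the cadre carries no demand.  A demand of exactly *k*
    CHW-years yields exactly *k* workers.

    Raises
    ------
    InfeasibilityError
        If a cadre has positive demand but zero available service hours.
    """
    demand = cadre_demand_hours(scenario)
    result: dict[str, CadreStaffing] = {}
    for cadre in scenario.cadres:
        d = demand[cadre.name]
        if d <= 0.0:
            avail = (
                available_service_hours(cadre.time_policy)
                if cadre.time_policy is not None
                else 0.0
            )
            result[cadre.name] = CadreStaffing(0, avail, d)
            continue
        avail = _policy_hours(cadre, needed_for="required workforce")
        if avail <= 0.0:
            raise InfeasibilityError(
                f"cadre {cadre.name!r} has {d:.1f} demand hours but zero available "
                f"service hours per CHW; no workforce size can meet the goal"
            )
        result[cadre.name] = CadreStaffing(max(1, _ceil_with_slack(d / avail)), avail, d)
    return StaffingResult(per_cadre=result)


def _effective_priority(scenario: "Scenario") -> dict[str, tuple[int, str]]:
    # explicit priority wins; unset priorities default to catalog order
    return {
        iv.name: (iv.priority if iv.priority is not None else idx, iv.name)
        for idx, iv in enumerate(scenario.interventions)
    }


def expected_coverage(scenario: "Scenario") -> CoverageResult:
    """Coverage achievable by the fixed workforce of each cadre.

    Supply per cadre is ``headcount x available service hours``.  When
    supply covers demand every intervention achieves its full goal;
    otherwise supply is allocated per the scenario's allocation mode
    (proportional or priority-fill).  The aggregate achievable share is
    ``min(1, supply / demand)`` in both modes.

    Raises
    ------
    ConfigurationError
        If a cadre with positive demand has no headcount set.
    """
    iv_demand = _demand_by_intervention(scenario)
    prio = _effective_priority(scenario)
    per_iv: dict[str, InterventionCoverage] = {}
    per_cadre: dict[str, CadreLoad] = {}

    for cadre in scenario.cadres:
        ivs = [iv for iv in scenario.interventions if iv.cadre == cadre.name]
        d_total = sum(iv_demand[iv.name] for iv in ivs)
        if d_total <= 0.0:
            supply = (
                (cadre.headcount or 0)
                * available_service_hours(cadre.time_policy)
                if cadre.time_policy is not None and cadre.headcount is not None
                else 0.0
            )
            per_cadre[cadre.name] = CadreLoad(supply, 0.0, 0.0, 1.0)
            for iv in ivs:
                per_iv[iv.name] = InterventionCoverage(cadre.name, 0.0, 0.0, 1.0)
            continue

        if cadre.headcount is None:
            raise ConfigurationError(
                f"cadre {cadre.name!r} carries {d_total:.1f} demand hours but its "
                f"headcount is unset; set one to compute expected coverage"
            )
        supply = cadre.headcount * _policy_hours(cadre, needed_for="expected coverage")
        if supply <= 0.0:
            share, load = 0.0, math.inf
        else:
            share = min(1.0, supply / d_total)
            load = d_total / supply
        per_cadre[cadre.name] = CadreLoad(supply, d_total, load, share)

        if scenario.allocation_mode == "priority-fill":
            remaining = min(supply, d_total)
            for iv in sorted(ivs, key=lambda iv: prio[iv.name]):
                d = iv_demand[iv.name]
                got = min(remaining, d)
                remaining -= got
                per_iv[iv.name] = InterventionCoverage(
                    cadre.name, d, got, got / d if d > 0 else 1.0
                )
        else:  # proportional
            for iv in ivs:
                d = iv_demand[iv.name]
                per_iv[iv.name] = InterventionCoverage(
                    cadre.name, d, d * share, share if d > 0 else 1.0
                )

    return CoverageResult(
        per_intervention=per_iv,
        per_cadre=per_cadre,
        allocation_mode=scenario.allocation_mode,
    )


def rank_time_consumers(scenario: "Scenario") -> list[RankedActivity]:
    """Interventions ordered from most to least time-consuming.

    The share column expresses each intervention's annual hours as a
    fraction of its own cadre's total demand (shares sum to 1 per cadre).
    Ties in hours are broken alphabetically by intervention name.
    """
    iv_demand = _demand_by_intervention(scenario)
    cadre_totals = cadre_demand_hours(scenario)
    rows = [
        RankedActivity(
            intervention=iv.name,
            cadre=iv.cadre,
            annual_hours=iv_demand[iv.name],
            share_of_cadre_demand=(
                iv_demand[iv.name] / cadre_totals[iv.cadre]
                if cadre_totals[iv.cadre] > 0
                else 0.0
            ),
        )
        for iv in scenario.interventions
    ]
    return sorted(rows, key=lambda r: (-r.annual_hours, r.intervention))
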