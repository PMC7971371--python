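"""Demographic target-population sizing.

A :class:`PopulationProfile` describes one planning population: its total
head count, the fractions of that total belonging to standing demographic
groups (children under 5, women of reproductive age, ...), and the annual
rates of demographic events (live births, pregnancies) expressed per
person per year.  A :class:`TargetSpec` then selects one group or event
stream and scales it down to the people a community health worker (CHW)
program actually has to reach: the in-need fraction applies the local
epidemiology (for instance malaria incidence scaling case-management
caseload), and the facility share removes the portion expected to be
served at health facilities rather than in the community.

All counts are kept as real numbers; rounding to whole persons happens
only when reports are written, so that rounding error never compounds
across an intervention package.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, ConfigDict, NonNegativeInt, field_validator, model_validator

from .errors import ConfigurationError

__all__ = [
    "PopulationProfile",
    "TargetSpec",
    "target_population",
    "build_profile_from_counts",
]


class PopulationProfile(BaseModel):
    """A planning population and the indicators needed to size target groups.

    Parameters
    ----------
    name:
        Free-form label (country, region, or typology name).
    total_population:
        Total persons in the catchment, a non-negative integer.
    group_fractions:
        Map from target-group key to the fraction of the total population
        in that group.  Each fraction lies in [0, 1].
    annual_event_rates:
        Map from event key to events per person per year (e.g. a crude
        birth rate of 31/1000 is entered as 0.031).  Rates are
        non-negative and may exceed 1 for high-frequency events.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    total_population: NonNegativeInt
    group_fractions: dict[str, float] = {}
    annual_event_rates: dict[str, float] = {}

    @model_validator(mode="before")
    @classmethod
    def _accept_group_counts(cls, data):
        # census tables publish absolute counts; accept a group_counts
        # mapping and convert to fractions on load
        if isinstance(data, dict) and "group_counts" in data:
            data = dict(data)
            counts = data.pop("group_counts") or {}
            total = data.get("total_population") or 0
            fractions = dict(data.get("group_fractions") or {})
            for key, count in counts.items():
                if total <= 0:
                    raise ValueError(
                        f"group_counts given ({key!r}) but total_population is {total}"
                    )
                if count > total:
                    raise ValueError(
                        f"group count {key!r} ({count}) exceeds total population ({total})"
                    )
                fractions[key] = count / total
            data["group_fractions"] = fractions
        return data

    @field_validator("group_fractions")
    @classmethod
    def _fractions_in_unit_interval(cls, v: dict[str, float]) -> dict[str, float]:
        for key, frac in v.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(
                    f"group fraction {key!r} is {frac}; fractions must lie in [0, 1]"
                )
        return v

    @field_validator("annual_event_rates")
    @classmethod
    def _rates_non_negative(cls, v: dict[str, float]) -> dict[str, float]:
        for key, rate in v.items():
            if rate < 0:
                raise ValueError(f"event rate {key!r} is {rate}; rates must be >= 0")
        return v


class TargetSpec(BaseModel):
    """Selects and scales the population an intervention must reach.

    ``kind`` distinguishes standing stock groups (sized by a fraction of
    the total population) from annual event streams (sized by a per-person
    annual rate).  ``in_need_fraction`` restricts the group to those who
    actually need the service; ``facility_share`` removes the portion
    expected to be served at facilities, leaving the community "last mile"
    to the CHW program.
    """

    model_config = ConfigDict(frozen=True)

    kind: Literal["stock-group", "annual-event"]
    key: str
    in_need_fraction: float = 1.0
    facility_share: float = 0.0

    @field_validator("in_need_fraction", "facility_share")
    @classmethod
    def _unit_interval(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"value {v} must lie in [0, 1]")
        return v


def target_population(profile: PopulationProfile, spec: TargetSpec) -> float:
    """Annual persons (stock groups) or events (event streams) a CHW
    program must serve for one intervention.

    Returns ``total_population x fraction_or_rate x in_need_fraction x
    (1 - facility_share)`` as a non-negative real number.

    Raises
    ------
    ConfigurationError
        If ``spec.key`` is absent from the corresponding profile map.
    """
    if spec.kind == "stock-group":
        table = profile.group_fractions
        what = "group"
    else:
        table = profile.annual_event_rates
        what = "event"
    if spec.key not in table:
        known = ", ".join(sorted(table)) or "(none defined)"
        raise ConfigurationError(
            f"unknown {what} key {spec.key!r} in profile {profile.name!r}; "
            f"known {what} keys: {known}"
        )
    return (
        profile.total_population
        * table[spec.key]
        * spec.in_need_fraction
        * (1.0 - spec.facility_share)
    )


def build_profile_from_counts(
    name: str,
    total: int,
    group_counts: dict[str, float] | None = None,
    annual_event_rates: dict[str, float] | None = None,
) -> PopulationProfile:
    """Build a profile from absolute group head counts.

    Census tables publish group sizes as counts, not fractions; this
    converts each count to ``count / total`` so that
    :func:`target_population` (with in-need 1 and facility share 0)
    reproduces the entered count to within one part in 1e9.

    Raises
    ------
    ValueError
        If ``total <= 0`` or any count exceeds the total.
    """
    if total <= 0:
        raise ValueError(f"total population must be positive, got {total}")
    fractions: dict[str, float] = {}
    for key, count in (group_counts or {}).items():
        if count < 0:
            raise ValueError(f"group count {key!r} is negative: {count}")
        if count > total:
            raise ValueError(
                f"group count {key!r} ({count}) exceeds total population ({total})"
            )
        fractions[key] = count / total
    return PopulationProfile(
        name=name,
        total_population=total,
        group_fractions=fractions,
        annual_event_rates=dict(annual_event_rates or {}),
    )
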