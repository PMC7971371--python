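"""Cadres, time policies, and intervention catalogs.

A CHW program is described by up to six *cadres* — categories of worker
with a defined scope (Rwanda's ASMs, binomes and health-promotion CHWs;
Zanzibar's community health volunteers).  Each cadre has a
:class:`TimePolicy` converting its weekly commitment into annual service
hours, and an intervention catalog assigns services to cadres with a
delivery mode, a target population, a dose (contacts per year x minutes
per contact) and a coverage goal.

Travel is modeled as a share of working time (the convention in volunteer
programs where travel absorbs a fixed portion of every working week, e.g.
one third); catalogs that prefer a per-visit surcharge can instead set
``travel_minutes_per_contact`` on individual interventions.  Campaigns
and other ad hoc block activities are entered as fixed annual hours on
the time policy rather than per-target contacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .demography import PopulationProfile, TargetSpec
from .errors import ConfigurationError, ConfigurationWarning

__all__ = [
    "TimePolicy",
    "Cadre",
    "Intervention",
    "MAX_CONVENTIONAL_CADRES",
    "validate_package",
    "ParameterRanges",
    "synthesize_package",
]

#: Planning convention: the tool is designed around at most six cadres.
#: More are accepted with a warning.
MAX_CONVENTIONAL_CADRES = 6

#: Default working year. A full-year-minus-leave convention; overridable
#: per policy.
DEFAULT_WEEKS_PER_YEAR = 48.0

Mode = Literal["home-visit", "group-session", "campaign", "referral-accompaniment"]


class TimePolicy(BaseModel):
    """Annual time budget of one CHW.

    Gross hours are ``hours_per_week x weeks_per_year``.  Training and
    campaign block hours are subtracted first; the travel and
    administration shares then scale what remains down to direct service
    time.  ``weeks_per_year`` defaults to 48 (a year minus leave); set it
    explicitly where a program specifies otherwise.
    """

    model_config = ConfigDict(frozen=True)

    hours_per_week: float
    weeks_per_year: float = DEFAULT_WEEKS_PER_YEAR
    travel_share: float = 0.0
    admin_share: float = 0.0
    training_hours_per_year: float = 0.0
    campaign_hours_per_year: float = 0.0

    @field_validator(
        "hours_per_week",
        "weeks_per_year",
        "training_hours_per_year",
        "campaign_hours_per_year",
    )
    @classmethod
    def _non_negative(cls, v: float) -> float:
        if v < 0:
            raise ValueError(f"value {v} must be >= 0")
        return v

    @field_validator("travel_share", "admin_share")
    @classmethod
    def _share_in_range(cls, v: float) -> float:
        if not 0.0 <= v < 1.0:
            raise ValueError(f"share {v} must lie in [0, 1)")
        return v

    @model_validator(mode="after")
    def _consistent(self) -> "TimePolicy":
        if self.travel_share + self.admin_share >= 1.0:
            raise ValueError(
                f"travel_share ({self.travel_share}) + admin_share "
                f"({self.admin_share}) must sum below 1"
            )
        gross = self.hours_per_week * self.weeks_per_year
        if self.training_hours_per_year > gross + 1e-9:
            raise ValueError(
                f"training_hours_per_year ({self.training_hours_per_year}) exceeds "
                f"gross annual hours ({gross})"
            )
        return self

    @property
    def gross_hours_per_year(self) -> float:
        return self.hours_per_week * self.weeks_per_year


class Cadre(BaseModel):
    """A CHW type: a name, an optional headcount, and a time policy.

    ``headcount`` may be left unset when the staffing question is "how
    many are needed" rather than "what can this many achieve".
    ``time_policy`` may be left unset for record-keeping cadres whose
    policies are unknown; any cadre that actually carries service demand
    must have one.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    headcount: Optional[int] = None
    time_policy: Optional[TimePolicy] = None

    @field_validator("headcount")
    @classmethod
    def _headcount_non_negative(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and v < 0:
            raise ValueError(f"headcount {v} must be >= 0")
        return v


class Intervention(BaseModel):
    """One service delivered by a cadre.

    The dose is ``contacts_per_year`` (contacts per target individual per
    year) at ``minutes_per_contact`` each.  ``coverage_goal`` is the
    policy-set fraction of the in-need population intended to be reached.
    Group sessions additionally require ``group_size``, the number of
    participants per session; the per-contact minutes then apply per
    session, not per participant.  ``priority`` (lower = more important)
    drives priority-fill allocation and defaults to catalog order.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    cadre: str
    mode: Mode
    target: TargetSpec
    contacts_per_year: float
    minutes_per_contact: float
    group_size: Optional[float] = None
    coverage_goal: float = 1.0
    priority: Optional[int] = None
    travel_minutes_per_contact: float = 0.0

    @field_validator("contacts_per_year", "minutes_per_contact", "travel_minutes_per_contact")
    @classmethod
    def _non_negative(cls, v: float) -> float:
        if v < 0:
            raise ValueError(f"value {v} must be >= 0")
        return v

    @field_validator("coverage_goal")
    @classmethod
    def _goal_in_unit_interval(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"coverage_goal {v} must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _group_size_iff_group_session(self) -> "Intervention":
        if self.mode == "group-session":
            if self.group_size is None:
                raise ValueError(f"intervention {self.name!r}: group-session mode requires group_size")
            if self.group_size < 1:
                raise ValueError(f"intervention {self.name!r}: group_size must be >= 1")
        elif self.group_size is not None:
            raise ValueError(
                f"intervention {self.name!r}: group_size is only meaningful for "
                f"group-session mode (mode is {self.mode!r})"
            )
        return self


def validate_package(
    cadres: list[Cadre], interventions: list[Intervention]
) -> tuple[list[Cadre], list[Intervention]]:
    """Cross-validate a cadre list against its intervention catalog.

    Checks that names are unique and every intervention references an
    existing cadre.  More than six cadres, or an empty catalog, is
    unusual enough to warn about but not an error.  Idempotent: running
    it on its own output changes nothing.

    Returns the (unchanged) lists for fluent use.

    Raises
    ------
    ConfigurationError
        Listing every dangling cadre reference or duplicated name found.
    """
    problems: list[str] = []

    cadre_names = [c.name for c in cadres]
    dup_cadres = sorted({n for n in cadre_names if cadre_names.count(n) > 1})
    if dup_cadres:
        problems.append(f"duplicate cadre names: {', '.join(dup_cadres)}")

    iv_names = [iv.name for iv in interventions]
    dup_ivs = sorted({n for n in iv_names if iv_names.count(n) > 1})
    if dup_ivs:
        problems.append(f"duplicate intervention names: {', '.join(dup_ivs)}")

    known = set(cadre_names)
    dangling = sorted({iv.cadre for iv in interventions if iv.cadre not in known})
    if dangling:
        problems.append(
            f"interventions reference unknown cadres: {', '.join(dangling)} "
            f"(known cadres: {', '.join(sorted(known)) or 'none'})"
        )

    if problems:
        raise ConfigurationError("invalid package: " + "; ".join(problems))

    if len(cadres) > MAX_CONVENTIONAL_CADRES:
        warnings.warn(
            f"{len(cadres)} cadres defined; the planning convention is at most "
            f"{MAX_CONVENTIONAL_CADRES}",
            ConfigurationWarning,
            stacklevel=2,
        )
    if not interventions:
        warnings.warn(
            "intervention catalog is empty; all results will be vacuous",
            ConfigurationWarning,
            stacklevel=2,
        )
    return cadres, interventions


@dataclass(frozen=True)
class ParameterRanges:
    """Uniform sampling ranges for the synthetic-scenario generator.

    Defaults describe a realistic national volunteer program: part-time
    workers (10-30 h/week over 44-50 weeks), travel absorbing up to 40%
    of time and administration up to 20%, catchments of fifty thousand to
    three million people, and interventions dosed between 1 and 12 annual
    contacts of 10-60 minutes at coverage goals of 50-100%.
    """

    total_population: tuple[int, int] = (50_000, 3_000_000)
    group_fraction: tuple[float, float] = (0.02, 0.25)
    event_rate: tuple[float, float] = (0.01, 0.05)
    n_groups: int = 3
    n_events: int = 2
    hours_per_week: tuple[float, float] = (10.0, 30.0)
    weeks_per_year: tuple[float, float] = (44.0, 50.0)
    travel_share: tuple[float, float] = (0.0, 0.4)
    admin_share: tuple[float, float] = (0.0, 0.2)
    training_hours: tuple[float, float] = (0.0, 40.0)
    campaign_hours: tuple[float, float] = (0.0, 40.0)
    headcount: tuple[int, int] = (20, 5_000)
    contacts_per_year: tuple[float, float] = (1.0, 12.0)
    minutes_per_contact: tuple[float, float] = (10.0, 60.0)
    group_size: tuple[int, int] = (5, 30)
    coverage_goal: tuple[float, float] = (0.5, 1.0)
    in_need_fraction: tuple[float, float] = (0.05, 1.0)
    facility_share: tuple[float, float] = (0.0, 0.6)
    modes: tuple[Mode, ...] = (
        "home-visit",
        "home-visit",
        "group-session",
        "referral-accompaniment",
        "campaign",
    )

    def __post_init__(self) -> None:
        for name in (
            "total_population", "group_fraction", "event_rate", "hours_per_week",
            "weeks_per_year", "travel_share", "admin_share", "training_hours",
            "campaign_hours", "headcount", "contacts_per_year",
            "minutes_per_contact", "group_size", "coverage_goal",
            "in_need_fraction", "facility_share",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"range {name} is not well-ordered: ({lo}, {hi})")


def synthesize_package(
    seed: int,
    n_cadres: int = 3,
    n_interventions: int = 10,
    ranges: ParameterRanges | None = None,
) -> tuple[PopulationProfile, list[Cadre], list[Intervention]]:
    """Generate a random but valid (profile, cadres, interventions) triple.

    Deterministic for a fixed seed; every invariant of the domain types
    holds by construction and the output always passes
    :func:`validate_package`.  Intended for property tests and for the
    ``synth`` CLI command.
    """
    if n_cadres < 1:
        raise ValueError("n_cadres must be >= 1")
    r = ranges or ParameterRanges()
    rng = np.random.default_rng(seed)

    groups = {
        f"group-{i + 1}": float(rng.uniform(*r.group_fraction)) for i in range(r.n_groups)
    }
    events = {
        f"event-{i + 1}": float(rng.uniform(*r.event_rate)) for i in range(r.n_events)
    }
    profile = PopulationProfile(
        name=f"synthetic-{seed}",
        total_population=int(rng.integers(r.total_population[0], r.total_population[1] + 1)),
        group_fractions=groups,
        annual_event_rates=events,
    )

    cadres: list[Cadre] = []
    for i in range(n_cadres):
        while True:
            travel = float(rng.uniform(*r.travel_share))
            admin = float(rng.uniform(*r.admin_share))
            if travel + admin < 0.95:
                break
        hours = float(rng.uniform(*r.hours_per_week))
        weeks = float(rng.uniform(*r.weeks_per_year))
        gross = hours * weeks
        training = float(rng.uniform(*r.training_hours))
        campaign = float(rng.uniform(*r.campaign_hours))
        # keep a strictly positive service budget so staffing questions
        # stay feasible by construction
        overhead = training + campaign
        if overhead >= 0.5 * gross:
            training, campaign = 0.25 * gross * training / overhead, 0.25 * gross * campaign / overhead
        cadres.append(
            Cadre(
                name=f"cadre-{i + 1}",
                headcount=int(rng.integers(r.headcount[0], r.headcount[1] + 1)),
                time_policy=TimePolicy(
                    hours_per_week=hours,
                    weeks_per_year=weeks,
                    travel_share=travel,
                    admin_share=admin,
                    training_hours_per_year=training,
                    campaign_hours_per_year=campaign,
                ),
            )
        )

    target_keys = [("stock-group", k) for k in groups] + [("annual-event", k) for k in events]
    interventions: list[Intervention] = []
    for i in range(n_interventions):
        kind, key = target_keys[int(rng.integers(0, len(target_keys)))]
        mode = r.modes[int(rng.integers(0, len(r.modes)))]
        interventions.append(
            Intervention(
                name=f"iv-{i + 1:02d}",
                cadre=cadres[int(rng.integers(0, n_cadres))].name,
                mode=mode,
                target=TargetSpec(
                    kind=kind,
                    key=key,
                    in_need_fraction=float(rng.uniform(*r.in_need_fraction)),
                    facility_share=float(rng.uniform(*r.facility_share)),
                ),
                contacts_per_year=float(rng.uniform(*r.contacts_per_year)),
                minutes_per_contact=float(rng.uniform(*r.minutes_per_contact)),
                group_size=(
                    float(rng.integers(r.group_size[0], r.group_size[1] + 1))
                    if mode == "group-session"
                    else None
                ),
                coverage_goal=float(rng.uniform(*r.coverage_goal)),
                priority=i + 1,
            )
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConfigurationWarning)
        validate_package(cadres, interventions)
    return profile, cadres, interventions
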