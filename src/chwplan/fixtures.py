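"""Built-in planning cases with published reference values.

Four cases ship with the package, each a YAML file under ``data/``:

* ``rwanda-eastern`` / ``rwanda-northwest`` — the two rural Rwandan
  regional typologies (higher- and lower-malaria), with 2012-census
  population figures and the headcounts of the three national cadres
  (ASMs, binomes, health-promotion CHWs);
* ``rwanda-national`` — the national workforce totals and 2019
  population estimate;
* ``zanzibar`` — the Zanzibar volunteer (CHV) program: population,
  under-5 count, the 2,200-CHV workforce and its 18 h/week time policy
  with travel absorbing one third of working time.

Each case carries ``known_values``: labelled quantities reported by the
programs themselves (population-per-CHW ratios, workforce totals, the
per-worker annual demand and supply hours of the overloaded
health-promotion cadre).  Tests and the acceptance script recompute
these through the engine and check them against the fixture labels.

Intervention-level catalogs for these programs were never published, so
the fixtures deliberately contain no intervention lists; where a case's
published result is a per-CHW aggregate (hours needed vs available),
:func:`aggregate_workload_scenario` builds a clearly-labelled synthetic
scenario reproducing that workload so the engine — not a lookup — does
the arithmetic.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .catalog import Cadre, Intervention, TimePolicy
from .demography import PopulationProfile, TargetSpec
from .errors import ConfigurationError, ConfigurationWarning, ParseError
from .scenario import Scenario

__all__ = [
    "KnownValue",
    "FixtureCase",
    "FIXTURE_NAMES",
    "load_fixture",
    "population_per_chw",
    "aggregate_workload_scenario",
]

_DATA_DIR = Path(__file__).parent / "data"

FIXTURE_NAMES = (
    "rwanda-eastern",
    "rwanda-northwest",
    "rwanda-national",
    "zanzibar",
)


class KnownValue(BaseModel):
    """A reported quantity attached to a fixture, with a provenance note."""

    model_config = ConfigDict(frozen=True)

    value: float
    note: str = ""


class FixtureCase(BaseModel):
    """A named planning case: profile, cadres, and reported values."""

    model_config = ConfigDict(frozen=True)

    name: str
    profile: PopulationProfile
    cadres: list[Cadre] = []
    known_values: dict[str, KnownValue] = {}

    @property
    def total_headcount(self) -> int:
        return sum(c.headcount or 0 for c in self.cadres)

    def to_scenario(
        self,
        interventions: list[Intervention] | None = None,
        allocation_mode: str = "proportional",
    ) -> Scenario:
        """Wrap the case in a scenario, optionally attaching a catalog."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConfigurationWarning)
            return Scenario(
                name=self.name,
                profile=self.profile,
                cadres=self.cadres,
                interventions=interventions or [],
                allocation_mode=allocation_mode,
            )


def load_fixture(name_or_path: str | Path) -> FixtureCase:
    """Load a built-in fixture by name, or any fixture file by path.

    Raises
    ------
    ConfigurationError
        For an unrecognized name, listing the available fixtures.
    """
    path = Path(name_or_path)
    if str(name_or_path) in FIXTURE_NAMES:
        path = _DATA_DIR / f"{name_or_path}.yaml"
    elif not path.exists():
        raise ConfigurationError(
            f"unknown fixture {name_or_path!r}; available fixtures: "
            + ", ".join(FIXTURE_NAMES)
        )
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"fixture file {path} is not valid YAML: {exc}") from exc
    return FixtureCase.model_validate(data)


def population_per_chw(case: FixtureCase) -> int:
    """Persons served per CHW across all cadres, rounded half-up.

    This is the planning ratio program tables report alongside cadre
    counts (total population divided by the combined workforce).

    Raises
    ------
    ConfigurationError
        If the case has no workforce to divide by.
    """
    heads = case.total_headcount
    if heads <= 0:
        raise ConfigurationError(
            f"fixture {case.name!r} has zero total headcount; "
            f"population-per-CHW is undefined"
        )
    return int(math.floor(case.profile.total_population / heads + 0.5))


def aggregate_workload_scenario(
    demand_hours_per_chw: float,
    available_hours_per_chw: float,
    headcount: int = 1,
    *,
    cadre_name: str = "cadre",
    name: str = "aggregate-workload",
) -> Scenario:
    """Synthetic single-cadre scenario reproducing reported per-CHW
    aggregates.

    Some programs publish only the bottom line of their time-use model:
    annual hours of assigned work per CHW versus annual hours available.
    This constructs a minimal scenario — one cadre, one stand-in
    intervention whose demand equals ``headcount x demand_hours_per_chw``
    and a time policy supplying exactly ``available_hours_per_chw`` — so
    the engine can recompute the achievable-workload share from those
    aggregates.  The scenario is synthetic: its intervention is a
    workload stand-in, not a real service.
    """
    if demand_hours_per_chw < 0 or available_hours_per_chw <= 0:
        raise ConfigurationError(
            "demand hours must be >= 0 and available hours > 0"
        )
    total_demand = demand_hours_per_chw * headcount
    # one person-contact-hour per demand hour: total x 1 contact x 60 min
    total_pop = max(1, math.ceil(total_demand))
    fraction = total_demand / total_pop if total_pop else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConfigurationWarning)
        return Scenario(
            name=name,
            profile=PopulationProfile(
                name=f"{name}-population",
                total_population=total_pop,
                group_fractions={"assigned-workload": fraction},
            ),
            cadres=[
                Cadre(
                    name=cadre_name,
                    headcount=headcount,
                    time_policy=TimePolicy(
                        hours_per_week=available_hours_per_chw,
                        weeks_per_year=1.0,
                    ),
                )
            ],
            interventions=[
                Intervention(
                    name="assigned-workload",
                    cadre=cadre_name,
                    mode="home-visit",
                    target=TargetSpec(kind="stock-group", key="assigned-workload"),
                    contacts_per_year=1.0,
                    minutes_per_contact=60.0,
                    coverage_goal=1.0,
                )
            ],
        )
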