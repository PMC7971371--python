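"""Scenarios: immutable bundles of inputs, what-if edits, and comparison.

A :class:`Scenario` bundles a population profile, the cadres and the
intervention catalog into one evaluable unit.  Scenarios are immutable
values: every what-if edit (:func:`edit`) returns a new scenario and
leaves the original untouched, so alternative designs can be compared
side by side.  :func:`compare` recomputes both scenarios and reports the
deltas; :func:`frontier` sweeps one cadre's headcount over a grid to
trace the coverage-vs-workforce curve (how many workers it takes before
the full assigned package fits in the time available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from . import engine
from .catalog import Cadre, Intervention, synthesize_package, validate_package
from .demography import PopulationProfile
from .errors import ConfigurationError, ConfigurationWarning

__all__ = [
    "Scenario",
    "ScenarioDelta",
    "DropIntervention",
    "SetField",
    "ScaleField",
    "SetHeadcount",
    "Edit",
    "edit",
    "compare",
    "frontier",
    "synthetic_scenario",
]

SCHEMA_VERSION = 1


class Scenario(BaseModel):
    """A complete, validated planning scenario.

    ``allocation_mode`` selects how an overloaded cadre's hours are split
    across its interventions: ``proportional`` (default — every
    intervention achieves the same fraction of its goal) or
    ``priority-fill`` (full demand in priority order until hours run
    out, supporting explicit deprioritization).  ``group_ceiling``
    switches group-session arithmetic from exact division to a rounded-up
    session count.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    profile: PopulationProfile
    cadres: list[Cadre]
    interventions: list[Intervention] = []
    allocation_mode: Literal["proportional", "priority-fill"] = "proportional"
    group_ceiling: bool = False
    schema_version: int = SCHEMA_VERSION

    @model_validator(mode="after")
    def _package_consistent(self) -> "Scenario":
        validate_package(self.cadres, self.interventions)
        return self

    # engine entry points, for fluent use
    def chws_needed(self) -> engine.StaffingResult:
        return engine.chws_needed(self)

    def expected_coverage(self) -> engine.CoverageResult:
        return engine.expected_coverage(self)

    def rank_time_consumers(self) -> list[engine.RankedActivity]:
        return engine.rank_time_consumers(self)

    def intervention(self, name: str) -> Intervention:
        for iv in self.interventions:
            if iv.name == name:
                return iv
        raise ConfigurationError(
            f"no intervention named {name!r}; valid names: "
            + (", ".join(sorted(iv.name for iv in self.interventions)) or "none")
        )

    def cadre(self, name: str) -> Cadre:
        for c in self.cadres:
            if c.name == name:
                return c
        raise ConfigurationError(
            f"no cadre named {name!r}; valid names: "
            + ", ".join(sorted(c.name for c in self.cadres))
        )


# ---------------------------------------------------------------------------
# what-if edits


@dataclass(frozen=True)
class DropIntervention:
    """Remove one intervention from the catalog."""

    name: str


@dataclass(frozen=True)
class SetField:
    """Set a (possibly dotted) field on an intervention, cadre, or the
    profile; e.g. ``SetField("cadre", "CHV", "time_policy.hours_per_week",
    20)``."""

    target: Literal["intervention", "cadre", "profile"]
    name: str  # ignored for target="profile"
    path: str
    value: object


@dataclass(frozen=True)
class ScaleField:
    """Multiply a numeric (possibly dotted) field by a factor."""

    target: Literal["intervention", "cadre", "profile"]
    name: str
    path: str
    factor: float


@dataclass(frozen=True)
class SetHeadcount:
    """Set a cadre's headcount (None to unset)."""

    cadre: str
    headcount: int | None


Edit = Union[DropIntervention, SetField, ScaleField, SetHeadcount]


def _dig(container: dict, path: str) -> tuple[dict, str]:
    parts = path.split(".")
    for p in parts[:-1]:
        nxt = container.get(p)
        if not isinstance(nxt, dict):
            raise ConfigurationError(f"no nested field {p!r} along path {path!r}")
        container = nxt
    if parts[-1] not in container:
        raise ConfigurationError(
            f"no field {parts[-1]!r} along path {path!r}; valid fields: "
            + ", ".join(sorted(container))
        )
    return container, parts[-1]


def _find_named(items: list[dict], name: str, what: str) -> dict:
    for d in items:
        if d["name"] == name:
            return d
    valid = ", ".join(sorted(d["name"] for d in items)) or "none"
    raise ConfigurationError(f"no {what} named {name!r}; valid names: {valid}")


def edit(scenario: Scenario, edits: list[Edit], *, name: str | None = None) -> Scenario:
    """Apply a list of edits, returning a new validated scenario.

    The input scenario is never modified.  Unknown edit targets raise a
    :class:`ConfigurationError` listing the valid names.  Edits are
    applied in order; edits touching disjoint elements compose in any
    order.
    """
    data = scenario.model_dump()
    for e in edits:
        if isinstance(e, DropIntervention):
            before = len(data["interventions"])
            _find_named(data["interventions"], e.name, "intervention")
            data["interventions"] = [
                iv for iv in data["interventions"] if iv["name"] != e.name
            ]
            assert len(data["interventions"]) == before - 1
        elif isinstance(e, SetHeadcount):
            _find_named(data["cadres"], e.cadre, "cadre")["headcount"] = e.headcount
        elif isinstance(e, (SetField, ScaleField)):
            if e.target == "profile":
                obj = data["profile"]
            elif e.target == "intervention":
                obj = _find_named(data["interventions"], e.name, "intervention")
            else:
                obj = _find_named(data["cadres"], e.name, "cadre")
            holder, key = _dig(obj, e.path)
            if isinstance(e, SetField):
                holder[key] = e.value
            else:
                old = holder[key]
                if not isinstance(old, (int, float)) or isinstance(old, bool):
                    raise ConfigurationError(
                        f"field {e.path!r} of {e.target} {e.name!r} is not numeric"
                    )
                holder[key] = old * e.factor
        else:  # pragma: no cover - exhaustive over Edit union
            raise TypeError(f"unknown edit type: {type(e).__name__}")
    if name is not None:
        data["name"] = name
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConfigurationWarning)
        return Scenario.model_validate(data)


# ---------------------------------------------------------------------------
# comparison


@dataclass(frozen=True)
class ScenarioDelta:
    """Differences between two scenarios (b minus a).

    Quantities present in only one scenario appear in ``added`` /
    ``removed`` rather than in the delta maps.  Deltas of unchanged
    quantities are exactly zero.  Coverage and load maps are empty when
    either scenario cannot answer the fixed-workforce question (headcount
    unset on a loaded cadre).
    """

    scenario_a: str
    scenario_b: str
    cadre_required_chws: dict[str, int] = field(default_factory=dict)
    cadre_load_ratio: dict[str, float] = field(default_factory=dict)
    intervention_annual_hours: dict[str, float] = field(default_factory=dict)
    intervention_coverage: dict[str, float] = field(default_factory=dict)
    added_interventions: list[str] = field(default_factory=list)
    removed_interventions: list[str] = field(default_factory=list)
    #: baseline (scenario a) values keyed "quantity:name", for relative change
    baselines: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: absolute delta plus relative change
        against the first scenario (``new`` when the baseline is zero)."""
        rows = []
        for kind, mapping in (
            ("cadre.required_chws", self.cadre_required_chws),
            ("cadre.load_ratio", self.cadre_load_ratio),
            ("intervention.annual_hours", self.intervention_annual_hours),
            ("intervention.coverage", self.intervention_coverage),
        ):
            for nm in sorted(mapping):
                delta = mapping[nm]
                base = self.baselines.get(f"{kind}:{nm}")
                if delta == 0:
                    rel = "0"
                elif base:
                    rel = format(delta / base, ".6g")
                else:
                    rel = "new"
                rows.append(
                    {"quantity": kind, "name": nm, "delta": delta, "relative": rel}
                )
        for nm in sorted(self.added_interventions):
            rows.append(
                {"quantity": "intervention.added", "name": nm,
                 "delta": float("nan"), "relative": "new"}
            )
        for nm in sorted(self.removed_interventions):
            rows.append(
                {"quantity": "intervention.removed", "name": nm,
                 "delta": float("nan"), "relative": "removed"}
            )
        return pd.DataFrame(rows, columns=["quantity", "name", "delta", "relative"])


def compare(a: Scenario, b: Scenario) -> ScenarioDelta:
    """Recompute both scenarios and report per-cadre and per-intervention
    deltas (b minus a); antisymmetric by construction."""
    if a.profile.name != b.profile.name:
        warnings.warn(
            f"comparing scenarios with different profiles "
            f"({a.profile.name!r} vs {b.profile.name!r})",
            ConfigurationWarning,
            stacklevel=2,
        )

    need_a, need_b = engine.chws_needed(a), engine.chws_needed(b)
    shared_cadres = sorted(set(need_a.per_cadre) & set(need_b.per_cadre))
    req = {
        c: need_b.per_cadre[c].required_chws - need_a.per_cadre[c].required_chws
        for c in shared_cadres
    }
    baselines = {
        f"cadre.required_chws:{c}": float(need_a.per_cadre[c].required_chws)
        for c in shared_cadres
    }

    dem_a = {t.intervention: t.annual_hours for t in engine.time_demands(a)}
    dem_b = {t.intervention: t.annual_hours for t in engine.time_demands(b)}
    shared_ivs = sorted(set(dem_a) & set(dem_b))
    hours = {n: dem_b[n] - dem_a[n] for n in shared_ivs}
    baselines.update({f"intervention.annual_hours:{n}": dem_a[n] for n in shared_ivs})

    load: dict[str, float] = {}
    covg: dict[str, float] = {}
    try:
        cov_a, cov_b = engine.expected_coverage(a), engine.expected_coverage(b)
    except ConfigurationError:
        pass  # headcounts unset somewhere: staffing deltas still reported
    else:
        load = {
            c: cov_b.per_cadre[c].load_ratio - cov_a.per_cadre[c].load_ratio
            for c in shared_cadres
        }
        covg = {
            n: cov_b.per_intervention[n].achievable_coverage
            - cov_a.per_intervention[n].achievable_coverage
            for n in shared_ivs
        }
        baselines.update(
            {f"cadre.load_ratio:{c}": cov_a.per_cadre[c].load_ratio for c in shared_cadres}
        )
        baselines.update(
            {
                f"intervention.coverage:{n}": cov_a.per_intervention[n].achievable_coverage
                for n in shared_ivs
            }
        )

    return ScenarioDelta(
        scenario_a=a.name,
        scenario_b=b.name,
        cadre_required_chws=req,
        cadre_load_ratio=load,
        intervention_annual_hours=hours,
        intervention_coverage=covg,
        added_interventions=sorted(set(dem_b) - set(dem_a)),
        removed_interventions=sorted(set(dem_a) - set(dem_b)),
        baselines=baselines,
    )


# ---------------------------------------------------------------------------
# workforce frontier


def frontier(
    scenario: Scenario, headcount_grid: list[int], cadre: str
) -> pd.DataFrame:
    """Sweep one cadre's headcount over a grid.

    Returns a table with one row per grid value: the headcount, the
    cadre's aggregate achievable share of its assigned workload at that
    headcount, and a flag marking headcounts at or above the workforce
    required for full coverage.  Other cadres are untouched and need not
    have headcounts set.
    """
    if not headcount_grid:
        raise ConfigurationError("headcount grid must be non-empty")
    if any(h <= 0 for h in headcount_grid):
        raise ConfigurationError("headcount grid values must be positive")
    c = scenario.cadre(cadre)
    demand = engine.cadre_demand_hours(scenario)[c.name]
    if demand > 0:
        required = engine.chws_needed(scenario).per_cadre[c.name].required_chws
        avail = engine.available_service_hours(c.time_policy) if c.time_policy else 0.0
    else:
        required, avail = 0, 0.0
    rows = []
    for h in headcount_grid:
        share = 1.0 if demand <= 0 else min(1.0, h * avail / demand)
        rows.append(
            {
                "headcount": int(h),
                "aggregate_achievable_share": share,
                "full_coverage": bool(h >= required),
            }
        )
    return pd.DataFrame(rows, columns=["headcount", "aggregate_achievable_share", "full_coverage"])


# ---------------------------------------------------------------------------
# synthetic scenarios


def synthetic_scenario(
    seed: int,
    n_cadres: int = 3,
    n_interventions: int = 10,
    *,
    allocation_mode: Literal["proportional", "priority-fill"] = "proportional",
    ranges=None,
) -> Scenario:
    """A random but valid scenario (thin wrapper over
    :func:`chwplan.catalog.synthesize_package`); deterministic per seed."""
    profile, cadres, interventions = synthesize_package(
        seed, n_cadres, n_interventions, ranges
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConfigurationWarning)
        return Scenario(
            name=f"synthetic-{seed}",
            profile=profile,
            cadres=cadres,
            interventions=interventions,
            allocation_mode=allocation_mode,
        )
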