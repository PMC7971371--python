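"""Scenario files and report tables.

A scenario lives in one human-editable YAML file (see the schema
reference in the package docs).  Loading is strict about values but
forgiving about vocabulary: unknown keys are reported as warnings and
ignored, so files written by newer versions still load.  Three error
classes are distinguished — the file does not parse (:class:`ParseError`),
it parses but violates the schema (:class:`SchemaError`, with every
field-level issue listed at once), or it is schematically fine but
semantically inconsistent (:class:`ConfigurationError`).

Report writers emit deterministic tables: rows in a fixed order, floats
at six significant digits, no thousands grouping — repeated runs on the
same inputs produce byte-identical files.  Formats: ``csv``,
``json-tables`` (the same tables as a JSON object), and ``figure-data``
(the paired needed-vs-available hours per CHW behind the standard
workload chart).
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
import warnings
from pathlib import Path

import pandas as pd
import yaml
from pydantic import ValidationError

from . import engine
from .catalog import Cadre, Intervention, TimePolicy
from .demography import TargetSpec
from .errors import ConfigurationWarning, ParseError, SchemaError
from .scenario import Scenario

__all__ = [
    "load_scenario",
    "save_scenario",
    "interventions_from_csv",
    "staffing_frame",
    "coverage_frames",
    "rank_frame",
    "figure_data_frame",
    "write_table",
    "file_digest",
    "OUTPUT_FORMATS",
]

OUTPUT_FORMATS = ("csv", "json-tables", "figure-data")

# documented vocabulary per file section, for forward-compatibility warnings
_KNOWN_KEYS = {
    "scenario": {
        "schema_version", "name", "profile", "cadres", "interventions",
        "allocation_mode", "group_ceiling",
    },
    "profile": {
        "name", "total_population", "group_fractions", "group_counts",
        "annual_event_rates",
    },
    "cadre": set(Cadre.model_fields),
    "time_policy": set(TimePolicy.model_fields),
    "intervention": set(Intervention.model_fields),
    "target": set(TargetSpec.model_fields),
}


def _warn_unknown_keys(data: dict, source: str) -> None:
    found: list[str] = []

    def check(obj, section: str, where: str) -> None:
        if not isinstance(obj, dict):
            return
        extras = sorted(set(obj) - _KNOWN_KEYS[section])
        found.extend(f"{where}: {k}" for k in extras)

    check(data, "scenario", "scenario")
    check(data.get("profile"), "profile", "profile")
    for c in data.get("cadres") or []:
        if isinstance(c, dict):
            where = f"cadre {c.get('name', '?')!r}"
            check(c, "cadre", where)
            check(c.get("time_policy"), "time_policy", f"{where} time_policy")
    for iv in data.get("interventions") or []:
        if isinstance(iv, dict):
            where = f"intervention {iv.get('name', '?')!r}"
            check(iv, "intervention", where)
            check(iv.get("target"), "target", f"{where} target")
    if found:
        warnings.warn(
            f"{source}: ignoring unrecognized keys ({'; '.join(found)})",
            ConfigurationWarning,
            stacklevel=3,
        )


def _schema_error(exc: ValidationError, source: str) -> SchemaError:
    issues = [
        ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
        for err in exc.errors()
    ]
    return SchemaError(f"{source} does not match the scenario schema", issues)


def load_scenario(path: str | Path) -> Scenario:
    """Load and fully validate a scenario file.

    All schema violations in the file are reported together in one
    :class:`SchemaError`; unknown keys warn and are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"scenario file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"{path} is not valid YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: top level must be a mapping, got {type(data).__name__}")
    _warn_unknown_keys(data, str(path))
    try:
        return Scenario.model_validate(data)
    except ValidationError as exc:
        raise _schema_error(exc, str(path)) from exc


def save_scenario(scenario: Scenario, path: str | Path) -> Path:
    """Write a scenario to YAML; ``load_scenario`` round-trips it
    losslessly (floats are written at full precision)."""
    path = Path(path)
    data = scenario.model_dump(exclude_none=True)
    path.write_text(yaml.safe_dump(data, sort_keys=False, allow_unicode=True))
    return path


# ---------------------------------------------------------------------------
# CSV catalog import

#: Column dictionary for intervention-catalog CSV import. Required:
#: name, cadre, mode, target_kind, target_key, contacts_per_year,
#: minutes_per_contact.  Optional (with defaults): in_need_fraction (1),
#: facility_share (0), group_size (group sessions only), coverage_goal
#: (1), priority (catalog order), travel_minutes_per_contact (0).
CSV_CATALOG_COLUMNS = {
    "name": str, "cadre": str, "mode": str, "target_kind": str,
    "target_key": str, "in_need_fraction": float, "facility_share": float,
    "contacts_per_year": float, "minutes_per_contact": float,
    "group_size": float, "coverage_goal": float, "priority": int,
    "travel_minutes_per_contact": float,
}
_CSV_REQUIRED = (
    "name", "cadre", "mode", "target_kind", "target_key",
    "contacts_per_year", "minutes_per_contact",
)


def interventions_from_csv(path: str | Path) -> list[Intervention]:
    """Read an intervention catalog from CSV (one row per intervention,
    columns per :data:`CSV_CATALOG_COLUMNS`)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot read catalog CSV {path}: {exc}") from exc
    missing = [c for c in _CSV_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(
            f"catalog CSV {path} lacks required columns", [f"missing: {m}" for m in missing]
        )
    out: list[Intervention] = []
    issues: list[str] = []
    for idx, row in df.iterrows():
        fields = {
            "name": row["name"],
            "cadre": row["cadre"],
            "mode": row["mode"],
            "target": {
                "kind": row["target_kind"],
                "key": row["target_key"],
                "in_need_fraction": row.get("in_need_fraction", 1.0),
                "facility_share": row.get("facility_share", 0.0),
            },
            "contacts_per_year": row["contacts_per_year"],
            "minutes_per_contact": row["minutes_per_contact"],
        }
        for opt in ("group_size", "coverage_goal", "priority", "travel_minutes_per_contact"):
            if opt in df.columns and not pd.isna(row[opt]):
                fields[opt] = row[opt]
        for key in ("in_need_fraction", "facility_share"):
            if pd.isna(fields["target"][key]):
                fields["target"][key] = 1.0 if key == "in_need_fraction" else 0.0
        try:
            out.append(Intervention.model_validate(fields))
        except ValidationError as exc:
            issues.extend(f"row {idx}: {e['msg']}" for e in exc.errors())
    if issues:
        raise SchemaError(f"catalog CSV {path} has invalid rows", issues)
    return out


# ---------------------------------------------------------------------------
# report tables


def staffing_frame(result: engine.StaffingResult) -> pd.DataFrame:
    """Per-cadre staffing table (workforce needed for full coverage)."""
    rows = [
        {
            "cadre": name,
            "total_demand_hours": c.total_demand_hours,
            "available_hours_per_chw": c.available_hours_per_chw,
            "required_chws": c.required_chws,
        }
        for name, c in sorted(result.per_cadre.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["cadre", "total_demand_hours", "available_hours_per_chw", "required_chws"],
    )


def coverage_frames(result: engine.CoverageResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-cadre, per-intervention) coverage tables for a fixed workforce."""
    cadre_rows = [
        {
            "cadre": name,
            "supply_hours": c.supply_hours,
            "demand_hours": c.demand_hours,
            "load_ratio": c.load_ratio,
            "aggregate_achievable_share": c.aggregate_achievable_share,
        }
        for name, c in sorted(result.per_cadre.items())
    ]
    iv_rows = [
        {
            "intervention": name,
            "cadre": c.cadre,
            "demand_hours": c.demand_hours,
            "allocated_hours": c.allocated_hours,
            "achievable_coverage": c.achievable_coverage,
        }
        for name, c in sorted(result.per_intervention.items())
    ]
    return (
        pd.DataFrame(
            cadre_rows,
            columns=["cadre", "supply_hours", "demand_hours", "load_ratio",
                     "aggregate_achievable_share"],
        ),
        pd.DataFrame(
            iv_rows,
            columns=["intervention", "cadre", "demand_hours", "allocated_hours",
                     "achievable_coverage"],
        ),
    )


def rank_frame(ranking: list[engine.RankedActivity]) -> pd.DataFrame:
    """Time-consumption ranking table (already ordered)."""
    return pd.DataFrame(
        [
            {
                "rank": i + 1,
                "intervention": r.intervention,
                "cadre": r.cadre,
                "annual_hours": r.annual_hours,
                "share_of_cadre_demand": r.share_of_cadre_demand,
            }
            for i, r in enumerate(ranking)
        ],
        columns=["rank", "intervention", "cadre", "annual_hours", "share_of_cadre_demand"],
    )


def figure_data_frame(scenario: Scenario) -> pd.DataFrame:
    """Paired needed-vs-available annual hours per CHW, one row per cadre
    with a set headcount — the data behind the standard workload chart."""
    demand = engine.cadre_demand_hours(scenario)
    rows = []
    for c in sorted(scenario.cadres, key=lambda c: c.name):
        if not c.headcount or c.time_policy is None:
            continue
        rows.append(
            {
                "cadre": c.name,
                "hours_needed_per_chw": demand[c.name] / c.headcount,
                "hours_available_per_chw": engine.available_service_hours(c.time_policy),
            }
        )
    return pd.DataFrame(
        rows, columns=["cadre", "hours_needed_per_chw", "hours_available_per_chw"]
    )


# ---------------------------------------------------------------------------
# deterministic writers


def _fmt(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        if math.isnan(v):
            return ""
        if math.isinf(v):
            return "inf"
        if v == int(v) and abs(v) < 1e15:
            return str(int(v))
        return format(v, ".6g")
    if pd.api.types.is_integer(v):
        return str(int(v))
    return str(v)


def write_table(frame: pd.DataFrame, path: str | Path, fmt: str = "csv") -> Path:
    """Write one table deterministically.

    ``csv`` writes plain CSV; ``json-tables`` writes
    ``{"columns": [...], "rows": [[...], ...]}``.  Floats carry six
    significant digits; integers are ungrouped.  Identical inputs yield
    byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cells = [[_fmt(v) for v in row] for row in frame.itertuples(index=False)]
    if fmt == "json-tables":
        payload = {"columns": list(frame.columns), "rows": cells}
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return path
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(frame.columns)
        writer.writerows(cells)
    return path


def file_digest(path: str | Path) -> str:
    """SHA-256 hex digest of a file, for run logging."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
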