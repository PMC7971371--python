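# Methods

## Model

`chwplan` is a deterministic time-use accounting model for community
health worker (CHW) programs.  It balances two annual quantities per
cadre:

**Demand.**  Each intervention targets either a standing demographic
group (sized as `total_population x group_fraction`) or an annual event
stream (sized as `total_population x rate`, e.g. live births).  The
target is scaled by an *in-need fraction* (epidemiology: not every
under-5 child needs case management) and reduced by a *facility share*
(the portion expected to be served at health facilities rather than in
the community).  Demand in hours is then

    target x coverage_goal x contacts_per_year x minutes_per_contact / 60.

Group sessions divide the contact count by the session size: a round of
sessions reaches `target x goal / group_size` groups.  By default this
division is exact; a per-round ceiling variant (`group_ceiling`) exists
for small catchments, where the rounding correction is not negligible.
An optional per-visit travel surcharge (`travel_minutes_per_contact`)
adds to the contact minutes for catalogs that model travel per trip
rather than as a share of time.

**Supply.**  A time policy converts one worker's commitment to annual
direct-service hours:

    (hours_per_week x weeks_per_year - training - campaign_block)
      x (1 - travel_share - admin_share),

floored at zero.  Travel and administration are shares of working time —
the natural parameterization for programs that report "travel takes a
third of the time" — while training and campaigns are block hours per
year, because programs schedule them as fixed events rather than as a
proportion of every week.

**The three questions.**

1. *Workforce needed*: per cadre, `ceil(total demand / supply per
   worker)`; zero when the cadre carries no demand; an error when demand
   is positive but the policy leaves zero service hours (no finite
   workforce suffices).
2. *Expected coverage*: with headcounts fixed, each cadre's aggregate
   achievable share of its assigned workload is `min(1, supply/demand)`.
   Overloaded cadres allocate hours across interventions by one of two
   first-class rules (a scenario flag):
   - **proportional** (default): every intervention achieves the same
     fraction `supply/demand` of its goal.  This matches how programs
     summarize overload ("the cadre can deliver under half its assigned
     workload") without presuming any priority ordering.
   - **priority-fill**: interventions receive their full demand in
     priority order (explicit rank, then catalog order, ties broken
     alphabetically) until hours run out — the rule implied by
     deprioritization decisions ("drop TB observation to protect child
     health visits").
   Both rules conserve hours (allocations sum to `min(supply, demand)`)
   and never allocate an intervention more than its own demand.  The
   aggregate share is the same under both rules; only its distribution
   across interventions differs.
3. *Scenario comparison*: scenarios are immutable values; edits (drop an
   intervention, set or scale a field, set a headcount) return new
   validated scenarios, so alternatives can be evaluated side by side.
   Comparison recomputes both scenarios and reports absolute deltas
   (antisymmetric by construction) plus relative change, with a zero
   baseline reported as "new".  The headcount *frontier* sweeps one
   cadre's workforce over a grid and reports the achievable share and a
   full-coverage flag per point.

## Duality

The staffing and coverage answers are mutually consistent by
construction: granting each cadre exactly its computed requirement makes
every achievable share 1, and removing a single worker from any binding
cadre (requirement > 0) drops that cadre below full coverage.  This is
asserted over large seeded scenario batteries in the test suite.

## Parameters and defaults

| Parameter | Unit | Default | Rationale |
|---|---|---|---|
| `weeks_per_year` | weeks | 48 | a working year minus leave; programs that state a full-year commitment (e.g. the Zanzibar fixture) override to 52 |
| `travel_share`, `admin_share` | fraction of working time | 0 | must sum below 1; entered from program assessments |
| `training_hours_per_year`, `campaign_hours_per_year` | h/year | 0 | block time, subtracted before the shares apply |
| `in_need_fraction`, `facility_share` | fraction | 1, 0 | neutral targeting unless epidemiology/facility data say otherwise |
| `coverage_goal` | fraction | 1 | policy target per intervention |
| `priority` | rank (lower = first) | catalog order | reproducible tie-break: explicit rank, then position, then name |
| allocation mode | — | proportional | see above |

Counts are kept as real numbers throughout; rounding to whole persons
or workers happens only at reporting.  Headcounts are the only integer
quantities in the engine (requirements round up; a demand of exactly
*k* worker-years yields exactly *k* workers, enforced with a 1e-9
relative slack on the ceiling so float summation noise never adds a
spurious worker).  Population-per-CHW ratios round half-up, matching
how program tables print them.

## Built-in planning cases

Four fixtures encode published program figures: two Rwandan regional
typologies (populations, under-5 counts, and the headcounts of the ASM,
binome, and health-promotion cadres), the Rwandan national totals, and
the Zanzibar volunteer program (population, under-5 count, 2,200 CHVs at
18 h/week with travel occupying one third of time; the 52-week year is a
fixture parameter, since the program states a weekly commitment only).

The Rwandan programs' intervention-level inputs (visit durations,
frequencies) were never published, so those fixtures deliberately carry
no intervention catalogs.  Their published bottom line — about 1,300
assigned hours versus 632 available hours per health-promotion CHW — is
stored as labelled per-worker aggregates, and
`fixtures.aggregate_workload_scenario` builds a clearly-labelled
*synthetic* one-cadre scenario from such aggregates so the coverage
engine recomputes the achievable share (632/1300 ≈ 48.6 %) rather than
looking it up.  No invented catalog is passed off as a country's real
inputs.

## Synthetic scenario generator

`synthesize_package(seed, ...)` draws uniform parameters emulating a
national part-time CHW program: catchments of 5×10⁴–3×10⁶ people, 2–4
demographic groups and event streams, 10–30 h/week over 44–50 weeks,
travel up to 40 % and administration up to 20 % of time, doses of 1–12
annual contacts at 10–60 minutes, coverage goals of 50–100 %, and mixed
delivery modes.  Generation is deterministic per seed and every output
satisfies the domain invariants by construction (overhead block hours
are rescaled if they would consume half the gross budget, keeping
staffing questions feasible).

The generator emulates the *structure* of real inputs, not their joint
distribution: real programs correlate travel with geography, dose with
intervention type, and headcounts with population, while the generator
samples independently.  Passing property tests on this battery therefore
demonstrates the engine's arithmetic and invariants (duality,
conservation, monotonicity, serialization fidelity) — not that any
particular country package is realistic.

## Numerical and design choices

- Exact division for group sessions by default keeps demand linear in
  its dose parameters, which the property tests exploit; the ceiling
  variant is the documented alternative.
- Scenario files are YAML with a schema version; loading reports every
  field violation at once, warns on (and ignores) unknown keys for
  forward compatibility, and distinguishes parse, schema, and semantic
  errors with distinct CLI exit codes (2/3/4; infeasibility is 5).
- Report writers format fractions at six significant digits with fixed
  row ordering, so repeated runs are byte-identical.
- A cadre's `time_policy` and `headcount` are optional at the type level
  — record-keeping cadres (known headcount, unpublished policy) and
  staffing questions (policy known, headcount sought) each omit one —
  and the engine raises a configuration error only when a computation
  actually needs the missing piece.
- More than six cadres warns rather than fails: six is the planning
  convention the tool is designed around, not a mathematical limit.

## Problem sizes

The test suite and the acceptance script run at desk scale: batteries of
50–200 synthetic scenarios with 1–4 cadres and 4–12 interventions, and
brute-force demand enumeration on packages of ≤ 5 interventions over
populations of ≤ 200 people.  These sizes exercise every code path while
keeping the full suite to a few seconds; the engine itself is closed-form
arithmetic and scales to national inputs trivially.

## Limitations

- Single planning year: no population growth, seasonality, or attrition.
- Deterministic accounting: no queueing or stochastic workload; the
  model bounds feasibility, it does not predict utilization.
- In-need multipliers (e.g. regional malaria caseload factors) are user
  inputs, not derived from surveillance data.
- Costing, supervision networks, and incentive design are out of scope;
  the outputs are meant to feed such tools, not replace them.
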