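"""Generic state-transition module interpreter and population generator.

A disease module is a JSON state machine (states of kind Initial, Simple,
Delay, Encounter, ConditionOnset, Procedure, Observation, Death, Terminal)
that each simulated person walks through at weekly time resolution, in the
style of generic-module clinical simulators: transitions are direct,
distributed (probability) or conditional (guards on person attributes);
Delay states wait a sampled number of weeks or until an age/sex hazard
fires.

Population generation follows the prevalence ("retrospective") semantics: the
engine keeps generating persons per demographic stratum until the stratum's
quota of persons *alive at the target date* is filled; every decedent attempt
is retained in a separate bucket.  Internally the engine is event-driven —
waiting times are sampled directly and rounded to whole weeks — which is
observationally equivalent to stepping week by week but runs orders of
magnitude faster.

Randomness: one root seed; each person gets an independent counter-based
stream (`Philox(key=[root_seed, stratum_id << 32 | attempt])`), so results do
not depend on generation order.
"""

from __future__ import annotations

import datetime
import json
import math
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .demography import WEEKS_PER_YEAR, LifeTable, default_life_table
from .tables import ParameterBundle, RateTable

__all__ = [
    "WEEK_ZERO",
    "week_to_date",
    "date_to_week",
    "default_target_week",
    "Event",
    "PersonRecord",
    "State",
    "Transition",
    "ModuleDefinition",
    "ModuleSchemaError",
    "load_module_definition",
    "EngineContext",
    "simulate_person",
    "SimulationConfig",
    "PopulationDataset",
    "generate_population",
    "simulate_crude_incidence",
    "compute_prevalence",
    "compute_incidence_series",
]

# calendar origin: week 0 is Monday 1900-01-01
WEEK_ZERO = datetime.date(1900, 1, 1)

STATE_KINDS = {
    "Initial", "Simple", "Delay", "Encounter", "ConditionOnset",
    "Procedure", "Observation", "Death", "Terminal",
}
EVENT_KINDS = {"Encounter": "encounter", "ConditionOnset": "condition",
               "Procedure": "procedure", "Observation": "observation"}


def week_to_date(week: int) -> datetime.date:
    return WEEK_ZERO + datetime.timedelta(weeks=int(week))

def date_to_week(d: datetime.date) -> int:
    return (d - WEEK_ZERO).days // 7

def default_target_week() -> int:
    """First week of 2022 (Monday 2022-01-03)."""
    return date_to_week(datetime.date(2022, 1, 3))


# ---------------------------------------------------------------------------
# person records
# ---------------------------------------------------------------------------


class Event(NamedTuple):
    week: int
    kind: str
    label: str
    code: str
    detail: str


@dataclass
class PersonRecord:
    """One synthetic person: demographics, attributes and timed events."""

    id: str
    sex: str
    birth_week: int
    death_week: int | None = None
    attributes: dict[str, Any] = field(default_factory=dict)
    events: list[Event] = field(default_factory=list)

    def age_years(self, week: int) -> float:
        return (week - self.birth_week) / WEEKS_PER_YEAR

    def alive_at(self, week: int) -> bool:
        return self.death_week is None or self.death_week > week

    def add_event(self, week: int, kind: str, label: str, code: str = "", detail: str = "") -> None:
        self.events.append(Event(int(week), kind, label, code, detail))

    def diagnosis_week(self, condition_label: str) -> int | None:
        return self.attributes.get(f"diagnosis_week::{condition_label}")

    def finalize(self) -> None:
        """Sort events and drop anything scheduled after death."""
        if self.death_week is not None:
            self.events = [e for e in self.events if e.week <= self.death_week]
        self.events.sort(key=lambda e: (e.week, e.kind, e.label))
        if self.death_week is not None and self.death_week < self.birth_week:
            raise ValueError(f"person {self.id}: death before birth")


# ---------------------------------------------------------------------------
# module definition
# ---------------------------------------------------------------------------


class ModuleSchemaError(ValueError):
    pass


@dataclass(frozen=True)
class Transition:
    to: str
    probability: float | None = None
    condition: Mapping[str, Any] | None = None


@dataclass(frozen=True)
class State:
    name: str
    kind: str
    payload: Mapping[str, Any] = field(default_factory=dict)
    transitions: tuple[Transition, ...] = ()
    provenance: str = ""


@dataclass(frozen=True)
class ModuleDefinition:
    name: str
    states: Mapping[str, State]
    initial_state: str

    def validate(self) -> None:
        kinds = [s.kind for s in self.states.values()]
        if kinds.count("Initial") != 1:
            raise ModuleSchemaError(f"module {self.name}: needs exactly one Initial state")
        if kinds.count("Terminal") < 1:
            raise ModuleSchemaError(f"module {self.name}: needs at least one Terminal state")
        if self.initial_state not in self.states or self.states[self.initial_state].kind != "Initial":
            raise ModuleSchemaError(f"module {self.name}: initial state {self.initial_state!r} missing or not Initial")
        for st in self.states.values():
            if st.kind not in STATE_KINDS:
                raise ModuleSchemaError(f"state {st.name}: unknown kind {st.kind!r}")
            targets = [t.to for t in st.transitions]
            for extra in ("on_fire", "on_expire"):
                if extra in st.payload:
                    targets.append(st.payload[extra])
            for t in targets:
                if t not in self.states:
                    raise ModuleSchemaError(f"state {st.name}: dangling transition target {t!r}")
            if st.kind in ("Death", "Terminal") and st.transitions:
                raise ModuleSchemaError(f"state {st.name}: {st.kind} states have no outgoing transitions")
            probs = [t.probability for t in st.transitions if t.probability is not None]
            if probs:
                if len(probs) != len(st.transitions):
                    raise ModuleSchemaError(f"state {st.name}: mixed distributed and direct transitions")
                total = math.fsum(probs)
                if abs(total - 1.0) > 1e-9:
                    raise ModuleSchemaError(f"state {st.name}: distributed transition sums to {total:g}")
            if st.kind == "Delay" and "weeks" in st.payload:
                lo, hi = st.payload["weeks"]
                if lo < 0 or hi < lo:
                    raise ModuleSchemaError(f"state {st.name}: invalid delay range {st.payload['weeks']}")
        # reachability from Initial
        seen = {self.initial_state}
        frontier = [self.initial_state]
        while frontier:
            st = self.states[frontier.pop()]
            nxt = [t.to for t in st.transitions]
            nxt += [st.payload[k] for k in ("on_fire", "on_expire") if k in st.payload]
            for t in nxt:
                if t not in seen:
                    seen.add(t)
                    frontier.append(t)
        unreachable = set(self.states) - seen
        if unreachable:
            raise ModuleSchemaError(f"module {self.name}: unreachable states {sorted(unreachable)}")

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "initial_state": self.initial_state,
            "states": {
                s.name: {
                    "kind": s.kind,
                    "payload": dict(s.payload),
                    "provenance": s.provenance,
                    "transitions": [
                        {k: v for k, v in
                         (("to", t.to), ("probability", t.probability), ("condition", t.condition))
                         if v is not None}
                        for t in s.transitions
                    ],
                }
                for s in self.states.values()
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def load_module_definition(text: str) -> ModuleDefinition:
    """Parse and validate a JSON module document."""
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModuleSchemaError(f"malformed module JSON: {exc}") from exc
    for key in ("name", "states", "initial_state"):
        if key not in raw:
            raise ModuleSchemaError(f"module document missing {key!r}")
    states = {}
    for name, s in raw["states"].items():
        transitions = tuple(
            Transition(t["to"], t.get("probability"), t.get("condition"))
            for t in s.get("transitions", ())
        )
        states[name] = State(name, s.get("kind", ""), s.get("payload", {}), transitions, s.get("provenance", ""))
    module = ModuleDefinition(raw["name"], states, raw["initial_state"])
    module.validate()
    return module


# ---------------------------------------------------------------------------
# simulation context
# ---------------------------------------------------------------------------

ActionFn = Callable[[PersonRecord, int, np.random.Generator, "EngineContext", Mapping[str, Any]], int | None]


@dataclass
class EngineContext:
    """Everything a module walk needs besides the person itself."""

    bundle: ParameterBundle
    actions: Mapping[str, ActionFn] = field(default_factory=dict)
    target_week: int = 0
    rate_factor: float = 1.0
    rate_table_override: str | None = None
    life_tables: Mapping[str, LifeTable] | None = None

    def life_table(self, sex: str) -> LifeTable:
        if self.life_tables is not None:
            return self.life_tables[sex]
        return default_life_table(sex)

    def resolve_rate_table(self, name: str, sex: str) -> RateTable:
        key = self.rate_table_override or f"{name}:{sex}"
        table = self.bundle.rate_tables.get(key) or self.bundle.rate_tables.get(name)
        if table is None:
            raise KeyError(f"no rate table {key!r} in bundle")
        return table


def _sample_hazard_week(
    table: RateTable, factor: float, birth_week: int, horizon_week: int, rng: np.random.Generator
) -> int | None:
    """First-passage week of a piecewise-constant age hazard, or None.

    Rates are per 100,000 person-years; the hazard is constant within each age
    bin.  The event must occur strictly before ``horizon_week`` (death or
    lifespan cap) to count.
    """
    target_cum = rng.exponential()
    cum = 0.0
    for (lo, hi), rate in zip(table.age_groups, table.rates):
        h_week = rate * factor / 100000.0 / WEEKS_PER_YEAR
        n_weeks = (hi - lo) * WEEKS_PER_YEAR
        if h_week <= 0:
            continue
        bin_cum = h_week * n_weeks
        if cum + bin_cum >= target_cum:
            offset = (target_cum - cum) / h_week
            age_week = lo * WEEKS_PER_YEAR + int(offset)
            week = birth_week + age_week
            return week if week < horizon_week else None
        cum += bin_cum
    return None


# ---------------------------------------------------------------------------
# per-person simulation
# ---------------------------------------------------------------------------


def _eval_condition(cond: Mapping[str, Any], person: PersonRecord, week: int) -> bool:
    attr = cond["attr"]
    value = {"sex": person.sex, "age": person.age_years(week)}.get(attr, person.attributes.get(attr))
    op = cond.get("op", "eq")
    ref = cond.get("value")
    if op == "eq":
        return value == ref
    if op == "ne":
        return value != ref
    if op == "in":
        return value in ref
    if op == "lt":
        return value is not None and value < ref
    if op == "ge":
        return value is not None and value >= ref
    if op == "is_set":
        return value is not None
    raise ModuleSchemaError(f"unknown condition operator {op!r}")


def _next_state(state: State, person: PersonRecord, week: int, rng: np.random.Generator) -> str | None:
    if not state.transitions:
        return None
    probs = [t.probability for t in state.transitions]
    if probs[0] is not None:
        idx = int(rng.choice(len(probs), p=np.asarray(probs, float)))
        return state.transitions[idx].to
    for t in state.transitions:
        if t.condition is None or _eval_condition(t.condition, person, week):
            return t.to
    return None


def simulate_person(
    birth_week: int,
    sex: str,
    modules: Sequence[ModuleDefinition],
    life_table: LifeTable,
    rng: np.random.Generator,
    context: EngineContext,
    person_id: str = "0",
) -> PersonRecord:
    """Simulate one person from birth: background mortality plus every module.

    Deterministic given inputs and the generator state.  Background mortality
    and module-induced death are both respected; a module may claim mortality
    authority for a window (e.g. a 5-year survival submodule whose anchors are
    all-cause) by setting the ``cancer_death_week`` / ``survived_window_until``
    attributes, in which case survivors re-enter background mortality with a
    conditional residual draw at the end of the window.
    """
    person = PersonRecord(id=person_id, sex=sex, birth_week=int(birth_week))
    person.death_week = birth_week + life_table.sample_death_week(rng)
    for module in modules:
        _walk_module(person, module, life_table, rng, context)
    # resolve mortality authority claimed by a survival submodule
    cancer_death = person.attributes.get("cancer_death_week")
    window_end = person.attributes.get("survived_window_until")
    if cancer_death is not None:
        person.death_week = int(cancer_death)
    elif window_end is not None:
        window_end = int(window_end)
        if person.death_week < window_end:
            age_at_end = window_end - person.birth_week
            person.death_week = person.birth_week + life_table.sample_death_week(rng, age_weeks=age_at_end)
            person.death_week = max(person.death_week, window_end)
        # persistent excess hazard beyond the window: the all-cause hazard of
        # the final window year minus background, as an independent competing
        # exponential (hazards add)
        final_hazard = person.attributes.get("final_year_hazard")
        if final_hazard is not None:
            age_w = window_end - person.birth_week
            mu_bg = -np.log(max(life_table.prob_alive(age_w + WEEKS_PER_YEAR), 1e-12)
                            / max(life_table.prob_alive(age_w), 1e-12))
            excess = max(0.0, float(final_hazard) - mu_bg)
            if excess > 0:
                excess_week = window_end + int(rng.exponential(1.0 / excess) * WEEKS_PER_YEAR)
                person.death_week = min(person.death_week, max(excess_week, window_end))
    person.finalize()
    return person


def _walk_module(
    person: PersonRecord,
    module: ModuleDefinition,
    life_table: LifeTable,
    rng: np.random.Generator,
    context: EngineContext,
) -> None:
    week = person.birth_week
    current: str | None = module.initial_state
    for _ in range(100000):
        if current is None:
            return
        state = module.states[current]
        kind = state.kind
        if kind == "Terminal":
            return
        if kind == "Death":
            attr = state.payload.get("week_attribute")
            death = person.attributes.get(attr, week) if attr else week
            person.death_week = int(death)
            return
        if kind == "Delay":
            if "hazard_table" in state.payload:
                table = context.resolve_rate_table(state.payload["hazard_table"], person.sex)
                horizon = person.death_week if person.death_week is not None else birth_plus_max(person)
                fired = _sample_hazard_week(table, context.rate_factor, person.birth_week, horizon, rng)
                if fired is not None:
                    week = fired
                    current = state.payload["on_fire"]
                else:
                    current = state.payload.get("on_expire")
                continue
            lo, hi = state.payload["weeks"]
            week += int(rng.integers(lo, hi + 1))
        elif kind in EVENT_KINDS:
            label = state.payload.get("label", state.name)
            person.add_event(week, EVENT_KINDS[kind], label,
                             state.payload.get("code", ""), state.payload.get("detail", ""))
            if kind == "ConditionOnset":
                person.attributes[f"diagnosis_week::{label}"] = week
        elif kind == "Simple":
            if "set" in state.payload:
                person.attributes.update(state.payload["set"])
            action = state.payload.get("action")
            if action is not None:
                fn = context.actions.get(action)
                if fn is None:
                    raise ModuleSchemaError(f"state {state.name}: unregistered action {action!r}")
                new_week = fn(person, week, rng, context, state.payload)
                if new_week is not None:
                    week = int(new_week)
        current = _next_state(module.states[current], person, week, rng)
    raise RuntimeError(f"module {module.name}: state loop exceeded 100000 steps")


def birth_plus_max(person: PersonRecord) -> int:
    from .demography import MAX_AGE_YEARS

    return person.birth_week + MAX_AGE_YEARS * WEEKS_PER_YEAR


# ---------------------------------------------------------------------------
# population generation
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Generation settings for one dataset run.

    ``mode="prevalence"`` reproduces a cross-section alive at the target date
    with a stationary age structure over ages 0-100; ``mode="enriched"``
    synthesizes only ages 40-100 (uniform, ~equal sex split) with the disease
    hazard multiplied by ``enrichment_factor`` to build a case repository.
    """

    mode: str = "prevalence"
    target_alive: int = 100_000
    target_week: int = field(default_factory=default_target_week)
    seed: int = 0
    male_fraction: float = 0.5
    enriched_age_range: tuple[int, int] = (40, 100)
    enrichment_factor: float = 300.0
    time_step_weeks: int = 1
    max_attempts_per_stratum: int = 2_000_000

    def __post_init__(self) -> None:
        if self.mode not in ("prevalence", "enriched"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.time_step_weeks != 1:
            raise ValueError("time step is fixed at one week")
        lo, hi = self.enriched_age_range
        if self.mode == "enriched" and (lo < 40 or hi > 100 or lo >= hi):
            raise ValueError("enriched mode requires ages within [40, 100]")


@dataclass
class PopulationDataset:
    alive: list[PersonRecord]
    deceased: list[PersonRecord]
    config: SimulationConfig
    module_names: tuple[str, ...]
    seed: int

    def all_records(self) -> Iterable[PersonRecord]:
        yield from self.alive
        yield from self.deceased


def _strata(config: SimulationConfig) -> list[tuple[str, int, int]]:
    """(sex, age_years_at_target, quota) with largest-remainder rounding."""
    sexes = [("male", config.male_fraction), ("female", 1.0 - config.male_fraction)]
    if config.mode == "prevalence":
        shares_by_sex = {s: default_life_table(s).stationary_year_shares(100) for s, _ in sexes}
        ages = np.arange(101)
    else:
        # realistic (stationary) age shape restricted to the enriched range
        lo, hi = config.enriched_age_range
        ages = np.arange(lo, hi + 1)
        shares_by_sex = {}
        for s, _ in sexes:
            shape = default_life_table(s).stationary_year_shares(100)[lo : hi + 1]
            shares_by_sex[s] = shape / shape.sum()
    cells = []
    weights = []
    for sex, frac in sexes:
        for i, age in enumerate(ages):
            cells.append((sex, int(age)))
            weights.append(frac * shares_by_sex[sex][i])
    weights = np.asarray(weights)
    weights = weights / weights.sum()
    quotas = _largest_remainder(weights * config.target_alive, config.target_alive)
    return [(sex, age, int(q)) for (sex, age), q in zip(cells, quotas)]


def _largest_remainder(raw: np.ndarray, total: int) -> np.ndarray:
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def generate_population(
    config: SimulationConfig,
    modules: Sequence[ModuleDefinition],
    context: EngineContext,
) -> PopulationDataset:
    """Fill every demographic stratum with persons alive at the target date.

    Persons who die before the target date are retained in the deceased
    bucket.  Reproducible from the config seed; person streams are
    counter-based so insertion order never changes results.
    """
    context.target_week = config.target_week
    if config.mode == "enriched":
        context.rate_factor = config.enrichment_factor
        context.rate_table_override = "incidence:pooled"
    alive: list[PersonRecord] = []
    deceased: list[PersonRecord] = []
    root = np.uint64(config.seed)
    for stratum_id, (sex, age, quota) in enumerate(_strata(config)):
        life_table = context.life_table(sex)
        got = 0
        attempt = 0
        while got < quota:
            if attempt >= config.max_attempts_per_stratum:
                raise RuntimeError(
                    f"stratum (sex={sex}, age={age}): attempt cap reached with {got}/{quota} alive; "
                    "survival to target may be impossible for this stratum"
                )
            key = np.array([root, np.uint64((stratum_id << 32) | attempt)], dtype=np.uint64)
            rng = np.random.Generator(np.random.Philox(key=key))
            birth_week = config.target_week - age * WEEKS_PER_YEAR - int(rng.integers(0, WEEKS_PER_YEAR))
            person = simulate_person(
                birth_week, sex, modules, life_table, rng, context,
                person_id=f"{stratum_id}-{attempt}",
            )
            if person.alive_at(config.target_week):
                alive.append(person)
                got += 1
            else:
                deceased.append(person)
            attempt += 1
    return PopulationDataset(alive, deceased, config, tuple(m.name for m in modules), config.seed)


def simulate_crude_incidence(
    table: RateTable,
    life_table: LifeTable,
    person_years: int,
    seed: int,
    rate_factor: float = 1.0,
) -> float:
    """Forward one-year incidence harness: diagnoses per 100,000 person-years.

    Samples persons from the stationary age structure, exposes each for one
    year of weekly Bernoulli trials at the age-specific hazard, and counts
    diagnoses — a direct Monte-Carlo check that the calibrated age-specific
    rates reproduce the crude registry rate.
    """
    rng = np.random.default_rng(seed)
    shares = life_table.stationary_year_shares(100)
    ages = rng.choice(len(shares), size=person_years, p=shares)
    rates = np.array([table.rate_at_age(a) * rate_factor for a in range(len(shares))])
    h_week = rates[ages] / 1e5 / WEEKS_PER_YEAR
    p_year = 1.0 - (1.0 - h_week) ** WEEKS_PER_YEAR
    events = rng.random(person_years) < p_year
    return float(1e5 * events.sum() / person_years)


# ---------------------------------------------------------------------------
# epidemiological summaries
# ---------------------------------------------------------------------------


def compute_prevalence(
    ds: PopulationDataset,
    condition_label: str,
    lookback_years: int = 25,
) -> dict[str, float]:
    """Period prevalence per 100,000 alive persons, overall and by sex.

    Counts persons alive at the target date whose diagnosis falls within the
    lookback window; sex-specific figures use sex-specific denominators.
    """
    if lookback_years <= 0:
        raise ValueError("lookback must be positive")
    if not ds.alive:
        raise ValueError("dataset has no alive persons")
    target = ds.config.target_week
    window_start = target - lookback_years * WEEKS_PER_YEAR
    counts = {"male": 0, "female": 0}
    denoms = {"male": 0, "female": 0}
    for p in ds.alive:
        denoms[p.sex] += 1
        dx = p.diagnosis_week(condition_label)
        if dx is not None and window_start < dx <= target:
            counts[p.sex] += 1
    out = {}
    for sex in ("male", "female"):
        out[sex] = 1e5 * counts[sex] / denoms[sex] if denoms[sex] else float("nan")
    out["overall"] = 1e5 * (counts["male"] + counts["female"]) / len(ds.alive)
    return out


def _mid_year_week(year: int) -> int:
    return date_to_week(datetime.date(year, 7, 1))


def compute_incidence_series(
    ds: PopulationDataset,
    condition_label: str,
    numerator: str = "alive",
    n_years: int | None = None,
) -> pd.DataFrame:
    """Diagnoses per calendar year per 100,000 persons alive mid-year.

    The denominator pools the alive and deceased buckets (persons who later
    died count as long as they were alive at mid-year).  With
    ``numerator="alive"`` (default) only diagnoses of persons alive at the
    target date are counted — the retrospective cross-section view, which
    under-estimates incidence the further back in time one looks because
    cases who died before the target date are invisible to the prevalent
    population.  ``numerator="pooled"`` also counts diagnoses of the retained
    decedents.
    """
    if numerator not in ("alive", "pooled"):
        raise ValueError(f"unknown numerator {numerator!r}")
    records = list(ds.alive) + list(ds.deceased)
    if not records:
        raise ValueError("dataset is empty")
    n_alive = len(ds.alive)
    birth = np.array([p.birth_week for p in records])
    death = np.array([p.death_week if p.death_week is not None else np.iinfo(np.int64).max for p in records])
    male = np.array([p.sex == "male" for p in records])
    dx = np.array([p.diagnosis_week(condition_label) or -1 for p in records])
    if numerator == "alive":
        dx[n_alive:] = -1
    target = ds.config.target_week
    target_year = week_to_date(target).year
    first_year = week_to_date(int(birth.min())).year
    if n_years is not None:
        first_year = max(first_year, target_year - n_years)
    rows = []
    for year in range(first_year, target_year):
        mid = _mid_year_week(year)
        y0, y1 = date_to_week(datetime.date(year, 1, 1)), date_to_week(datetime.date(year + 1, 1, 1))
        at_risk = (birth <= mid) & (death > mid)
        incident = (dx >= y0) & (dx < y1) & (dx <= target)
        row = {"year": year}
        for label, mask in (("total", np.ones(len(records), bool)), ("male", male), ("female", ~male)):
            denom = int(np.sum(at_risk & mask))
            num = int(np.sum(incident & mask))
            row[label] = 1e5 * num / denom if denom else np.nan
            row[f"n_{label}"] = denom
        rows.append(row)
    return pd.DataFrame(rows).set_index("year")
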