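"""Probability, rate and survival tables for the disease module.

Every quantity the disease module consumes lives here: categorical
distributions (with a provenance string per entry, mirroring the sourcing
practice of evidence-annotated clinical modules), conditional tables keyed by
parent-variable combinations, age-specific incidence-rate tables calibrated to
a crude registry rate, and the yearly conditional-survival table
(stage level x age group x year).  All tables round-trip through a single CSV
layout and a JSON bundle.
"""

from __future__ import annotations

import csv
import io
import itertools
import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CategoricalDistribution",
    "ConditionalTable",
    "RateTable",
    "SurvivalTable",
    "EvidenceGapConstants",
    "EVIDENCE_GAP",
    "DistributionValidation",
    "validate_distribution",
    "build_age_specific_incidence",
    "derive_conditional_table",
    "build_survival_table",
    "apply_evidence_gap_rule",
    "rake_joint",
    "ParameterBundle",
]

_SUM_TOL = 1e-9


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategoricalDistribution:
    """A categorical distribution over ordered, unique levels.

    Probabilities are fractions in [0, 1] that must sum to one within 1e-9;
    ``provenance`` records where the numbers come from (registry table,
    guideline, placeholder estimate, ...).
    """

    levels: tuple[str, ...]
    probs: tuple[float, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        object.__setattr__(self, "probs", tuple(float(p) for p in self.probs))
        if len(self.levels) != len(self.probs):
            raise ValueError("levels and probs must have equal length")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float], provenance: str = "") -> "CategoricalDistribution":
        return cls(tuple(mapping.keys()), tuple(mapping.values()), provenance)

    @classmethod
    def from_percent(cls, mapping: Mapping[str, float], provenance: str = "") -> "CategoricalDistribution":
        """Build from printed percentages, renormalising to sum exactly to 1.

        Printed registry percentages carry rounding artifacts (their sum can be
        99.9 or 100.1); the proportional adjustment is recorded in provenance.
        """
        total = float(sum(mapping.values()))
        if total <= 0:
            raise ValueError("percentages must have a positive sum")
        note = provenance
        if abs(total - 100.0) > 1e-12:
            note = f"{provenance} [renormalised from printed sum {total:g}%]"
        return cls(tuple(mapping.keys()), tuple(v / total for v in mapping.values()), note)

    def prob(self, level: str) -> float:
        return self.probs[self.levels.index(level)]

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.levels, self.probs))

    def sample(self, rng: np.random.Generator) -> str:
        return self.levels[int(rng.choice(len(self.levels), p=self.probs))]

    def sample_many(self, rng: np.random.Generator, n: int) -> np.ndarray:
        idx = rng.choice(len(self.levels), size=n, p=self.probs)
        return np.asarray(self.levels, dtype=object)[idx]


@dataclass(frozen=True)
class DistributionValidation:
    ok: bool
    violations: tuple[str, ...] = ()
    repaired: CategoricalDistribution | None = None


def validate_distribution(
    dist: CategoricalDistribution,
    tol: float = _SUM_TOL,
    repair: str | None = None,
) -> DistributionValidation:
    """Check the invariants of a categorical distribution.

    Violations are returned as data, not raised.  ``repair="largest"`` allows a
    near-miss normalisation (printed percentages) to be fixed by assigning the
    deficit to the largest probability; the repaired distribution is returned
    alongside an ok verdict when the repair succeeds.
    """
    violations: list[str] = []
    if len(dist.levels) < 1:
        raise ValueError("distribution must have at least one level")
    if len(set(dist.levels)) != len(dist.levels):
        violations.append("levels not unique")
    if any(p < 0 for p in dist.probs):
        violations.append("negative probability")
    total = math.fsum(dist.probs)
    sum_bad = abs(total - 1.0) > tol
    if sum_bad:
        violations.append(f"sum != 1 (got {total:.6g})")
    if violations and repair == "largest" and violations == [f"sum != 1 (got {total:.6g})"] and abs(total - 1.0) < 0.05:
        probs = list(dist.probs)
        probs[int(np.argmax(probs))] += 1.0 - total
        fixed = replace(
            dist,
            probs=tuple(probs),
            provenance=f"{dist.provenance} [sum {total:g} repaired onto largest level]",
        )
        return DistributionValidation(True, (), fixed)
    return DistributionValidation(not violations, tuple(violations), None)


@dataclass(frozen=True)
class ConditionalTable:
    """P(child | parents): one CategoricalDistribution per parent combination."""

    child_variable: str
    parent_variables: tuple[str, ...]
    rows: Mapping[tuple[str, ...], CategoricalDistribution]

    def __post_init__(self) -> None:
        object.__setattr__(self, "parent_variables", tuple(self.parent_variables))
        object.__setattr__(self, "rows", dict(self.rows))

    def row(self, parent_values: Sequence[str]) -> CategoricalDistribution:
        key = tuple(parent_values)
        try:
            return self.rows[key]
        except KeyError:
            raise KeyError(
                f"no row for {self.child_variable} | "
                f"{dict(zip(self.parent_variables, key))}"
            ) from None

    def sample(self, parent_values: Sequence[str], rng: np.random.Generator) -> str:
        return self.row(parent_values).sample(rng)

    def validate(self, parent_levels: Mapping[str, Sequence[str]] | None = None) -> list[str]:
        problems: list[str] = []
        for key, dist in self.rows.items():
            res = validate_distribution(dist)
            if not res.ok:
                problems.append(f"row {key}: {'; '.join(res.violations)}")
        if parent_levels is not None:
            expected = set(itertools.product(*(tuple(parent_levels[v]) for v in self.parent_variables)))
            got = set(self.rows)
            for missing in sorted(expected - got):
                problems.append(f"missing parent combination {missing}")
            for extra in sorted(got - expected):
                problems.append(f"unexpected parent combination {extra}")
        return problems

    def marginalize(self, parent_joint: Mapping[tuple[str, ...], float]) -> CategoricalDistribution:
        """Collapse the table against a joint distribution of the parents."""
        first = next(iter(self.rows.values()))
        acc = {lvl: 0.0 for lvl in first.levels}
        for key, w in parent_joint.items():
            dist = self.row(key)
            for lvl, p in zip(dist.levels, dist.probs):
                acc[lvl] += w * p
        return CategoricalDistribution.from_mapping(acc, provenance="marginalized")


@dataclass(frozen=True)
class RateTable:
    """Age-specific event rates per 100,000 person-years for one sex.

    Age groups are 5-year bins spanning 40-100 (ages below 40 carry no risk).
    """

    sex: str
    age_groups: tuple[tuple[int, int], ...]
    rates: tuple[float, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "age_groups", tuple((int(a), int(b)) for a, b in self.age_groups))
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))
        if len(self.age_groups) != len(self.rates):
            raise ValueError("age_groups and rates must align")
        if any(r < 0 for r in self.rates):
            raise ValueError("rates must be nonnegative")

    def rate_at_age(self, age_years: float) -> float:
        for (lo, hi), r in zip(self.age_groups, self.rates):
            if lo <= age_years < hi:
                return r
        return 0.0

    def crude(self, pop_age_structure: Sequence[float]) -> float:
        """Population-weighted crude rate for structure shares aligned to bins."""
        return float(np.dot(np.asarray(pop_age_structure, float), np.asarray(self.rates)))

    def scaled(self, factor: float) -> "RateTable":
        return replace(self, rates=tuple(r * factor for r in self.rates),
                       provenance=f"{self.provenance} [x{factor:g}]")


@dataclass(frozen=True)
class SurvivalTable:
    """Yearly conditional survival by stage level x age group, years 1..5.

    ``conditional[s, g, y-1]`` is the probability of surviving year ``y`` given
    alive at its start — 5 stage levels x 4 age groups x 5 years = 100 node
    probabilities.
    """

    stage_levels: tuple[str, ...]
    age_groups: tuple[str, ...]
    conditional: np.ndarray  # shape (n_stage, n_age, 5)
    provenance: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.conditional, dtype=float)
        object.__setattr__(self, "conditional", arr)
        if arr.shape != (len(self.stage_levels), len(self.age_groups), 5):
            raise ValueError("conditional must have shape (stages, age groups, 5)")

    def validate(self) -> list[str]:
        problems = []
        if self.conditional.size != len(self.stage_levels) * len(self.age_groups) * 5:
            problems.append("wrong entry count")
        if np.any(self.conditional < 0) or np.any(self.conditional > 1):
            problems.append("entries outside [0, 1]")
        return problems

    def yearly(self, stage: str, age_group: str) -> np.ndarray:
        return self.conditional[self.stage_levels.index(stage), self.age_groups.index(age_group)]

    def five_year(self, stage: str, age_group: str) -> float:
        return float(np.prod(self.yearly(stage, age_group)))


@dataclass(frozen=True)
class EvidenceGapConstants:
    """Frequencies imputed where guidelines state only qualitative frequency.

    A condition or treatment described as occurring in "isolated cases" is
    carried at 5%; one described as "rare" or "second-line" at 10%.
    """

    isolated_cases_freq: float = 0.05
    rare_or_second_line_freq: float = 0.10


EVIDENCE_GAP = EvidenceGapConstants()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def build_age_specific_incidence(
    case_age_shares: Mapping[str, float] | Sequence[float],
    pop_age_structure: Mapping[str, float] | Sequence[float],
    crude_target: float,
    sex: str = "male",
    age_groups: Sequence[tuple[int, int]] | None = None,
    provenance: str = "",
) -> RateTable:
    """Convert case age shares into age-specific rates hitting a crude target.

    rate_g is proportional to case_share_g / pop_share_g, scaled so the
    population-weighted crude rate equals ``crude_target`` (events per 100,000
    person-years).  Both share vectors must sum to 1 over the modelled bins.
    """
    if isinstance(case_age_shares, Mapping):
        labels = list(case_age_shares)
        shares = np.array([case_age_shares[k] for k in labels], float)
        pop = np.array([pop_age_structure[k] for k in labels], float)
        if age_groups is None:
            age_groups = [_parse_age_label(k) for k in labels]
    else:
        shares = np.asarray(case_age_shares, float)
        pop = np.asarray(pop_age_structure, float)
    if crude_target <= 0:
        raise ValueError("crude_target must be positive")
    if abs(shares.sum() - 1.0) > 1e-6 or abs(pop.sum() - 1.0) > 1e-6:
        raise ValueError("case shares and population structure must each sum to 1")
    bad = (pop == 0) & (shares > 0)
    if np.any(bad):
        raise ValueError(f"unsupported stratum: zero population share with nonzero case share at index {np.nonzero(bad)[0][0]}")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(pop > 0, shares / pop, 0.0)
    # crude(raw) = sum(pop * shares/pop) = 1, so the scale factor is the target
    rates = raw * crude_target
    if age_groups is None:
        n = len(rates)
        age_groups = [(40 + 5 * i, 45 + 5 * i) for i in range(n)]
    return RateTable(sex=sex, age_groups=tuple(age_groups), rates=tuple(rates), provenance=provenance)


def _parse_age_label(label: str) -> tuple[int, int]:
    label = label.replace("–", "-")
    if label.endswith("+"):
        lo = int(label[:-1])
        return (lo, 100)
    lo, hi = label.split("-")
    return (int(lo), int(hi) + 1)


def derive_conditional_table(
    child_marginal: CategoricalDistribution,
    parent_dist: CategoricalDistribution,
    coupling: str | Mapping[str, float] = "independence",
    child_variable: str = "child",
    parent_variable: str = "parent",
) -> ConditionalTable:
    """Build P(child | parent) whose parent-marginalisation reproduces the child marginal.

    ``coupling="independence"`` copies the child marginal into every row (exact
    left-inverse of marginalisation).  A mapping ``{parent_level: odds_multiplier}``
    tilts a *binary* child: the odds of the first child level under parent
    level ``l`` are ``m_l`` times the odds under the reference (multiplier-1)
    level, solved so the marginal is preserved.  Raises ``ValueError`` when no
    solution keeps every row in [0, 1].
    """
    for d in (child_marginal, parent_dist):
        res = validate_distribution(d)
        if not res.ok:
            raise ValueError(f"invalid marginal: {res.violations}")
    if coupling == "independence":
        rows = {(lvl,): child_marginal for lvl in parent_dist.levels}
        return ConditionalTable(child_variable, (parent_variable,), rows)
    if not isinstance(coupling, Mapping):
        raise ValueError(f"unknown coupling {coupling!r}")
    if len(child_marginal.levels) != 2:
        raise ValueError("odds-multiplier coupling requires a binary child variable")
    mult = np.array([float(coupling.get(lvl, 1.0)) for lvl in parent_dist.levels])
    if np.any(mult <= 0):
        raise ValueError("odds multipliers must be positive")
    w = np.asarray(parent_dist.probs)
    target = child_marginal.probs[0]

    def marginal(odds_ref: float) -> float:
        o = mult * odds_ref
        return float(np.dot(w, o / (1.0 + o))) - target

    if target <= 0.0 or target >= 1.0:
        p_rows = np.full(len(w), target)
    else:
        lo, hi = 1e-12, 1e12
        if marginal(lo) > 0 or marginal(hi) < 0:
            raise ValueError("infeasible odds multipliers: no solution preserves the marginal in [0, 1]")
        odds_ref = brentq(marginal, lo, hi, xtol=1e-14, rtol=1e-14)
        o = mult * odds_ref
        p_rows = o / (1.0 + o)
    rows = {
        (lvl,): CategoricalDistribution(
            child_marginal.levels, (p, 1.0 - p),
            provenance=f"odds-multiplier coupling (m={coupling.get(lvl, 1.0)})",
        )
        for lvl, p in zip(parent_dist.levels, p_rows)
    }
    return ConditionalTable(child_variable, (parent_variable,), rows)


def build_survival_table(
    five_year_survival_by_stage: Mapping[str, float],
    age_multipliers: Mapping[str, float],
    cohort_age_weights: Mapping[str, float] | None = None,
    year_weights: Sequence[float] | None = None,
    provenance: str = "",
) -> SurvivalTable:
    """Expand 5-year survival anchors into the 100 yearly conditional nodes.

    By default the hazard is constant within the 5-year window: for the
    reference age group the yearly conditional survival is S5**(1/5); an age
    group with log-hazard multiplier m gets S5**(m/5).  ``year_weights`` (five
    nonnegative shares summing to 1) redistribute the cumulative log-hazard
    across the years — cancer mortality is front-loaded, so a declining
    profile can be calibrated against a printed 1-year survival anchor without
    disturbing the 5-year anchors.  When ``cohort_age_weights`` is given the
    multipliers are rescaled per stage (common positive factor) so that the
    weighted 5-year survival over age groups reproduces the stage anchor
    exactly; otherwise the multiplier-1 group is the reference.
    """
    stages = tuple(five_year_survival_by_stage)
    ages = tuple(age_multipliers)
    m = np.array([age_multipliers[a] for a in ages], float)
    if np.any(m <= 0):
        raise ValueError("age multipliers must be positive")
    if year_weights is None:
        yw = np.full(5, 0.2)
    else:
        yw = np.asarray(year_weights, float)
        if yw.shape != (5,) or np.any(yw < 0) or abs(yw.sum() - 1.0) > 1e-9:
            raise ValueError("year_weights must be five nonnegative shares summing to 1")
    cond = np.empty((len(stages), len(ages), 5))
    clipped = 0
    for i, s in enumerate(stages):
        s5 = float(five_year_survival_by_stage[s])
        if s5 <= 0.0:
            raise ValueError(f"degenerate survival for stage {s}; use an explicit yearly table instead")
        if s5 > 1.0:
            raise ValueError(f"5-year survival for stage {s} must be in (0, 1]")
        if cohort_age_weights is not None and s5 < 1.0:
            w = np.array([cohort_age_weights[a] for a in ages], float)
            w = w / w.sum()

            def anchor_gap(k: float) -> float:
                return float(np.dot(w, s5 ** (k * m))) - s5

            k = brentq(anchor_gap, 1e-9, 1e3, xtol=1e-15, rtol=1e-15)
            eff = k * m
        else:
            eff = m
        for j in range(len(ages)):
            for y_idx in range(5):
                y = s5 ** (eff[j] * 5.0 * yw[y_idx] / 5.0)
                if y > 1.0 or y < 0.0:
                    clipped += 1
                    y = min(max(y, 0.0), 1.0)
                cond[i, j, y_idx] = y
    note = provenance
    if clipped:
        note = f"{provenance} [{clipped} entries clipped to [0,1]]"
    return SurvivalTable(stages, ages, cond, provenance=note)


def apply_evidence_gap_rule(
    dist: CategoricalDistribution,
    flags: Mapping[str, str],
    constants: EvidenceGapConstants = EVIDENCE_GAP,
) -> CategoricalDistribution:
    """Impose the 5% (isolated cases) / 10% (rare, second-line) frequencies.

    Flagged levels receive their constant frequency; the remaining mass is
    distributed over the unflagged levels proportionally to their configured
    probabilities.
    """
    fixed = {}
    for lvl, flag in flags.items():
        if flag == "isolated":
            fixed[lvl] = constants.isolated_cases_freq
        elif flag in ("rare", "second-line"):
            fixed[lvl] = constants.rare_or_second_line_freq
        else:
            raise ValueError(f"unknown evidence-gap flag {flag!r}")
    spare = 1.0 - sum(fixed.values())
    if spare < 0:
        raise ValueError("flagged frequencies exceed 1")
    free_mass = sum(p for lvl, p in zip(dist.levels, dist.probs) if lvl not in fixed)
    probs = []
    for lvl, p in zip(dist.levels, dist.probs):
        if lvl in fixed:
            probs.append(fixed[lvl])
        else:
            probs.append(spare * (p / free_mass if free_mass > 0 else 1.0 / (len(dist.levels) - len(fixed))))
    return replace(dist, probs=tuple(probs),
                   provenance=f"{dist.provenance} [evidence-gap rule applied to {sorted(fixed)}]")


def rake_joint(
    marginals: Mapping[str, CategoricalDistribution],
    partition: Callable[[Mapping[str, str]], str] | None = None,
    partition_target: CategoricalDistribution | None = None,
    tol: float = 1e-12,
    max_iter: int = 5000,
) -> dict[tuple[str, ...], float]:
    """Iterative proportional fitting of a joint distribution.

    Starts from the independence joint of ``marginals`` and rakes it to match
    every single-variable marginal plus, optionally, the distribution of a
    derived label ``partition(cell)`` (each constraint is a partition of the
    cells, so classical IPF applies).  Returns cell -> probability keyed by the
    variable order of ``marginals``.  Raises if the constraints are infeasible
    (no convergence).
    """
    variables = list(marginals)
    level_sets = [marginals[v].levels for v in variables]
    cells = list(itertools.product(*level_sets))
    p = np.ones(len(cells))
    for ax, v in enumerate(variables):
        lookup = marginals[v].as_mapping()
        p *= np.array([lookup[c[ax]] for c in cells])
    targets: list[tuple[np.ndarray, np.ndarray]] = []
    for ax, v in enumerate(variables):
        labels = np.array([level_sets[ax].index(c[ax]) for c in cells])
        targets.append((labels, np.asarray(marginals[v].probs)))
    if partition is not None:
        if partition_target is None:
            raise ValueError("partition_target required with partition")
        lab_names = partition_target.levels
        labels = np.array([lab_names.index(partition(dict(zip(variables, c)))) for c in cells])
        targets.append((labels, np.asarray(partition_target.probs)))
    for _ in range(max_iter):
        worst = 0.0
        for labels, want in targets:
            got = np.bincount(labels, weights=p, minlength=len(want))
            worst = max(worst, float(np.max(np.abs(got - want))))
            with np.errstate(divide="ignore", invalid="ignore"):
                factor = np.where(got > 0, want / np.maximum(got, 1e-300), 0.0)
            p = p * factor[labels]
        if worst < tol:
            break
    else:
        raise ValueError(f"IPF did not converge (residual {worst:.3g}); constraints may be infeasible")
    return {cell: float(q) for cell, q in zip(cells, p)}


# ---------------------------------------------------------------------------
# bundle + serialization
# ---------------------------------------------------------------------------


@dataclass
class ParameterBundle:
    """Named collection of every table the disease module consumes."""

    distributions: dict[str, CategoricalDistribution] = field(default_factory=dict)
    conditionals: dict[str, ConditionalTable] = field(default_factory=dict)
    rate_tables: dict[str, RateTable] = field(default_factory=dict)
    survival: SurvivalTable | None = None
    flags: dict[str, dict[str, str]] = field(default_factory=dict)
    constants: EvidenceGapConstants = field(default_factory=EvidenceGapConstants)
    meta: dict[str, str] = field(default_factory=dict)

    # -- JSON ---------------------------------------------------------------

    def to_json(self) -> str:
        def dist(d: CategoricalDistribution) -> dict:
            return {"levels": list(d.levels), "probs": list(d.probs), "provenance": d.provenance}

        payload = {
            "meta": self.meta,
            "constants": {
                "isolated_cases_freq": self.constants.isolated_cases_freq,
                "rare_or_second_line_freq": self.constants.rare_or_second_line_freq,
            },
            "distributions": {k: dist(v) for k, v in self.distributions.items()},
            "conditionals": {
                k: {
                    "child_variable": t.child_variable,
                    "parent_variables": list(t.parent_variables),
                    "rows": [{"parents": list(key), **dist(v)} for key, v in t.rows.items()],
                }
                for k, t in self.conditionals.items()
            },
            "rate_tables": {
                k: {
                    "sex": r.sex,
                    "age_groups": [list(g) for g in r.age_groups],
                    "rates": list(r.rates),
                    "provenance": r.provenance,
                }
                for k, r in self.rate_tables.items()
            },
            "survival": None
            if self.survival is None
            else {
                "stage_levels": list(self.survival.stage_levels),
                "age_groups": list(self.survival.age_groups),
                "conditional": self.survival.conditional.tolist(),
                "provenance": self.survival.provenance,
            },
            "flags": self.flags,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ParameterBundle":
        raw = json.loads(text)

        def dist(d: dict) -> CategoricalDistribution:
            return CategoricalDistribution(tuple(d["levels"]), tuple(d["probs"]), d.get("provenance", ""))

        bundle = cls(meta=dict(raw.get("meta", {})))
        c = raw.get("constants", {})
        bundle.constants = EvidenceGapConstants(
            c.get("isolated_cases_freq", 0.05), c.get("rare_or_second_line_freq", 0.10)
        )
        bundle.distributions = {k: dist(v) for k, v in raw.get("distributions", {}).items()}
        bundle.conditionals = {
            k: ConditionalTable(
                v["child_variable"],
                tuple(v["parent_variables"]),
                {tuple(row["parents"]): dist(row) for row in v["rows"]},
            )
            for k, v in raw.get("conditionals", {}).items()
        }
        bundle.rate_tables = {
            k: RateTable(v["sex"], tuple(tuple(g) for g in v["age_groups"]), tuple(v["rates"]), v.get("provenance", ""))
            for k, v in raw.get("rate_tables", {}).items()
        }
        if raw.get("survival"):
            s = raw["survival"]
            bundle.survival = SurvivalTable(
                tuple(s["stage_levels"]), tuple(s["age_groups"]), np.array(s["conditional"]), s.get("provenance", "")
            )
        bundle.flags = {k: dict(v) for k, v in raw.get("flags", {}).items()}
        return bundle

    # -- CSV ----------------------------------------------------------------

    _CSV_HEADER = ["variable", "parent_variables", "parent_values", "level", "probability", "provenance"]

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(self._CSV_HEADER)
        for name, d in self.distributions.items():
            for lvl, p in zip(d.levels, d.probs):
                w.writerow([name, "", "", lvl, repr(p), d.provenance])
        for name, t in self.conditionals.items():
            for key, d in t.rows.items():
                for lvl, p in zip(d.levels, d.probs):
                    w.writerow([name, "|".join(t.parent_variables), "|".join(key), lvl, repr(p), d.provenance])
        for name, r in self.rate_tables.items():
            for (lo, hi), rate in zip(r.age_groups, r.rates):
                w.writerow([f"rate:{name}", "sex", r.sex, f"{lo}-{hi}", repr(rate), r.provenance])
        if self.survival is not None:
            s = self.survival
            for i, stage in enumerate(s.stage_levels):
                for j, ag in enumerate(s.age_groups):
                    for y in range(5):
                        w.writerow(
                            ["survival", "stage|age_group", f"{stage}|{ag}", f"year{y + 1}",
                             repr(float(s.conditional[i, j, y])), s.provenance]
                        )
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "ParameterBundle":
        bundle = cls()
        dist_rows: dict[str, list] = {}
        cond_rows: dict[str, dict] = {}
        rate_rows: dict[str, dict] = {}
        surv_rows: list = []
        for row in csv.DictReader(io.StringIO(text)):
            var, pv, pvals, lvl, p, prov = (
                row["variable"], row["parent_variables"], row["parent_values"],
                row["level"], float(row["probability"]), row["provenance"],
            )
            if var == "survival":
                stage, ag = pvals.split("|")
                surv_rows.append((stage, ag, int(lvl[4:]), p, prov))
            elif var.startswith("rate:"):
                rate_rows.setdefault(var[5:], {"sex": pvals, "groups": [], "prov": prov})
                lo, hi = lvl.split("-")
                rate_rows[var[5:]]["groups"].append(((int(lo), int(hi)), p))
            elif pv:
                cond_rows.setdefault(var, {"parents": tuple(pv.split("|")), "rows": {}})
                cond_rows[var]["rows"].setdefault(tuple(pvals.split("|")), []).append((lvl, p, prov))
            else:
                dist_rows.setdefault(var, []).append((lvl, p, prov))
        for name, entries in dist_rows.items():
            bundle.distributions[name] = CategoricalDistribution(
                tuple(e[0] for e in entries), tuple(e[1] for e in entries), entries[0][2]
            )
        for name, spec in cond_rows.items():
            rows = {
                key: CategoricalDistribution(tuple(e[0] for e in entries), tuple(e[1] for e in entries), entries[0][2])
                for key, entries in spec["rows"].items()
            }
            bundle.conditionals[name] = ConditionalTable(name, spec["parents"], rows)
        for name, spec in rate_rows.items():
            bundle.rate_tables[name] = RateTable(
                spec["sex"], tuple(g for g, _ in spec["groups"]), tuple(r for _, r in spec["groups"]), spec["prov"]
            )
        if surv_rows:
            stages = list(dict.fromkeys(r[0] for r in surv_rows))
            ages = list(dict.fromkeys(r[1] for r in surv_rows))
            cond = np.zeros((len(stages), len(ages), 5))
            for stage, ag, year, p, prov in surv_rows:
                cond[stages.index(stage), ages.index(ag), year - 1] = p
            bundle.survival = SurvivalTable(tuple(stages), tuple(ages), cond, surv_rows[0][4])
        return bundle
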