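"""Incidence-view cohort construction from a prevalence-style pool.

A prevalence (or enriched-prevalence) dataset is a cross-section: its alive
bucket over-represents cases diagnosed recently and under-represents cases
with poor survival.  For survival analysis a cohort is needed that contains
diagnosed cases *alive and dead*, matched to the real-world age-at-diagnosis
and sex distribution.  ``max_feasible_cohort`` computes the largest total
cohort the pool supports ("as many as possible") and ``draw_cohort`` samples
it without replacement per stratum.

``generate_reference_cohort`` synthesizes a cohort of diagnosed cases directly
at the target mix (no pool) — used both for fast calibration studies and as
the reference follow-up sample in the validation battery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .demography import WEEKS_PER_YEAR
from .engine import PopulationDataset, PersonRecord, default_target_week
from .larynx import (
    CONDITION_LABEL,
    assign_adjuvant,
    assign_initial_treatment,
    sample_survival_time,
    sample_tumor_characteristics,
)
from .registry import (
    AGE_AT_DIAGNOSIS_PERCENT,
    COHORT_AGE_BANDS,
    SEX_SHARE_PERCENT,
    cohort_age_band,
)
from .tables import ParameterBundle

__all__ = [
    "CohortTarget",
    "CohortRecord",
    "CohortDataset",
    "registry_cohort_target",
    "max_feasible_cohort",
    "draw_cohort",
    "generate_reference_cohort",
    "pool_case_counts",
]

FOLLOWUP_CAP_WEEKS = 5 * WEEKS_PER_YEAR

Stratum = tuple[str, str]  # (sex, age band at diagnosis)


@dataclass(frozen=True)
class CohortTarget:
    """Target share per (sex x 10-year age-at-diagnosis band) stratum."""

    shares: Mapping[Stratum, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "shares", dict(self.shares))
        total = math.fsum(self.shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stratum shares must sum to 1 (got {total:g})")
        if any(s < 0 for s in self.shares.values()):
            raise ValueError("negative stratum share")


def registry_cohort_target() -> CohortTarget:
    """The registry age/sex-at-diagnosis mix (share = sex share x age | sex)."""
    shares = {}
    for sex in ("male", "female"):
        sex_share = SEX_SHARE_PERCENT[sex] / 100.0
        age = AGE_AT_DIAGNOSIS_PERCENT[sex]
        age_total = sum(age.values())
        for band, _, _ in COHORT_AGE_BANDS:
            shares[(sex, band)] = sex_share * age[band] / age_total
    return CohortTarget(shares)


@dataclass(frozen=True)
class CohortRecord:
    person_id: str
    sex: str
    age_group: str
    age_at_diagnosis: float
    diagnosis_week: int
    T: str
    N: str
    M: str
    UICC: str
    grading: str
    ecog: int
    localization: str
    initial_treatment: str
    neck_dissection: str
    r_status: str
    adjuvant: str
    followup_weeks: int
    event: bool


@dataclass
class CohortDataset:
    records: list[CohortRecord]
    quotas: dict[Stratum, int]
    seed: int
    target_week: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def survival_arrays(self, uicc: str | None = None, sex: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        recs = [r for r in self.records
                if (uicc is None or r.UICC == uicc) and (sex is None or r.sex == sex)]
        times = np.array([r.followup_weeks for r in recs], float)
        events = np.array([r.event for r in recs], bool)
        return times, events


# ---------------------------------------------------------------------------
# quota arithmetic
# ---------------------------------------------------------------------------


def max_feasible_cohort(
    pool_counts: Mapping[Stratum, int], target: CohortTarget
) -> tuple[int, dict[Stratum, int]]:
    """Largest total N (and per-stratum quotas) the pool supports at the target mix.

    N = floor(min over strata of pool_s / share_s); quotas are rounded by
    largest remainder so they sum to N and never exceed availability.  A
    stratum with positive share and an empty pool forces N = 0.
    """
    n = None
    for stratum, share in target.shares.items():
        if share <= 0:
            continue
        avail = pool_counts.get(stratum, 0)
        bound = math.floor(avail / share)
        n = bound if n is None else min(n, bound)
    n = int(n or 0)
    if n == 0:
        empty = [s for s, share in target.shares.items() if share > 0 and pool_counts.get(s, 0) == 0]
        if empty:
            return 0, {s: 0 for s in target.shares}
    strata = list(target.shares)
    raw = np.array([n * target.shares[s] for s in strata])
    base = np.floor(raw).astype(int)
    short = n - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    for idx in order:
        if short <= 0:
            break
        if base[idx] + 1 <= pool_counts.get(strata[idx], 0):
            base[idx] += 1
            short -= 1
    # availability guard (binding strata may sit exactly at their pool count)
    for i, s in enumerate(strata):
        if base[i] > pool_counts.get(s, 0):
            base[i] = pool_counts.get(s, 0)
    return n, {s: int(q) for s, q in zip(strata, base)}


def pool_case_counts(
    pool: PopulationDataset, condition_label: str = CONDITION_LABEL
) -> dict[Stratum, int]:
    counts: dict[Stratum, int] = {}
    for _, _, stratum in _iter_cases(pool, condition_label):
        counts[stratum] = counts.get(stratum, 0) + 1
    return counts


def _iter_cases(pool: PopulationDataset, condition_label: str):
    target = pool.config.target_week
    for person in pool.all_records():
        dx = person.diagnosis_week(condition_label)
        if dx is None or dx > target:
            continue
        age_dx = person.age_years(dx)
        band = cohort_age_band(age_dx)
        if band is None:
            continue
        yield person, dx, (person.sex, band)


# ---------------------------------------------------------------------------
# cohort drawing
# ---------------------------------------------------------------------------


def _followup(person_death: int | None, dx: int, target_week: int) -> tuple[int, bool]:
    cap = min(FOLLOWUP_CAP_WEEKS, target_week - dx)
    if person_death is not None and person_death - dx <= cap:
        return max(person_death - dx, 0), True
    return cap, False


def draw_cohort(
    pool: PopulationDataset,
    quotas: Mapping[Stratum, int],
    seed: int,
    condition_label: str = CONDITION_LABEL,
) -> CohortDataset:
    """Simple random sample without replacement within each stratum.

    Alive and deceased cases enter the same stratum pools — that is the point
    of the cohort view.  Follow-up runs from diagnosis to death, censored at
    five years or at the target date, whichever comes first.
    """
    by_stratum: dict[Stratum, list[tuple[PersonRecord, int]]] = {}
    for person, dx, stratum in _iter_cases(pool, condition_label):
        by_stratum.setdefault(stratum, []).append((person, dx))
    rng = np.random.default_rng(seed)
    records: list[CohortRecord] = []
    target = pool.config.target_week
    for stratum in sorted(quotas):
        quota = quotas[stratum]
        candidates = by_stratum.get(stratum, [])
        if quota > len(candidates):
            raise ValueError(
                f"quota {quota} exceeds availability {len(candidates)} in stratum {stratum}; "
                "call max_feasible_cohort first"
            )
        idx = rng.choice(len(candidates), size=quota, replace=False) if quota else []
        for i in sorted(int(j) for j in np.atleast_1d(idx)):
            person, dx = candidates[i]
            fu, event = _followup(person.death_week, dx, target)
            a = person.attributes
            records.append(CohortRecord(
                person_id=person.id, sex=person.sex, age_group=stratum[1],
                age_at_diagnosis=person.age_years(dx), diagnosis_week=dx,
                T=a.get("T", ""), N=a.get("N", ""), M=a.get("M", ""), UICC=a.get("UICC", ""),
                grading=a.get("grading", ""), ecog=int(a.get("ecog", -1)),
                localization=a.get("localization", ""),
                initial_treatment=a.get("initial_treatment", ""),
                neck_dissection=a.get("neck_dissection", ""),
                r_status=a.get("r_status", ""), adjuvant=a.get("adjuvant", ""),
                followup_weeks=int(fu), event=bool(event),
            ))
    return CohortDataset(records, dict(quotas), seed, target)


# ---------------------------------------------------------------------------
# direct cohort-mode generation
# ---------------------------------------------------------------------------


def generate_reference_cohort(
    n: int,
    bundle: ParameterBundle,
    seed: int,
    target: CohortTarget | None = None,
    target_week: int | None = None,
    diagnosis_window_years: int = 25,
) -> CohortDataset:
    """Synthesize diagnosed cases directly at the target age/sex mix.

    Each case gets a diagnosis age uniform within its stratum band, a
    diagnosis date uniform over the lookback window, a dependent tumor
    profile, a treatment plan, and a survival time from the 5-year submodule;
    follow-up is censored at five years or the target date.
    """
    target = target or registry_cohort_target()
    target_week = default_target_week() if target_week is None else target_week
    strata = sorted(target.shares)
    raw = np.array([n * target.shares[s] for s in strata])
    base = np.floor(raw).astype(int)
    order = np.argsort(-(raw - base), kind="stable")
    base[order[: n - int(base.sum())]] += 1
    band_range = {label: (lo, hi) for label, lo, hi in COHORT_AGE_BANDS}
    rng = np.random.default_rng(seed)
    records: list[CohortRecord] = []
    counter = 0
    for stratum, quota in zip(strata, base):
        sex, band = stratum
        lo, hi = band_range[band]
        for _ in range(int(quota)):
            age_dx = float(rng.uniform(lo, hi))
            dx_week = target_week - int(rng.integers(0, diagnosis_window_years * WEEKS_PER_YEAR))
            tc = sample_tumor_characteristics(sex, bundle, rng)
            plan = assign_adjuvant(assign_initial_treatment(tc, bundle, rng), tc, bundle, rng)
            offset = sample_survival_time(tc.UICC, age_dx, bundle.survival, rng)
            death = dx_week + offset if offset is not None else None
            fu, event = _followup(death, dx_week, target_week)
            records.append(CohortRecord(
                person_id=f"ref-{counter}", sex=sex, age_group=band,
                age_at_diagnosis=age_dx, diagnosis_week=dx_week,
                T=tc.T, N=tc.N, M=tc.M, UICC=tc.UICC, grading=tc.grading, ecog=tc.ecog,
                localization=tc.localization, initial_treatment=plan.initial,
                neck_dissection=plan.neck_dissection, r_status=plan.r_status or "",
                adjuvant=plan.adjuvant, followup_weeks=int(fu), event=bool(event),
            ))
            counter += 1
    quotas = {s: int(q) for s, q in zip(strata, base)}
    return CohortDataset(records, quotas, seed, target_week)
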