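"""The laryngeal cancer disease model.

Covers the full clinical arc of one synthetic case: onset (age/sex-specific
incidence gate), descriptive risk factors, dependent tumor characterisation
(T by sex, N by T and sex, M by T and N, UICC stage deterministic from TNM,
then grading, localisation, HPV, precursor lesion and ECOG by stage),
treatment assignment with the 5%/10% evidence-gap rules, the four key
encounters with the healthcare system (first doctor visit, second visit with
confirmed diagnosis, initial treatment, adjuvant therapy) plus symptom onsets
up to one year before diagnosis, and the 5-year survival submodule.

Everything is exposed both as plain sampling operations and as a JSON
ModuleDefinition (``laryngeal_cancer.json``) interpreted by the engine; the
engine's action states call back into the operations below, so both routes
execute the same code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

from .engine import (
    EngineContext,
    ModuleDefinition,
    PersonRecord,
    State,
    Transition,
    load_module_definition,
)
from .demography import WEEKS_PER_YEAR
from .registry import survival_age_group, uicc_from_tnm
from .tables import (
    CategoricalDistribution,
    ParameterBundle,
    SurvivalTable,
    apply_evidence_gap_rule,
)

__all__ = [
    "CONDITION_LABEL",
    "TumorCharacteristics",
    "TreatmentPlan",
    "EncounterTimeline",
    "uicc_from_tnm",
    "sample_tumor_characteristics",
    "assign_initial_treatment",
    "assign_adjuvant",
    "sample_survival_time",
    "build_timeline",
    "build_laryngeal_module",
    "load_shipped_module",
    "larynx_actions",
    "SURGICAL_TREATMENTS",
    "SYMPTOMS",
]

CONDITION_LABEL = "Laryngeal cancer"
CONDITION_CODE = "ICD-10:C32"
SURVIVAL_WINDOW_WEEKS = 5 * WEEKS_PER_YEAR

SURGICAL_TREATMENTS = frozenset(
    {"open partial laryngectomy", "transoral partial laryngectomy", "laryngectomy"}
)
SYMPTOMS = ("hoarseness", "otalgia", "dysphagia", "insomnia",
            "mouth symptoms", "chest infection", "sore throat", "dysphonia")

# default care intervals in weeks (configurable plausible values; the clinical
# sources state the encounter sequence, not its spacing)
FIRST_TO_SECOND_VISIT_WEEKS = (1, 4)
SECOND_VISIT_TO_TREATMENT_WEEKS = (2, 6)
TREATMENT_TO_ADJUVANT_WEEKS = (4, 12)
SYMPTOM_WINDOW_WEEKS = 52


@dataclass(frozen=True)
class TumorCharacteristics:
    T: str
    N: str
    M: str
    UICC: str
    grading: str
    localization: str
    hpv: bool
    precursor: str
    ecog: int
    metastasis_sites: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if uicc_from_tnm(self.T, self.N, self.M) != self.UICC:
            raise ValueError(f"UICC {self.UICC} inconsistent with ({self.T},{self.N},{self.M})")
        if (self.M == "M1") != bool(self.metastasis_sites):
            raise ValueError("metastasis sites must be nonempty iff M1")


@dataclass(frozen=True)
class TreatmentPlan:
    initial: str
    neck_dissection: str = "none"
    r_status: str | None = None
    adjuvant: str = "none"

    def __post_init__(self) -> None:
        surgical = self.initial in SURGICAL_TREATMENTS
        if surgical != (self.r_status is not None):
            raise ValueError("R status present iff initial treatment is surgical")
        if not surgical and self.adjuvant != "none":
            raise ValueError("adjuvant therapy only after surgical initial treatment")


@dataclass(frozen=True)
class EncounterTimeline:
    diagnosis_week: int
    symptom_onsets: tuple[tuple[str, int], ...]
    first_visit_week: int
    second_visit_week: int
    initial_treatment_week: int
    adjuvant_week: int | None = None

    def __post_init__(self) -> None:
        if not (self.first_visit_week <= self.second_visit_week
                <= self.initial_treatment_week
                <= (self.adjuvant_week if self.adjuvant_week is not None else self.initial_treatment_week)):
            raise ValueError("encounter ordering violated")
        for label, week in self.symptom_onsets:
            if not (self.diagnosis_week - SYMPTOM_WINDOW_WEEKS <= week <= self.diagnosis_week):
                raise ValueError(f"symptom {label} outside the one-year pre-diagnosis window")


# ---------------------------------------------------------------------------
# sampling operations
# ---------------------------------------------------------------------------


def sample_tumor_characteristics(
    sex: str, tables: ParameterBundle, rng: np.random.Generator
) -> TumorCharacteristics:
    """Sample a dependent tumor profile: T|sex -> N|T,sex -> M|T,N -> stage -> rest."""
    t_parent = tables.distributions[f"T:{sex}"].sample(rng)
    n = tables.conditionals["N|T"].sample((sex, t_parent), rng)
    m = tables.conditionals["M|TN"].sample((sex, t_parent, n), rng)
    uicc = uicc_from_tnm(t_parent, n, m)
    t = t_parent
    if t_parent in ("T1", "T4"):
        t = tables.distributions[f"{t_parent}_split"].sample(rng)
    sites: tuple[str, ...] = ()
    if m == "M1":
        sites = (tables.distributions["metastasis_site"].sample(rng),)
    return TumorCharacteristics(
        T=t, N=n, M=m, UICC=uicc,
        grading=tables.distributions[f"grading:{sex}"].sample(rng),
        localization=tables.distributions["localization"].sample(rng),
        hpv=tables.distributions["hpv"].sample(rng) == "yes",
        precursor=tables.distributions["precursor"].sample(rng),
        ecog=int(tables.conditionals["ecog"].sample((uicc,), rng)),
        metastasis_sites=sites,
    )


def assign_initial_treatment(
    tc: TumorCharacteristics, tables: ParameterBundle, rng: np.random.Generator
) -> TreatmentPlan:
    """Sample the initial treatment for the tumor's stage stratum.

    Options flagged "rare"/"second-line" in the bundle receive the 10%
    evidence-gap frequency, "isolated cases" 5%, with the remaining first-line
    mass renormalised.  Surgical treatments get a neck-dissection decision and
    a resection (R) status.
    """
    row = tables.conditionals["initial_treatment"].row((tc.UICC,))
    flags = tables.flags.get("initial_treatment", {})
    if flags:
        row = apply_evidence_gap_rule(row, flags, tables.constants)
    initial = row.sample(rng)
    if initial in SURGICAL_TREATMENTS:
        return TreatmentPlan(
            initial=initial,
            neck_dissection=tables.conditionals["neck_dissection"].sample((tc.UICC,), rng),
            r_status=tables.distributions["r_status"].sample(rng),
        )
    return TreatmentPlan(initial=initial)


def assign_adjuvant(
    plan: TreatmentPlan, tc: TumorCharacteristics, tables: ParameterBundle, rng: np.random.Generator
) -> TreatmentPlan:
    """Sample postoperative therapy; non-surgical initial treatment gets none.

    The adjuvant row is keyed by resection status, so incomplete resections
    (R1/R2) can be routed to a more aggressive postoperative mix.
    """
    if plan.initial not in SURGICAL_TREATMENTS:
        return plan
    adjuvant = tables.conditionals["adjuvant"].sample((plan.r_status,), rng)
    return TreatmentPlan(plan.initial, plan.neck_dissection, plan.r_status, adjuvant)


def sample_survival_time(
    uicc: str, age_at_diagnosis: float, table: SurvivalTable, rng: np.random.Generator
) -> int | None:
    """Death week offset within the 5-year window, or None if alive at 5 years.

    Survival is a Bernoulli chain over the five yearly conditional nodes of
    the (stage, age group) cell; the death week is uniform within the failing
    year.  Survivors of the window revert to background mortality.
    """
    yearly = table.yearly(uicc, survival_age_group(age_at_diagnosis))
    for year in range(5):
        if rng.uniform() >= yearly[year]:
            return year * WEEKS_PER_YEAR + int(rng.integers(0, WEEKS_PER_YEAR))
    return None


def build_timeline(
    tc: TumorCharacteristics,
    plan: TreatmentPlan,
    diagnosis_week: int,
    tables: ParameterBundle,
    rng: np.random.Generator,
) -> EncounterTimeline:
    """Lay out symptoms and the four key encounters around the diagnosis week.

    Each symptom is present independently at its configured frequency with
    onset uniform in the year before diagnosis; the second doctor visit (where
    the diagnosis is confirmed) pins the diagnosis week.
    """
    onsets = []
    for name in SYMPTOMS:
        dist = tables.distributions[f"symptom:{name}"]
        if rng.uniform() < dist.prob("yes"):
            onsets.append((name, diagnosis_week - int(rng.integers(0, SYMPTOM_WINDOW_WEEKS + 1))))
    second = diagnosis_week
    first = second - int(rng.integers(*_incl(FIRST_TO_SECOND_VISIT_WEEKS)))
    treatment = second + int(rng.integers(*_incl(SECOND_VISIT_TO_TREATMENT_WEEKS)))
    adjuvant = None
    if plan.adjuvant != "none":
        adjuvant = treatment + int(rng.integers(*_incl(TREATMENT_TO_ADJUVANT_WEEKS)))
    return EncounterTimeline(
        diagnosis_week=diagnosis_week,
        symptom_onsets=tuple(onsets),
        first_visit_week=first,
        second_visit_week=second,
        initial_treatment_week=treatment,
        adjuvant_week=adjuvant,
    )


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    return rng_pair[0], rng_pair[1] + 1


# ---------------------------------------------------------------------------
# engine actions
# ---------------------------------------------------------------------------


def _act_risk_profile(person: PersonRecord, week: int, rng, context: EngineContext, payload) -> None:
    b = context.bundle
    person.attributes["smoking"] = b.distributions["smoking"].sample(rng)
    person.attributes["alcohol"] = b.distributions["alcohol"].sample(rng)
    return None


def _act_characterize_tumor(person: PersonRecord, week: int, rng, context: EngineContext, payload) -> None:
    tc = sample_tumor_characteristics(person.sex, context.bundle, rng)
    person.attributes["_tumor"] = tc
    person.attributes.update({
        "T": tc.T, "N": tc.N, "M": tc.M, "UICC": tc.UICC, "grading": tc.grading,
        "localization": tc.localization, "hpv": "yes" if tc.hpv else "no",
        "precursor": tc.precursor, "ecog": tc.ecog,
        "metastasis_sites": "|".join(tc.metastasis_sites),
    })
    return None


def _act_assign_treatment(person: PersonRecord, week: int, rng, context: EngineContext, payload) -> None:
    tc: TumorCharacteristics = person.attributes["_tumor"]
    plan = assign_adjuvant(assign_initial_treatment(tc, context.bundle, rng), tc, context.bundle, rng)
    person.attributes["_plan"] = plan
    person.attributes.update({
        "initial_treatment": plan.initial,
        "neck_dissection": plan.neck_dissection,
        "r_status": plan.r_status or "",
        "adjuvant": plan.adjuvant,
    })
    return None


def _act_build_timeline(person: PersonRecord, week: int, rng, context: EngineContext, payload) -> None:
    tc: TumorCharacteristics = person.attributes["_tumor"]
    plan: TreatmentPlan = person.attributes["_plan"]
    tl = build_timeline(tc, plan, week, context.bundle, rng)
    for name, onset in tl.symptom_onsets:
        person.add_event(onset, "observation", name, detail="symptom onset")
    person.add_event(tl.first_visit_week, "encounter", "first doctor visit",
                     detail="history and physical examination; laryngeal cancer suspected")
    person.add_event(tl.second_visit_week, "encounter", "second doctor visit",
                     detail="diagnostic confirmation of laryngeal cancer")
    person.add_event(tl.initial_treatment_week, "procedure", plan.initial, detail="initial treatment")
    if plan.neck_dissection != "none":
        person.add_event(tl.initial_treatment_week, "procedure", f"{plan.neck_dissection} neck dissection")
    if tl.adjuvant_week is not None:
        person.add_event(tl.adjuvant_week, "procedure", plan.adjuvant, detail="adjuvant therapy")
    person.attributes["initial_treatment_week"] = tl.initial_treatment_week
    return None


def _act_survival_submodule(person: PersonRecord, week: int, rng, context: EngineContext, payload) -> None:
    tc: TumorCharacteristics = person.attributes["_tumor"]
    age = person.age_years(week)
    offset = sample_survival_time(tc.UICC, age, context.bundle.survival, rng)
    if offset is not None:
        person.attributes["cancer_death_week"] = week + offset
        person.attributes["cancer_died"] = True
    else:
        person.attributes["survived_window_until"] = week + SURVIVAL_WINDOW_WEEKS
        person.attributes["cancer_died"] = False
        # long-term survivors keep the excess over background implied by the
        # final window year (persistent excess mortality of cancer survivors)
        c5 = context.bundle.survival.yearly(tc.UICC, survival_age_group(age))[4]
        person.attributes["final_year_hazard"] = float(-np.log(max(c5, 1e-12)))
    return None


def larynx_actions() -> dict:
    return {
        "risk_profile": _act_risk_profile,
        "characterize_tumor": _act_characterize_tumor,
        "assign_treatment": _act_assign_treatment,
        "build_timeline": _act_build_timeline,
        "survival_submodule": _act_survival_submodule,
    }


# ---------------------------------------------------------------------------
# module definition
# ---------------------------------------------------------------------------

_SH = "Cancer Registry Schleswig-Holstein, laryngeal cancer 1997-2021"
_S3 = "German S3 guideline for laryngeal cancer"


def build_laryngeal_module() -> ModuleDefinition:
    """Construct the laryngeal cancer module as an engine state machine."""
    states = {
        "Initial": State("Initial", "Initial",
                         transitions=(Transition("OnsetGate"),),
                         provenance="module entry"),
        "OnsetGate": State(
            "OnsetGate", "Delay",
            payload={"hazard_table": "incidence", "on_fire": "RiskProfile", "on_expire": "NoDisease"},
            provenance=f"{_SH}: gender- and age-specific probability of disease, age <40 excluded",
        ),
        "NoDisease": State("NoDisease", "Terminal", provenance="person never develops laryngeal cancer"),
        "RiskProfile": State(
            "RiskProfile", "Simple", payload={"action": "risk_profile"},
            transitions=(Transition("TumorCharacterization"),),
            provenance="risk factor frequencies: placeholder estimates (smoking/alcohol literature)",
        ),
        "TumorCharacterization": State(
            "TumorCharacterization", "Simple", payload={"action": "characterize_tumor"},
            transitions=(Transition("Diagnosis"),),
            provenance=f"{_SH}: T by sex, N by T and sex, M by T and N; UICC compiled from TNM",
        ),
        "Diagnosis": State(
            "Diagnosis", "ConditionOnset",
            payload={"label": CONDITION_LABEL, "code": CONDITION_CODE},
            transitions=(Transition("TreatmentAssignment"),),
            provenance="diagnosis confirmed at the second doctor visit",
        ),
        "TreatmentAssignment": State(
            "TreatmentAssignment", "Simple", payload={"action": "assign_treatment"},
            transitions=(Transition("CareTimeline"),),
            provenance=f"{_S3}; second-line options carried at the 10% evidence-gap frequency",
        ),
        "CareTimeline": State(
            "CareTimeline", "Simple", payload={"action": "build_timeline"},
            transitions=(Transition("SurvivalSubmodule"),),
            provenance="four key encounters; symptom onset up to one year before diagnosis",
        ),
        "SurvivalSubmodule": State(
            "SurvivalSubmodule", "Simple", payload={"action": "survival_submodule"},
            transitions=(
                Transition("CancerDeath", condition={"attr": "cancer_died", "op": "eq", "value": True}),
                Transition("Survivorship"),
            ),
            provenance=f"{_SH}: 5-year overall survival by stage and age group (100 yearly nodes)",
        ),
        "CancerDeath": State(
            "CancerDeath", "Death", payload={"week_attribute": "cancer_death_week"},
            provenance="death within the 5-year survival window (all-cause anchors)",
        ),
        "Survivorship": State(
            "Survivorship", "Terminal",
            provenance="alive at 5 years; reverts to background mortality",
        ),
    }
    module = ModuleDefinition("laryngeal_cancer", states, "Initial")
    module.validate()
    return module


def load_shipped_module() -> ModuleDefinition:
    """Load ``laryngeal_cancer.json`` as shipped in the package data."""
    text = resources.files("larynxsim").joinpath("data/laryngeal_cancer.json").read_text()
    return load_module_definition(text)
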