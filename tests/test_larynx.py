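"""Laryngeal cancer disease model: staging, treatment, survival, timeline."""

import numpy as np
import pytest

from larynxsim.larynx import (
    SURGICAL_TREATMENTS,
    SYMPTOMS,
    TumorCharacteristics,
    assign_adjuvant,
    assign_initial_treatment,
    build_timeline,
    sample_survival_time,
    sample_tumor_characteristics,
    uicc_from_tnm,
)
from larynxsim.registry import survival_age_group
from larynxsim.tables import (
    CategoricalDistribution,
    ConditionalTable,
    ParameterBundle,
    build_survival_table,
)

# condensed stage mapping transcribed independently of the implementation:
# M1 -> IV; T4 or N2/N3 -> IV; T3 or N1 -> III; T2 -> II; T1 -> I
EXPECTED_STAGE = {}
for _t, _base in (("T1", "I"), ("T1a", "I"), ("T1b", "I"), ("T2", "II"),
                  ("T3", "III"), ("T4", "IV"), ("T4a", "IV"), ("T4b", "IV")):
    for _n in ("N0", "N1", "N2", "N3"):
        for _m in ("M0", "M1"):
            if _m == "M1" or _n in ("N2", "N3") or _base == "IV":
                stage = "IV"
            elif _n == "N1" or _base == "III":
                stage = "III"
            else:
                stage = _base
            EXPECTED_STAGE[(_t, _n, _m)] = stage


class TestUiccMapping:
    def test_metastasis_dominates(self):
        assert uicc_from_tnm("T1", "N0", "M1") == "IV"

    def test_low_stage_examples(self):
        assert uicc_from_tnm("T1", "N0", "M0") == "I"
        assert uicc_from_tnm("T2", "N0", "M0") == "II"

    def test_exhaustive_enumeration(self):
        for (t, n, m), want in EXPECTED_STAGE.items():
            assert uicc_from_tnm(t, n, m) == want, (t, n, m)


def degenerate_bundle() -> ParameterBundle:
    """Every distribution concentrated: always (T1, N0, M0, G2, glottis)."""
    b = ParameterBundle()
    point = lambda lvl, levels: CategoricalDistribution(
        tuple(levels), tuple(1.0 if x == lvl else 0.0 for x in levels))
    b.distributions["T:male"] = point("T1", ("T1", "T2", "T3", "T4"))
    b.distributions["T1_split"] = point("T1a", ("T1a", "T1b"))
    b.distributions["T4_split"] = point("T4a", ("T4a", "T4b"))
    b.distributions["grading:male"] = point("G2", ("G1", "G2", "G3"))
    b.distributions["localization"] = point("glottis", ("glottis", "supraglottis", "subglottis"))
    b.distributions["hpv"] = point("no", ("yes", "no"))
    b.distributions["precursor"] = point("none", ("none", "severe"))
    b.distributions["metastasis_site"] = point("lung", ("lung", "bone"))
    b.conditionals["N|T"] = ConditionalTable("N", ("sex", "T"), {
        ("male", "T1"): point("N0", ("N0", "N1", "N2", "N3"))})
    b.conditionals["M|TN"] = ConditionalTable("M", ("sex", "T", "N"), {
        ("male", "T1", "N0"): point("M0", ("M0", "M1"))})
    b.conditionals["ecog"] = ConditionalTable("ecog", ("UICC",), {
        ("I",): point("0", ("0", "1", "2", "3", "4", "5"))})
    return b


class TestTumorSampling:
    def test_degenerate_tables_force_the_tumor(self, rng):
        b = degenerate_bundle()
        for _ in range(25):
            tc = sample_tumor_characteristics("male", b, rng)
            assert (tc.T, tc.N, tc.M, tc.UICC) == ("T1a", "N0", "M0", "I")
            assert tc.grading == "G2" and tc.localization == "glottis"
            assert tc.metastasis_sites == ()

    def test_missing_table_row_names_the_stratum(self, rng):
        b = degenerate_bundle()
        b.distributions["T:female"] = b.distributions["T:male"]
        b.distributions["grading:female"] = b.distributions["grading:male"]
        # the N|T table has no (female, T1) row; the error must name it
        with pytest.raises(KeyError, match="sex.*female.*T1"):
            sample_tumor_characteristics("female", b, rng)

    def test_marginal_frequency_recovery(self, bundle, rng):
        # sampled T/N/M marginals stay within 99% binomial bands of the inputs
        n = 12000
        draws = [sample_tumor_characteristics("male", bundle, rng) for _ in range(n)]
        t_input = bundle.distributions["T:male"].as_mapping()
        for level, p in t_input.items():
            freq = np.mean([tc.T.startswith(level) for tc in draws])
            band = 3.29 * np.sqrt(p * (1 - p) / n)
            assert abs(freq - p) < band + 1e-9, level
        n0 = bundle.distributions["N_marginal:male"].prob("N0")
        freq = np.mean([tc.N == "N0" for tc in draws])
        assert abs(freq - n0) < 3.29 * np.sqrt(n0 * (1 - n0) / n)

    def test_uicc_consistency_on_every_draw(self, bundle, rng):
        for _ in range(2000):
            tc = sample_tumor_characteristics("male", bundle, rng)
            assert tc.UICC == uicc_from_tnm(tc.T, tc.N, tc.M)
            assert (tc.M == "M1") == bool(tc.metastasis_sites)

    def test_inconsistent_characteristics_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            TumorCharacteristics("T1", "N0", "M0", "IV", "G2", "glottis", False, "none", 0)


def treatment_bundle(rows, flags=None, adjuvant_rows=None):
    b = ParameterBundle()
    treatments = ("transoral partial laryngectomy", "laryngectomy", "radiotherapy",
                  "chemotherapy", "radio-chemotherapy", "open partial laryngectomy")
    b.conditionals["initial_treatment"] = ConditionalTable(
        "initial_treatment", ("UICC",),
        {(k,): CategoricalDistribution(treatments, tuple(v.get(t, 0.0) for t in treatments))
         for k, v in rows.items()})
    if flags:
        b.flags["initial_treatment"] = flags
    b.conditionals["neck_dissection"] = ConditionalTable("neck_dissection", ("UICC",), {
        (k,): CategoricalDistribution(("none", "elective", "curative"), (1.0, 0.0, 0.0))
        for k in rows})
    b.distributions["r_status"] = CategoricalDistribution(("R0", "R1", "R2"), (1.0, 0.0, 0.0))
    adj = adjuvant_rows or {
        ("R0",): {"none": 1.0, "postoperative radiotherapy": 0.0, "postoperative radio-chemotherapy": 0.0}}
    b.conditionals["adjuvant"] = ConditionalTable("adjuvant", ("R",), {
        k: CategoricalDistribution.from_mapping(v) for k, v in adj.items()})
    return b


def tumor(uicc="I", r_status=None):
    t = {"I": "T1", "II": "T2", "III": "T3", "IV": "T4"}[uicc]
    return TumorCharacteristics(t, "N0", "M0", uicc, "G2", "glottis", False, "none", 0)


class TestTreatmentAssignment:
    def test_certain_row_needs_no_r_status(self, rng):
        b = treatment_bundle({"I": {"radio-chemotherapy": 1.0}})
        plan = assign_initial_treatment(tumor("I"), b, rng)
        assert plan.initial == "radio-chemotherapy"
        assert plan.r_status is None and plan.adjuvant == "none"

    def test_rare_option_receives_ten_percent(self, rng):
        b = treatment_bundle({"I": {"radiotherapy": 1.0, "chemotherapy": 0.0}},
                             flags={"chemotherapy": "rare"})
        n = 8000
        draws = [assign_initial_treatment(tumor("I"), b, rng).initial for _ in range(n)]
        freq = np.mean([d == "chemotherapy" for d in draws])
        assert abs(freq - 0.10) < 3.29 * np.sqrt(0.1 * 0.9 / n)
        assert abs(np.mean([d == "radiotherapy" for d in draws]) - 0.90) < 0.02

    def test_surgical_treatment_carries_r_status(self, rng):
        b = treatment_bundle({"I": {"laryngectomy": 1.0}})
        plan = assign_initial_treatment(tumor("I"), b, rng)
        assert plan.initial in SURGICAL_TREATMENTS
        assert plan.r_status == "R0"

    def test_frequency_recovery_per_stratum(self, rng):
        rows = {"I": {"radiotherapy": 0.4, "transoral partial laryngectomy": 0.6},
                "IV": {"radio-chemotherapy": 0.7, "laryngectomy": 0.3}}
        b = treatment_bundle(rows)
        n = 8000
        for stage, row in rows.items():
            draws = [assign_initial_treatment(tumor(stage), b, rng).initial for _ in range(n)]
            for option, p in row.items():
                freq = np.mean([d == option for d in draws])
                assert abs(freq - p) < 3.29 * np.sqrt(p * (1 - p) / n) + 1e-9


class TestAdjuvant:
    def test_non_surgical_initial_gets_none(self, rng):
        b = treatment_bundle({"I": {"radiotherapy": 1.0}})
        plan = assign_initial_treatment(tumor("I"), b, rng)
        assert assign_adjuvant(plan, tumor("I"), b, rng).adjuvant == "none"

    def test_frequency_recovery_after_surgery(self, rng):
        adj = {("R0",): {"none": 0.5, "postoperative radiotherapy": 0.3,
                         "postoperative radio-chemotherapy": 0.2}}
        b = treatment_bundle({"I": {"laryngectomy": 1.0}}, adjuvant_rows=adj)
        n = 8000
        draws = []
        for _ in range(n):
            plan = assign_initial_treatment(tumor("I"), b, rng)
            draws.append(assign_adjuvant(plan, tumor("I"), b, rng).adjuvant)
        for option, p in adj[("R0",)].items():
            freq = np.mean([d == option for d in draws])
            assert abs(freq - p) < 3.29 * np.sqrt(p * (1 - p) / n)

    def test_incomplete_resection_routes_to_its_own_row(self, rng):
        adj = {("R0",): {"none": 1.0, "postoperative radiotherapy": 0.0,
                         "postoperative radio-chemotherapy": 0.0},
               ("R1",): {"none": 0.0, "postoperative radiotherapy": 0.0,
                         "postoperative radio-chemotherapy": 1.0}}
        b = treatment_bundle({"I": {"laryngectomy": 1.0}}, adjuvant_rows=adj)
        b.distributions["r_status"] = CategoricalDistribution(("R0", "R1", "R2"), (0.0, 1.0, 0.0))
        plan = assign_initial_treatment(tumor("I"), b, rng)
        assert assign_adjuvant(plan, tumor("I"), b, rng).adjuvant == "postoperative radio-chemotherapy"


class TestSurvivalSubmodule:
    def test_certain_survival_always_censors(self, rng):
        table = build_survival_table({"I": 1.0}, {g: 1.0 for g in ("<55", "55-64", "65-74", "75+")})
        assert all(sample_survival_time("I", 60, table, rng) is None for _ in range(200))

    def test_five_year_survival_recovers_the_cell_value(self, bundle):
        rng = np.random.default_rng(77)
        n = 20000
        cell = bundle.survival.five_year("I", survival_age_group(60))
        alive = sum(sample_survival_time("I", 60, bundle.survival, rng) is None for _ in range(n))
        freq = alive / n
        assert abs(freq - cell) < 3.29 * np.sqrt(cell * (1 - cell) / n)

    def test_fixed_seed_reproduces_death_week(self, bundle):
        draws = {sample_survival_time("IV", 70, bundle.survival, np.random.default_rng(3))
                 for _ in range(5)}
        assert len(draws) == 1

    def test_death_week_within_the_window(self, bundle, rng):
        for _ in range(2000):
            offset = sample_survival_time("IV", 80, bundle.survival, rng)
            assert offset is None or 0 <= offset < 260

    def test_survival_monotone_in_stage_and_age(self, bundle):
        # the calibrated table itself must be ordered I -> IV and young -> old
        for g in bundle.survival.age_groups:
            vals = [bundle.survival.five_year(s, g) for s in ("I", "II", "III", "IV")]
            assert vals == sorted(vals, reverse=True)
        for s in ("I", "II", "III", "IV"):
            vals = [bundle.survival.five_year(s, g) for g in bundle.survival.age_groups]
            assert vals == sorted(vals, reverse=True)


class TestTimeline:
    def test_three_encounters_without_adjuvant(self, bundle, rng):
        plan = assign_initial_treatment(tumor("I"), treatment_bundle({"I": {"radiotherapy": 1.0}}), rng)
        tl = build_timeline(tumor("I"), plan, diagnosis_week=6000, tables=bundle, rng=rng)
        assert tl.adjuvant_week is None
        assert tl.first_visit_week <= tl.second_visit_week <= tl.initial_treatment_week

    def test_all_symptoms_present_when_frequencies_are_one(self, bundle, rng):
        b = ParameterBundle()
        for s in SYMPTOMS:
            b.distributions[f"symptom:{s}"] = CategoricalDistribution(("yes", "no"), (1.0, 0.0))
        plan = assign_initial_treatment(tumor("I"), treatment_bundle({"I": {"radiotherapy": 1.0}}), rng)
        tl = build_timeline(tumor("I"), plan, diagnosis_week=6000, tables=b, rng=rng)
        assert sorted(s for s, _ in tl.symptom_onsets) == sorted(SYMPTOMS)
        assert all(6000 - 52 <= w <= 6000 for _, w in tl.symptom_onsets)

    def test_ordering_invariant_over_many_samples(self, bundle, rng):
        adj = {("R0",): {"none": 0.0, "postoperative radiotherapy": 1.0,
                         "postoperative radio-chemotherapy": 0.0}}
        tb = treatment_bundle({"I": {"laryngectomy": 1.0}}, adjuvant_rows=adj)
        for _ in range(1000):
            plan = assign_adjuvant(assign_initial_treatment(tumor("I"), tb, rng), tumor("I"), tb, rng)
            tl = build_timeline(tumor("I"), plan, diagnosis_week=6000, tables=bundle, rng=rng)
            assert (tl.first_visit_week <= tl.second_visit_week
                    <= tl.initial_treatment_week <= tl.adjuvant_week)
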