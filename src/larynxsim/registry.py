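"""Reference parameter values and the default calibrated parameter bundle.

Quantitative anchors come from German registry sources: age/sex-specific
crude incidence of laryngeal cancer (ICD-10 C32) from the German Center for
Cancer Registry Data (ZfKD, average 1999-2019), and distributions of age at
diagnosis, T/N/M category, UICC stage, grading and 1-/5-year overall survival
from the Cancer Registry Schleswig-Holstein (laryngeal cancer 1997-2021).
Quantities that the registry material does not publish (treatment mix, ECOG by
stage, symptom and risk-factor frequencies, localisation, metastasis sites)
ship as clearly-labelled placeholder estimates and can be overridden through
the CSV/JSON bundle without code changes.

The T/N/M dependency structure is calibrated by iterative proportional
fitting: the shipped joint P(T, N, M) per sex reproduces the registry T, N
and M marginals *and* the registry UICC stage distribution (stage is a
deterministic function of TNM, and the registry stage mix is far from the
independence coupling, which would put only ~30% of male cases in stage I
against the observed ~41%).
"""

from __future__ import annotations

import functools

import numpy as np

from .demography import default_life_table
from .tables import (
    CategoricalDistribution,
    ConditionalTable,
    ParameterBundle,
    RateTable,
    build_age_specific_incidence,
    build_survival_table,
    rake_joint,
)

_SH = "Cancer Registry Schleswig-Holstein, laryngeal cancer 1997-2021"
_ZFKD = "ZfKD crude incidence per 100,000/yr, average 1999-2019"
_PLACEHOLDER = "placeholder estimate (guideline/literature value not published numerically); override via bundle"

# -- printed registry percentages -------------------------------------------

T_PERCENT = {
    # NOTE: the female column is suspected to be a transcription duplicate of
    # a simulated male column in the source material; it is shipped as printed
    # but no calibration check asserts on female T frequencies.
    "male": {"T1": 43.3, "T2": 21.0, "T3": 18.5, "T4": 17.1},
    "female": {"T1": 43.2, "T2": 21.0, "T3": 18.9, "T4": 16.9},
}
N_PERCENT = {
    "male": {"N0": 72.0, "N1": 7.6, "N2": 17.7, "N3": 2.7},
    "female": {"N0": 66.6, "N1": 9.2, "N2": 22.4, "N3": 2.9},
}
M_PERCENT = {
    "male": {"M0": 95.6, "M1": 4.4},
    "female": {"M0": 93.9, "M1": 6.1},
}
# Male stage IV is the complement of the printed I-III values: the printed
# male column sums to 105.5 with a IV entry identical to the female column,
# a transcription artifact; I-III keep their printed values.
UICC_PERCENT = {
    "male": {"I": 41.4, "II": 14.7, "III": 15.3, "IV": 28.6},
    "female": {"I": 35.1, "II": 15.5, "III": 15.3, "IV": 34.1},
}
GRADING_PERCENT = {
    "male": {"G1": 8.7, "G2": 67.8, "G3": 23.5},
    "female": {"G1": 8.3, "G2": 62.5, "G3": 29.2},
}
AGE_AT_DIAGNOSIS_PERCENT = {
    "male": {"40-49": 6.6, "50-59": 23.1, "60-69": 35.0, "70-79": 25.2, "80+": 10.1},
    "female": {"40-49": 9.4, "50-59": 23.6, "60-69": 32.8, "70-79": 21.9, "80+": 12.3},
}
SEX_SHARE_PERCENT = {"female": 15.8, "male": 84.2}

CRUDE_INCIDENCE = {"male": 8.3, "female": 1.2, "total": 4.68}

FIVE_YEAR_SURVIVAL_BY_UICC = {"I": 0.769, "II": 0.679, "III": 0.589, "IV": 0.358}
ONE_YEAR_SURVIVAL = {"male": 0.869, "female": 0.857}
FIVE_YEAR_SURVIVAL = {"male": 0.589, "female": 0.636}

SURVIVAL_AGE_GROUPS = ("<55", "55-64", "65-74", "75+")
SURVIVAL_AGE_MULTIPLIERS = {"<55": 0.7, "55-64": 0.9, "65-74": 1.1, "75+": 1.5}
# the tumor sampler never emits stage X; the level exists because the survival
# submodule is defined over five stage characteristics
SURVIVAL_STAGE_X_ANCHOR = 0.50

COHORT_AGE_BANDS = (("40-49", 40, 50), ("50-59", 50, 60), ("60-69", 60, 70),
                    ("70-79", 70, 80), ("80+", 80, 90))


def uicc_from_tnm(t: str, n: str, m: str) -> str:
    """Condensed UICC stage I-IV from T, N, M (sub-levels collapse first)."""
    t = t[:2]  # T1a -> T1, T4b -> T4
    if m == "M1":
        return "IV"
    if n in ("N2", "N3") or t == "T4":
        return "IV"
    if n == "N1" or t == "T3":
        return "III"
    if t == "T2":
        return "II"
    return "I"


# -- derived structures ------------------------------------------------------


def survival_age_group(age_years: float) -> str:
    if age_years < 55:
        return "<55"
    if age_years < 65:
        return "55-64"
    if age_years < 75:
        return "65-74"
    return "75+"


def cohort_age_band(age_years: float) -> str | None:
    for label, lo, hi in COHORT_AGE_BANDS:
        if lo <= age_years < (hi if label != "80+" else 101):
            return label
    return None


_AGE_BAND_SPLIT = {
    "40-49": {"<55": 1.0},
    "50-59": {"<55": 0.5, "55-64": 0.5},
    "60-69": {"55-64": 0.5, "65-74": 0.5},
    "70-79": {"65-74": 0.5, "75+": 0.5},
    "80+": {"75+": 1.0},
}


def _survival_age_weights(sex: str | None = None) -> dict[str, float]:
    """Diagnosis-age mix mapped onto the four survival age groups.

    Ten-year diagnosis-age bands are split evenly across the two survival
    groups they straddle; without a sex the mix pools both sexes at the
    registry sex share.
    """
    mix = {g: 0.0 for g in SURVIVAL_AGE_GROUPS}
    sexes = [(sex, 1.0)] if sex else [
        (s, SEX_SHARE_PERCENT[s] / 100) for s in ("male", "female")
    ]
    for s, sex_share in sexes:
        for band, pct in AGE_AT_DIAGNOSIS_PERCENT[s].items():
            for group, frac in _AGE_BAND_SPLIT[band].items():
                mix[group] += sex_share * pct / 100.0 * frac
    total = sum(mix.values())
    return {k: v / total for k, v in mix.items()}


def _fit_year_weights(target_one_year: float | None = None) -> np.ndarray:
    """Within-window hazard profile from the printed 1-year survival anchor.

    The five yearly log-hazard shares decline geometrically, w_y ~ rho**(y-1);
    the single shape parameter rho is solved so that the male cohort-mixed
    1-year overall survival hits the registry anchor (86.9%).  Constant hazard
    (rho = 1) would imply ~89.9% and understate early cancer mortality.
    """
    from scipy.optimize import brentq

    if target_one_year is None:
        target_one_year = ONE_YEAR_SURVIVAL["male"]
    stage_mix = {k: v / sum(UICC_PERCENT["male"].values()) for k, v in UICC_PERCENT["male"].items()}
    age_mix = _survival_age_weights("male")
    anchors = dict(FIVE_YEAR_SURVIVAL_BY_UICC)

    # per-cell 5-year survival with the anchor-preserving age normalisation
    def cell_s5() -> dict[tuple[str, str], float]:
        table = build_survival_table(
            dict(anchors, X=SURVIVAL_STAGE_X_ANCHOR), SURVIVAL_AGE_MULTIPLIERS,
            cohort_age_weights=_survival_age_weights())
        return {(st, g): table.five_year(st, g) for st in anchors for g in SURVIVAL_AGE_GROUPS}

    s5 = cell_s5()

    def one_year_gap(rho: float) -> float:
        w1 = (1.0 - rho) / (1.0 - rho ** 5) if abs(rho - 1.0) > 1e-9 else 0.2
        got = sum(stage_mix[st] * age_mix[g] * s5[(st, g)] ** w1
                  for st in stage_mix for g in SURVIVAL_AGE_GROUPS)
        return got - target_one_year

    rho = brentq(one_year_gap, 0.2, 3.0, xtol=1e-12)
    w = np.array([rho ** i for i in range(5)])
    return w / w.sum()


def _incidence_rate_table(sex: str, pooled: bool = False) -> RateTable:
    """Calibrate 5-year age-specific rates to the crude registry rate.

    Ten-year case-age shares are split into 5-year bins proportionally to the
    stationary population within each band (constant rate inside a band).  The
    crude target is quoted per 100,000 of the *total* population, so shares and
    target are rescaled by the 40+ population fraction before calibration.
    """
    bins = [(a, a + 5) for a in range(40, 100, 5)]
    if pooled:
        shares10 = {
            band: sum(SEX_SHARE_PERCENT[s] / 100 * AGE_AT_DIAGNOSIS_PERCENT[s][band] for s in ("male", "female"))
            for band in AGE_AT_DIAGNOSIS_PERCENT["male"]
        }
        pop_year = sum(0.5 * default_life_table(s).stationary_year_shares(100) for s in ("male", "female"))
        crude = CRUDE_INCIDENCE["total"]
        label = "pooled"
    else:
        shares10 = AGE_AT_DIAGNOSIS_PERCENT[sex]
        pop_year = default_life_table(sex).stationary_year_shares(100)
        crude = CRUDE_INCIDENCE[sex]
        label = sex
    pop_bin = np.array([pop_year[lo:hi].sum() for lo, hi in bins])
    band_of_bin = [f"{lo - lo % 10}-{lo - lo % 10 + 9}" if lo < 80 else "80+" for lo, _ in bins]
    band_pop = {band: sum(p for p, b in zip(pop_bin, band_of_bin) if b == band) for band in set(band_of_bin)}
    shares5 = np.array([
        shares10[band] / 100.0 * (p / band_pop[band] if band_pop[band] > 0 else 0.0)
        for p, band in zip(pop_bin, band_of_bin)
    ])
    frac40 = pop_bin.sum()
    table = build_age_specific_incidence(
        case_age_shares=shares5 / shares5.sum(),
        pop_age_structure=pop_bin / frac40,
        crude_target=crude / frac40,
        sex=label,
        age_groups=bins,
        provenance=f"{_ZFKD}; age shape from {_SH}",
    )
    return table


def _tnm_conditionals(sex: str) -> tuple[ConditionalTable, ConditionalTable]:
    """P(N | sex, T) and P(M | sex, T, N) raked to the stage distribution."""
    t = CategoricalDistribution.from_percent(T_PERCENT[sex], _SH)
    n = CategoricalDistribution.from_percent(N_PERCENT[sex], _SH)
    m = CategoricalDistribution.from_percent(M_PERCENT[sex], _SH)
    stage = CategoricalDistribution.from_percent(UICC_PERCENT[sex], _SH)
    joint = rake_joint(
        {"T": t, "N": n, "M": m},
        partition=lambda cell: uicc_from_tnm(cell["T"], cell["N"], cell["M"]),
        partition_target=stage,
        tol=1e-12,
    )
    n_rows = {}
    m_rows = {}
    for t_lvl in t.levels:
        pn = {n_lvl: sum(p for (tt, nn, mm), p in joint.items() if tt == t_lvl and nn == n_lvl)
              for n_lvl in n.levels}
        tot = sum(pn.values())
        n_rows[(sex, t_lvl)] = CategoricalDistribution(
            tuple(pn), tuple(v / tot for v in pn.values()),
            provenance=f"{_SH}; raked to registry stage distribution",
        )
        for n_lvl in n.levels:
            pm = {m_lvl: joint[(t_lvl, n_lvl, m_lvl)] for m_lvl in m.levels}
            tot_m = sum(pm.values())
            m_rows[(sex, t_lvl, n_lvl)] = CategoricalDistribution(
                tuple(pm), tuple(v / tot_m for v in pm.values()),
                provenance=f"{_SH}; raked to registry stage distribution",
            )
    return (
        ConditionalTable("N", ("sex", "T"), n_rows),
        ConditionalTable("M", ("sex", "T", "N"), m_rows),
    )


def _placeholder_tables(bundle: ParameterBundle) -> None:
    P = _PLACEHOLDER
    bundle.distributions.update({
        "localization": CategoricalDistribution.from_mapping(
            {"glottis": 0.65, "supraglottis": 0.30, "subglottis": 0.05}, P),
        "hpv": CategoricalDistribution.from_mapping({"yes": 0.10, "no": 0.90}, P),
        "smoking": CategoricalDistribution.from_mapping(
            {"active smoker": 0.60, "former smoker": 0.25, "non-smoker": 0.15}, P),
        "alcohol": CategoricalDistribution.from_mapping(
            {"no": 0.15, "occasionally": 0.25, "regular": 0.30, "excessive": 0.20, "former excessive": 0.10}, P),
        "precursor": CategoricalDistribution.from_mapping(
            {"none": 0.70, "carcinoma-in-situ": 0.06, "NOS": 0.04, "mild": 0.08, "moderate": 0.07, "severe": 0.05}, P),
        "metastasis_site": CategoricalDistribution.from_mapping(
            {"lung": 0.60, "bone": 0.20, "skin": 0.05, "CNS": 0.05, "other": 0.10}, P),
        "T1_split": CategoricalDistribution.from_mapping({"T1a": 0.5, "T1b": 0.5}, P),
        "T4_split": CategoricalDistribution.from_mapping({"T4a": 0.5, "T4b": 0.5}, P),
        "r_status": CategoricalDistribution.from_mapping({"R0": 0.82, "R1": 0.13, "R2": 0.05}, P),
    })
    for name, freq in (("hoarseness", 0.85), ("sore throat", 0.30), ("dysphagia", 0.25),
                       ("dysphonia", 0.20), ("otalgia", 0.15), ("chest infection", 0.10),
                       ("insomnia", 0.10), ("mouth symptoms", 0.10)):
        bundle.distributions[f"symptom:{name}"] = CategoricalDistribution.from_mapping(
            {"yes": freq, "no": 1.0 - freq}, P)

    treatments = ("open partial laryngectomy", "transoral partial laryngectomy", "laryngectomy",
                  "radiotherapy", "chemotherapy", "radio-chemotherapy")
    rows = {
        ("I",): {"open partial laryngectomy": 0.10, "transoral partial laryngectomy": 0.50,
                 "laryngectomy": 0.0, "radiotherapy": 0.40, "chemotherapy": 0.0, "radio-chemotherapy": 0.0},
        ("II",): {"open partial laryngectomy": 0.20, "transoral partial laryngectomy": 0.35,
                  "laryngectomy": 0.05, "radiotherapy": 0.40, "chemotherapy": 0.0, "radio-chemotherapy": 0.0},
        ("III",): {"open partial laryngectomy": 0.15, "transoral partial laryngectomy": 0.10,
                   "laryngectomy": 0.30, "radiotherapy": 0.15, "chemotherapy": 0.0, "radio-chemotherapy": 0.30},
        ("IV",): {"open partial laryngectomy": 0.05, "transoral partial laryngectomy": 0.0,
                  "laryngectomy": 0.30, "radiotherapy": 0.10, "chemotherapy": 0.0, "radio-chemotherapy": 0.55},
    }
    bundle.conditionals["initial_treatment"] = ConditionalTable(
        "initial_treatment", ("UICC",),
        {k: CategoricalDistribution(treatments, tuple(v[t] for t in treatments), P) for k, v in rows.items()},
    )
    # chemotherapy alone is a second-line option in every stage row
    bundle.flags["initial_treatment"] = {"chemotherapy": "rare"}

    nd_rows = {
        ("I",): {"none": 0.70, "elective": 0.25, "curative": 0.05},
        ("II",): {"none": 0.50, "elective": 0.35, "curative": 0.15},
        ("III",): {"none": 0.25, "elective": 0.35, "curative": 0.40},
        ("IV",): {"none": 0.20, "elective": 0.25, "curative": 0.55},
    }
    bundle.conditionals["neck_dissection"] = ConditionalTable(
        "neck_dissection", ("UICC",),
        {k: CategoricalDistribution.from_mapping(v, P) for k, v in nd_rows.items()},
    )
    adj_rows = {
        ("R0",): {"none": 0.65, "postoperative radiotherapy": 0.25, "postoperative radio-chemotherapy": 0.10},
        ("R1",): {"none": 0.15, "postoperative radiotherapy": 0.45, "postoperative radio-chemotherapy": 0.40},
        ("R2",): {"none": 0.10, "postoperative radiotherapy": 0.40, "postoperative radio-chemotherapy": 0.50},
    }
    bundle.conditionals["adjuvant"] = ConditionalTable(
        "adjuvant", ("R",),
        {k: CategoricalDistribution.from_mapping(v, P) for k, v in adj_rows.items()},
    )
    ecog_rows = {
        ("I",): {"0": 0.55, "1": 0.30, "2": 0.10, "3": 0.04, "4": 0.01, "5": 0.0},
        ("II",): {"0": 0.45, "1": 0.33, "2": 0.14, "3": 0.06, "4": 0.02, "5": 0.0},
        ("III",): {"0": 0.30, "1": 0.35, "2": 0.22, "3": 0.09, "4": 0.04, "5": 0.0},
        ("IV",): {"0": 0.15, "1": 0.30, "2": 0.30, "3": 0.17, "4": 0.08, "5": 0.0},
    }
    bundle.conditionals["ecog"] = ConditionalTable(
        "ecog", ("UICC",),
        {k: CategoricalDistribution.from_mapping(v, P) for k, v in ecog_rows.items()},
    )


@functools.lru_cache(maxsize=1)
def default_bundle() -> ParameterBundle:
    """The shipped, registry-calibrated parameter bundle (cached)."""
    bundle = ParameterBundle(meta={"description": "laryngeal cancer (ICD-10 C32) default parameter bundle"})
    for sex in ("male", "female"):
        bundle.distributions[f"T:{sex}"] = CategoricalDistribution.from_percent(T_PERCENT[sex], _SH)
        bundle.distributions[f"grading:{sex}"] = CategoricalDistribution.from_percent(GRADING_PERCENT[sex], _SH)
        bundle.distributions[f"age_at_diagnosis:{sex}"] = CategoricalDistribution.from_percent(
            AGE_AT_DIAGNOSIS_PERCENT[sex], _SH)
        bundle.distributions[f"uicc_target:{sex}"] = CategoricalDistribution.from_percent(UICC_PERCENT[sex], _SH)
        bundle.distributions[f"N_marginal:{sex}"] = CategoricalDistribution.from_percent(N_PERCENT[sex], _SH)
        bundle.distributions[f"M_marginal:{sex}"] = CategoricalDistribution.from_percent(M_PERCENT[sex], _SH)
        n_tab, m_tab = _tnm_conditionals(sex)
        if "N|T" in bundle.conditionals:
            bundle.conditionals["N|T"] = ConditionalTable(
                "N", ("sex", "T"), {**bundle.conditionals["N|T"].rows, **n_tab.rows})
            bundle.conditionals["M|TN"] = ConditionalTable(
                "M", ("sex", "T", "N"), {**bundle.conditionals["M|TN"].rows, **m_tab.rows})
        else:
            bundle.conditionals["N|T"] = n_tab
            bundle.conditionals["M|TN"] = m_tab
        bundle.rate_tables[f"incidence:{sex}"] = _incidence_rate_table(sex)
    bundle.distributions["sex_at_diagnosis"] = CategoricalDistribution.from_percent(SEX_SHARE_PERCENT, _SH)
    bundle.rate_tables["incidence:pooled"] = _incidence_rate_table("pooled", pooled=True)
    anchors = dict(FIVE_YEAR_SURVIVAL_BY_UICC, X=SURVIVAL_STAGE_X_ANCHOR)
    bundle.survival = build_survival_table(
        anchors,
        SURVIVAL_AGE_MULTIPLIERS,
        cohort_age_weights=_survival_age_weights(),
        year_weights=_fit_year_weights(),
        provenance=f"{_SH} 5-year overall-survival anchors; declining within-window hazard fitted to the "
                   "printed 1-year survival; age multipliers normalised to preserve stage anchors "
                   "(stage X is a placeholder)",
    )
    _placeholder_tables(bundle)
    return bundle
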