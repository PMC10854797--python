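# Methods

## Overview

`larynxsim` is a microsimulation of laryngeal cancer (ICD-10 C32) in a
synthetic population. Each person is simulated individually from birth at
weekly time resolution: background mortality decides a provisional lifespan,
the disease module decides whether and when laryngeal cancer occurs, and —
for cases — the dependent tumor profile, the care pathway and survival. The
package produces three kinds of datasets (population prevalence, enriched
prevalence, matched incidence cohort) and ships the statistical battery used
to check generated data against the registry reference tables.

All quantitative inputs are aggregate registry statistics (German national
cancer registry data for crude incidence; the Schleswig-Holstein cancer
registry for age, stage, grading and survival distributions). Quantities the
registries do not publish — treatment mix by stage, ECOG by stage, symptom
and risk-factor frequencies, tumor localisation, metastasis sites, encounter
spacing — are shipped as placeholder distributions whose provenance string
says so; they can be replaced through the CSV/JSON parameter bundle without
touching code, and no calibration result depends on them.

## Calendar and demographics

Time is measured in whole weeks since Monday 1900-01-01; the default target
date is the first week of 2022. Background mortality is a Gompertz–Makeham
hazard per sex, μ(a) = λ + α·e^{βa} with λ = 2·10⁻⁴/yr and β = 0.09/yr,
with α calibrated by root finding so period life expectancy at birth is 78
years (men) and 83 years (women). The population age structure at the target
date is the stationary distribution of that life table (share of age a ∝
survivorship ℓ(a)), which makes the generated world demographically
self-consistent: the pool of regeneration attempts then reconstructs every
historical birth cohort at equal intensity. A user-supplied life table (CSV:
age, survival) replaces the built-in hazard without code changes.

These demographics are deliberately simple stand-ins — no migration, no
cohort effects, no period trends — so absolute prevalence agreement with
registry data is expected only within a tolerance band, not exactly.

## Incidence

Age- and sex-specific diagnosis rates (events per 100,000 person-years, ages
40–100 in 5-year bins; below 40 the rate is zero) are derived from the
registry's 10-year age-at-diagnosis shares: rate_g ∝ case-share_g /
population-share_g, scaled so the population-weighted crude rate equals the
registry anchor (8.3/100,000/yr men, 1.2 women). Ten-year case shares are
split into 5-year bins proportionally to the stationary population inside
each band (constant rate within a band). The engine samples the onset week
analytically as the first passage of the piecewise-constant hazard (inverse
cumulative-hazard transform), capped by the person's death — observationally
identical to weekly Bernoulli stepping but far cheaper.

## Tumor characterisation

Sampling follows the dependency order T | sex → N | T, sex → M | T, N →
UICC(T, N, M) → grading, localisation, HPV, precursor, ECOG | UICC;
metastasis sites are sampled only for M1. UICC stage is the deterministic
condensed mapping (M1 → IV; T4 or N2/N3 → IV; T3 or N1 → III; T2 → II;
else I); T1/T4 refine to a/b sub-levels with a configurable 50/50 split.

The conditional tables P(N | T, sex) and P(M | T, N, sex) are not published.
They are obtained by iterative proportional fitting of the 4×4×2 joint
P(T, N, M) per sex, raked simultaneously to the registry T, N and M marginals
and to the registry UICC stage distribution (stage is a partition of the TNM
cells, so classical IPF applies; convergence to 10⁻¹² is checked). This
coupling is essential: under independence the male stage-I share would be
P(T1)·P(N0)·P(M0) ≈ 30%, far from the observed ≈ 41% — early tumors are
strongly concentrated in N0 M0. The generic
`derive_conditional_table` operation retains independence as its default
coupling, with an odds-multiplier hook for binary children.

## Treatment

Initial treatment is sampled from a per-UICC-stage row; surgical options
(open/transoral partial laryngectomy, laryngectomy) additionally draw a
neck-dissection decision and a resection status, and only surgical cases can
receive adjuvant therapy, whose row is keyed by R status so incomplete
resections route to a more aggressive postoperative mix. Where guidelines
describe an option only qualitatively, fixed evidence-gap frequencies are
imposed at sampling time: 5% for "isolated cases", 10% for "rare" or
"second-line", with the remaining first-line mass renormalised
proportionally.

## Survival

The survival submodule is a 100-node table: 5 stage levels (UICC I–IV plus
an X/unknown level that the tumor sampler never emits and that carries a
placeholder anchor of 0.50) × 4 age groups at diagnosis (<55, 55–64, 65–74,
75+) × 5 years. Death within the window is a Bernoulli chain over the yearly
conditionals, with the death week uniform inside the failing year.

The yearly conditionals are S5^(k·m_g·5·w_y / 5) where

* S5 is the stage's 5-year overall-survival anchor (male registry column:
  I 76.9%, II 67.9%, III 58.9%, IV 35.8%). A single table serves both sexes:
  the submodule is stage × age only, consistent with finding no survival
  difference by gender in the generated data;
* m_g are age-group log-hazard multipliers (defaults 0.7 / 0.9 / 1.1 / 1.5,
  young → old), rescaled per stage by a common factor k (root find) so the
  cohort-age-mix-weighted 5-year survival reproduces the stage anchor
  exactly;
* w_y are five year-weights (shares of the window's cumulative log-hazard)
  declining geometrically, w_y ∝ ρ^{y−1}. The single shape parameter ρ
  (fitted value ≈ 0.87) is solved so the male cohort-mixed 1-year survival
  equals the printed 86.9% anchor. Constant hazard (w_y = 1/5, the
  `build_survival_table` default) would imply ≈ 89.9% at one year and
  understate early cancer mortality — which matters, because the
  retrospective incidence bias of prevalence data is a direct signature of
  how front-loaded case mortality is.

The anchors are *overall* (all-cause) survival, so while the window runs the
submodule claims mortality authority: background mortality is suppressed for
260 weeks (otherwise all-cause deaths would be double-counted, depressing
stage-I 5-year survival by several points). Survivors of the window re-enter
background mortality via a conditional residual draw, plus a persistent
excess hazard equal to the final window year's all-cause hazard minus
background, added as an independent competing exponential. This
zero-parameter continuation reflects the established excess mortality of
long-term cancer survivors; reverting to pure background mortality would
overstate the 25-year prevalence by roughly 30%.

## Dataset modes

**Population prevalence.** Per stratum (sex × single year of age 0–100,
stationary weights, equal sex split), persons are regenerated until the
stratum's alive-at-target quota fills; every decedent attempt is kept in the
deceased bucket. Quotas use largest-remainder rounding. Per-person
randomness comes from counter-based Philox streams keyed by (root seed,
stratum, attempt), so results are independent of generation order and
byte-reproducible.

**Enriched prevalence.** Ages 40–100 only (stationary shape restricted to
that range — uniform ages would spend most of the run regenerating 95+
strata with sub-percent survival-to-target), ~equal sex split, and a
sex-pooled incidence shape multiplied by an enrichment factor (default 300,
fixed once so that roughly three in five synthesized persons carry the
diagnosis, matching the case-repository design). The enriched pool is a case
repository, not an epidemiologically interpretable population.

**Matched cohort.** From the enriched pool's diagnosed cases — alive and
deceased together, which is the point of the cohort view — the largest
cohort matching the registry age-at-diagnosis × sex distribution is N =
floor(min_s pool_s / share_s), with largest-remainder quotas and simple
random sampling without replacement per stratum. Stratum age is age *at
diagnosis*, not current age. Follow-up runs from diagnosis to death,
censored at five years or at the target date. A direct cohort-mode generator
(`generate_reference_cohort`) synthesizes cases straight at the target mix
(diagnosis age uniform within its 10-year band, diagnosis date uniform over
the 25-year lookback, the 80+ band spanning ages 80–90); it powers fast
calibration studies and supplies the reference follow-up samples for the
validation battery.

## Epidemiological summaries

25-year prevalence counts alive persons diagnosed within the lookback
window per 100,000 alive, with sex-specific denominators. The incidence
series divides diagnoses per calendar year by persons alive at mid-year
pooled over both buckets; by default the numerator counts only persons alive
at the target date — the retrospective cross-section view, in which cases
who died before the target date are invisible, so the series is biased
downward the further back one looks while the prevalence remains realistic.
(With full decedent retention a fully pooled numerator is unbiased — the
attempt pool is an iid sample of each birth cohort — and would show no bias
at all; the `numerator="pooled"` option exposes exactly that.)

## Validation battery

Cohorts are compared against the reference tables per variable (age group,
T, N, M, UICC, grading: two-sample KS on level codes against a synthetic
reference sample of matched size; sex: chi-square against the reference
share) and for survival (overall and per stage: log-rank against
reference-generated follow-up of matched size). KM is the product-limit
estimator with events-before-censorings tie handling; the log-rank uses the
hypergeometric variance with ties and a 1-df chi-square tail, implemented in
vectorised numpy so 10,000-replicate null-calibration studies run in
seconds (`lifelines` serves as an independent oracle in the test suite). KS
uses the asymptotic p-value: the compared samples are large and heavily
tied. Significance is flagged at 1% with no further multiple-testing
correction — the strict level *is* the correction. Type-I error of both
tests under their null simulations measures ≈ 0.7–0.9% at α = 1%.

## Numerical choices

* Printed registry percentages are renormalised proportionally when they do
  not sum to 100 (rounding artifacts); the adjustment is recorded in the
  distribution's provenance. One column is treated specially: the male UICC
  registry column sums to 105.5 with a IV entry duplicating the female
  column, so stage IV is taken as the complement of the printed I–III.
* The female T-category registry column is shipped as printed but treated as
  unreliable (suspected transcription duplicate); no calibration check
  asserts on it.
* IPF tolerance 10⁻¹²; marginal-preservation contract of
  `derive_conditional_table` 10⁻⁶; survival-table product identity 10⁻⁹;
  probability sums 10⁻⁹.
* Ties in exported event timelines sort by (week, event kind, label), making
  serialisations byte-deterministic.

## Problem sizes

The test suite runs prevalence mode at 500,000 alive persons and cohort
calibration at 50,007 cases (about one minute in total); the acceptance
script runs the prevalence analysis at the full 2,000,000 alive persons,
10,000,000 person-years for the forward incidence harness, and the same
50,007-case cohort (a few minutes). Monte-Carlo allowances in the checks are
computed from the realised case counts.

## Limitations

* Demographics are stationary stand-ins; absolute prevalence and the
  retrospective-bias magnitude inherit a ±15%-scale uncertainty from them.
* Risk factors (smoking, alcohol, HPV, precursor lesions) are descriptive
  attributes only; they do not modify onset, stage or survival.
* No recurrence or second-line progression, no treatment-dependent survival,
  no comorbidity interactions, no relative-survival decomposition, no
  healthcare-cost modelling, no FHIR/OMOP export.
* Placeholder distributions (treatment mix, ECOG, symptoms, localisation,
  metastasis sites) are plausible but not registry-derived; conclusions
  about those variables describe the placeholders, not reality.
* Passing self-validation shows the generator reproduces its own reference
  tables at realistic sample sizes — it does not show the tables capture
  every dependency present in real registry microdata (e.g. stage–age or
  treatment–survival correlations are absent by construction).
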