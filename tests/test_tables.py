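"""Parameter-table types, calibration operations and serialization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from larynxsim.registry import UICC_PERCENT, default_bundle, uicc_from_tnm
from larynxsim.tables import (
    CategoricalDistribution,
    ParameterBundle,
    apply_evidence_gap_rule,
    build_age_specific_incidence,
    build_survival_table,
    derive_conditional_table,
    rake_joint,
    validate_distribution,
)


def dist(mapping, provenance=""):
    return CategoricalDistribution.from_mapping(mapping, provenance)


@st.composite
def distributions(draw, max_levels=6):
    n = draw(st.integers(2, max_levels))
    raw = draw(st.lists(st.floats(0.01, 1.0), min_size=n, max_size=n))
    total = sum(raw)
    return CategoricalDistribution(
        tuple(f"L{i}" for i in range(n)), tuple(v / total for v in raw)
    )


class TestValidateDistribution:
    def test_exact_normalization_ok(self):
        assert validate_distribution(dist({"A": 0.5, "B": 0.5})).ok

    def test_sum_violation_reported(self):
        res = validate_distribution(dist({"A": 0.5, "B": 0.4}))
        assert not res.ok
        assert any("sum" in v for v in res.violations)

    def test_printed_percentages_need_repair(self):
        # male T-category column as printed sums to 99.9%
        printed = CategoricalDistribution(
            ("T1", "T2", "T3", "T4"), (0.433, 0.210, 0.185, 0.171))
        assert not validate_distribution(printed).ok
        repaired = validate_distribution(printed, repair="largest")
        assert repaired.ok
        assert abs(sum(repaired.repaired.probs) - 1.0) < 1e-12
        assert repaired.repaired.probs[0] > 0.433  # deficit went to the largest level

    def test_duplicate_levels_and_negative_probs(self):
        bad = CategoricalDistribution(("A", "A"), (0.5, 0.5))
        assert "levels not unique" in validate_distribution(bad).violations
        neg = CategoricalDistribution(("A", "B"), (-0.1, 1.1))
        assert "negative probability" in validate_distribution(neg).violations


class TestAgeSpecificIncidence:
    def test_single_stratum_passes_target_through(self):
        table = build_age_specific_incidence([1.0], [1.0], 8.3, age_groups=[(40, 100)])
        assert table.rates == (8.3,)

    def test_two_strata_closed_form(self):
        # rate_g = target * share_g / pop_g
        table = build_age_specific_incidence([0.5, 0.5], [0.8, 0.2], 10.0,
                                             age_groups=[(40, 70), (70, 100)])
        assert np.allclose(table.rates, [6.25, 25.0])
        assert abs(table.crude([0.8, 0.2]) - 10.0) < 1e-9

    def test_calibration_identity_on_shipped_table(self, bundle):
        # population-weighted crude equals the registry target by construction
        from larynxsim.demography import default_life_table
        from larynxsim.registry import CRUDE_INCIDENCE

        for sex in ("male", "female"):
            table = bundle.rate_tables[f"incidence:{sex}"]
            year_shares = default_life_table(sex).stationary_year_shares(100)
            pop = [year_shares[lo:hi].sum() for lo, hi in table.age_groups]
            assert abs(table.crude(pop) - CRUDE_INCIDENCE[sex]) < 1e-6

    @given(st.floats(0.1, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, target):
        base = build_age_specific_incidence([0.3, 0.7], [0.5, 0.5], target,
                                            age_groups=[(40, 70), (70, 100)])
        doubled = build_age_specific_incidence([0.3, 0.7], [0.5, 0.5], 2 * target,
                                               age_groups=[(40, 70), (70, 100)])
        assert np.allclose(np.array(doubled.rates), 2 * np.array(base.rates))

    def test_zero_population_share_with_cases_is_an_error(self):
        with pytest.raises(ValueError, match="unsupported stratum"):
            build_age_specific_incidence([0.5, 0.5], [1.0, 0.0], 5.0,
                                         age_groups=[(40, 70), (70, 100)])


class TestDeriveConditionalTable:
    @given(distributions(), distributions())
    @settings(max_examples=40, deadline=None)
    def test_independence_is_left_inverse_of_marginalization(self, child, parent):
        table = derive_conditional_table(child, parent, "independence")
        joint = {(lvl,): p for lvl, p in parent.as_mapping().items()}
        back = table.marginalize(joint)
        assert np.allclose(back.probs, child.probs, atol=1e-12)

    def test_binary_odds_multiplier_solution(self):
        # odds(yes | B) = 2 * odds(yes | A), marginal P(yes) = 0.3 preserved;
        # expected row probabilities solved independently with a 1-d root find
        child = dist({"yes": 0.3, "no": 0.7})
        parent = dist({"A": 0.5, "B": 0.5})
        table = derive_conditional_table(child, parent, {"B": 2.0})
        p_a = table.row(("A",)).prob("yes")
        p_b = table.row(("B",)).prob("yes")
        assert p_a == pytest.approx(0.228286, abs=1e-5)
        assert p_b == pytest.approx(0.371714, abs=1e-5)
        assert 0.5 * p_a + 0.5 * p_b == pytest.approx(0.3, abs=1e-9)
        odds = lambda p: p / (1 - p)
        assert odds(p_b) / odds(p_a) == pytest.approx(2.0, abs=1e-6)

    def test_invalid_couplings_rejected(self):
        child = dist({"yes": 0.3, "no": 0.7})
        parent = dist({"A": 0.5, "B": 0.5})
        with pytest.raises(ValueError, match="positive"):
            derive_conditional_table(child, parent, {"B": -1.0})
        three = dist({"x": 0.2, "y": 0.3, "z": 0.5})
        with pytest.raises(ValueError, match="binary"):
            derive_conditional_table(three, parent, {"B": 2.0})


class TestSurvivalTable:
    def test_certain_survival(self):
        table = build_survival_table({"I": 1.0}, {"ref": 1.0})
        assert np.all(table.conditional == 1.0)

    def test_fifth_root_interpolation(self):
        # male stage-I anchor: each yearly conditional is 0.769 ** (1/5)
        table = build_survival_table({"I": 0.769}, {"ref": 1.0})
        assert np.allclose(table.yearly("I", "ref"), 0.769 ** 0.2)
        assert table.five_year("I", "ref") == pytest.approx(0.769, abs=1e-12)

    def test_age_multiplier_closed_form(self):
        table = build_survival_table({"I": 0.5}, {"ref": 1.0, "old": 2.0})
        assert np.allclose(table.yearly("I", "old"), 0.5 ** 0.4)
        assert table.five_year("I", "old") == pytest.approx(0.25, abs=1e-9)

    @given(
        st.lists(st.floats(0.05, 1.0), min_size=3, max_size=3),
        st.lists(st.floats(0.3, 3.0), min_size=4, max_size=4),
    )
    @settings(max_examples=40, deadline=None)
    def test_reconstruction_product_identity(self, s5s, mults):
        anchors = {f"S{i}": s for i, s in enumerate(s5s)}
        multipliers = {f"G{i}": m for i, m in enumerate(mults)}
        table = build_survival_table(anchors, multipliers)
        assert table.conditional.size == 3 * 4 * 5
        for stage, s5 in anchors.items():
            for group, m in multipliers.items():
                expect = min(s5 ** m, 1.0)
                assert table.five_year(stage, group) == pytest.approx(expect, abs=1e-9)

    def test_shipped_table_preserves_anchors_under_cohort_weights(self, bundle):
        from larynxsim.registry import FIVE_YEAR_SURVIVAL_BY_UICC, _survival_age_weights

        weights = _survival_age_weights()
        for stage, anchor in FIVE_YEAR_SURVIVAL_BY_UICC.items():
            mixed = sum(weights[g] * bundle.survival.five_year(stage, g)
                        for g in bundle.survival.age_groups)
            assert mixed == pytest.approx(anchor, abs=1e-9)

    def test_degenerate_survival_is_an_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_survival_table({"I": 0.0}, {"ref": 1.0})

    def test_year_weights_shift_early_mortality_but_not_the_anchor(self):
        table = build_survival_table({"I": 0.6}, {"ref": 1.0},
                                     year_weights=[0.4, 0.2, 0.2, 0.1, 0.1])
        yearly = table.yearly("I", "ref")
        assert yearly[0] < yearly[4]  # more of the hazard falls in year one
        assert table.five_year("I", "ref") == pytest.approx(0.6, abs=1e-9)


class TestEvidenceGapRule:
    def test_rare_option_gets_ten_percent(self):
        row = dist({"first-line": 0.97, "second-line": 0.03})
        fixed = apply_evidence_gap_rule(row, {"second-line": "rare"})
        assert fixed.as_mapping() == pytest.approx({"first-line": 0.90, "second-line": 0.10})

    def test_isolated_gets_five_percent_and_rest_renormalizes(self):
        row = dist({"a": 0.5, "b": 0.4, "c": 0.1})
        fixed = apply_evidence_gap_rule(row, {"c": "isolated"})
        assert fixed.prob("c") == pytest.approx(0.05)
        assert fixed.prob("a") / fixed.prob("b") == pytest.approx(0.5 / 0.4)
        assert sum(fixed.probs) == pytest.approx(1.0, abs=1e-12)


class TestRaking:
    def test_shipped_tnm_coupling_reproduces_marginals_and_stage(self, bundle):
        for sex in ("male", "female"):
            t = bundle.distributions[f"T:{sex}"]
            n_marg = bundle.distributions[f"N_marginal:{sex}"]
            m_marg = bundle.distributions[f"M_marginal:{sex}"]
            stage = bundle.distributions[f"uicc_target:{sex}"]
            got_n = {lvl: 0.0 for lvl in n_marg.levels}
            got_m = {lvl: 0.0 for lvl in m_marg.levels}
            got_u = {lvl: 0.0 for lvl in stage.levels}
            for t_lvl, t_p in t.as_mapping().items():
                n_row = bundle.conditionals["N|T"].row((sex, t_lvl))
                for n_lvl, n_p in n_row.as_mapping().items():
                    m_row = bundle.conditionals["M|TN"].row((sex, t_lvl, n_lvl))
                    for m_lvl, m_p in m_row.as_mapping().items():
                        w = t_p * n_p * m_p
                        got_n[n_lvl] += w
                        got_m[m_lvl] += w
                        got_u[uicc_from_tnm(t_lvl, n_lvl, m_lvl)] += w
            assert got_n == pytest.approx(n_marg.as_mapping(), abs=1e-6)
            assert got_m == pytest.approx(m_marg.as_mapping(), abs=1e-6)
            assert got_u == pytest.approx(stage.as_mapping(), abs=1e-6)

    def test_rake_without_partition_returns_independence(self):
        a = dist({"x": 0.3, "y": 0.7})
        b = dist({"u": 0.6, "v": 0.4})
        joint = rake_joint({"A": a, "B": b})
        assert joint[("x", "u")] == pytest.approx(0.18, abs=1e-12)

    def test_infeasible_partition_target_raises(self):
        a = dist({"x": 0.3, "y": 0.7})
        b = dist({"u": 0.6, "v": 0.4})
        # demanding 90% of mass on a cell set that can hold at most 30%
        target = dist({"hot": 0.9, "cold": 0.1})
        with pytest.raises(ValueError, match="IPF"):
            rake_joint({"A": a, "B": b},
                       partition=lambda c: "hot" if c["A"] == "x" else "cold",
                       partition_target=target, max_iter=200)


class TestBundleSerialization:
    def test_json_round_trip_is_lossless(self, bundle):
        back = ParameterBundle.from_json(bundle.to_json())
        assert set(back.distributions) == set(bundle.distributions)
        for name, d in bundle.distributions.items():
            assert back.distributions[name].levels == d.levels
            assert back.distributions[name].probs == pytest.approx(d.probs, abs=0)
        for name, t in bundle.conditionals.items():
            assert back.conditionals[name].rows.keys() == t.rows.keys()
        assert np.array_equal(back.survival.conditional, bundle.survival.conditional)
        assert back.flags == bundle.flags

    def test_csv_round_trip_preserves_every_table(self, bundle):
        back = ParameterBundle.from_csv(bundle.to_csv())
        for name, d in bundle.distributions.items():
            assert back.distributions[name].probs == pytest.approx(d.probs, abs=0)
        for name, t in bundle.conditionals.items():
            for key, row in t.rows.items():
                assert back.conditionals[name].row(key).probs == pytest.approx(row.probs, abs=0)
        for name, r in bundle.rate_tables.items():
            assert back.rate_tables[name].rates == pytest.approx(r.rates, abs=0)
            assert back.rate_tables[name].age_groups == r.age_groups
        assert np.array_equal(back.survival.conditional, bundle.survival.conditional)

    def test_every_shipped_distribution_is_valid(self, bundle):
        for name, d in bundle.distributions.items():
            assert validate_distribution(d).ok, name
        for name, t in bundle.conditionals.items():
            assert t.validate() == [], name
        assert bundle.survival.validate() == []
        assert bundle.survival.conditional.size == 100
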