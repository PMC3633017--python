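"""Model equations, state-chart rates and scenario handling."""

from __future__ import annotations

import numpy as np
import pytest

import tumourimmune as ti
from tumourimmune.exceptions import ScenarioError

from conftest import net_flows


class TestGenericGrowth:
    def test_empty_population_is_fixed_point(self):
        params = ti.GenericGrowthParams(a=2.0, alpha=0.5, b=1.0, beta=1.5)
        assert ti.generic_growth_rhs(0.0, params) == 0.0

    def test_identity_rate_gives_exponential_growth(self):
        params = ti.GenericGrowthParams(a=1.0, alpha=0.0, b=0.0, beta=0.0)
        assert ti.generic_growth_rhs(10.0, params) == pytest.approx(10.0)

    def test_logistic_fixed_point_at_a_over_b(self):
        params = ti.GenericGrowthParams(a=0.5, alpha=0.0, b=0.005, beta=1.0)
        assert ti.generic_growth_rhs(100.0, params) == pytest.approx(0.0, abs=1e-12)

    def test_negative_population_rejected(self):
        params = ti.GenericGrowthParams(a=1.0, alpha=0.0, b=0.0, beta=0.0)
        with pytest.raises(ScenarioError):
            ti.generic_growth_rhs(-1.0, params)


class TestCaseRhs:
    def test_case1_hand_substitution(self):
        params = ti.Case1Params(a=1.0, b=0.01, n=1.0, p=1.0, g=10.0, m=0.01, d=0.1, s=0.0)
        deriv = ti.case1_rhs({"T": 50.0, "E": 5.0}, params)
        assert deriv["T"] == pytest.approx(50 * 0.5 - 250)
        assert deriv["E"] == pytest.approx(250 / 60 - 2.5 - 0.5)

    def test_case1_pure_treatment_influx(self):
        params = ti.Case1Params(a=1.0, b=0.01, n=1.0, p=1.0, g=10.0, m=0.01, d=0.1, s=0.318)
        deriv = ti.case1_rhs({"T": 50.0, "E": 0.0}, params)
        assert deriv["E"] == pytest.approx(0.318)

    def test_case2_hand_substitution(self, case2_scenario):
        deriv = ti.case2_rhs({"T": 50.0, "E": 10.0, "I": 0.0}, case2_scenario.params)
        assert deriv["E"] == pytest.approx(0.05 * 50 - 0.03 * 10)
        assert deriv["T"] == pytest.approx(0.18 * 50 * (1 - 50e-9) - 500 / 100050)
        assert deriv["I"] == pytest.approx(2500 / 1050)

    def test_case3_hand_substitution(self, case3_scenario):
        state = {"T": 1.0, "E": 1.0, "I": 10.0, "S": 0.0}
        deriv = ti.case3_rhs(state, case3_scenario.params)
        assert deriv["S"] == pytest.approx(2.84 / (1e12 + 1))
        assert deriv["I"] == pytest.approx(5 / 1001 - 100)
        assert deriv["E"] == pytest.approx(0.035 - 0.03 + (0.1245 * 10 / (2e7 + 10)) * 0.1245)

    @pytest.mark.parametrize(
        "model_id,params,state",
        [
            ("case1", ti.Case1Params(a=1.6, b=0.002, n=1, p=1.1, g=20, m=0.003, d=0.2, s=0.0), {"T": 0, "E": 0}),
            (
                "case2",
                ti.Case2Params(c=0.05, mu2=0.03, p1=0.12, g1=2e7, s1=0, a=0.18, b=1e-9, aa=1, g2=1e5, p2=5, g3=1e3, mu3=10, s2=0),
                {"T": 0, "E": 0, "I": 0},
            ),
            (
                "case3",
                ti.load_scenario("case3").params,
                {"T": 0, "E": 0, "I": 0, "S": 0},
            ),
        ],
    )
    def test_origin_is_fixed_point_without_influx(self, model_id, params, state):
        deriv = ti.rhs_for(model_id)(state, params)
        assert all(value == 0.0 for value in deriv.values())

    def test_negative_abundance_rejected(self, case2_scenario):
        with pytest.raises(ScenarioError):
            ti.case2_rhs({"T": -1.0, "E": 0.0, "I": 0.0}, case2_scenario.params)


def _transition(chart, name):
    matches = [t for t in chart.transitions if t.name == name]
    assert len(matches) == 1, name
    return matches[0]


class TestStateCharts:
    def test_case1_branch_boundary_silences_growth_and_death(self):
        scenario = ti.load_scenario("case1-s1")
        chart = ti.build_case1_statechart(scenario.params)
        counts = {"T": scenario.params.a / scenario.params.b, "E": 3.0}
        assert _transition(chart, "growthBranch").rate(counts) == pytest.approx(0.0)

    def test_case1_no_effectors_no_kill_rate(self):
        scenario = ti.load_scenario("case1-s1")
        chart = ti.build_case1_statechart(scenario.params)
        counts = {"T": 50.0, "E": 0.0}
        assert _transition(chart, "dieKilledByEffectorCells").rate(counts) == 0.0

    def test_case1_scenario1_rates_match_hand_evaluation(self):
        scenario = ti.load_scenario("case1-s1")
        p = scenario.params
        chart = ti.build_case1_statechart(p)
        counts = {"T": 50.0, "E": 7.0}
        assert _transition(chart, "growthBranch").rate(counts) == pytest.approx(1.636 - 0.002 * 50)
        assert _transition(chart, "dieKilledByEffectorCells").rate(counts) == pytest.approx(7.0)
        assert _transition(chart, "causeEffectorDamage").rate(counts) == pytest.approx(0.00311)
        assert _transition(chart, "Proliferation").rate(counts) == pytest.approx(1.131 * 50 / (20.19 + 50))
        assert _transition(chart, "DieWithAge").rate(counts) == pytest.approx(0.1908)
        assert chart.events[0].rate == pytest.approx(0.318)

    def test_case2_reproduce_needs_il2(self, case2_scenario):
        chart = ti.build_case2_statechart(case2_scenario.params)
        counts = {"T": 50.0, "E": 10.0, "I": 0.0}
        assert _transition(chart, "Reproduce").rate(counts) == 0.0

    def test_case2_kill_rate_hand_evaluation(self, case2_scenario):
        chart = ti.build_case2_statechart(case2_scenario.params)
        counts = {"T": 50.0, "E": 10.0, "I": 0.0}
        assert _transition(chart, "killTumour").rate(counts) == pytest.approx(50 / 100050)

    def test_case2_no_treatment_events(self, case2_scenario):
        chart = ti.build_case2_statechart(case2_scenario.params)
        assert all(event.rate == 0.0 for event in chart.events)

    def test_case3_reproduce_rate_without_tgf(self, case3_scenario):
        chart = ti.build_case3_statechart(case3_scenario.params)
        counts = {"T": 10.0, "E": 2.0, "I": 500.0, "S": 0.0}
        expected = 0.1245 * 500 / (2e7 + 500) * 0.1245
        assert _transition(chart, "Reproduce").rate(counts) == pytest.approx(expected)

    def test_case3_tumour_free_rates_vanish(self, case3_scenario):
        chart = ti.build_case3_statechart(case3_scenario.params)
        counts = {"T": 0.0, "E": 5.0, "I": 10.0, "S": 2.0}
        for name in ("ProduceTGF", "ProduceIL2", "KillTumour"):
            assert _transition(chart, name).rate(counts) == 0.0
        # recruitment is a tumour-agent transition: zero tumour agents, zero flow
        assert _transition(chart, "EffectorRecruitment").total_rate(counts) == 0.0

    def test_case3_tgf_production_half_maximum_at_theta(self, case3_scenario):
        chart = ti.build_case3_statechart(case3_scenario.params)
        counts = {"T": 1e6, "E": 0.0, "I": 0.0, "S": 0.0}
        assert _transition(chart, "ProduceTGF").total_rate(counts) == pytest.approx(2.84 / 2)

    @pytest.mark.parametrize("model_id", ["case1", "case2", "case3"])
    def test_ode_faithful_rates_aggregate_to_model_flows(self, model_id):
        """Per-agent rates times counts must recover the equations' flows."""
        scenario = ti.load_scenario("case1-s1" if model_id == "case1" else model_id)
        chart = ti.build_statechart(model_id, scenario.params, rate_mode="ode_faithful")
        rhs = ti.rhs_for(model_id)
        rng = np.random.default_rng(42)
        species = list(chart.species)
        for trial in range(100):
            counts = {name: float(rng.uniform(0, 1000)) for name in species}
            if trial % 10 == 0:
                counts[species[trial % len(species)]] = 0.0
            flows = net_flows(chart, counts)
            expected = rhs(counts, scenario.params)
            for name in species:
                assert flows[name] == pytest.approx(expected[name], rel=1e-10, abs=1e-12)

    def test_case1_as_printed_damage_diverges_as_published(self):
        scenario = ti.load_scenario("case1-s1")
        chart = ti.build_case1_statechart(scenario.params, rate_mode="as_printed")
        counts = {"T": 123.0, "E": 45.0}
        # published transition table: per-tumour-agent rate m, aggregate m*T
        assert _transition(chart, "causeEffectorDamage").total_rate(counts) == pytest.approx(0.00311 * 123)

    def test_case3_as_printed_stimulation_diverges_as_published(self, case3_scenario):
        chart = ti.build_case3_statechart(case3_scenario.params, rate_mode="as_printed")
        counts = {"T": 77.0, "E": 0.0, "I": 0.0, "S": 40.0}
        # published transition table: per-TGF-agent rate p2*S/(g3+S)
        expected = 0.27 * 40 * 40 / (2e7 + 40)
        assert _transition(chart, "StimulatesTumourGrowth").total_rate(counts) == pytest.approx(expected)

    def test_unknown_rate_mode_rejected(self, case2_scenario):
        with pytest.raises(ScenarioError):
            ti.build_case2_statechart(case2_scenario.params, rate_mode="whatever")


class TestScenarios:
    def test_builtin_labels(self):
        assert ti.builtin_scenarios() == (
            "case1-s1",
            "case1-s2",
            "case1-s3",
            "case1-s4",
            "case2",
            "case3",
        )

    def test_case1_s2_published_row(self):
        scenario = ti.load_scenario("case1-s2")
        assert scenario.params.b == 0.004
        assert scenario.params.d == 2.0
        assert scenario.params.s == 0.318
        assert scenario.initial_state == {"T": 50, "E": 5}
        assert scenario.horizon_days == 100

    def test_case3_published_values(self, case3_scenario):
        params = case3_scenario.params
        assert params.theta == 1e6
        assert params.p4 == 2.84
        assert params.mu3 == 10
        assert params.K == 1e10
        assert case3_scenario.initial_state == {"T": 1, "E": 1, "I": 10, "S": 0}
        assert case3_scenario.horizon_days == 600

    def test_case2_initial_state_and_horizon(self, case2_scenario):
        assert case2_scenario.initial_state == {"T": 50, "E": 10, "I": 0}
        assert case2_scenario.horizon_days == 600

    def test_case1_external_default_provenance(self):
        scenario = ti.load_scenario("case1-s1")
        for name in ("a", "n", "p", "g", "m"):
            assert scenario.provenance[name] == "external-default"
        for name in ("b", "d", "s"):
            assert scenario.provenance[name] == "published-table"
        assert scenario.params.a == ti.KUZNETSOV_DEFAULTS["a"]

    def test_unknown_scenario_error_lists_builtins(self):
        with pytest.raises(ScenarioError, match="case1-s1.*case3"):
            ti.load_scenario("no-such-model")

    @pytest.mark.parametrize("label", ti.builtin_scenarios())
    def test_serialisation_round_trip(self, label, tmp_path):
        scenario = ti.load_scenario(label)
        path = tmp_path / f"{label}.yaml"
        ti.save_scenario(scenario, str(path))
        assert ti.load_scenario(str(path)) == scenario

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ScenarioError):
            ti.Case1Params(a=-1.0, b=0.002, n=1, p=1.1, g=20, m=0.003, d=0.2, s=0)
        with pytest.raises(ScenarioError):
            ti.Case2Params(c=0.05, mu2=0.03, p1=0.12, g1=0.0, s1=0, a=0.18, b=1e-9, aa=1, g2=1e5, p2=5, g3=1e3, mu3=10, s2=0)

    def test_scenario_rejects_mismatched_species(self, case2_scenario):
        with pytest.raises(ScenarioError):
            ti.ScenarioSpec(
                model_id="case1",
                label="bad",
                params=ti.load_scenario("case1-s1").params,
                initial_state={"T": 50},  # E missing
                horizon_days=100,
            )
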