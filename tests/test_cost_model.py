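"""Costing of tree paths and expected per-arm cost.

The expected-cost checks compare the module against an independent
brute-force enumeration written directly from the unit-cost inputs, kept
free of any package costing code.
"""

import pytest
from hypothesis import given
from hypothesis import strategies as st

import pphcea as P
from pphcea.synthetic_data import random_parameter_set


def brute_force_expected_cost(p: P.ParameterSet, arm: str) -> float:
    """Enumerate all ten (mode, terminal) paths with explicit arithmetic."""
    prevention = (
        p.cost_prevention_oxytocin if arm == "oxytocin" else p.cost_prevention_carbetocin
    )
    rr = 1.0 if arm == "oxytocin" else p.rr_carbetocin
    total = 0.0
    for mode, weight, p_pph_base, massive_frac, base_los in (
        ("vaginal", 1 - p.p_csection, p.p_pph_oxy_vaginal,
         p.p_massive_given_pph_vaginal, p.los_vaginal_no_pph),
        ("csection", p.p_csection, p.p_pph_oxy_csection,
         p.p_massive_given_pph_csection, p.los_csection_no_pph),
    ):
        p_pph = min(1.0, p_pph_base * rr)
        p_massive = p_pph * massive_frac
        p_hyst = p_massive * p.p_hysterectomy_given_massive
        cost_non_massive = (
            p.cost_uterotonic_treatment
            + base_los * p.los_pph_multiplier * p.cost_day_pph_no_hyst
        )
        cost_massive = (
            p.cost_uterotonic_treatment
            + p.cost_second_line
            + p.los_second_line * p.cost_day_pph_no_hyst
        )
        cost_hyst = (
            p.cost_uterotonic_treatment
            + p.cost_second_line
            + p.cost_hysterectomy
            + p.los_hysterectomy * p.cost_day_pph_hyst
        )
        total += weight * (
            (p_pph - p_massive) * cost_non_massive
            + (p_massive - p_hyst) * cost_massive
            + p_hyst * cost_hyst
        )
    return prevention + total


class TestPathCost:
    def test_non_massive_csection_path(self, params):
        pc = P.path_cost(params, "oxytocin", "csection", "pph_non_massive")
        assert pc.prevention_cost == 1.03
        assert pc.treatment_drug_cost == 63.0
        assert pc.procedure_cost == 0.0
        assert pc.stay_cost == pytest.approx(4.52 * 1.264 * 654)
        assert pc.total == pytest.approx(1.03 + 63 + 4.52 * 1.264 * 654)

    def test_carbetocin_no_pph_is_prevention_only(self, params):
        for mode in P.MODES:
            pc = P.path_cost(params, "carbetocin", mode, "no_pph")
            assert pc.total == 25.6

    def test_hysterectomy_paths_cost_the_same_dead_or_alive(self, params):
        a = P.path_cost(params, "oxytocin", "vaginal", "hysterectomy_survive")
        b = P.path_cost(params, "oxytocin", "vaginal", "hysterectomy_death")
        assert a.total == b.total
        assert a.procedure_cost == pytest.approx(2765 + 11477)

    def test_all_unit_costs_zero_gives_zero(self, params):
        zeroed = params.replace(
            cost_prevention_oxytocin=0, cost_prevention_carbetocin=0,
            cost_uterotonic_treatment=0, cost_second_line=0, cost_hysterectomy=0,
            cost_day_general=0, cost_day_hdu=0, cost_day_icu=0,
            cost_day_pph_no_hyst=0, cost_day_pph_hyst=0,
        )
        for arm in P.ARMS:
            for mode in P.MODES:
                for terminal in P.TERMINAL_STATES:
                    assert P.path_cost(zeroed, arm, mode, terminal).total == 0.0

    def test_unknown_terminal_rejected(self, params):
        with pytest.raises(ValueError, match="unknown terminal"):
            P.path_cost(params, "oxytocin", "vaginal", "not_a_state")


class TestExpectedArmCost:
    def test_base_case_totals_match_published_rounding(self, params):
        oxy = P.expected_arm_cost(params, "oxytocin")
        carb = P.expected_arm_cost(params, "carbetocin")
        assert round(oxy.expected_cost_per_birth) == 190
        assert round(carb.expected_cost_per_birth) == 161

    def test_oxytocin_treatment_component(self, params):
        # frozen from the brute-force enumeration below
        oxy = P.expected_arm_cost(params, "oxytocin")
        assert oxy.treatment_component == pytest.approx(188.556, abs=5e-3)

    def test_breakdown_sums_to_expected_cost(self, params):
        for arm in P.ARMS:
            ac = P.expected_arm_cost(params, arm)
            total = sum(pc.total * p for pc, p in ac.breakdown)
            assert total == pytest.approx(ac.expected_cost_per_birth, rel=1e-9)
            assert sum(p for _, p in ac.breakdown) == pytest.approx(1.0, abs=1e-12)

    @given(seed=st.integers(0, 5_000))
    def test_agreement_with_brute_force_enumeration(self, config, seed):
        p = random_parameter_set(config.ranges, seed=seed)
        for arm in P.ARMS:
            expected = brute_force_expected_cost(p, arm)
            got = P.expected_arm_cost(p, arm).expected_cost_per_birth
            assert got == pytest.approx(expected, rel=1e-12)

    @given(seed=st.integers(0, 5_000))
    def test_treatment_component_linear_in_relative_risk(self, config, seed):
        p = random_parameter_set(config.ranges, seed=seed)
        oxy = P.expected_arm_cost(p, "oxytocin")
        carb = P.expected_arm_cost(p, "carbetocin")
        assert carb.treatment_component == pytest.approx(
            p.rr_carbetocin * oxy.treatment_component, rel=1e-12
        )

    def test_incremental_cost_closed_form(self, params):
        # dCost = (rr - 1) T + (c_carb - c_oxy), T the oxytocin treatment part
        oxy = P.expected_arm_cost(params, "oxytocin")
        carb = P.expected_arm_cost(params, "carbetocin")
        dc = carb.expected_cost_per_birth - oxy.expected_cost_per_birth
        closed = (params.rr_carbetocin - 1) * oxy.treatment_component + (
            params.cost_prevention_carbetocin - params.cost_prevention_oxytocin
        )
        assert dc == pytest.approx(closed, rel=1e-12)

    def test_cost_non_decreasing_in_unit_costs_and_csection(self, params):
        base = P.expected_arm_cost(params, "oxytocin").expected_cost_per_birth
        for bump in (
            {"cost_hysterectomy": 12_000},
            {"cost_day_pph_no_hyst": 1_000},
            {"cost_uterotonic_treatment": 150},
            {"p_csection": 0.5},
        ):
            bumped = P.expected_arm_cost(
                params.replace(**bump), "oxytocin"
            ).expected_cost_per_birth
            assert bumped >= base
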