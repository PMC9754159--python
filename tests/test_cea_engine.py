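"""CEA engine: base case, DSA, threshold search, two-way curve, PSA."""

import numpy as np
import pytest

import pphcea as P
from pphcea.cea_engine import THRESHOLD_XTOL


def closed_form_rr_threshold(params, life_table, wtp):
    """Linear solution for the relative-risk threshold at a given WTP.

    dCost(rr) = (rr-1) T + dPrev and dQALYsaved(rr) = (1-rr) Q, so the net
    monetary benefit vanishes at rr* = 1 - dPrev / (T + wtp Q).
    """
    T = P.expected_arm_cost(params, "oxytocin").treatment_component
    Q = P.expected_arm_qaly_loss(params, "oxytocin", life_table).qaly_loss_per_birth
    d_prev = params.cost_prevention_carbetocin - params.cost_prevention_oxytocin
    return 1.0 - d_prev / (T + wtp * Q)


class TestBaseCase:
    def test_carbetocin_dominant_at_base_case(self, params, life_table):
        res = P.base_case(params, life_table)
        assert res.dominant
        assert res.icer is None
        assert res.decision == "carbetocin"
        assert res.incremental_cost == pytest.approx(-28.2, abs=0.5)
        # rounded per-arm totals differ by the published USD 29
        saving = round(res.cost_oxytocin.expected_cost_per_birth) - round(
            res.cost_carbetocin.expected_cost_per_birth
        )
        assert saving == 29

    def test_incremental_qaly_saved(self, params, life_table):
        res = P.base_case(params, life_table)
        assert res.incremental_qaly_saved == pytest.approx(0.00059, rel=0.05)

    def test_identical_arms_give_zero_increments(self, params, life_table):
        p = params.replace(
            rr_carbetocin=1.0,
            cost_prevention_carbetocin=params.cost_prevention_oxytocin,
        )
        res = P.base_case(p, life_table)
        assert res.incremental_cost == pytest.approx(0.0, abs=1e-12)
        assert res.incremental_qaly_saved == pytest.approx(0.0, abs=1e-15)
        assert res.decision == "carbetocin"  # ties resolve to accept


@pytest.fixture(scope="module")
def tornado(config, life_table):
    return P.one_way_dsa(config.params, config.iter_ranges(), life_table)


class TestOneWayDSA:
    def test_carbetocin_saves_qalys_at_every_range_end(self, tornado):
        assert (tornado["incremental_qaly_saved_low"] > 0).all()
        assert (tornado["incremental_qaly_saved_high"] > 0).all()

    def test_only_relative_risk_flips_cost_saving(self, tornado):
        rr_row = tornado.set_index("parameter").loc["rr_carbetocin"]
        assert rr_row["incremental_cost_low"] < 0
        assert rr_row["incremental_cost_high"] > 0  # 0.93 above the ~0.87 threshold

    def test_only_relative_risk_flips_the_decision(self, tornado):
        # the rr range high (0.93) lies above the WTP threshold (~0.915),
        # so rr is the one parameter whose decision flips
        flipped = set(tornado.loc[tornado["decision_flips"], "parameter"])
        assert flipped == {"rr_carbetocin"}

    def test_zero_width_range_gives_identical_ends(self, params, life_table):
        rng = P.SensitivityRange(parameter_name="p_csection", low=0.304, high=0.304)
        out = P.one_way_dsa(params, [rng], life_table)
        assert out.loc[0, "incremental_cost_low"] == out.loc[0, "incremental_cost_high"]


class TestFindThreshold:
    def test_cost_saving_threshold_matches_closed_form(self, params, life_table):
        res = P.find_threshold(
            params, "rr_carbetocin", "cost_saving", life_table=life_table
        )
        assert res.found
        closed = closed_form_rr_threshold(params, life_table, wtp=0.0)
        assert res.threshold == pytest.approx(closed, abs=THRESHOLD_XTOL)

    def test_wtp_threshold_matches_closed_form(self, params, life_table):
        wtp = params.wtp_threshold
        res = P.find_threshold(
            params, "rr_carbetocin", "cost_effective_at_wtp",
            wtp=wtp, life_table=life_table,
        )
        closed = closed_form_rr_threshold(params, life_table, wtp=wtp)
        assert res.threshold == pytest.approx(closed, abs=THRESHOLD_XTOL)

    def test_decision_flips_across_the_threshold(self, params, life_table):
        res = P.find_threshold(
            params, "rr_carbetocin", "cost_saving", life_table=life_table
        )
        eps = 1e-4
        below = P.base_case(
            params.replace(rr_carbetocin=res.threshold - eps), life_table
        )
        above = P.base_case(
            params.replace(rr_carbetocin=res.threshold + eps), life_table
        )
        assert below.incremental_cost < 0 < above.incremental_cost

    def test_no_sign_change_returns_no_threshold_result(self, params, life_table):
        res = P.find_threshold(
            params, "rr_carbetocin", "cost_saving",
            life_table=life_table, search_interval=(0.01, 0.5),
        )
        assert not res.found
        assert res.threshold is None
        assert res.constant_decision == "carbetocin"


class TestTwoWayCurve:
    def test_threshold_increases_with_csection_proportion(self, params, life_table):
        curve = P.two_way_threshold_curve(
            params, "p_csection", "rr_carbetocin",
            x_grid=np.linspace(0.0, 1.0, 6), life_table=life_table,
        )
        thresholds = curve["rr_carbetocin_threshold"].to_numpy()
        assert curve["found"].all()
        assert np.all(np.diff(thresholds) > 0)

    def test_zero_wtp_reduces_to_cost_saving_threshold(self, params, life_table):
        curve = P.two_way_threshold_curve(
            params, "p_csection", "rr_carbetocin",
            x_grid=[params.p_csection], wtp=0.0, life_table=life_table,
        )
        cs = P.find_threshold(
            params, "rr_carbetocin", "cost_saving", life_table=life_table
        )
        assert curve["rr_carbetocin_threshold"].iloc[0] == pytest.approx(
            cs.threshold, abs=2 * THRESHOLD_XTOL
        )


class TestPSA:
    def test_fixed_seed_is_bit_reproducible(self, config, life_table):
        kw = dict(n_draws=300, seed=99, life_table=life_table)
        a = P.run_psa(config.params, config.distributions, **kw)
        b = P.run_psa(config.params, config.distributions, **kw)
        assert np.array_equal(a.incremental_cost, b.incremental_cost)
        assert np.array_equal(a.incremental_qaly_saved, b.incremental_qaly_saved)

    def test_degenerate_distributions_reproduce_base_case(self, config, life_table):
        dists = [
            P.DistributionSpec(parameter_name=name, family="fixed",
                               value=getattr(config.params, name))
            for name in config.distributions
        ]
        res = P.run_psa(config.params, dists, n_draws=5, seed=1, life_table=life_table)
        base = P.base_case(config.params, life_table)
        assert np.allclose(res.incremental_cost, base.incremental_cost)
        assert np.allclose(res.incremental_qaly_saved, base.incremental_qaly_saved)

    def test_acceptance_fractions_and_decision_rule_consistency(
        self, config, life_table
    ):
        res = P.run_psa(
            config.params, config.distributions,
            n_draws=1_000, seed=7, life_table=life_table,
        )
        assert 0.0 <= res.fraction_cost_saving <= 1.0
        assert res.fraction_qaly_saving == 1.0  # rr support < 1
        # dominated-draw acceptance holds at every WTP >= 0
        dominant = (res.incremental_cost <= 0) & (res.incremental_qaly_saved >= 0)
        for wtp in (0.0, 1.0, 49_630.0, 1e9):
            dc, dq = res.incremental_cost, res.incremental_qaly_saved
            accept = ((dq >= 0) & (dc <= 0)) | ((dq > 0) & (dc <= wtp * dq))
            assert np.all(accept[dominant])
            assert res.fraction_cost_effective(wtp) >= res.fraction_cost_saving
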