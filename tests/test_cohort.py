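import numpy as np
import pytest

from pscea.cohort import (
    AdverseEvent,
    CostSet,
    ModelConfig,
    UtilitySet,
    build_trace,
    discount_factor,
    docetaxel_dose,
    run_arm,
    state_membership,
)
from pscea.survival import ParametricFit


def expo(rate):
    return ParametricFit("exponential", {"rate": rate}, 1, 0.0, 0.0, 0)


def lognorm(mu, sigma):
    return ParametricFit("lognormal", {"mu": mu, "sigma": sigma}, 2, 0.0, 0.0, 0)


ZERO_COSTS = CostSet(drug_cost_per_cycle=0.0)


class TestStateMembership:
    def test_everyone_progression_free_at_baseline(self):
        assert state_membership(expo(0.2), expo(0.1), 0.0) == (1.0, 0.0, 0.0)

    def test_partition_reads_off_the_two_curves(self):
        # S_OS = 0.6, S_PFS = 0.25 -> (0.25, 0.35, 0.40)
        t = 5.0
        pfs_fit = expo(-np.log(0.25) / t)
        os_fit = expo(-np.log(0.6) / t)
        pfs, pd_, dead = state_membership(pfs_fit, os_fit, t)
        assert pfs == pytest.approx(0.25)
        assert pd_ == pytest.approx(0.35)
        assert dead == pytest.approx(0.40)

    def test_incoherent_tail_clips_pd_and_conserves_occupancy(self):
        # S_OS = 0.2 < S_PFS = 0.3 -> (0.3, 0, 0.7)
        t = 5.0
        pfs_fit = expo(-np.log(0.3) / t)
        os_fit = expo(-np.log(0.2) / t)
        pfs, pd_, dead = state_membership(pfs_fit, os_fit, t)
        assert pfs == pytest.approx(0.3)
        assert pd_ == 0.0
        assert dead == pytest.approx(0.7)
        assert pfs + pd_ + dead == pytest.approx(1.0, abs=1e-12)


class TestBuildTrace:
    def test_equal_curves_leave_no_progressed_state(self):
        trace = build_trace(ModelConfig(), expo(0.1), expo(0.1))
        assert np.all(trace.pd == 0.0)

    def test_exponential_death_matches_closed_form(self):
        cfg = ModelConfig(half_cycle_correction=False)
        trace = build_trace(cfg, expo(0.1), expo(0.1))
        t120 = 120 * cfg.cycle_months
        assert trace.dead[-1] == pytest.approx(1 - np.exp(-0.1 * t120), abs=1e-12)

    def test_single_cycle_trace(self):
        cfg = ModelConfig(n_cycles=1, half_cycle_correction=False)
        trace = build_trace(cfg, expo(0.1), expo(0.05))
        assert trace.cycle.size == 1
        assert trace.time_months[0] == pytest.approx(cfg.cycle_months)

    def test_occupancy_conserved_and_death_monotone(self):
        trace = build_trace(ModelConfig(), lognorm(np.log(5.6), 1.1), lognorm(np.log(10.6), 1.1))
        np.testing.assert_allclose(trace.pfs + trace.pd + trace.dead, 1.0, atol=1e-9)
        assert np.all(np.diff(trace.dead) >= 0)
        assert np.all(np.diff(trace.pfs) <= 1e-12)
        assert np.all(trace.new_deaths >= 0)


class TestDiscounting:
    def test_zero_rate_never_discounts(self):
        assert discount_factor(0.0, 7.3) == 1.0

    def test_one_year_at_five_percent(self):
        assert discount_factor(0.05, 1.0) == pytest.approx(1 / 1.05)

    def test_fractional_years_match_log_domain_evaluation(self):
        assert discount_factor(0.03, 2.5) == pytest.approx(
            np.exp(-2.5 * np.log(1.03)), rel=1e-12
        )

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-0.01, 1.0)
        with pytest.raises(ValueError):
            discount_factor(0.03, -1.0)


class TestDose:
    def test_fixed_dose_override(self):
        assert docetaxel_dose(1.72, 75.0, fixed_dose_mg=140.0) == 140.0

    def test_bsa_based_dose(self):
        assert docetaxel_dose(1.82, 75.0) == pytest.approx(136.5)

    def test_vial_rounding_ceils_to_multiples(self):
        assert docetaxel_dose(1.82, 75.0, vial_size_mg=20.0) == 140.0

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            docetaxel_dose(0.0, 75.0)


class TestRunArm:
    def test_zero_inputs_give_zero_totals(self):
        res = run_arm(
            ModelConfig(),
            ZERO_COSTS,
            UtilitySet(u_pfs=0.0, u_pd=0.0),
            expo(0.1),
            expo(0.05),
        )
        assert res.total_cost == 0.0
        assert res.total_qaly == 0.0

    def test_geometric_series_oracle_for_exponential_arm(self):
        """With OS = PFS exponential, zero discount, drug cost only: totals
        equal the closed-form sums c·Σe^{−λt_c} and u·Δy·Σe^{−λt_c}."""
        lam, c, u = 0.1, 100.0, 0.8
        cfg = ModelConfig(
            discount_rate_cost=0.0, discount_rate_qaly=0.0, half_cycle_correction=False
        )
        res = run_arm(
            cfg,
            CostSet(drug_cost_per_cycle=c),
            UtilitySet(u_pfs=u, u_pd=0.0),
            expo(lam),
            expo(lam),
        )
        t = np.arange(1, 121) * cfg.cycle_months
        surv_sum = np.sum(np.exp(-lam * t))
        assert res.total_cost == pytest.approx(c * surv_sum, rel=1e-12)
        assert res.total_qaly == pytest.approx(u * cfg.cycle_years * surv_sum, rel=1e-12)

    def test_discounting_strictly_reduces_qalys(self):
        pfs, os_ = lognorm(np.log(5.6), 1.1), lognorm(np.log(10.6), 1.1)
        util = UtilitySet(u_pfs=0.8, u_pd=0.3)
        undisc = run_arm(
            ModelConfig(discount_rate_cost=0.0, discount_rate_qaly=0.0),
            ZERO_COSTS, util, pfs, os_,
        )
        disc = run_arm(ModelConfig(), ZERO_COSTS, util, pfs, os_)
        assert disc.total_qaly < undisc.total_qaly

    def test_costs_scale_linearly_and_utilities_scale_qalys(self):
        pfs, os_ = lognorm(np.log(5.6), 1.1), lognorm(np.log(10.6), 1.1)
        costs = CostSet(
            drug_cost_per_cycle=100.0,
            followup_cost_per_cycle=10.0,
            hospitalization_cost_per_cycle=20.0,
            bsc_cost_per_cycle=30.0,
            terminal_cost=500.0,
            ae_events=(AdverseEvent("x", 0.1, 1000.0),),
        )
        doubled = CostSet(
            drug_cost_per_cycle=200.0,
            followup_cost_per_cycle=20.0,
            hospitalization_cost_per_cycle=40.0,
            bsc_cost_per_cycle=60.0,
            terminal_cost=1000.0,
            ae_events=(AdverseEvent("x", 0.1, 2000.0),),
        )
        u1 = UtilitySet(u_pfs=0.4, u_pd=0.15)
        u2 = UtilitySet(u_pfs=0.8, u_pd=0.30)
        r1 = run_arm(ModelConfig(), costs, u1, pfs, os_)
        r2 = run_arm(ModelConfig(), doubled, u2, pfs, os_)
        assert r2.total_cost == pytest.approx(2 * r1.total_cost, rel=1e-12)
        assert r2.total_qaly == pytest.approx(2 * r1.total_qaly, rel=1e-12)

    def test_breakdown_sums_to_totals(self, base_case):
        for res in base_case.arm_results.values():
            assert sum(res.cost_breakdown.values()) == pytest.approx(
                res.total_cost, abs=1e-6
            )
            assert sum(res.qaly_breakdown.values()) == pytest.approx(
                res.total_qaly, abs=1e-6
            )

    def test_halving_cycle_length_changes_totals_under_two_percent(self):
        pfs, os_ = lognorm(np.log(5.6), 1.1), lognorm(np.log(10.6), 1.1)
        costs = CostSet(drug_cost_per_cycle=100.0, bsc_cost_per_cycle=30.0)
        util = UtilitySet(u_pfs=0.8, u_pd=0.3)
        coarse = run_arm(ModelConfig(), costs, util, pfs, os_)
        halved = CostSet(drug_cost_per_cycle=50.0, bsc_cost_per_cycle=15.0)
        fine = run_arm(
            ModelConfig(cycle_length_days=30.4375 / 2, n_cycles=240),
            halved, util, pfs, os_,
        )
        assert fine.total_qaly == pytest.approx(coarse.total_qaly, rel=0.02)
        assert fine.total_cost == pytest.approx(coarse.total_cost, rel=0.02)

    def test_weekly_cycles_match_continuous_integration_within_one_percent(self):
        """Discrete trace converges on the time integral as cycles shrink."""
        from scipy import integrate

        lam, u, r = 0.1, 0.8, 0.05
        n_weeks = int(round(120 * 30.4375 / 7))
        cfg = ModelConfig(
            cycle_length_days=7.0,
            n_cycles=n_weeks,
            discount_rate_cost=r,
            discount_rate_qaly=r,
        )
        res = run_arm(cfg, ZERO_COSTS, UtilitySet(u_pfs=u, u_pd=0.0), expo(lam), expo(lam))
        horizon_months = n_weeks * cfg.cycle_months
        integral, _ = integrate.quad(
            lambda t: u * np.exp(-lam * t) * (1 + r) ** (-t / 12.0) / 12.0,
            0, horizon_months,
        )
        assert res.total_qaly == pytest.approx(integral, rel=0.01)


def test_inverted_utilities_warn_but_are_accepted():
    with pytest.warns(UserWarning):
        UtilitySet(u_pfs=0.3, u_pd=0.5)
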