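"""Cost/utility accrual, treatment schedules and half-cycle discounting."""

import numpy as np
import pytest

from adcea import (
    accrue,
    classification_for,
    discount_halfcycle,
    run_cohort,
    run_strategy,
    treatment_cost_schedule,
)
from adcea.economics import ALL_SECTORS, CycleLedger
from adcea.params import EconSettings, TreatmentSpec


class TestTreatmentCostSchedule:
    def test_base_year1_components(self, base_params):
        sched = treatment_cost_schedule(base_params.treatment, 1,
                                        base_params.costs)
        assert sched["drug"] == 5000.0
        assert sched["administration"] == 26 * 285.0
        # every 3rd month: 4 visits + 4 MRI
        assert sched["monitoring"] == 4 * 300.0 + 4 * 300.0
        assert sched["total"] == sum(
            sched[k] for k in ("drug", "administration", "monitoring"))

    def test_subcutaneous_has_no_administration(self, params):
        params.treatment.admin_mode = "subcutaneous"
        sched = treatment_cost_schedule(params.treatment, 1, params.costs)
        assert sched["administration"] == 0.0

    def test_maintenance_monitoring_is_one_visit_one_mri(self, params):
        params.costs.physician_visit_cost = 123.0
        params.costs.mri_cost = 456.0
        for year in (2, 3, 10):
            sched = treatment_cost_schedule(params.treatment, year,
                                            params.costs)
            assert sched["monitoring"] == 123.0 + 456.0


def _constant_ledger(horizon, cost=0.0, qaly=0.0, diag=0.0):
    zeros = np.zeros(horizon + 1)
    return CycleLedger(
        horizon=horizon,
        sector_costs={"medical_open_care": np.full(horizon + 1, cost)},
        drug_cost=zeros.copy(), admin_cost=zeros.copy(),
        monitoring_cost=zeros.copy(), productivity_cost=zeros.copy(),
        diagnostic_cost=diag, qalys=np.full(horizon + 1, qaly),
        person_years={"MCI": np.ones(horizon + 1)}, deaths=0.0)


class TestDiscountHalfcycle:
    def test_constant_stream_closed_form(self):
        """½ + Σ₁²⁹ 1.03^−t + ½·1.03^−30 = 19.894448…"""
        ledger = _constant_ledger(30, cost=1.0)
        econ = EconSettings(discount_rate=0.03, horizon_years=30)
        res = discount_halfcycle(ledger, econ)
        expected = 0.5 + sum(1.03 ** -t for t in range(1, 30)) \
            + 0.5 * 1.03 ** -30
        assert res.cost_total == pytest.approx(expected, abs=1e-9)
        assert res.cost_total == pytest.approx(19.8944, abs=5e-4)

    def test_zero_rate_is_trapezoid(self):
        ledger = _constant_ledger(10, qaly=1.0)
        econ = EconSettings(discount_rate=0.0, horizon_years=10)
        res = discount_halfcycle(ledger, econ)
        assert res.qalys == pytest.approx(10.0)  # ½ + 9 + ½

    def test_cycle0_only_stream_gets_half_weight(self):
        ledger = _constant_ledger(5)
        ledger.qalys[0] = 1.0
        res = discount_halfcycle(ledger, EconSettings(horizon_years=5))
        assert res.qalys == pytest.approx(0.5)

    def test_diagnostic_cost_exempt_from_half_cycle_weight(self):
        ledger = _constant_ledger(5, diag=714.0)
        res = discount_halfcycle(ledger, EconSettings(horizon_years=5))
        assert res.cost_total == pytest.approx(714.0)


class TestAccrue:
    def test_soc_has_no_treatment_components(self, base_params):
        cls = classification_for(base_params, "SoC")
        trace = run_cohort(cls, base_params, "SoC")
        ledger = accrue(trace, base_params, "SoC")
        assert not ledger.drug_cost.any()
        assert not ledger.admin_cost.any()
        assert not ledger.monitoring_cost.any()
        assert ledger.diagnostic_cost == 714.0

    def test_single_cycle_utility_unit_case(self, params):
        """100% MCI occupancy for one undiscounted, unweighted cycle
        contributes exactly the MCI utility."""
        params.transitions.probs = {"AD": {}, "nonAD": {}}
        params.mortality.life_table = {a: 0.0 for a in range(40, 101)}
        params.econ.discount_rate = 0.0
        cls = classification_for(params, "SoC")
        trace = run_cohort(cls, params, "SoC")
        ledger = accrue(trace, params, "SoC")
        assert ledger.qalys[1] == pytest.approx(
            params.utilities.utilities["MCI"])

    def test_fp_disutility_unit_case(self, params):
        """A −0.05 misdiagnosis disutility on an alive FP arm lowers that
        cycle's QALY flow by 0.05 per FP person."""
        params.utilities.misdiagnosis_disutility = 0.05
        params.transitions.probs = {"AD": {}, "nonAD": {}}
        params.mortality.life_table = {a: 0.0 for a in range(40, 101)}
        cls = classification_for(params, "CSF")
        trace = run_cohort(cls, params, "CSF")
        base_utility = sum(
            cls.fraction(sg) * params.utilities.utilities["MCI"]
            for sg in ("TP", "TN", "FP", "FN"))
        ledger = accrue(trace, params, "CSF")
        penalty = 0.05 * (cls.fp + cls.fn)
        assert ledger.qalys[1] == pytest.approx(base_utility - penalty)

    def test_soc_never_accrues_misdiagnosis_disutility(self, params):
        """Nobody is misdiagnosed without a test: the SoC QALY stream is
        unchanged by the disutility setting."""
        cls = classification_for(params, "SoC")
        trace = run_cohort(cls, params, "SoC")
        before = accrue(trace, params, "SoC").qalys.copy()
        params.utilities.misdiagnosis_disutility = 0.05
        after = accrue(trace, params, "SoC").qalys
        assert after == pytest.approx(before)

    def test_disutility_duration_limits_penalty(self, params):
        params.utilities.misdiagnosis_disutility = 0.05
        params.utilities.disutility_duration = 2.0
        params.transitions.probs = {"AD": {}, "nonAD": {}}
        params.mortality.life_table = {a: 0.0 for a in range(40, 101)}
        cls = classification_for(params, "CSF")
        trace = run_cohort(cls, params, "CSF")
        ledger = accrue(trace, params, "CSF")
        assert ledger.qalys[1] < ledger.qalys[3]  # penalty only in years 0-1

    def test_productivity_cost_only_below_retirement(self, params):
        params.cohort.start_age = 60.0
        params.econ.horizon_years = 40
        cls = classification_for(params, "SoC")
        trace = run_cohort(cls, params, "SoC")
        ledger = accrue(trace, params, "SoC")
        assert ledger.productivity_cost[:5].all()   # ages 60-64
        assert not ledger.productivity_cost[5:].any()  # 65 onward


class TestStrategyResultInvariants:
    @pytest.mark.parametrize("name", ["SoC", "CSF", "BBM", "BBM_CSF"])
    def test_sector_costs_sum_to_total(self, base_params, name):
        res = run_strategy(base_params, name)
        assert sum(res.cost_by_sector.values()) == pytest.approx(
            res.cost_total, abs=1e-6)
        assert sum(res.cost_by_sector_undiscounted.values()) == pytest.approx(
            res.cost_total_undiscounted, abs=1e-6)
        assert set(res.cost_by_sector) == set(ALL_SECTORS)

    def test_person_years_account_for_whole_horizon(self, base_params):
        res = run_strategy(base_params, "SoC")
        assert res.py_alive + res.py_dead == pytest.approx(
            res.horizon, abs=1e-9)
        assert res.py_dead == pytest.approx(res.person_years["dead"], abs=1e-9)

    def test_higher_discount_never_raises_totals(self, params):
        last_cost, last_qaly = np.inf, np.inf
        for rate in (0.0, 0.03, 0.05, 0.10):
            params.econ.discount_rate = rate
            res = run_strategy(params, "CSF")
            assert res.cost_total <= last_cost + 1e-9
            assert res.qalys <= last_qaly + 1e-9
            last_cost, last_qaly = res.cost_total, res.qalys

    def test_cost_affine_in_drug_price_with_treated_time_slope(self, params):
        """Total cost is affine in the drug price; the slope equals the
        discounted treated person-time in treatable states."""
        costs = {}
        for price in (0.0, 5000.0, 10000.0):
            params.treatment.drug_price = price
            costs[price] = run_strategy(params, "CSF").cost_total
        slope1 = (costs[5000] - costs[0]) / 5000
        slope2 = (costs[10000] - costs[5000]) / 5000
        assert slope1 == pytest.approx(slope2, rel=1e-9)
        assert slope1 > 0

    def test_unit_utilities_give_discounted_life_years(self, params):
        """With every living utility at 1 and no disutility, QALYs equal
        half-cycle-weighted discounted life-years."""
        params.utilities.utilities = {s: 1.0 for s in
                                      ("MCI", "mild", "moderate", "severe")}
        params.utilities.utilities["dead"] = 0.0
        cls = classification_for(params, "SoC")
        trace = run_cohort(cls, params, "SoC")
        res = run_strategy(params, "SoC")
        H = params.econ.horizon_years
        w = np.ones(H + 1)
        w[0] = w[-1] = 0.5
        disc = 1.03 ** -np.arange(H + 1)
        alive = 1.0 - trace.dead_fraction()
        assert res.qalys == pytest.approx(float((w * disc) @ alive), abs=1e-9)
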