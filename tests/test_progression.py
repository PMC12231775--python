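"""Markov engine: closed-form pieces and cohort-trace invariants."""

import numpy as np
import pytest

from adcea import (
    ModelParams,
    ParamError,
    annualize,
    build_cycle_matrix,
    classification_for,
    effective_effect,
    mortality_prob,
    ordered_logit_probs,
    run_cohort,
    run_strategy,
)
from adcea.params import MortalityModel, TreatmentSpec
from adcea.progression import ArmState, transitions_from_ordered_logit
from adcea.params import OrderedLogitSpec
from adcea.synthetic import synth_params


class TestOrderedLogit:
    def test_symmetric_cutpoints_closed_form(self):
        # logistic CDF at ±ln(3) gives 0.25 / 0.75
        c = np.log(3.0)
        probs = ordered_logit_probs([-c, c], 0.0)
        assert probs == pytest.approx([0.25, 0.50, 0.25], abs=1e-9)

    def test_single_cutpoint_symmetry(self):
        assert ordered_logit_probs([0.0], 0.0) == pytest.approx([0.5, 0.5])

    def test_large_linear_predictor_limit(self):
        probs = ordered_logit_probs([-1.0, 1.0], 50.0)
        assert probs[-1] == pytest.approx(1.0, abs=1e-12)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            cuts = np.sort(rng.normal(size=4))
            if np.any(np.diff(cuts) <= 0):
                continue
            p = ordered_logit_probs(cuts, rng.normal())
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(p >= 0)

    def test_non_increasing_cutpoints_rejected(self):
        with pytest.raises(ParamError):
            ordered_logit_probs([1.0, 1.0], 0.0)

    def test_transitions_from_fit(self):
        spec = OrderedLogitSpec(cutpoints=[0.0],
                                linear_predictor={"AD": {"MCI": 0.0},
                                                  "nonAD": {"MCI": -1.0}})
        probs = transitions_from_ordered_logit(spec)
        assert probs["AD"]["MCI"] == pytest.approx(0.5)
        assert probs["nonAD"]["MCI"] < 0.5


class TestAnnualize:
    def test_three_year_conversion(self):
        # 0.729^(1/3) = 0.9 exactly
        assert annualize(0.271, 3) == pytest.approx(0.100, abs=1e-12)

    def test_identity_and_zero(self):
        assert annualize(0.37, 1) == pytest.approx(0.37)
        assert annualize(0.0, 7) == 0.0

    def test_certain_event_rejected(self):
        with pytest.raises(ParamError):
            annualize(1.0, 3)


class TestMortality:
    def _model(self, q):
        return MortalityModel(life_table={70: q},
                              hr_by_state={"MCI": 1.0, "mild": 1.5,
                                           "moderate": 2.5, "severe": 3.5})

    def test_unit_hazard_ratio_is_identity(self):
        m = self._model(0.0317)
        assert mortality_prob(m, 70, "MCI") == pytest.approx(0.0317)

    def test_hazard_composition_closed_form(self):
        m = self._model(0.02)
        # 1 - 0.98^2.5
        assert mortality_prob(m, 70, "moderate") == pytest.approx(
            1 - 0.98 ** 2.5, abs=1e-12)
        assert mortality_prob(m, 70, "moderate") == pytest.approx(
            0.049252, abs=1e-6)

    def test_zero_baseline_stays_zero(self):
        m = self._model(0.0)
        for state in ("MCI", "mild", "moderate", "severe"):
            assert mortality_prob(m, 70, state) == 0.0

    def test_age_outside_table_rejected(self):
        with pytest.raises(ParamError, match="life table"):
            mortality_prob(self._model(0.02), 71, "MCI")


class TestEffectiveEffect:
    def test_no_waning_constant(self):
        t = TreatmentSpec(effect_mci=0.30)
        for year in (1, 5, 20):
            assert effective_effect(t, year, "MCI") == pytest.approx(0.30)

    def test_waning_decay(self):
        t = TreatmentSpec(effect_mci=0.30, waning_rate=0.10)
        assert effective_effect(t, 3, "MCI") == pytest.approx(0.243)

    def test_full_effect_and_cap(self):
        assert effective_effect(TreatmentSpec(effect_mci=1.0), 4, "MCI") == 1.0
        grow = TreatmentSpec(effect_mci=0.30, waning_rate=-0.20)
        assert effective_effect(grow, 30, "MCI") == 1.0  # capped

    def test_state_outside_effect_states_is_zero(self):
        t = TreatmentSpec(effect_mci=0.30, effect_mild=0.30)
        assert effective_effect(t, 1, "moderate") == 0.0


class TestCycleMatrix:
    def test_rows_stochastic_for_random_bundles(self):
        for seed in range(10):
            p = synth_params(seed)
            for treated in (False, True):
                arm = ArmState("TP" if treated else "FN", "AD", treated,
                               years_on_treatment=3)
                M = build_cycle_matrix(arm, 72, p)
                assert np.all(M >= 0)
                assert M.sum(axis=1) == pytest.approx(np.ones(5), abs=1e-12)

    def test_identity_with_no_progression_no_mortality(self, params):
        params.transitions.probs = {"AD": {}, "nonAD": {}}
        params.mortality.life_table = {a: 0.0 for a in range(40, 101)}
        arm = ArmState("FN", "AD", False)
        M = build_cycle_matrix(arm, 70, params)
        assert M == pytest.approx(np.eye(5))

    def test_full_effect_halts_conversion(self, params):
        params.treatment.effect_mci = 1.0
        q = mortality_prob(params.mortality, 70, "MCI")
        arm = ArmState("TP", "AD", True, years_on_treatment=1)
        M = build_cycle_matrix(arm, 70, params)
        assert M[0, 0] == pytest.approx(1 - q)
        assert M[0, 4] == pytest.approx(q)
        assert M[0, 1] == 0.0

    def test_untreated_two_state_composition(self, params):
        """Death first, then survival-conditional conversion."""
        c = params.transitions.probs["AD"]["MCI"]
        q = mortality_prob(params.mortality, 70, "MCI")
        M = build_cycle_matrix(ArmState("FN", "AD", False), 70, params)
        assert M[0, 1] == pytest.approx((1 - q) * c, abs=1e-15)
        assert M[0, 0] == pytest.approx((1 - q) * (1 - c), abs=1e-15)

    def test_effect_not_applied_to_non_ad_track(self, params):
        treated = build_cycle_matrix(
            ArmState("FP", "nonAD", True, years_on_treatment=1), 70, params)
        untreated = build_cycle_matrix(
            ArmState("TN", "nonAD", False, years_on_treatment=1), 70, params)
        assert treated == pytest.approx(untreated)


class TestRunCohort:
    def test_frozen_cohort_without_dynamics(self, params):
        params.transitions.probs = {"AD": {}, "nonAD": {}}
        params.mortality.life_table = {a: 0.0 for a in range(40, 101)}
        cls = classification_for(params, "CSF")
        trace = run_cohort(cls, params, "CSF")
        assert np.allclose(trace.occupancy, trace.occupancy[0])

    def test_null_treatment_reproduces_soc_occupancy(self, params):
        """With zero effect the tested cohort progresses exactly like SoC."""
        params.treatment.effect_mci = 0.0
        params.treatment.effect_mild = 0.0
        soc = run_cohort(classification_for(params, "SoC"), params, "SoC")
        csf = run_cohort(classification_for(params, "CSF"), params, "CSF")
        for t in range(soc.horizon + 1):
            assert soc.state_occupancy(t) == pytest.approx(
                csf.state_occupancy(t), abs=1e-12)

    def test_trace_invariants_on_base_case(self, base_params):
        for name in ("SoC", "CSF", "BBM", "BBM_CSF"):
            trace = run_cohort(classification_for(base_params, name),
                               base_params, name)
            trace.validate()  # mass conservation, dead monotone, >= 0
            assert trace.dead_fraction()[-1] > 0.99

    def test_discontinuation_is_convex_combination(self, params):
        """The d>0 trace equals (1−d)·(always treated) + d·(treated one
        year, then off) — verified against direct simulation."""
        d = 0.15
        params.treatment.discontinuation_year1 = d
        cls = classification_for(params, "CSF")
        mixed = run_cohort(cls, params, "CSF")

        p_on = params.model_copy(deep=True)
        p_on.treatment.discontinuation_year1 = 0.0
        stay = run_cohort(cls, p_on, "CSF")
        p_off = params.model_copy(deep=True)
        p_off.treatment.discontinuation_year1 = 1.0
        leave = run_cohort(cls, p_off, "CSF")

        for t in range(mixed.horizon + 1):
            expect = (1 - d) * stay.state_occupancy(t) \
                + d * leave.state_occupancy(t)
            assert mixed.state_occupancy(t) == pytest.approx(expect, abs=1e-12)

    def test_stronger_effect_never_increases_late_state_time(self, params):
        """Lifetime person-years in moderate+severe fall (weakly) as the
        treatment effect grows."""
        last = np.inf
        for effect in (0.0, 0.15, 0.30, 0.45, 1.0):
            params.treatment.effect_mci = effect
            params.treatment.effect_mild = effect
            res = run_strategy(params, "CSF")
            late = res.person_years["moderate"] + res.person_years["severe"]
            assert late <= last + 1e-12
            last = late

    def test_long_format_export(self, base_params):
        trace = run_cohort(classification_for(base_params, "CSF"),
                           base_params, "CSF")
        df = trace.to_frame()
        assert set(df.columns) >= {"cycle", "subgroup", "state", "fraction"}
        per_cycle = df.groupby("cycle")["fraction"].sum()
        assert np.allclose(per_cycle, 1.0)


def test_arm_state_track_consistency():
    with pytest.raises(ParamError):
        ArmState("TP", "nonAD", True)
    with pytest.raises(ParamError):
        ArmState("TN", "nonAD", True)  # untested subgroup cannot be treated


def test_synthetic_bundle_traces_valid():
    for seed in (0, 1, 2):
        p = synth_params(seed)
        trace = run_cohort(classification_for(p, "CSF"), p, "CSF")
        trace.validate()
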