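"""One-way sensitivity scenarios: named overrides on the base parameters.

Each scenario is a set of field-path overrides applied to a deep copy of
the base :class:`ModelParams` (the base object is never mutated),
re-validated, and run against its comparator pair(s).  The catalogue
reproduces the published one-way analyses: treatment start age, waning,
discontinuation, effect size, start state, treated states, horizon,
price, administration route, discount rate, misdiagnosis disutility,
drug-specific (lecanemab / donanemab) variants, and alternative BBM
accuracy sources quoted as predictive values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Optional

import pandas as pd

from .cea import compare
from .economics import run_strategy
from .params import (
    ModelParams,
    ParamError,
    accuracy_from_predictive_values,
    load_base_case,
)

log = logging.getLogger(__name__)

#: Default comparison: the CSF test-treat strategy against standard of care.
DEFAULT_PAIR = ("CSF", "SoC")


@dataclass(frozen=True)
class ScenarioOverride:
    """Named parameter overrides plus the comparator pairs to run."""

    name: str
    overrides: dict[str, Any] = field(default_factory=dict)
    comparisons: tuple[tuple[str, str], ...] = (DEFAULT_PAIR,)


def _set_path(obj: Any, path: str, value: Any) -> None:
    parts = path.split(".")
    for part in parts[:-1]:
        if isinstance(obj, dict):
            if part not in obj:
                raise ParamError(f"override path {path!r}: no key {part!r}")
            obj = obj[part]
        else:
            if not hasattr(obj, part):
                raise ParamError(f"override path {path!r}: no field {part!r}")
            obj = getattr(obj, part)
    last = parts[-1]
    if isinstance(obj, dict):
        obj[last] = value
    else:
        if not hasattr(obj, last):
            raise ParamError(f"override path {path!r}: no field {last!r}")
        setattr(obj, last, value)


def apply_override(base: ModelParams,
                   override: ScenarioOverride) -> ModelParams:
    """Deep-copied parameters with the overrides applied; base unchanged.

    Paths are dotted (``treatment.drug_price``); dict keys are path
    segments too (``costs.diagnostic_costs.SoC``).  The result is
    re-validated, so an override that breaks an invariant is rejected.
    """
    params = base.model_copy(deep=True)
    for path, value in override.overrides.items():
        _set_path(params, path, value)
    # round-trip through validation so cross-field invariants re-run
    try:
        return ModelParams.model_validate(params.model_dump())
    except Exception as exc:
        raise ParamError(
            f"scenario {override.name!r} produces invalid parameters: {exc}"
        ) from exc


def _csf_positive_rate(base: ModelParams) -> float:
    """Marginal P(CSF+): the prevalence of the BBM's reference condition."""
    csf = base.tests["csf"]
    prev = base.cohort.prevalence
    return csf.sens * prev + (1.0 - csf.spec) * (1.0 - prev)


def _horizon_to_100(start_age: float) -> int:
    return max(int(round(100 - start_age)), 1)


def scenario_catalogue(base: Optional[ModelParams] = None
                       ) -> list[ScenarioOverride]:
    """The named one-way scenarios (base parameters default to the
    bundled base case; needed to invert quoted PPV/NPV for the
    alternative BBM accuracy sources at the configured prevalence)."""
    if base is None:
        base = load_base_case()
    mild_start = {"AD": {"mild": 1.0}, "nonAD": {"mild": 1.0}}
    csf_pos = _csf_positive_rate(base)

    def bbm_alt(name: str, ppv: float, npv: float) -> dict[str, Any]:
        test = accuracy_from_predictive_values(ppv, npv, csf_pos, name=name)
        return {"tests.bbm": test}

    scenarios = [
        ScenarioOverride("aat_start_60", {
            "cohort.start_age": 60.0,
            "econ.horizon_years": _horizon_to_100(60)}),
        ScenarioOverride("aat_start_65", {
            "cohort.start_age": 65.0,
            "econ.horizon_years": _horizon_to_100(65)}),
        ScenarioOverride("discontinuation_10",
                         {"treatment.discontinuation_year1": 0.10}),
        ScenarioOverride("discontinuation_20",
                         {"treatment.discontinuation_year1": 0.20}),
        ScenarioOverride("waning_10", {"treatment.waning_rate": 0.10}),
        ScenarioOverride("waning_20", {"treatment.waning_rate": 0.20}),
        ScenarioOverride("waning_minus_10", {"treatment.waning_rate": -0.10}),
        ScenarioOverride("waning_minus_20", {"treatment.waning_rate": -0.20}),
        ScenarioOverride("effect_100", {"treatment.effect_mci": 1.0,
                                        "treatment.effect_mild": 1.0}),
        ScenarioOverride("effect_45", {"treatment.effect_mci": 0.45,
                                       "treatment.effect_mild": 0.45}),
        ScenarioOverride("effect_15", {"treatment.effect_mci": 0.15,
                                       "treatment.effect_mild": 0.15}),
        ScenarioOverride("start_in_mild",
                         {"cohort.start_state_mix": mild_start}),
        ScenarioOverride("treat_also_moderate", {
            "treatment.treat_states": ("MCI", "mild", "moderate"),
            "treatment.effect_states": ("MCI", "mild", "moderate"),
            "treatment.effect_moderate": base.treatment.effect_mild}),
        ScenarioOverride("horizon_10", {"econ.horizon_years": 10}),
        ScenarioOverride("horizon_20", {"econ.horizon_years": 20}),
        ScenarioOverride("price_2500", {"treatment.drug_price": 2500.0}),
        ScenarioOverride("price_25000", {"treatment.drug_price": 25_000.0}),
        ScenarioOverride("soc_diagnostics_as_csf", {
            "costs.diagnostic_costs.SoC":
                base.costs.diagnostic_costs["CSF"]}),
        ScenarioOverride("subcutaneous_weekly",
                         {"treatment.admin_mode": "subcutaneous"}),
        ScenarioOverride("discount_0", {"econ.discount_rate": 0.0}),
        ScenarioOverride("discount_5", {"econ.discount_rate": 0.05}),
        ScenarioOverride("disutility_fp_fn",
                         {"utilities.misdiagnosis_disutility": 0.05},
                         comparisons=(("CSF", "SoC"), ("BBM", "SoC"),
                                      ("BBM_CSF", "SoC"))),
        ScenarioOverride("discontinuation_10_waning_10", {
            "treatment.discontinuation_year1": 0.10,
            "treatment.waning_rate": 0.10}),
        ScenarioOverride("discontinuation_10_waning_10_subcutaneous", {
            "treatment.discontinuation_year1": 0.10,
            "treatment.waning_rate": 0.10,
            "treatment.admin_mode": "subcutaneous"}),
        ScenarioOverride("lecanemab", {
            "cohort.start_age": 71.0,
            "econ.horizon_years": _horizon_to_100(71),
            "cohort.start_state_mix": {"AD": {"MCI": 0.615, "mild": 0.385},
                                       "nonAD": {"MCI": 0.615, "mild": 0.385}},
            "treatment.effect_mci": 0.28,
            "treatment.effect_mild": 0.27,
            "treatment.discontinuation_year1": 0.069}),
        ScenarioOverride("donanemab", {
            "cohort.start_age": 73.0,
            "econ.horizon_years": _horizon_to_100(73),
            "cohort.start_state_mix": {"AD": {"MCI": 0.17, "mild": 0.83},
                                       "nonAD": {"MCI": 0.17, "mild": 0.83}},
            "treatment.effect_mci": 0.30,
            "treatment.effect_mild": 0.33,
            "treatment.discontinuation_year1": 0.131}),
        ScenarioOverride("bbm_aps2", bbm_alt("bbm_aps2", ppv=0.886, npv=0.909),
                         comparisons=(("BBM", "SoC"), ("BBM_CSF", "SoC"))),
        ScenarioOverride("bbm_ptau217_ratio",
                         bbm_alt("bbm_ptau217_ratio", ppv=0.840, npv=0.945),
                         comparisons=(("BBM", "SoC"), ("BBM_CSF", "SoC"))),
    ]
    return scenarios


def run_sensitivity(base: ModelParams,
                    catalogue: Optional[list[ScenarioOverride]] = None,
                    wtp: Optional[float] = None) -> pd.DataFrame:
    """One row per scenario × comparison: ΔCost, ΔQALY, ICER, iNHB.

    The first row is the unmodified base case.  A failing scenario is
    logged and reported with an error message; the run continues.
    """
    if catalogue is None:
        catalogue = scenario_catalogue(base)
    if wtp is None:
        wtp = base.econ.wtp
    rows = []
    entries = [ScenarioOverride("base_case")] + list(catalogue)
    for scenario in entries:
        try:
            params = apply_override(base, scenario)
            results = {}
            for strat, ref in scenario.comparisons:
                for name in (strat, ref):
                    if name not in results:
                        results[name] = run_strategy(params, name)
                cmp = compare(results[strat], results[ref], wtp)
                rows.append({
                    "scenario": scenario.name, "strategy": strat,
                    "reference": ref, "d_cost": cmp.d_cost,
                    "d_qaly": cmp.d_qaly, "icer": cmp.icer,
                    "icer_label": cmp.icer_label, "inhb": cmp.inhb,
                    "error": "",
                })
        except Exception as exc:  # keep going: report the failure
            log.warning("scenario %s failed: %s", scenario.name, exc)
            rows.append({"scenario": scenario.name, "strategy": "",
                         "reference": "", "d_cost": float("nan"),
                         "d_qaly": float("nan"), "icer": None,
                         "icer_label": "error", "inhb": float("nan"),
                         "error": str(exc)})
    return pd.DataFrame(rows)
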