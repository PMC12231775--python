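"""Costs, utilities and discounting over the cohort trace.

Each cycle books state costs by payer sector, treatment costs (drug,
administration, monitoring) for on-treatment arms occupying treatable
states, QALYs from state utilities (with the optional misdiagnosis
disutility for tested FP/FN arms), and the optional productivity cost
below retirement age.  The diagnostic work-up is a one-time cost at
model entry.  Lifetime totals apply trapezoidal half-cycle weights
(½ at cycle 0 and the final cycle) combined with annual discounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .diagnostics import (
    Classification,
    StrategyRule,
    classify,
    get_strategy,
    joint_outcome_table,
)
from .params import (
    LIVING_STATES,
    RETIREMENT_AGE,
    SECTORS,
    STATES,
    CostSet,
    EconSettings,
    ModelParams,
    ParamError,
    TreatmentSpec,
)
from .progression import CohortTrace, run_cohort

_STATE_INDEX = {s: i for i, s in enumerate(STATES)}

#: Derived sectors appended to the configured payer sectors in reports.
AAT_SECTOR = "medical_aat"
DIAG_SECTOR = "medical_diagnostics"
PROD_SECTOR = "productivity"
ALL_SECTORS = SECTORS + (AAT_SECTOR, DIAG_SECTOR, PROD_SECTOR)


def treatment_cost_schedule(treatment: TreatmentSpec, year_on_treatment: int,
                            unit_costs: CostSet) -> dict[str, float]:
    """EUR per fully-treated person for a given treatment year.

    Drug price + administration (infusions × unit cost; zero for
    subcutaneous dosing at home) + monitoring (year 1: the intensive
    schedule; later years: the maintenance schedule).
    """
    if year_on_treatment < 1:
        raise ParamError("year_on_treatment must be >= 1")
    drug = treatment.drug_price
    if treatment.admin_mode == "infusion":
        admin = treatment.infusions_per_year * treatment.admin_unit_cost
    else:
        admin = 0.0
    sched = (treatment.monitoring_year1 if year_on_treatment == 1
             else treatment.monitoring_later)
    monitoring = (sched.physician_visits * unit_costs.physician_visit_cost
                  + sched.mri * unit_costs.mri_cost)
    return {"drug": drug, "administration": admin, "monitoring": monitoring,
            "total": drug + admin + monitoring}


@dataclass
class CycleLedger:
    """Per-cycle costs (per person of the cohort), QALYs and person-years."""

    horizon: int
    sector_costs: dict[str, np.ndarray]   # configured payer sectors
    drug_cost: np.ndarray
    admin_cost: np.ndarray
    monitoring_cost: np.ndarray
    productivity_cost: np.ndarray
    diagnostic_cost: float                # one-time, cycle 0
    qalys: np.ndarray
    person_years: dict[str, np.ndarray]   # occupancy per state per cycle
    deaths: float                         # dead fraction at the horizon

    def aat_cost(self) -> np.ndarray:
        return self.drug_cost + self.admin_cost + self.monitoring_cost


def accrue(trace: CohortTrace, params: ModelParams,
           strategy: Union[str, StrategyRule]) -> CycleLedger:
    """Attach costs and utilities to every cycle of the trace."""
    rule = get_strategy(strategy) if isinstance(strategy, str) else strategy
    H = trace.horizon
    costs, utils, treat = params.costs, params.utilities, params.treatment
    tested = rule.treats  # SoC administers no test: nobody is misdiagnosed
    misdiag = utils.misdiagnosis_disutility
    duration = utils.disutility_duration
    treat_idx = [_STATE_INDEX[s] for s in treat.treat_states]
    living_idx = [_STATE_INDEX[s] for s in LIVING_STATES]

    sector_costs = {sec: np.zeros(H + 1) for sec in SECTORS}
    drug = np.zeros(H + 1)
    admin = np.zeros(H + 1)
    monitoring = np.zeros(H + 1)
    productivity = np.zeros(H + 1)
    qalys = np.zeros(H + 1)

    unit_state_cost = {
        s: {sec: costs.sector_cost(s, sec) for sec in SECTORS}
        for s in LIVING_STATES}
    unit_utility = {s: utils.utility(s) for s in LIVING_STATES}

    for t in range(H + 1):
        age = trace.start_age + t
        year_on_treatment = t + 1
        sched = None
        for i, arm in enumerate(trace.arms):
            occ = trace.occupancy[t, i]
            if not occ.any():
                continue
            for s in LIVING_STATES:
                mass = occ[_STATE_INDEX[s]]
                if mass == 0.0:
                    continue
                for sec in SECTORS:
                    sector_costs[sec][t] += mass * unit_state_cost[s][sec]
                qalys[t] += mass * unit_utility[s]
            alive = occ[living_idx].sum()
            if tested and misdiag > 0.0 and arm.subgroup in ("FP", "FN"):
                within = duration == "lifetime" or t < float(duration)
                if within:
                    qalys[t] -= misdiag * alive
            if arm.on_treatment and rule.treats:
                treated_mass = occ[treat_idx].sum()
                if treated_mass > 0.0:
                    if sched is None:
                        sched = treatment_cost_schedule(
                            treat, year_on_treatment, costs)
                    drug[t] += treated_mass * sched["drug"]
                    admin[t] += treated_mass * sched["administration"]
                    monitoring[t] += treated_mass * sched["monitoring"]
            if costs.productivity_cost_annual is not None \
                    and age < RETIREMENT_AGE:
                productivity[t] += alive * costs.productivity_cost_annual

    try:
        diagnostic = costs.diagnostic_costs[rule.name]
    except KeyError:
        raise ParamError(f"no diagnostic cost for strategy {rule.name!r}")

    person_years = {
        s: trace.occupancy[:, :, _STATE_INDEX[s]].sum(axis=1) for s in STATES}
    return CycleLedger(
        horizon=H, sector_costs=sector_costs, drug_cost=drug,
        admin_cost=admin, monitoring_cost=monitoring,
        productivity_cost=productivity, diagnostic_cost=diagnostic,
        qalys=qalys, person_years=person_years,
        deaths=float(trace.dead_fraction()[-1]))


@dataclass
class StrategyResult:
    """Discounted lifetime per-person results for one strategy.

    ``cost_by_sector`` includes the configured payer sectors plus the
    derived AAT, diagnostics and productivity entries; their sum equals
    ``cost_total``.  Person-years are undiscounted but half-cycle
    weighted, matching the headline per-person presentation.
    """

    strategy: str
    cost_total: float
    cost_by_sector: dict[str, float]
    qalys: float
    cost_total_undiscounted: float
    cost_by_sector_undiscounted: dict[str, float]
    qalys_undiscounted: float
    person_years: dict[str, float]
    py_alive: float
    py_dead: float
    deaths: float
    horizon: int
    aat_components: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for total, sectors in (
                (self.cost_total, self.cost_by_sector),
                (self.cost_total_undiscounted, self.cost_by_sector_undiscounted)):
            if abs(total - sum(sectors.values())) > 1e-6:
                raise ParamError("sector costs do not sum to the total cost")


def _halfcycle_weights(horizon: int, half_cycle: bool) -> np.ndarray:
    w = np.ones(horizon + 1)
    if half_cycle:
        w[0] = w[-1] = 0.5
    return w


def discount_halfcycle(ledger: CycleLedger, econ: EconSettings,
                       strategy: str = "") -> StrategyResult:
    """Collapse the cycle ledger into lifetime totals.

    Trapezoidal half-cycle weights combine with discount factors
    (1+r)^(−t), applied identically to costs and QALYs; the one-time
    diagnostic work-up cost enters at full weight at time 0.
    Person-years use the same half-cycle weights, undiscounted.
    """
    H = ledger.horizon
    w = _halfcycle_weights(H, econ.half_cycle)
    disc = (1.0 + econ.discount_rate) ** -np.arange(H + 1)

    def totals(discounted: bool) -> tuple[float, dict[str, float]]:
        f = w * disc if discounted else w
        sectors = {sec: float(f @ arr)
                   for sec, arr in ledger.sector_costs.items()}
        sectors[AAT_SECTOR] = float(f @ ledger.aat_cost())
        sectors[DIAG_SECTOR] = ledger.diagnostic_cost
        sectors[PROD_SECTOR] = float(f @ ledger.productivity_cost)
        return sum(sectors.values()), sectors

    cost_total, by_sector = totals(True)
    cost_undisc, by_sector_undisc = totals(False)
    fd = w * disc
    qalys = float(fd @ ledger.qalys)
    qalys_undisc = float(w @ ledger.qalys)
    person_years = {s: float(w @ arr)
                    for s, arr in ledger.person_years.items()}
    py_alive = sum(person_years.get(s, 0.0) for s in LIVING_STATES)
    aat = {"drug": float(fd @ ledger.drug_cost),
           "administration": float(fd @ ledger.admin_cost),
           "monitoring": float(fd @ ledger.monitoring_cost)}
    return StrategyResult(
        strategy=strategy, cost_total=cost_total, cost_by_sector=by_sector,
        qalys=qalys, cost_total_undiscounted=cost_undisc,
        cost_by_sector_undiscounted=by_sector_undisc,
        qalys_undiscounted=qalys_undisc, person_years=person_years,
        py_alive=py_alive, py_dead=H - py_alive, deaths=ledger.deaths,
        horizon=H, aat_components=aat)


def run_strategy(params: ModelParams,
                 strategy: Union[str, StrategyRule]) -> StrategyResult:
    """Full pipeline for one strategy: classify → trace → accrue → discount."""
    rule = get_strategy(strategy) if isinstance(strategy, str) else strategy
    joint = joint_outcome_table(params.tests["csf"], params.tests["bbm"],
                                params.cohort.prevalence)
    cls = classify(rule, joint)
    trace = run_cohort(cls, params, rule)
    ledger = accrue(trace, params, rule)
    return discount_halfcycle(ledger, params.econ, strategy=rule.name)


def classification_for(params: ModelParams,
                       strategy: Union[str, StrategyRule]) -> Classification:
    """The strategy's TP/TN/FP/FN fractions under the configured tests."""
    rule = get_strategy(strategy) if isinstance(strategy, str) else strategy
    joint = joint_outcome_table(params.tests["csf"], params.tests["bbm"],
                                params.cohort.prevalence)
    return classify(rule, joint)
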