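"""Synthetic inputs and an individual-level microsimulation oracle.

Everything here exists so the full pipeline is testable without any
registry or trial data: a Gompertz life table, binomial diagnostic
validation samples, random invariant-satisfying parameter bundles, and
a microsimulation that pushes individuals through the *same* per-cycle
transition matrices and accounting rules as the cohort engine, giving
Monte-Carlo means and standard errors to validate the deterministic
trace against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .diagnostics import Classification, StrategyRule, get_strategy
from .economics import treatment_cost_schedule
from .params import (
    LIVING_STATES,
    RETIREMENT_AGE,
    SECTORS,
    STATES,
    CohortSpec,
    CostSet,
    DiagnosticTest,
    EconSettings,
    ModelParams,
    MortalityModel,
    MonitoringSchedule,
    ParamError,
    TransitionModel,
    TreatmentSpec,
    UtilitySet,
)
from .progression import SUBGROUP_TRACK, ArmState, build_cycle_matrix

_STATE_INDEX = {s: i for i, s in enumerate(STATES)}
_DEAD = _STATE_INDEX["dead"]


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic generators; the seed fixes all randomness."""

    seed: int = 0
    n_individuals: int = 200_000
    gompertz_a: float = 2e-5
    gompertz_b: float = 0.1
    accuracy_sample_n: int = 100_000
    age_range: tuple[int, int] = (40, 100)

    def __post_init__(self) -> None:
        if self.gompertz_a <= 0 or self.gompertz_b <= 0:
            raise ParamError("Gompertz parameters must be positive")


def synth_life_table(cfg: SynthConfig) -> dict[int, float]:
    """Gompertz life table: q(age) = 1 − exp(−a·exp(b·age)), capped at 0.999.

    Monotone non-decreasing in age for any positive parameters.
    """
    lo, hi = cfg.age_range
    return {age: min(1.0 - math.exp(-cfg.gompertz_a
                                    * math.exp(cfg.gompertz_b * age)), 0.999)
            for age in range(lo, hi + 1)}


def synth_accuracy_sample(n: int, prevalence: float, sens: float, spec: float,
                          seed: int) -> dict[str, int]:
    """Simulate a 2×2 diagnostic validation sample of size n.

    Condition status is binomial at the prevalence; the test result is
    binomial given condition.  With large n,
    :func:`~adcea.params.accuracy_from_counts` recovers the inputs.
    """
    for label, p in (("prevalence", prevalence), ("sens", sens),
                     ("spec", spec)):
        if not 0.0 <= p <= 1.0:
            raise ParamError(f"{label} outside [0, 1]")
    rng = np.random.default_rng(seed)
    n_pos = int(rng.binomial(n, prevalence))
    tp = int(rng.binomial(n_pos, sens)) if n_pos else 0
    tn = int(rng.binomial(n - n_pos, spec)) if n - n_pos else 0
    return {"tp": tp, "fn": n_pos - tp, "tn": tn, "fp": n - n_pos - tn}


def synth_params(seed: int) -> ModelParams:
    """A random but invariant-satisfying parameter bundle.

    Utilities are ordered MCI ≥ mild ≥ moderate ≥ severe, state costs
    rise with severity, all probabilities are valid, and the life table
    covers the horizon — so every draw passes load-time validation.
    """
    rng = np.random.default_rng(seed)
    cfg = SynthConfig(seed=seed,
                      gompertz_a=float(rng.uniform(1e-5, 5e-5)),
                      gompertz_b=float(rng.uniform(0.08, 0.12)))
    life = synth_life_table(cfg)

    prog_ad = {"MCI": float(rng.uniform(0.05, 0.20)),
               "mild": float(rng.uniform(0.10, 0.30)),
               "moderate": float(rng.uniform(0.15, 0.35))}
    prog_non = {s: p * float(rng.uniform(0.5, 1.0))
                for s, p in prog_ad.items()}

    u = float(rng.uniform(0.70, 0.90))
    utilities = {}
    for state in LIVING_STATES:
        utilities[state] = round(u, 4)
        u *= float(rng.uniform(0.6, 0.95))
    utilities["dead"] = 0.0

    base_total = float(rng.uniform(3_000, 8_000))
    state_costs = {}
    for state in LIVING_STATES:
        weights = rng.dirichlet(np.ones(len(SECTORS)))
        state_costs[state] = {sec: round(base_total * float(w), 2)
                              for sec, w in zip(SECTORS, weights)}
        base_total *= float(rng.uniform(1.5, 3.0))

    prevalence = float(rng.uniform(0.30, 0.60))
    tests = {
        "csf": DiagnosticTest(name="csf",
                              sens=float(rng.uniform(0.85, 0.99)),
                              spec=float(rng.uniform(0.85, 0.99))),
        "bbm": DiagnosticTest(name="bbm",
                              sens=float(rng.uniform(0.65, 0.95)),
                              spec=float(rng.uniform(0.65, 0.95))),
    }
    treatment = TreatmentSpec(
        effect_mci=float(rng.uniform(0.0, 0.5)),
        effect_mild=float(rng.uniform(0.0, 0.5)),
        waning_rate=float(rng.uniform(-0.10, 0.20)),
        discontinuation_year1=float(rng.uniform(0.0, 0.2)),
        drug_price=float(rng.uniform(2_000, 10_000)),
        admin_mode="infusion" if rng.random() < 0.7 else "subcutaneous",
        admin_unit_cost=float(rng.uniform(100, 500)),
        infusions_per_year=int(rng.choice([13, 26])),
    )
    utilset = UtilitySet(
        utilities=utilities,
        misdiagnosis_disutility=(0.0 if rng.random() < 0.5
                                 else float(rng.uniform(0.0, 0.05))),
    )
    return ModelParams(
        cohort=CohortSpec(size=100_000, start_age=70.0, prevalence=prevalence),
        tests=tests,
        treatment=treatment,
        transitions=TransitionModel(probs={"AD": prog_ad, "nonAD": prog_non}),
        mortality=MortalityModel(
            life_table=life,
            hr_by_state={"MCI": 1.0,
                         "mild": float(rng.uniform(1.2, 2.0)),
                         "moderate": float(rng.uniform(2.0, 3.0)),
                         "severe": float(rng.uniform(3.0, 5.0))}),
        costs=CostSet(
            state_costs=state_costs,
            diagnostic_costs={name: round(float(rng.uniform(500, 2_000)), 2)
                              for name in ("SoC", "CSF", "BBM", "BBM_CSF")}),
        utilities=utilset,
        econ=EconSettings(discount_rate=float(rng.uniform(0.0, 0.05)),
                          horizon_years=30),
        rng_seed=seed,
    )


@dataclass
class MicrosimResult:
    """Monte-Carlo estimates (mean ± standard error of the mean)."""

    n: int
    mean: dict[str, float]
    se: dict[str, float]
    person_years_mean: dict[str, float]
    person_years_se: dict[str, float]


def microsim(cls: Classification, params: ModelParams,
             n: int, seed: int,
             strategy: Union[str, StrategyRule, None] = None
             ) -> MicrosimResult:
    """Individual-level simulation through the cohort engine's matrices.

    Individuals are assigned a diagnostic subgroup, a start state from
    the track's mix, and (for treated subgroups) a year-1
    discontinuation flag; each cycle they move by categorical sampling
    from the identical :func:`build_cycle_matrix` rows, and the
    identical cost/utility ledger is accumulated per individual with
    half-cycle weights and discounting.  Same seed → identical output.
    """
    if n < 1:
        raise ParamError("n must be >= 1")
    rule = get_strategy(strategy) if isinstance(strategy, str) else strategy
    if rule is None:
        # treatment arms exist exactly when the classification has
        # test positives
        treats = cls.tp + cls.fp > 0
        rule = get_strategy("CSF") if treats else get_strategy("SoC")
    rng = np.random.default_rng(seed)
    H = params.econ.horizon_years
    econ, treat, costs, utils = (params.econ, params.treatment,
                                 params.costs, params.utilities)

    subgroups = ("TP", "TN", "FP", "FN")
    fractions = np.array([cls.fraction(sg) for sg in subgroups])
    sg_idx = rng.choice(4, size=n, p=fractions)
    track_is_ad = np.isin(sg_idx, [0, 3])          # TP, FN
    treated = rule.treats & np.isin(sg_idx, [0, 2])  # TP, FP
    d = treat.discontinuation_year1
    discontinued = treated & (rng.random(n) < d)

    # start states per track
    state = np.zeros(n, dtype=np.int8)
    for is_ad, track in ((True, "AD"), (False, "nonAD")):
        mask = track_is_ad == is_ad
        if not mask.any():
            continue
        mix = params.cohort.start_state_mix[track]
        names = list(mix)
        probs = np.array([mix[s] for s in names])
        draws = rng.choice(len(names), size=int(mask.sum()), p=probs)
        state[mask] = np.array([_STATE_INDEX[s] for s in names],
                               dtype=np.int8)[draws]

    # per-state unit quantities
    state_cost_total = np.zeros(5)
    utility = np.zeros(5)
    for s in LIVING_STATES:
        i = _STATE_INDEX[s]
        state_cost_total[i] = sum(costs.sector_cost(s, sec) for sec in SECTORS)
        utility[i] = utils.utility(s)
    in_treat_state = np.zeros(5, dtype=bool)
    for s in treat.treat_states:
        in_treat_state[_STATE_INDEX[s]] = True
    alive_state = np.arange(5) != _DEAD

    misdiag_member = rule.treats and utils.misdiagnosis_disutility > 0.0
    misdiagnosed = np.isin(sg_idx, [2, 3]) if misdiag_member else \
        np.zeros(n, dtype=bool)
    duration = utils.disutility_duration

    w = np.ones(H + 1)
    if econ.half_cycle:
        w[0] = w[-1] = 0.5
    disc = (1.0 + econ.discount_rate) ** -np.arange(H + 1)
    fw = w * disc

    cost_i = np.full(n, costs.diagnostic_costs[rule.name], dtype=float)
    qaly_i = np.zeros(n)
    py_i = np.zeros((n, 5))

    def accrue_cycle(t: int) -> None:
        age = params.cohort.start_age + t
        on_t = treated & ~(discontinued & (t >= 1))
        alive = alive_state[state]
        cyc_cost = state_cost_total[state].copy()
        cyc_qaly = utility[state].copy()
        if misdiag_member:
            within = duration == "lifetime" or t < float(duration)
            if within:
                cyc_qaly[misdiagnosed & alive] -= utils.misdiagnosis_disutility
        treated_now = on_t & in_treat_state[state]
        if treated_now.any():
            sched = treatment_cost_schedule(treat, t + 1, costs)
            cyc_cost[treated_now] += sched["total"]
        if costs.productivity_cost_annual is not None and age < RETIREMENT_AGE:
            cyc_cost[alive] += costs.productivity_cost_annual
        cost_i[:] += fw[t] * cyc_cost
        qaly_i[:] += fw[t] * cyc_qaly
        py_i[np.arange(n), state] += w[t]

    accrue_cycle(0)
    for t in range(H):
        age = params.cohort.start_age + t
        on_t = treated & ~(discontinued & (t >= 1))
        # three distinct dynamics: AD on treatment, AD off, nonAD
        group_defs = (
            (track_is_ad & on_t,
             ArmState("TP", "AD", True, years_on_treatment=t + 1)),
            (track_is_ad & ~on_t,
             ArmState("FN", "AD", False, years_on_treatment=t + 1)),
            (~track_is_ad,
             ArmState("TN", "nonAD", False, years_on_treatment=t + 1)),
        )
        new_state = state.copy()
        for mask, arm in group_defs:
            if not mask.any():
                continue
            M = build_cycle_matrix(arm, age, params)
            cum = np.cumsum(M, axis=1)
            for s in range(5):
                sel = mask & (state == s)
                m = int(sel.sum())
                if m == 0:
                    continue
                u = rng.random(m)
                new_state[sel] = np.searchsorted(cum[s], u,
                                                 side="right").astype(np.int8)
        state = new_state
        accrue_cycle(t + 1)

    dead_i = (state == _DEAD).astype(float)

    mean, se = {}, {}
    for key, arr in (("cost_total", cost_i), ("qalys", qaly_i),
                     ("deaths", dead_i)):
        m, s = float(arr.mean()), (float(arr.std(ddof=1) / math.sqrt(n))
                                   if n > 1 else 0.0)
        mean[key], se[key] = m, s
    py_mean, py_se = {}, {}
    for s_name in STATES:
        arr = py_i[:, _STATE_INDEX[s_name]]
        py_mean[s_name] = float(arr.mean())
        py_se[s_name] = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return MicrosimResult(n=n, mean=mean, se=se,
                          person_years_mean=py_mean, person_years_se=py_se)
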