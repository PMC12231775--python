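"""Markov cohort engine for disease progression under treatment.

States are MCI → mild → moderate → severe → dead, with no backward
transitions.  Each diagnostic subgroup (TP/TN/FP/FN) evolves as a
separate arm on its track (AD or non-AD).  Within a cycle death comes
first, taken from the general-population life table scaled by a
severity-specific hazard ratio; progression is conditional on survival.
Treated true positives have their MCI→mild and mild→moderate
conversions reduced by the treatment effect (possibly waning over
time); treated false positives are on the non-AD track and gain
nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np
from scipy.special import expit

from .diagnostics import Classification, StrategyRule, get_strategy
from .params import (
    LIVING_STATES,
    STATES,
    ModelParams,
    MortalityModel,
    OrderedLogitSpec,
    ParamError,
    TreatmentSpec,
)

_STATE_INDEX = {s: i for i, s in enumerate(STATES)}
_DEAD = _STATE_INDEX["dead"]

#: Diagnostic subgroup → progression track.  TP/FN carry amyloid
#: pathology (AD track); TN/FP do not.
SUBGROUP_TRACK = {"TP": "AD", "FN": "AD", "TN": "nonAD", "FP": "nonAD"}


@dataclass(frozen=True)
class ArmState:
    """One cohort arm: diagnostic subgroup × treatment status."""

    subgroup: str          # TP / TN / FP / FN
    track: str             # AD / nonAD
    treated: bool
    years_on_treatment: int = 0
    discontinued: bool = False

    def __post_init__(self) -> None:
        if self.subgroup not in SUBGROUP_TRACK:
            raise ParamError(f"unknown subgroup {self.subgroup!r}")
        if self.track != SUBGROUP_TRACK[self.subgroup]:
            raise ParamError(
                f"subgroup {self.subgroup} must be on track "
                f"{SUBGROUP_TRACK[self.subgroup]}, got {self.track}")
        if self.treated and self.subgroup in ("TN", "FN"):
            raise ParamError("only test-positive subgroups (TP/FP) are treated")

    @property
    def on_treatment(self) -> bool:
        return self.treated and not self.discontinued


def ordered_logit_probs(cutpoints: list[float] | np.ndarray,
                        linear_predictor: float) -> np.ndarray:
    """Category probabilities of a cumulative-logit (ordered) model.

    P(category ≤ k) = logistic(cutpoint_k − linear_predictor); the
    category probabilities are the consecutive differences and sum to 1.
    """
    c = np.asarray(cutpoints, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ParamError("cutpoints must be a non-empty 1-D sequence")
    if np.any(np.diff(c) <= 0):
        raise ParamError("cutpoints must be strictly increasing")
    cum = expit(c - linear_predictor)
    return np.diff(np.concatenate(([0.0], cum, [1.0])))


def transitions_from_ordered_logit(spec: OrderedLogitSpec
                                   ) -> dict[str, dict[str, float]]:
    """Annual one-step progression probabilities from an ordered-logit fit.

    The derived probability of leaving a source state is the mass the
    model places above that state's category, P(next category > source).
    """
    probs: dict[str, dict[str, float]] = {}
    for track, lps in spec.linear_predictor.items():
        probs[track] = {}
        for state, lp in lps.items():
            idx = LIVING_STATES.index(state)
            cat = ordered_logit_probs(spec.cutpoints, lp)
            probs[track][state] = float(cat[idx + 1:].sum())
    return probs


def annualize(cumulative_prob: float, years: float) -> float:
    """Convert a cumulative transition probability to an annual one.

    Constant-hazard assumption: 1 − (1 − p)^(1/years).
    """
    if not 0.0 <= cumulative_prob < 1.0:
        raise ParamError(
            f"cumulative probability must be in [0, 1), got {cumulative_prob}"
            + (" (rate undefined at 1)" if cumulative_prob == 1.0 else ""))
    if years <= 0:
        raise ParamError(f"years must be positive, got {years}")
    return 1.0 - (1.0 - cumulative_prob) ** (1.0 / years)


def mortality_prob(mortality: MortalityModel, age: float, state: str) -> float:
    """Annual death probability at `age` in `state`.

    The severity hazard ratio scales the general-population hazard:
    q = 1 − exp(−HR·r) with r = −ln(1 − q_gen), i.e. 1 − (1−q_gen)^HR.
    MCI has HR 1 (general-population risk).
    """
    a = int(np.floor(age))
    try:
        q_gen = mortality.life_table[a]
    except KeyError:
        raise ParamError(f"age {a} outside the life table "
                         f"({min(mortality.life_table)}.."
                         f"{max(mortality.life_table)})")
    hr = mortality.hr_by_state[state]
    if q_gen >= 1.0:
        return 1.0 if hr > 0 else 0.0
    return 1.0 - (1.0 - q_gen) ** hr


def effective_effect(treatment: TreatmentSpec, years_on_treatment: int,
                     state: str = "MCI") -> float:
    """Fractional progression reduction in a given treatment year.

    Full effect in year 1; each later year multiplies by
    (1 − waning_rate).  A negative waning rate grows the effect, capped
    at 1 (complete halt of conversion).
    """
    if years_on_treatment < 1:
        raise ParamError("years_on_treatment must be >= 1")
    base = treatment.effect_for(state)
    e = base * (1.0 - treatment.waning_rate) ** (years_on_treatment - 1)
    return float(min(max(e, 0.0), 1.0))


def build_cycle_matrix(arm: ArmState, age: float,
                       params: ModelParams) -> np.ndarray:
    """Row-stochastic one-cycle transition matrix over the five states.

    Death first (life table × severity HR), then survival-conditional
    one-step progression; treated, non-discontinued AD arms in effect
    states progress at (1 − effect) times the natural rate.
    """
    M = np.zeros((5, 5))
    tr = params.transitions
    for state in LIVING_STATES:
        i = _STATE_INDEX[state]
        q = mortality_prob(params.mortality, age, state)
        prog = tr.progression(arm.track, state)
        if (arm.on_treatment and arm.track == "AD"
                and state in params.treatment.effect_states):
            e = effective_effect(params.treatment,
                                 max(arm.years_on_treatment, 1), state)
            prog *= (1.0 - e)
        if prog > 1.0:
            raise ParamError(
                f"progression out of {state!r} exceeds 1 after composition")
        M[i, _DEAD] = q
        if state != "severe":
            M[i, i + 1] = (1.0 - q) * prog
            M[i, i] = (1.0 - q) * (1.0 - prog)
        else:
            M[i, i] = 1.0 - q
    M[_DEAD, _DEAD] = 1.0
    return M


@dataclass
class CohortTrace:
    """State occupancy by cycle for every arm (fractions of the cohort)."""

    arms: tuple[ArmState, ...]
    occupancy: np.ndarray  # shape (horizon+1, n_arms, 5)
    start_age: float

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def state_occupancy(self, cycle: int) -> np.ndarray:
        """Total occupancy per state at a cycle, summed over arms."""
        return self.occupancy[cycle].sum(axis=0)

    def dead_fraction(self) -> np.ndarray:
        return self.occupancy[:, :, _DEAD].sum(axis=1)

    def validate(self) -> None:
        occ = self.occupancy
        if np.any(occ < -1e-12):
            raise ParamError("negative occupancy in trace")
        totals = occ.sum(axis=(1, 2))
        if np.any(np.abs(totals - 1.0) > 1e-10):
            raise ParamError("occupancy does not sum to 1 in every cycle")
        dead = self.dead_fraction()
        if np.any(np.diff(dead) < -1e-12):
            raise ParamError("dead occupancy decreases between cycles")

    def to_frame(self) -> "pd.DataFrame":
        """Long-format trace (cycle, arm, state, fraction)."""
        import pandas as pd
        records = []
        for t in range(self.horizon + 1):
            for a, arm in enumerate(self.arms):
                for s, state in enumerate(STATES):
                    records.append({
                        "cycle": t,
                        "age": self.start_age + t,
                        "subgroup": arm.subgroup,
                        "treated": arm.treated,
                        "discontinued": arm.discontinued,
                        "state": state,
                        "fraction": self.occupancy[t, a, s],
                    })
        return pd.DataFrame.from_records(records)


def _initial_occupancy(arm: ArmState, mass: float,
                       params: ModelParams) -> np.ndarray:
    row = np.zeros(5)
    mix = params.cohort.start_state_mix[arm.track]
    for state, frac in mix.items():
        row[_STATE_INDEX[state]] = mass * frac
    return row


def run_cohort(cls: Classification, params: ModelParams,
               strategy: Union[str, StrategyRule]) -> CohortTrace:
    """Evolve the classified cohort over the full horizon.

    Arms start in the configured state mix at cycle 0.  The year-1
    discontinuation fraction of each treated arm moves to a matching
    off-treatment arm at the end of cycle 1 (same subgroup and track;
    drug, administration, monitoring and effect all cease).
    """
    rule = get_strategy(strategy) if isinstance(strategy, str) else strategy
    if abs(cls.total - 1.0) > 1e-9:
        raise ParamError("classification fractions must sum to 1")

    arms = []
    for subgroup in ("TP", "TN", "FP", "FN"):
        treated = rule.treats and subgroup in ("TP", "FP")
        arms.append(ArmState(subgroup=subgroup,
                             track=SUBGROUP_TRACK[subgroup],
                             treated=treated))
    d = params.treatment.discontinuation_year1
    split = rule.treats and d > 0.0
    if split:
        arms += [ArmState(subgroup=sg, track=SUBGROUP_TRACK[sg],
                          treated=True, discontinued=True)
                 for sg in ("TP", "FP")]
    arms = tuple(arms)
    index = {(a.subgroup, a.discontinued): i for i, a in enumerate(arms)}

    H = params.econ.horizon_years
    occ = np.zeros((H + 1, len(arms), 5))
    for i, arm in enumerate(arms):
        if arm.discontinued:
            continue
        occ[0, i] = _initial_occupancy(arm, cls.fraction(arm.subgroup), params)

    for t in range(H):
        age = params.cohort.start_age + t
        for i, arm in enumerate(arms):
            if not occ[t, i].any():
                occ[t + 1, i] = 0.0
                continue
            M = build_cycle_matrix(replace(arm, years_on_treatment=t + 1),
                                   age, params)
            occ[t + 1, i] = occ[t, i] @ M
        if t == 0 and split:
            for sg in ("TP", "FP"):
                src = index[(sg, False)]
                dst = index[(sg, True)]
                moved = d * occ[1, src]
                occ[1, src] -= moved
                occ[1, dst] += moved

    trace = CohortTrace(arms=arms, occupancy=occ,
                        start_age=params.cohort.start_age)
    trace.validate()
    return trace
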