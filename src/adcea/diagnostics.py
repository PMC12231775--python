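"""Diagnostic decision tree: joint biomarker outcomes and classification.

The blood-based biomarker (BBM, plasma p-tau 217) is validated against
CSF Aβ42/40, and CSF against amyloid PET.  Chaining the two accuracy
tables under conditional independence (BBM ⊥ PET | CSF) yields the joint
distribution of the eight (BBM±, CSF±, PET±) outcomes, from which every
strategy's cohort is classified into true/false positives/negatives
against PET amyloid status — the reference standard throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Optional

import pandas as pd

from .params import CohortSpec, CostSet, DiagnosticTest, ParamError

Outcome = tuple[bool, bool, bool]  # (bbm positive, csf positive, pet positive)


@dataclass(frozen=True)
class JointOutcomeTable:
    """Probability of each (BBM±, CSF±, PET±) combination.

    Cells sum to 1; the PET+ marginal equals the configured prevalence.
    """

    probs: dict[Outcome, float]

    @property
    def prevalence(self) -> float:
        return sum(p for (_, _, pet), p in self.probs.items() if pet)

    def marginal(self, bbm: Optional[bool] = None, csf: Optional[bool] = None,
                 pet: Optional[bool] = None) -> float:
        """Sum of cells matching the given (possibly partial) outcome."""
        total = 0.0
        for (b, c, a), p in self.probs.items():
            if bbm is not None and b is not bbm:
                continue
            if csf is not None and c is not csf:
                continue
            if pet is not None and a is not pet:
                continue
            total += p
        return total


def joint_outcome_table(csf_given_pet: DiagnosticTest,
                        bbm_given_csf: DiagnosticTest,
                        prevalence: float) -> JointOutcomeTable:
    """Chain the two accuracy tables under conditional independence.

    P(b, c, p) = P(b | c) · P(c | p) · P(p), where ``csf_given_pet``
    provides P(c | p) (sens/spec vs PET) and ``bbm_given_csf`` provides
    P(b | c) (sens/spec vs CSF).
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ParamError(f"prevalence {prevalence} outside [0, 1]")
    probs: dict[Outcome, float] = {}
    for bbm, csf, pet in product((True, False), repeat=3):
        p_pet = prevalence if pet else 1.0 - prevalence
        if pet:
            p_csf = csf_given_pet.sens if csf else 1.0 - csf_given_pet.sens
        else:
            p_csf = 1.0 - csf_given_pet.spec if csf else csf_given_pet.spec
        if csf:
            p_bbm = bbm_given_csf.sens if bbm else 1.0 - bbm_given_csf.sens
        else:
            p_bbm = 1.0 - bbm_given_csf.spec if bbm else bbm_given_csf.spec
        probs[(bbm, csf, pet)] = p_bbm * p_csf * p_pet
    return JointOutcomeTable(probs=probs)


@dataclass(frozen=True)
class StrategyRule:
    """A diagnostic strategy: which tests run and when the work-up is positive.

    A positive work-up triggers anti-amyloid treatment.  SoC administers
    no amyloid test and treats no one.
    """

    name: str
    uses: tuple[str, ...]
    positive: Callable[[bool, bool], bool] = field(compare=False)

    @property
    def treats(self) -> bool:
        return len(self.uses) > 0


STRATEGIES: dict[str, StrategyRule] = {
    "SoC": StrategyRule("SoC", (), lambda bbm, csf: False),
    "CSF": StrategyRule("CSF", ("csf",), lambda bbm, csf: csf),
    "BBM": StrategyRule("BBM", ("bbm",), lambda bbm, csf: bbm),
    "BBM_CSF": StrategyRule("BBM_CSF", ("bbm", "csf"),
                            lambda bbm, csf: bbm and csf),
}


def get_strategy(name: str) -> StrategyRule:
    try:
        return STRATEGIES[name]
    except KeyError:
        raise ParamError(
            f"unknown strategy {name!r}; valid: {sorted(STRATEGIES)}")


@dataclass(frozen=True)
class Classification:
    """TP/TN/FP/FN fractions of the cohort against PET amyloid status."""

    tp: float
    tn: float
    fp: float
    fn: float

    @property
    def prevalence(self) -> float:
        return self.tp + self.fn

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn

    def fraction(self, subgroup: str) -> float:
        return {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn}[
            subgroup]


def classify(rule: StrategyRule, joint: JointOutcomeTable) -> Classification:
    """Classify the cohort under a strategy's positivity rule.

    SoC tests no one: nobody is treated, so everyone with amyloid
    pathology is an (untreated) false negative and everyone without is a
    true negative.
    """
    if isinstance(rule, str):
        rule = get_strategy(rule)
    tp = fp = 0.0
    for (bbm, csf, pet), p in joint.probs.items():
        if rule.positive(bbm, csf):
            if pet:
                tp += p
            else:
                fp += p
    prev = joint.prevalence
    return Classification(tp=tp, tn=(1.0 - prev) - fp, fp=fp, fn=prev - tp)


def round_half_away(x: float) -> int:
    """Round half away from zero (report-time person counts)."""
    import math
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def person_counts(cls: Classification, size: int) -> dict[str, int]:
    return {k: round_half_away(cls.fraction(k) * size)
            for k in ("TP", "TN", "FP", "FN")}


@dataclass(frozen=True)
class DiagnosticCosting:
    """Strategy-level diagnostic work-up costs.

    ``per_tp``/``per_tn`` are None (undefined) when the strategy has no
    true positives / true negatives.
    """

    strategy: str
    per_person: float
    total: float
    per_tp: Optional[float]
    per_tn: Optional[float]


def diagnostic_costing(rule: StrategyRule, cls: Classification,
                       costs: CostSet, cohort: CohortSpec) -> DiagnosticCosting:
    """Total cohort work-up cost and cost per true positive / negative case."""
    if isinstance(rule, str):
        rule = get_strategy(rule)
    try:
        per_person = costs.diagnostic_costs[rule.name]
    except KeyError:
        raise ParamError(
            f"no diagnostic cost configured for strategy {rule.name!r}")
    total = per_person * cohort.size
    per_tp = total / (cls.tp * cohort.size) if cls.tp > 0 else None
    per_tn = total / (cls.tn * cohort.size) if cls.tn > 0 else None
    return DiagnosticCosting(strategy=rule.name, per_person=per_person,
                             total=total, per_tp=per_tp, per_tn=per_tn)


def classification_table(joint: JointOutcomeTable, size: int,
                         strategies: Optional[list[str]] = None
                         ) -> pd.DataFrame:
    """Diagnostic-category block (persons per cohort) for each strategy."""
    names = strategies or ["CSF", "BBM", "BBM_CSF"]
    rows = {}
    for name in names:
        cls = classify(get_strategy(name), joint)
        rows[name] = person_counts(cls, size)
    df = pd.DataFrame(rows)
    df.index = ["True positive", "True negative",
                "False positive", "False negative"]
    return df
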