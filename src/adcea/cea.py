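"""Cost-effectiveness comparison metrics and the drug-price threshold.

ICER = ΔCost/ΔQALY between a strategy and its reference; net monetary
benefit NMB = QALY·WTP − Cost; net health benefit NHB = QALY − Cost/WTP;
incremental NHB = ΔQALY − ΔCost/WTP.  In the south-west quadrant
(cheaper, fewer QALYs) the ICER reads as savings per QALY lost.  The
price threshold exploits that incremental cost is affine in the annual
drug price while QALYs do not depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .diagnostics import StrategyRule, get_strategy
from .economics import StrategyResult, run_strategy
from .params import ModelParams, ParamError


@dataclass(frozen=True)
class CEAComparison:
    """Pairwise decision metrics of a strategy against a reference."""

    strategy: str
    reference: str
    d_cost: float
    d_qaly: float
    icer: Optional[float]       # None when undefined or dominance applies
    icer_label: str             # "ICER", "ICER (savings per QALY lost)",
                                # "dominant", "dominated", "undefined"
    nmb: float                  # of the strategy itself
    nhb: float
    inhb: float                 # incremental NHB vs the reference
    wtp: float


def compare(result: StrategyResult, reference: StrategyResult,
            wtp: float) -> CEAComparison:
    """Compute ΔCost, ΔQALY, ICER (with quadrant label), NMB/NHB, iNHB."""
    if result.horizon != reference.horizon:
        raise ParamError("results compare only over an identical horizon")
    d_cost = result.cost_total - reference.cost_total
    d_qaly = result.qalys - reference.qalys
    if d_qaly == 0.0:
        icer, label = None, "undefined"
    elif d_cost < 0.0 and d_qaly > 0.0:
        icer, label = None, "dominant"
    elif d_cost > 0.0 and d_qaly < 0.0:
        icer, label = None, "dominated"
    else:
        icer = d_cost / d_qaly
        label = ("ICER (savings per QALY lost)"
                 if d_cost < 0.0 and d_qaly < 0.0 else "ICER")
    nmb = result.qalys * wtp - result.cost_total
    nhb = result.qalys - result.cost_total / wtp
    inhb = d_qaly - d_cost / wtp
    return CEAComparison(strategy=result.strategy,
                         reference=reference.strategy,
                         d_cost=d_cost, d_qaly=d_qaly, icer=icer,
                         icer_label=label, nmb=nmb, nhb=nhb, inhb=inhb,
                         wtp=wtp)


def _with_price(params: ModelParams, price: float) -> ModelParams:
    p = params.model_copy(deep=True)
    p.treatment.drug_price = price
    return p


def price_threshold(params: ModelParams,
                    strategy: Union[str, StrategyRule],
                    reference: Union[str, StrategyRule],
                    wtp: float,
                    verify_tol: float = 1e-6) -> float:
    """Annual drug price at which the ICER vs the reference reaches WTP.

    QALYs are independent of the price, so ΔCost is affine in it; two
    model evaluations identify slope and intercept, and the threshold
    solves ΔCost(price) = wtp·ΔQALY (at wtp = 0: the cost-saving
    price).  The result is verified by one re-run.
    """
    rule = get_strategy(strategy) if isinstance(strategy, str) else strategy
    ref = get_strategy(reference) if isinstance(reference, str) else reference
    if not rule.treats:
        raise ParamError(f"strategy {rule.name!r} includes no treatment")
    p0, p1 = 0.0, 10_000.0
    ref_result = run_strategy(params, ref)
    r0 = run_strategy(_with_price(params, p0), rule)
    r1 = run_strategy(_with_price(params, p1), rule)
    d_qaly = r0.qalys - ref_result.qalys
    if d_qaly <= 0.0:
        raise ParamError("price threshold requires a positive QALY gain "
                         "versus the reference")
    intercept = r0.cost_total - ref_result.cost_total
    slope = (r1.cost_total - r0.cost_total) / (p1 - p0)
    if slope <= 0.0:
        raise ParamError("incremental cost does not increase with price; "
                         "no threshold exists")
    threshold = (wtp * d_qaly - intercept) / slope

    check = run_strategy(_with_price(params, threshold), rule)
    d_cost = check.cost_total - ref_result.cost_total
    target = wtp * d_qaly
    scale = max(abs(target), abs(wtp), 1.0)
    if abs(d_cost - target) > verify_tol * scale:
        raise ParamError("threshold verification failed: incremental cost "
                         f"{d_cost:.6f} != wtp x dQALY {target:.6f}")
    return threshold
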