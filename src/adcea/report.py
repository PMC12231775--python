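"""Report tables mirroring the published layouts.

Full-precision DataFrames; the ``format_*`` helpers round the way the
published tables do (costs to whole €, QALYs to 3 decimals, incremental
net health benefit to 2).  Stored CSVs keep full precision; negative
numbers use the ASCII minus.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .cea import compare, price_threshold
from .diagnostics import diagnostic_costing, person_counts
from .economics import (
    ALL_SECTORS,
    StrategyResult,
    classification_for,
    run_strategy,
)
from .params import SECTORS, ModelParams

PY_ROWS = (
    ("PY alive", "py_alive"),
    ("PY nondementia", "MCI"),
    ("PY mild dementia", "mild"),
    ("PY moderate dementia", "moderate"),
    ("PY severe dementia", "severe"),
    ("PY dead", "py_dead"),
)


def person_year_table(params: ModelParams,
                      results: dict[str, StrategyResult]) -> pd.DataFrame:
    """Lifetime person-years, deaths and diagnostic counts per strategy."""
    size = params.cohort.size
    rows: dict[str, dict[str, float]] = {}
    for label, key in PY_ROWS:
        rows[label] = {}
        for name, res in results.items():
            if key in ("py_alive", "py_dead"):
                rows[label][name] = getattr(res, key)
            else:
                rows[label][name] = res.person_years[key]
    dementia = {name: res.person_years["mild"] + res.person_years["moderate"]
                + res.person_years["severe"] for name, res in results.items()}
    rows["PY dementia"] = dementia
    rows["Deaths"] = {name: res.deaths * size for name, res in results.items()}
    for name in results:
        cls = classification_for(params, name)
        counts = person_counts(cls, size)
        for sub, label in (("TP", "True positive"), ("TN", "True negative"),
                           ("FP", "False positive"), ("FN", "False negative")):
            rows.setdefault(label, {})[name] = (
                counts[sub] if name != "SoC" else float("nan"))
    order = [r for r, _ in PY_ROWS[:2]] + ["PY dementia"] + \
        [r for r, _ in PY_ROWS[2:]] + ["Deaths", "True positive",
                                       "True negative", "False positive",
                                       "False negative"]
    return pd.DataFrame(rows).T.loc[order]


def comparison_table(params: ModelParams,
                     results: dict[str, StrategyResult],
                     reference: str,
                     wtp: Optional[float] = None) -> pd.DataFrame:
    """Per-strategy lifetime cost/QALY, net benefits, increments vs the
    reference, and diagnostic costs per true case."""
    wtp = wtp if wtp is not None else params.econ.wtp
    ref = results[reference]
    records = []
    for name, res in results.items():
        row = {"strategy": name, "cost": res.cost_total, "qaly": res.qalys,
               "nmb": res.qalys * wtp - res.cost_total,
               "nhb": res.qalys - res.cost_total / wtp}
        if name != reference:
            cmp = compare(res, ref, wtp)
            row.update({"d_cost": cmp.d_cost, "d_qaly": cmp.d_qaly,
                        "icer": cmp.icer, "icer_label": cmp.icer_label,
                        "inhb": cmp.inhb})
        cls = classification_for(params, name)
        costing = diagnostic_costing(name, cls, params.costs, params.cohort)
        row["diag_cost_per_tp"] = costing.per_tp
        row["diag_cost_per_tn"] = costing.per_tn
        records.append(row)
    return pd.DataFrame.from_records(records).set_index("strategy")


def sector_cost_table(params: ModelParams,
                      results: dict[str, StrategyResult],
                      reference: str = "SoC") -> pd.DataFrame:
    """Cumulated lifetime cohort costs (million €) by payer sector, with
    share of total and difference versus the reference strategy."""
    size = params.cohort.size
    records = []
    for sector in ALL_SECTORS:
        row: dict[str, float | str] = {"sector": sector}
        for name, res in results.items():
            m_eur = res.cost_by_sector.get(sector, 0.0) * size / 1e6
            row[f"{name}_m_eur"] = m_eur
            row[f"{name}_pct"] = 100.0 * res.cost_by_sector.get(sector, 0.0) \
                / res.cost_total
        records.append(row)
    total_row: dict[str, float | str] = {"sector": "total"}
    for name, res in results.items():
        total_row[f"{name}_m_eur"] = res.cost_total * size / 1e6
        total_row[f"{name}_pct"] = 100.0
    records.append(total_row)
    df = pd.DataFrame.from_records(records).set_index("sector")
    if reference in results:
        for name in results:
            if name == reference:
                continue
            df[f"{name}_diff_vs_{reference}"] = (
                df[f"{name}_m_eur"] - df[f"{reference}_m_eur"])
    return df


def threshold_table(params: ModelParams, strategy: str, reference: str,
                    wtp_levels: list[float]) -> pd.DataFrame:
    """Drug-price threshold per WTP level, infusion and subcutaneous.

    A negative solution means even a free drug exceeds the WTP level;
    rendered as missing (the published tables print "n/a").
    """
    sub = params.model_copy(deep=True)
    sub.treatment.admin_mode = "subcutaneous"
    rows = []
    for wtp in wtp_levels:
        row = {"wtp": wtp}
        for label, p in (("infusion", params), ("subcutaneous", sub)):
            t = price_threshold(p, strategy, reference, wtp)
            row[label] = t if t >= 0 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("wtp")


def format_costs(x: float) -> str:
    return f"{x:,.0f}".replace(",", " ") if pd.notna(x) else "n/a"


def format_comparison_table(df: pd.DataFrame) -> pd.DataFrame:
    """Published rounding: € to integers, QALYs 3 dp, iNHB 2 dp."""
    out = df.copy()
    for col in ("cost", "nmb", "d_cost", "icer", "diag_cost_per_tp",
                "diag_cost_per_tn"):
        if col in out:
            out[col] = out[col].map(
                lambda v: f"{v:.0f}" if pd.notna(v) else "n/a")
    for col, nd in (("qaly", 3), ("nhb", 3), ("d_qaly", 3), ("inhb", 2)):
        if col in out:
            out[col] = out[col].map(
                lambda v, nd=nd: f"{v:.{nd}f}" if pd.notna(v) else "n/a")
    return out


def run_all_strategies(params: ModelParams,
                       names: tuple[str, ...] = ("SoC", "CSF", "BBM",
                                                 "BBM_CSF")
                       ) -> dict[str, StrategyResult]:
    return {name: run_strategy(params, name) for name in names}


def cost_difference_by_cycle(params: ModelParams, strategy: str,
                             reference: str = "SoC") -> pd.DataFrame:
    """Cohort cost difference (million €) per cycle, half-cycle weighted
    and discounted — the trace behind the published cost-difference
    figure."""
    import numpy as np
    from .diagnostics import get_strategy
    from .economics import accrue, classification_for
    from .progression import run_cohort

    size = params.cohort.size
    series = {}
    for name in (strategy, reference):
        rule = get_strategy(name)
        cls = classification_for(params, rule)
        trace = run_cohort(cls, params, rule)
        ledger = accrue(trace, params, rule)
        H = ledger.horizon
        w = np.ones(H + 1)
        if params.econ.half_cycle:
            w[0] = w[-1] = 0.5
        disc = (1.0 + params.econ.discount_rate) ** -np.arange(H + 1)
        per_cycle = sum(ledger.sector_costs.values()) + ledger.aat_cost() \
            + ledger.productivity_cost
        per_cycle = per_cycle * w * disc
        per_cycle[0] += ledger.diagnostic_cost
        series[name] = per_cycle * size / 1e6
    return pd.DataFrame({
        "cycle": range(params.econ.horizon_years + 1),
        "difference_m_eur": series[strategy] - series[reference],
    }).set_index("cycle")
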