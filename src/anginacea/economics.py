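"""Costs, QALYs, life-years and the incremental comparison.

Accrual conventions (these reconcile the published deterministic table):

* rewards accrue on start-of-cycle occupancy for the full cycle length,
  with no half-cycle correction;
* each non-drug category accrues ``annual_cost / cycles_per_year`` per
  cycle of state occupancy; the dead state accrues nothing;
* drug acquisition accrues ``monthly_cost x months_per_cycle`` on the
  proportion alive at cycle start;
* the ICER is computed from unrounded totals.

A discounting hook is provided (per-cycle factors at the annual rate);
the base case uses rate 0 over its 1-year horizon, where it is the
identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .markov import CohortTrace, run_cohort
from .parameters import COST_CATEGORIES, ModelParameters, StrategySpec

__all__ = [
    "EconomicResult",
    "IncrementalResult",
    "accrue_life_years",
    "accrue_qalys",
    "accrue_costs",
    "evaluate_strategy",
    "incremental_analysis",
    "net_monetary_benefit",
    "results_to_frame",
]

MONTHS_PER_YEAR = 12.0

Classification = Literal[
    "intervention_dominant", "comparator_dominant", "tradeoff_icer", "equal"
]


@dataclass(frozen=True)
class EconomicResult:
    """Per-strategy totals over the model horizon (per patient)."""

    strategy: str
    total_cost: float
    cost_by_category: Mapping[str, float]  # COST_CATEGORIES + "drug"
    qalys: float
    life_years: float


@dataclass(frozen=True)
class IncrementalResult:
    """Intervention minus comparator, with dominance classification.

    ``icer`` is ``delta_cost / delta_effect`` when the comparison is a
    genuine tradeoff and undefined (``None``) otherwise — in particular
    under dominance and when ``delta_effect`` is zero.
    """

    delta_cost: float
    delta_effect: float
    icer: float | None
    classification: Classification


def _discount_weights(params: ModelParameters) -> np.ndarray:
    """Per-cycle discount factors applied to rewards at cycle start."""
    if params.discount_rate == 0.0:
        return np.ones(params.n_cycles)
    times = np.arange(params.n_cycles) * params.cycle_length_years
    return (1.0 + params.discount_rate) ** -times


def accrue_life_years(
    trace: CohortTrace, cycle_length_years: float, weights: np.ndarray | None = None
) -> float:
    """Sum of cycle length times the proportion alive at cycle start."""
    w = np.ones(trace.n_cycles) if weights is None else weights
    return float(cycle_length_years * (w * trace.alive).sum())


def accrue_qalys(
    trace: CohortTrace,
    utilities: np.ndarray,
    cycle_length_years: float,
    weights: np.ndarray | None = None,
) -> float:
    """Utility-weighted state time; the dead state contributes zero."""
    w = np.ones(trace.n_cycles) if weights is None else weights
    per_cycle = trace.occupancy[:, :4] @ np.asarray(utilities, dtype=float)
    return float(cycle_length_years * (w * per_cycle).sum())


def accrue_costs(
    trace: CohortTrace,
    state_costs: Mapping[str, np.ndarray],
    monthly_drug_cost: float,
    cycle_length_years: float,
    weights: np.ndarray | None = None,
) -> dict[str, float]:
    """Per-category cost totals, including the ``"drug"`` category."""
    w = np.ones(trace.n_cycles) if weights is None else weights
    out: dict[str, float] = {}
    for cat in COST_CATEGORIES:
        per_cycle = trace.occupancy[:, :4] @ (
            np.asarray(state_costs[cat], dtype=float) * cycle_length_years
        )
        out[cat] = float((w * per_cycle).sum())
    months_per_cycle = MONTHS_PER_YEAR * cycle_length_years
    out["drug"] = float(
        monthly_drug_cost * months_per_cycle * (w * trace.alive).sum()
    )
    return out


def evaluate_strategy(
    params: ModelParameters, strategy: StrategySpec
) -> EconomicResult:
    """Run the cohort and accrue all rewards for one strategy."""
    trace = run_cohort(params, strategy)
    w = _discount_weights(params)
    costs = accrue_costs(
        trace, params.state_costs, strategy.monthly_drug_cost,
        params.cycle_length_years, w,
    )
    return EconomicResult(
        strategy=strategy.name,
        total_cost=float(sum(costs.values())),
        cost_by_category=costs,
        qalys=accrue_qalys(trace, params.utilities, params.cycle_length_years, w),
        life_years=accrue_life_years(trace, params.cycle_length_years, w),
    )


def incremental_analysis(
    intervention: EconomicResult, comparator: EconomicResult
) -> IncrementalResult:
    """Incremental cost, effect, classification and (where defined) ICER."""
    dc = intervention.total_cost - comparator.total_cost
    de = intervention.qalys - comparator.qalys
    if dc == 0.0 and de == 0.0:
        cls: Classification = "equal"
        icer = None
    elif dc < 0.0 and de > 0.0:
        cls = "intervention_dominant"
        icer = None
    elif dc > 0.0 and de < 0.0:
        cls = "comparator_dominant"
        icer = None
    else:
        cls = "tradeoff_icer"
        icer = dc / de if de != 0.0 else None
    return IncrementalResult(delta_cost=dc, delta_effect=de, icer=icer, classification=cls)


def net_monetary_benefit(result: EconomicResult, wtp: float) -> float:
    """``wtp * qalys - total_cost`` (EUR)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * result.qalys - result.total_cost


def results_to_frame(
    intervention: EconomicResult,
    comparator: EconomicResult,
    incremental: IncrementalResult | None = None,
) -> pd.DataFrame:
    """Deterministic-results table: categories, totals, QALYs, LYs, ICER."""
    if incremental is None:
        incremental = incremental_analysis(intervention, comparator)
    rows = []

    def add(label, a, b, inc):
        rows.append({
            "quantity": label,
            intervention.strategy: a,
            comparator.strategy: b,
            "incremental": inc,
        })

    add("total_cost_eur", intervention.total_cost, comparator.total_cost,
        incremental.delta_cost)
    for cat in ("drug",) + COST_CATEGORIES:
        a = intervention.cost_by_category[cat]
        b = comparator.cost_by_category[cat]
        add(f"cost_{cat}_eur", a, b, a - b)
    add("qalys", intervention.qalys, comparator.qalys, incremental.delta_effect)
    add("life_years", intervention.life_years, comparator.life_years,
        intervention.life_years - comparator.life_years)
    add("icer_eur_per_qaly", np.nan, np.nan,
        np.nan if incremental.icer is None else incremental.icer)
    return pd.DataFrame(rows)
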