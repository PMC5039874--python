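"""One-way sensitivity analysis (tornado) and deterministic scenarios.

Every scalar input is addressable by a :class:`ParameterHandle` whose id
follows a small path grammar::

    transition:<strategy>:<origin>:<destination>
    utility:<state>
    mortality:<state>
    cost:<category>:<state>
    drug_cost:<strategy>

Clinical handles (transitions, utilities, mortality) vary by +/-10 % and
cost handles by +/-20 % by default.

Transition rows must stay stochastic under perturbation.  Two balancing
conventions are provided: ``"proportional"`` rescales the other three
cells of the row proportionally (the generic default), while ``"stay"``
absorbs the change entirely in the row's same-state cell — the natural
convention when the stay probability is the derived remainder of the
row, which is how the tornado treats transitions.  The default tornado
handle set therefore omits the stay cells (not independent parameters
under that convention) and the regulated drug acquisition prices, which
are explored through dedicated scenario analyses (rebates, price
changes) instead of sampling-style bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .economics import (
    IncrementalResult,
    evaluate_strategy,
    incremental_analysis,
    net_monetary_benefit,
)
from .parameters import ANGINA_STATES, COST_CATEGORIES, ModelParameters, StrategySpec

__all__ = [
    "ParameterHandle",
    "OWSAEntry",
    "default_handles",
    "resolve_parameter",
    "perturb_parameter",
    "run_owsa",
    "rebate_scenario",
    "owsa_to_frame",
]

Kind = Literal["cost", "clinical"]
RowBalance = Literal["proportional", "stay"]

_STATE_INDEX = {s: i for i, s in enumerate(ANGINA_STATES)}


@dataclass(frozen=True)
class ParameterHandle:
    """Path to one scalar input plus its sensitivity class."""

    id: str
    kind: Kind

    @property
    def parts(self) -> tuple[str, ...]:
        return tuple(self.id.split(":"))


def default_handles(
    params: ModelParameters,
    include_stay_cells: bool = False,
    include_drug_costs: bool = False,
) -> list[ParameterHandle]:
    """Tornado handle set: transition cells, utilities, mortality and
    medical category costs.

    Stay-in-state cells are excluded by default (they are the derived
    remainder under the tornado's row-balancing convention), as are the
    drug acquisition prices (regulated quantities handled as scenarios);
    both can be added back via the flags.
    """
    handles: list[ParameterHandle] = []
    for strat in params.strategies:
        for origin in ANGINA_STATES:
            for dest in ANGINA_STATES:
                if origin == dest and not include_stay_cells:
                    continue
                handles.append(
                    ParameterHandle(f"transition:{strat.name}:{origin}:{dest}", "clinical")
                )
    for s in ANGINA_STATES:
        handles.append(ParameterHandle(f"utility:{s}", "clinical"))
        handles.append(ParameterHandle(f"mortality:{s}", "clinical"))
    for cat in COST_CATEGORIES:
        for s in ANGINA_STATES:
            handles.append(ParameterHandle(f"cost:{cat}:{s}", "cost"))
    if include_drug_costs:
        for strat in params.strategies:
            handles.append(ParameterHandle(f"drug_cost:{strat.name}", "cost"))
    return handles


def _strategy_by_name(params: ModelParameters, name: str) -> tuple[str, StrategySpec]:
    if params.intervention.name == name:
        return "intervention", params.intervention
    if params.comparator.name == name:
        return "comparator", params.comparator
    raise KeyError(f"no strategy named {name!r}")


def resolve_parameter(params: ModelParameters, handle: ParameterHandle) -> float:
    """Current value of the scalar a handle points at."""
    parts = handle.parts
    if parts[0] == "transition":
        _, strat = _strategy_by_name(params, parts[1])
        return float(strat.transition_matrix[_STATE_INDEX[parts[2]], _STATE_INDEX[parts[3]]])
    if parts[0] == "utility":
        return float(params.utilities[_STATE_INDEX[parts[1]]])
    if parts[0] == "mortality":
        return float(params.annual_mortality[_STATE_INDEX[parts[1]]])
    if parts[0] == "cost":
        return float(params.state_costs[parts[1]][_STATE_INDEX[parts[2]]])
    if parts[0] == "drug_cost":
        _, strat = _strategy_by_name(params, parts[1])
        return strat.monthly_drug_cost
    raise KeyError(f"unknown handle id {handle.id!r}")


def _perturb_row(
    row: np.ndarray, i: int, j: int, factor: float, clamp: bool, balance: RowBalance
) -> np.ndarray:
    """Scale cell ``j`` of row ``i``'s probabilities and rebalance."""
    old = row[j]
    new = old * factor
    if new > 1.0:
        if not clamp:
            raise ValueError(f"perturbed transition probability {new:.4f} exceeds 1")
        new = 1.0
    out = row.copy()
    out[j] = new
    if balance == "stay" and i != j:
        out[i] = row[i] - (new - old)
        if out[i] < 0.0:
            raise ValueError(
                "stay-cell balancing would drive a transition probability below 0"
            )
        return out
    rest = 1.0 - old
    if rest > 0.0:
        scale = (1.0 - new) / rest
        mask = np.arange(4) != j
        out[mask] = row[mask] * scale
    elif new != 1.0:
        raise ValueError(
            "cannot renormalize a transition row whose only mass is in the perturbed cell"
        )
    return out


def perturb_parameter(
    params: ModelParameters,
    handle: ParameterHandle,
    factor: float,
    clamp: bool = False,
    row_balance: RowBalance = "proportional",
) -> ModelParameters:
    """Copy of ``params`` with one scalar multiplied by ``factor``.

    The input is never mutated.  Probabilities are kept valid: transition
    rows are rebalanced (see module docstring for the two conventions)
    and utilities capped at 1.  A perturbation that would force a
    transition probability above 1 raises ``ValueError`` unless
    ``clamp`` is set, in which case the cell saturates at 1.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    parts = handle.parts
    if parts[0] == "transition":
        field, strat = _strategy_by_name(params, parts[1])
        m = strat.transition_matrix.copy()
        i, j = _STATE_INDEX[parts[2]], _STATE_INDEX[parts[3]]
        m[i] = _perturb_row(m[i], i, j, factor, clamp, row_balance)
        return params.replace(
            **{field: StrategySpec(strat.name, m, strat.monthly_drug_cost)}
        )
    if parts[0] == "utility":
        u = params.utilities.copy()
        u[_STATE_INDEX[parts[1]]] = min(1.0, u[_STATE_INDEX[parts[1]]] * factor)
        return params.replace(utilities=u)
    if parts[0] == "mortality":
        mort = params.annual_mortality.copy()
        i = _STATE_INDEX[parts[1]]
        mort[i] *= factor
        if mort[i] >= 1.0:
            raise ValueError(f"perturbed annual mortality {mort[i]:.4f} not below 1")
        return params.replace(annual_mortality=mort)
    if parts[0] == "cost":
        costs = {c: v.copy() for c, v in params.state_costs.items()}
        costs[parts[1]][_STATE_INDEX[parts[2]]] *= factor
        return params.replace(state_costs=costs)
    if parts[0] == "drug_cost":
        field, strat = _strategy_by_name(params, parts[1])
        return params.replace(
            **{field: StrategySpec(
                strat.name, strat.transition_matrix.copy(),
                strat.monthly_drug_cost * factor,
            )}
        )
    raise KeyError(f"unknown handle id {handle.id!r}")


@dataclass(frozen=True)
class OWSAEntry:
    """One tornado bar: endpoint analyses for a single parameter.

    ``spread`` is the width of the cost-per-QALY range across the two
    endpoints when the incremental effect keeps its sign (the signed
    ratio is well defined even when one endpoint is dominant); if the
    effect changes sign or vanishes the spread falls back to the
    incremental-NMB range at the configured WTP so the tornado ordering
    is always defined.
    """

    handle: ParameterHandle
    low_value: float
    high_value: float
    result_low: IncrementalResult
    result_high: IncrementalResult
    nmb_low: float   # incremental NMB at the configured WTP, low endpoint
    nmb_high: float
    spread: float

    @property
    def icer_low(self) -> float | str:
        return self.result_low.icer if self.result_low.icer is not None \
            else self.result_low.classification

    @property
    def icer_high(self) -> float | str:
        return self.result_high.icer if self.result_high.icer is not None \
            else self.result_high.classification


def _endpoint(params: ModelParameters, handle: ParameterHandle, factor: float):
    p = perturb_parameter(params, handle, factor, clamp=True, row_balance="stay")
    a = evaluate_strategy(p, p.intervention)
    b = evaluate_strategy(p, p.comparator)
    inc = incremental_analysis(a, b)
    dnmb = net_monetary_benefit(a, p.wtp_threshold) - net_monetary_benefit(b, p.wtp_threshold)
    return inc, dnmb


def _spread(inc_lo: IncrementalResult, inc_hi: IncrementalResult,
            nmb_lo: float, nmb_hi: float) -> float:
    de_lo, de_hi = inc_lo.delta_effect, inc_hi.delta_effect
    if de_lo != 0.0 and de_hi != 0.0 and np.sign(de_lo) == np.sign(de_hi):
        ratio_lo = inc_lo.delta_cost / de_lo
        ratio_hi = inc_hi.delta_cost / de_hi
        return abs(ratio_hi - ratio_lo)
    return abs(nmb_hi - nmb_lo)


def run_owsa(
    params: ModelParameters,
    handles: Iterable[ParameterHandle] | None = None,
    cost_factor: float = 0.2,
    clinical_factor: float = 0.1,
) -> list[OWSAEntry]:
    """Vary each handle to its low/high bound and rank by spread.

    Entries are returned in descending spread order with the handle id
    as a deterministic tie-break, so the ordering does not depend on the
    order handles are supplied.
    """
    if handles is None:
        handles = default_handles(params)
    entries: list[OWSAEntry] = []
    for h in handles:
        f = cost_factor if h.kind == "cost" else clinical_factor
        base_value = resolve_parameter(params, h)
        inc_lo, nmb_lo = _endpoint(params, h, 1.0 - f)
        inc_hi, nmb_hi = _endpoint(params, h, 1.0 + f)
        entries.append(OWSAEntry(
            handle=h,
            low_value=base_value * (1.0 - f),
            high_value=base_value * (1.0 + f),
            result_low=inc_lo, result_high=inc_hi,
            nmb_low=nmb_lo, nmb_high=nmb_hi,
            spread=_spread(inc_lo, inc_hi, nmb_lo, nmb_hi),
        ))
    entries.sort(key=lambda e: (-e.spread, e.handle.id))
    return entries


def rebate_scenario(params: ModelParameters, rebate_fraction: float) -> IncrementalResult:
    """Incremental analysis with both drug costs cut by ``rebate_fraction``."""
    if not 0.0 <= rebate_fraction < 1.0:
        raise ValueError("rebate_fraction must lie in [0, 1)")
    keep = 1.0 - rebate_fraction
    p = params.replace(
        intervention=StrategySpec(
            params.intervention.name,
            params.intervention.transition_matrix.copy(),
            params.intervention.monthly_drug_cost * keep,
        ),
        comparator=StrategySpec(
            params.comparator.name,
            params.comparator.transition_matrix.copy(),
            params.comparator.monthly_drug_cost * keep,
        ),
    )
    return incremental_analysis(
        evaluate_strategy(p, p.intervention), evaluate_strategy(p, p.comparator)
    )


def owsa_to_frame(entries: Sequence[OWSAEntry]) -> pd.DataFrame:
    """Tornado-ready table, one row per handle, ranked by spread."""
    rows = []
    for rank, e in enumerate(entries, start=1):
        rows.append({
            "handle_id": e.handle.id,
            "kind": e.handle.kind,
            "low_value": e.low_value,
            "high_value": e.high_value,
            "icer_low": e.icer_low,
            "icer_high": e.icer_high,
            "nmb_low": e.nmb_low,
            "nmb_high": e.nmb_high,
            "spread": e.spread,
            "rank": rank,
        })
    return pd.DataFrame(rows)
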