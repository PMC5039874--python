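"""Model inputs: health states, parameter containers, validation and I/O.

The model describes chronic stable angina with four severity states
(defined by angina-episode frequency: minimal, mild, moderate, severe)
plus an absorbing death state.  A complete analysis needs, per strategy,
a 4x4 three-month transition matrix among the living states and a net
monthly drug-acquisition cost, together with strategy-independent annual
mortality per state, EQ-5D utility weights, the baseline distribution of
the cohort and annual per-state medical costs by resource category.

All probabilities are stored as fractions in [0, 1]; costs are plain
numbers in euros (price-year recorded in ``metadata``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ANGINA_STATES",
    "STATES",
    "DEAD",
    "COST_CATEGORIES",
    "StrategySpec",
    "ModelParameters",
    "paper_fixture",
    "load_parameters",
    "validate_parameters",
    "serialize_parameters",
    "save_parameters",
    "parameters_to_frame",
]

#: Living states, ordered by increasing severity.
ANGINA_STATES: tuple[str, ...] = ("minimal", "mild", "moderate", "severe")
DEAD: str = "dead"
#: All five model states; ``dead`` is absorbing.
STATES: tuple[str, ...] = ANGINA_STATES + (DEAD,)

#: Medical resource-use categories with state-dependent annual costs.
#: Drug acquisition is handled separately (per strategy, per month alive).
COST_CATEGORIES: tuple[str, ...] = (
    "outpatient_visits",
    "diagnostic_tests",
    "laboratory_tests",
    "hosp_no_revasc",
    "hosp_revasc",
)

#: A transition row whose printed percentages carry rounding error may be
#: off from 1 by up to this relative amount and is silently renormalized;
#: larger deviations raise.
ROW_SUM_SLACK = 5e-3
#: Tolerance for exact row-stochasticity after construction/renormalization.
ROW_SUM_TOL = 1e-9


def _as_readonly(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    a.setflags(write=False)
    return a


@dataclass(frozen=True, eq=False)
class StrategySpec:
    """One treatment strategy: name, angina transition matrix, drug cost.

    ``transition_matrix`` is 4x4, row = origin state, column = destination,
    conditional on surviving the cycle.  ``monthly_drug_cost`` is the net
    monthly acquisition cost to the payer in euros.
    """

    name: str
    transition_matrix: np.ndarray
    monthly_drug_cost: float

    def __post_init__(self) -> None:
        m = np.asarray(self.transition_matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(
                f"strategy {self.name!r}: transition_matrix must be 4x4, got {m.shape}"
            )
        object.__setattr__(self, "transition_matrix", _as_readonly(m))
        object.__setattr__(self, "monthly_drug_cost", float(self.monthly_drug_cost))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StrategySpec):
            return NotImplemented
        return (
            self.name == other.name
            and self.monthly_drug_cost == other.monthly_drug_cost
            and np.array_equal(self.transition_matrix, other.transition_matrix)
        )


@dataclass(frozen=True, eq=False)
class ModelParameters:
    """Complete, validated input bundle for one incremental analysis.

    Arrays are indexed by :data:`ANGINA_STATES` order.  ``state_costs``
    maps each category in :data:`COST_CATEGORIES` to annual per-patient
    costs by state.  The horizon is ``n_cycles * cycle_length_years``
    (one year in the base case, hence ``discount_rate`` 0).
    """

    intervention: StrategySpec
    comparator: StrategySpec
    annual_mortality: np.ndarray
    utilities: np.ndarray
    baseline: np.ndarray
    state_costs: Mapping[str, np.ndarray]
    n_cycles: int = 4
    cycle_length_years: float = 0.25
    wtp_threshold: float = 34_000.0
    discount_rate: float = 0.0
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("annual_mortality", "utilities", "baseline"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (4,):
                raise ValueError(f"{name} must have one entry per angina state")
            object.__setattr__(self, name, _as_readonly(v))
        costs = {}
        for cat in COST_CATEGORIES:
            if cat not in self.state_costs:
                raise ValueError(f"state_costs missing category {cat!r}")
            row = np.asarray(self.state_costs[cat], dtype=float)
            if row.shape != (4,):
                raise ValueError(f"state_costs[{cat!r}] must have one entry per angina state")
            costs[cat] = _as_readonly(row)
        unknown = set(self.state_costs) - set(COST_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown cost categories: {sorted(unknown)}")
        object.__setattr__(self, "state_costs", costs)

    @property
    def strategies(self) -> tuple[StrategySpec, StrategySpec]:
        """(intervention, comparator) pair."""
        return (self.intervention, self.comparator)

    @property
    def horizon_years(self) -> float:
        return self.n_cycles * self.cycle_length_years

    def replace(self, **changes: Any) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModelParameters):
            return NotImplemented
        return (
            self.intervention == other.intervention
            and self.comparator == other.comparator
            and np.array_equal(self.annual_mortality, other.annual_mortality)
            and np.array_equal(self.utilities, other.utilities)
            and np.array_equal(self.baseline, other.baseline)
            and all(
                np.array_equal(self.state_costs[c], other.state_costs[c])
                for c in COST_CATEGORIES
            )
            and self.n_cycles == other.n_cycles
            and self.cycle_length_years == other.cycle_length_years
            and self.wtp_threshold == other.wtp_threshold
            and self.discount_rate == other.discount_rate
        )


# ---------------------------------------------------------------------------
# Packaged base-case parameter set
# ---------------------------------------------------------------------------

# Three-month transition percentages are published rounded to two decimals,
# but each row is an exact multinomial fraction over the per-state trial
# denominators (e.g. 97/184 prints as 52.72 %).  The fixture stores the
# exact fractions; the deterministic results then reproduce the published
# cost-utility table to within rounding of the printed drug prices.
_TMZ_COUNTS = (
    (248, 11, 3, 0),    # minimal, n = 262
    (97, 76, 10, 1),    # mild,    n = 184
    (20, 63, 16, 4),    # moderate,n = 103
    (15, 19, 26, 45),   # severe,  n = 105
)
_SOC_COUNTS = (
    (164, 17, 0, 0),    # minimal, n = 181
    (89, 80, 18, 4),    # mild,    n = 191
    (23, 39, 21, 6),    # moderate,n = 89
    (15, 34, 20, 59),   # severe,  n = 128
)
# Baseline cohort: symptomatic patients only (mild/moderate/severe),
# 184 + 103 + 105 = 392; prints as 47 % / 26 % / 27 %.
_BASELINE_COUNTS = (0, 184, 103, 105)


def _counts_to_rows(counts) -> np.ndarray:
    return np.array(
        [[float(Fraction(c, sum(row))) for c in row] for row in counts]
    )


def paper_fixture() -> ModelParameters:
    """The packaged Greek base-case parameter set (euro 2016 prices).

    Trimetazidine (TMZ) 35 mg b.i.d. added to standard of care (SoC)
    versus SoC alone; 3-month cycles, 1-year horizon, third-party-payer
    perspective, willingness-to-pay threshold 34,000 EUR/QALY.
    """
    tmz = StrategySpec(
        name="TMZ+SoC",
        transition_matrix=_counts_to_rows(_TMZ_COUNTS),
        monthly_drug_cost=29.18,
    )
    soc = StrategySpec(
        name="SoC",
        transition_matrix=_counts_to_rows(_SOC_COUNTS),
        monthly_drug_cost=23.40,
    )
    baseline = np.array(_BASELINE_COUNTS, dtype=float)
    baseline /= baseline.sum()
    return ModelParameters(
        intervention=tmz,
        comparator=soc,
        annual_mortality=np.array([0.046, 0.048, 0.081, 0.109]),
        utilities=np.array([0.81, 0.75, 0.60, 0.39]),
        baseline=baseline,
        state_costs={
            "outpatient_visits": np.array([8.00, 15.75, 39.88, 76.50]),
            "diagnostic_tests": np.array([41.62, 62.05, 101.00, 122.37]),
            "laboratory_tests": np.array([20.41, 25.63, 45.31, 61.24]),
            "hosp_no_revasc": np.array([4.67, 35.03, 331.06, 1428.63]),
            "hosp_revasc": np.array([586.24, 683.62, 1583.23, 1972.77]),
        },
        metadata={
            "currency": "EUR2016",
            "description": "TMZ 70 mg/d add-on vs standard of care, Greece",
            # per-row multinomial denominators behind the transition rows
            "transition_row_n": {
                "TMZ+SoC": [sum(r) for r in _TMZ_COUNTS],
                "SoC": [sum(r) for r in _SOC_COUNTS],
            },
            "baseline_n": sum(_BASELINE_COUNTS),
        },
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_parameters(params: ModelParameters) -> list[str]:
    """Check every structural invariant; return a list of violations.

    An empty list means the parameter set is valid.  This reports rather
    than raises so callers can surface all problems at once.
    """
    out: list[str] = []
    for strat in params.strategies:
        m = strat.transition_matrix
        if np.any(m < 0) or np.any(m > 1):
            out.append(f"strategy {strat.name!r}: transition probabilities outside [0, 1]")
        sums = m.sum(axis=1)
        for s, total in zip(ANGINA_STATES, sums):
            if abs(total - 1.0) > ROW_SUM_TOL:
                out.append(
                    f"strategy {strat.name!r}: transition row {s!r} sums to {total:.6f}, not 1"
                )
        if strat.monthly_drug_cost < 0:
            out.append(f"strategy {strat.name!r}: monthly_drug_cost is negative")
    for s, p in zip(ANGINA_STATES, params.annual_mortality):
        if not (0.0 <= p < 1.0):
            out.append(f"annual_mortality[{s!r}] = {p} outside [0, 1)")
    for s, u in zip(ANGINA_STATES, params.utilities):
        if not (0.0 <= u <= 1.0):
            out.append(f"utility[{s!r}] = {u} outside [0, 1]")
    if np.any(params.baseline < 0):
        out.append("baseline distribution has negative entries")
    if abs(params.baseline.sum() - 1.0) > ROW_SUM_TOL:
        out.append(f"baseline distribution sums to {params.baseline.sum():.6f}, not 1")
    for cat in COST_CATEGORIES:
        if np.any(params.state_costs[cat] < 0):
            out.append(f"state_costs[{cat!r}] has negative entries")
    if params.n_cycles < 1:
        out.append(f"n_cycles = {params.n_cycles} must be >= 1")
    if params.cycle_length_years <= 0:
        out.append("cycle_length_years must be positive")
    if params.discount_rate < 0:
        out.append("discount_rate must be non-negative")
    if params.wtp_threshold < 0:
        out.append("wtp_threshold must be non-negative")
    return out


# ---------------------------------------------------------------------------
# Serialization (JSON configuration schema)
# ---------------------------------------------------------------------------
#
# {
#   "strategies": {
#     "intervention": {"name": ..., "monthly_drug_cost": ...,
#                      "transition_matrix": {"minimal": {"minimal": p, ...}, ...}},
#     "comparator": {...}},
#   "annual_mortality": {"minimal": p, ...},
#   "utilities": {...}, "baseline": {...},
#   "state_costs": {"outpatient_visits": {"minimal": c, ...}, ...},
#   "n_cycles": 4, "cycle_length_years": 0.25,
#   "wtp_threshold": 34000, "discount_rate": 0, "metadata": {...}
# }
#
# Probabilities are fractions; any probability > 1 is rejected to guard
# against percentage/fraction unit mistakes.


def _vec_to_map(v: np.ndarray) -> dict[str, float]:
    return {s: float(x) for s, x in zip(ANGINA_STATES, v)}


def _strategy_to_dict(s: StrategySpec) -> dict[str, Any]:
    return {
        "name": s.name,
        "monthly_drug_cost": s.monthly_drug_cost,
        "transition_matrix": {
            origin: _vec_to_map(row)
            for origin, row in zip(ANGINA_STATES, s.transition_matrix)
        },
    }


def serialize_parameters(params: ModelParameters) -> dict[str, Any]:
    """Lossless plain-dict form of ``params`` (JSON-serializable)."""
    return {
        "strategies": {
            "intervention": _strategy_to_dict(params.intervention),
            "comparator": _strategy_to_dict(params.comparator),
        },
        "annual_mortality": _vec_to_map(params.annual_mortality),
        "utilities": _vec_to_map(params.utilities),
        "baseline": _vec_to_map(params.baseline),
        "state_costs": {c: _vec_to_map(params.state_costs[c]) for c in COST_CATEGORIES},
        "n_cycles": params.n_cycles,
        "cycle_length_years": params.cycle_length_years,
        "wtp_threshold": params.wtp_threshold,
        "discount_rate": params.discount_rate,
        "metadata": dict(params.metadata),
    }


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write ``params`` to ``path`` as a JSON configuration file."""
    Path(path).write_text(json.dumps(serialize_parameters(params), indent=2))


class ParameterError(ValueError):
    """A configuration document violates the parameter schema."""


def _get(mapping: Mapping, key: str, context: str) -> Any:
    try:
        return mapping[key]
    except (KeyError, TypeError):
        raise ParameterError(f"missing key {key!r} in {context}") from None


def _read_state_map(obj: Any, context: str, probability: bool = False) -> np.ndarray:
    vals = []
    for s in ANGINA_STATES:
        x = _get(obj, s, context)
        try:
            x = float(x)
        except (TypeError, ValueError):
            raise ParameterError(f"{context}[{s!r}] is not a number: {x!r}") from None
        if probability and x > 1.0:
            raise ParameterError(
                f"{context}[{s!r}] = {x} exceeds 1; probabilities must be "
                "fractions (0.5272), not percentages (52.72)"
            )
        vals.append(x)
    return np.array(vals)


def _read_strategy(obj: Any, context: str) -> StrategySpec:
    name = _get(obj, "name", context)
    cost = float(_get(obj, "monthly_drug_cost", context))
    tm = _get(obj, "transition_matrix", context)
    rows = []
    for origin in ANGINA_STATES:
        row = _read_state_map(
            _get(tm, origin, f"{context}.transition_matrix"),
            f"{context}.transition_matrix[{origin!r}]",
            probability=True,
        )
        total = row.sum()
        if abs(total - 1.0) > ROW_SUM_SLACK:
            raise ParameterError(
                f"{context}.transition_matrix[{origin!r}] sums to {total:.6f}; "
                f"rows must sum to 1 within {ROW_SUM_SLACK:.1%}"
            )
        if total > 0 and abs(total - 1.0) > ROW_SUM_TOL:
            row = row / total  # printed-percentage rounding: renormalize
        rows.append(row)
    return StrategySpec(name=name, transition_matrix=np.array(rows), monthly_drug_cost=cost)


def load_parameters(source: str | Path | Mapping[str, Any]) -> ModelParameters:
    """Load and validate a parameter set from a path or a mapping.

    Transition rows within 0.5 % of summing to 1 (printed-percentage
    rounding) are proportionally renormalized; larger deviations raise
    :class:`ParameterError`, as does any other schema violation.
    """
    if isinstance(source, (str, Path)):
        doc = json.loads(Path(source).read_text())
    else:
        doc = source
    strategies = _get(doc, "strategies", "configuration")
    params = ModelParameters(
        intervention=_read_strategy(_get(strategies, "intervention", "strategies"), "intervention"),
        comparator=_read_strategy(_get(strategies, "comparator", "strategies"), "comparator"),
        annual_mortality=_read_state_map(
            _get(doc, "annual_mortality", "configuration"), "annual_mortality", probability=True
        ),
        utilities=_read_state_map(
            _get(doc, "utilities", "configuration"), "utilities", probability=True
        ),
        baseline=_read_state_map(
            _get(doc, "baseline", "configuration"), "baseline", probability=True
        ),
        state_costs={
            c: _read_state_map(
                _get(_get(doc, "state_costs", "configuration"), c, "state_costs"),
                f"state_costs[{c!r}]",
            )
            for c in COST_CATEGORIES
        },
        n_cycles=int(doc.get("n_cycles", 4)),
        cycle_length_years=float(doc.get("cycle_length_years", 0.25)),
        wtp_threshold=float(doc.get("wtp_threshold", 34_000.0)),
        discount_rate=float(doc.get("discount_rate", 0.0)),
        metadata=dict(doc.get("metadata", {})),
    )
    problems = validate_parameters(params)
    if problems:
        raise ParameterError("invalid parameters: " + "; ".join(problems))
    return params


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def parameters_to_frame(params: ModelParameters) -> pd.DataFrame:
    """Flatten all scalars to a tidy table (one row per parameter)."""
    rows: list[dict[str, Any]] = []

    def add(pid, value, units, strategy="", state="", category=""):
        rows.append(
            dict(id=pid, strategy=strategy, state=state, category=category,
                 value=value, units=units)
        )

    for strat in params.strategies:
        for i, origin in enumerate(ANGINA_STATES):
            for j, dest in enumerate(ANGINA_STATES):
                add(f"transition:{strat.name}:{origin}:{dest}",
                    strat.transition_matrix[i, j], "probability/cycle",
                    strategy=strat.name, state=origin, category=dest)
        add(f"drug_cost:{strat.name}", strat.monthly_drug_cost, "EUR/month",
            strategy=strat.name)
    for i, s in enumerate(ANGINA_STATES):
        add(f"mortality:{s}", params.annual_mortality[i], "probability/year", state=s)
        add(f"utility:{s}", params.utilities[i], "QALY weight", state=s)
        add(f"baseline:{s}", params.baseline[i], "proportion", state=s)
    for cat in COST_CATEGORIES:
        for i, s in enumerate(ANGINA_STATES):
            add(f"cost:{cat}:{s}", params.state_costs[cat][i], "EUR/year",
                state=s, category=cat)
    add("n_cycles", params.n_cycles, "cycles")
    add("cycle_length_years", params.cycle_length_years, "years")
    add("wtp_threshold", params.wtp_threshold, "EUR/QALY")
    add("discount_rate", params.discount_rate, "fraction/year")
    return pd.DataFrame(rows)
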