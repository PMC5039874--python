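"""Probabilistic sensitivity analysis (second-order Monte Carlo).

Distribution families follow standard practice for decision models:

* gamma for every state cost (mean preserved, sd = cv * mean); drug
  acquisition costs are held fixed;
* beta for utilities and annual mortality, parameterized by the base
  value and an effective sample size (method of moments);
* Dirichlet for each transition row, ``alpha = row * ess``.

Each iteration draws one coherent parameter set, evaluates both
strategies through the deterministic engine and records the incremental
cost/effect pair.  Decisions at a willingness-to-pay threshold use the
net-monetary-benefit formulation (per-draw ICERs are never averaged).

Draw order is fixed so results are reproducible from a seed: costs
(category-major, state-minor), utilities, mortality, then transition
rows for the intervention and comparator in origin-state order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .economics import evaluate_strategy
from .parameters import ANGINA_STATES, COST_CATEGORIES, ModelParameters, StrategySpec

__all__ = [
    "UncertaintySpec",
    "SamplingModel",
    "assign_distributions",
    "run_psa",
    "PSAResult",
    "ceac",
    "probability_cost_effective",
    "psa_to_frame",
    "ceac_to_frame",
]


@dataclass(frozen=True)
class UncertaintySpec:
    """Family-level uncertainty settings.

    ``cost_cv`` is the coefficient of variation of the gamma cost
    distributions; the ``*_ess`` fields are effective sample sizes for
    the beta/Dirichlet families.  ``cost_cv = 0`` or an infinite ess
    collapses that family to a point mass (degenerate mode).
    """

    cost_cv: float = 0.102
    utility_ess: float = 100.0
    transition_ess: float = 100.0
    mortality_ess: float = 100.0

    def __post_init__(self) -> None:
        if self.cost_cv < 0:
            raise ValueError("cost_cv must be non-negative")
        for name in ("utility_ess", "transition_ess", "mortality_ess"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def degenerate(cls) -> "UncertaintySpec":
        """Zero-variance spec: every draw equals the base value."""
        return cls(cost_cv=0.0, utility_ess=math.inf,
                   transition_ess=math.inf, mortality_ess=math.inf)


def _draw_gamma(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv == 0.0 or mean == 0.0:
        return mean  # zero-cost inputs stay a point mass at 0
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, mean * cv**2))


def _draw_beta(rng: np.random.Generator, mean: float, ess: float) -> float:
    if not math.isfinite(ess) or mean in (0.0, 1.0):
        return mean
    return float(rng.beta(mean * ess, (1.0 - mean) * ess))


def _draw_dirichlet_row(rng: np.random.Generator, row: np.ndarray, ess: float) -> np.ndarray:
    if not math.isfinite(ess):
        return row.copy()
    out = np.zeros_like(row)
    mask = row > 0.0
    if mask.sum() == 1:
        out[mask] = 1.0
        return out
    out[mask] = rng.dirichlet(row[mask] * ess)
    return out


@dataclass(frozen=True)
class SamplingModel:
    """Base parameters plus the distributions assigned around them."""

    base: ModelParameters
    spec: UncertaintySpec

    def sample(self, rng: np.random.Generator) -> ModelParameters:
        """Draw one coherent parameter set (fixed draw order)."""
        base, spec = self.base, self.spec
        costs = {
            cat: np.array([
                _draw_gamma(rng, base.state_costs[cat][i], spec.cost_cv)
                for i in range(4)
            ])
            for cat in COST_CATEGORIES
        }
        utilities = np.array([
            _draw_beta(rng, base.utilities[i], spec.utility_ess) for i in range(4)
        ])
        mortality = np.array([
            _draw_beta(rng, base.annual_mortality[i], spec.mortality_ess)
            for i in range(4)
        ])
        strategies = {}
        for field in ("intervention", "comparator"):
            strat: StrategySpec = getattr(base, field)
            rows = np.vstack([
                _draw_dirichlet_row(rng, strat.transition_matrix[i], spec.transition_ess)
                for i in range(4)
            ])
            strategies[field] = StrategySpec(
                strat.name, rows, strat.monthly_drug_cost  # drug cost fixed in PSA
            )
        return base.replace(
            annual_mortality=mortality, utilities=utilities, state_costs=costs,
            **strategies,
        )


def assign_distributions(
    params: ModelParameters, spec: UncertaintySpec | None = None
) -> SamplingModel:
    """Bind an :class:`UncertaintySpec` to a base parameter set."""
    return SamplingModel(base=params, spec=spec or UncertaintySpec())


@dataclass(frozen=True)
class PSAResult:
    """Paired incremental draws from one PSA run."""

    delta_cost: np.ndarray    # (n_iterations,)
    delta_effect: np.ndarray  # (n_iterations,)
    n_iterations: int
    seed: int | None

    def __post_init__(self) -> None:
        dc = np.asarray(self.delta_cost, dtype=float)
        de = np.asarray(self.delta_effect, dtype=float)
        if dc.shape != (self.n_iterations,) or de.shape != (self.n_iterations,):
            raise ValueError("draw arrays must have length n_iterations")
        dc.setflags(write=False)
        de.setflags(write=False)
        object.__setattr__(self, "delta_cost", dc)
        object.__setattr__(self, "delta_effect", de)


def run_psa(
    model: SamplingModel, n_iterations: int = 5000, seed: int | None = None
) -> PSAResult:
    """Monte Carlo over parameter draws; reproducible for a given seed."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    dc = np.empty(n_iterations)
    de = np.empty(n_iterations)
    for i in range(n_iterations):
        p = model.sample(rng)
        a = evaluate_strategy(p, p.intervention)
        b = evaluate_strategy(p, p.comparator)
        dc[i] = a.total_cost - b.total_cost
        de[i] = a.qalys - b.qalys
    return PSAResult(delta_cost=dc, delta_effect=de,
                     n_iterations=n_iterations, seed=seed)


def probability_cost_effective(result: PSAResult, wtp: float) -> float:
    """Fraction of draws with positive incremental NMB at ``wtp``."""
    if result.n_iterations == 0:
        raise ValueError("empty PSA result")
    return float(np.mean(wtp * result.delta_effect - result.delta_cost > 0.0))


def ceac(result: PSAResult, wtp_grid: Sequence[float]) -> list[tuple[float, float]]:
    """Cost-effectiveness acceptability curve over a WTP grid."""
    return [(float(w), probability_cost_effective(result, w)) for w in wtp_grid]


def psa_to_frame(result: PSAResult) -> pd.DataFrame:
    return pd.DataFrame({
        "iteration": np.arange(1, result.n_iterations + 1),
        "delta_cost": result.delta_cost,
        "delta_effect": result.delta_effect,
    })


def ceac_to_frame(points: Sequence[tuple[float, float]]) -> pd.DataFrame:
    return pd.DataFrame(points, columns=["wtp", "probability"])
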