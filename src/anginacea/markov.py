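"""Cohort engine: per-cycle state occupancy for one strategy.

Event ordering within a cycle (the model's fixed convention):

1. occupancy is measured at cycle start and rewards accrue on it;
2. at cycle end, each living patient dies with the state-specific cycle
   probability of the state occupied *during* the cycle;
3. survivors of cycle 1 then transition between angina states according
   to the strategy's matrix; from cycle 2 onwards survivors remain in
   their state (treatment effect observed over one cycle, then carried
   forward in the absence of longer-term efficacy data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ANGINA_STATES, ROW_SUM_TOL, STATES, ModelParameters, StrategySpec

__all__ = [
    "annual_to_cycle_probability",
    "build_cycle_transition",
    "run_cohort",
    "CohortTrace",
    "trace_to_frame",
]

_DEAD = 4  # column index of the absorbing state


def annual_to_cycle_probability(p_annual, cycles_per_year: int = 4):
    """Convert an annual probability to a per-cycle probability.

    Assumes a constant hazard within the year:
    ``p_cycle = 1 - exp(ln(1 - p_annual) / cycles_per_year)``, so that
    ``1 - (1 - p_cycle)**cycles_per_year == p_annual``.  Accepts scalars
    or arrays; requires ``0 <= p_annual < 1``.
    """
    p = np.asarray(p_annual, dtype=float)
    if cycles_per_year < 1:
        raise ValueError("cycles_per_year must be >= 1")
    if np.any(p < 0) or np.any(p >= 1):
        raise ValueError("annual probability must lie in [0, 1)")
    out = 1.0 - np.exp(np.log1p(-p) / cycles_per_year)
    return float(out) if np.isscalar(p_annual) else out


@dataclass(frozen=True)
class CohortTrace:
    """Occupancy of the five states over the model horizon.

    ``occupancy[c]`` is the distribution at the start of cycle ``c + 1``
    (the distribution on which that cycle's rewards accrue);
    ``final_distribution`` is the distribution after the last cycle.
    Rows sum to 1 and the dead share never decreases.
    """

    occupancy: np.ndarray        # (n_cycles, 5)
    final_distribution: np.ndarray  # (5,)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        fin = np.asarray(self.final_distribution, dtype=float)
        occ.setflags(write=False)
        fin.setflags(write=False)
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "final_distribution", fin)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    @property
    def alive(self) -> np.ndarray:
        """Proportion alive at the start of each cycle."""
        return 1.0 - self.occupancy[:, _DEAD]


def build_cycle_transition(
    params: ModelParameters, strategy: StrategySpec, cycle_index: int
) -> np.ndarray:
    """Full 5x5 row-stochastic transition matrix for one cycle.

    ``cycle_index`` is 1-based.  For each angina origin ``s`` with cycle
    death probability ``d_s``: the entry to dead is ``d_s``; in cycle 1
    survivors distribute over angina states as ``(1 - d_s) * M[s]``;
    from cycle 2 onwards survivors stay put.  Dead is absorbing.
    """
    if not 1 <= cycle_index <= params.n_cycles:
        raise ValueError(
            f"cycle_index {cycle_index} out of range 1..{params.n_cycles}"
        )
    cycles_per_year = round(1.0 / params.cycle_length_years)
    d = annual_to_cycle_probability(params.annual_mortality, cycles_per_year)
    full = np.zeros((5, 5))
    full[:4, _DEAD] = d
    if cycle_index == 1:
        full[:4, :4] = (1.0 - d)[:, None] * strategy.transition_matrix
    else:
        full[:4, :4] = np.diag(1.0 - d)
    full[_DEAD, _DEAD] = 1.0
    assert np.allclose(full.sum(axis=1), 1.0, atol=ROW_SUM_TOL)
    return full


def run_cohort(params: ModelParameters, strategy: StrategySpec) -> CohortTrace:
    """Propagate the cohort through ``params.n_cycles`` cycles."""
    occ = np.zeros((params.n_cycles, 5))
    occ[0, :4] = params.baseline
    for c in range(1, params.n_cycles):
        occ[c] = occ[c - 1] @ build_cycle_transition(params, strategy, c)
    final = occ[-1] @ build_cycle_transition(params, strategy, params.n_cycles)
    return CohortTrace(occupancy=occ, final_distribution=final)


def trace_to_frame(trace: CohortTrace) -> pd.DataFrame:
    """Long-form table (cycle, state, occupancy) for export."""
    rows = [
        {"cycle": c + 1, "state": s, "occupancy": trace.occupancy[c, j]}
        for c in range(trace.n_cycles)
        for j, s in enumerate(STATES)
    ]
    return pd.DataFrame(rows)
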