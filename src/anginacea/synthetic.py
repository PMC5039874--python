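"""Synthetic parameter sets and an individual-level simulation oracle.

``generate_random_parameters`` draws structurally valid inputs with the
same qualitative shape as real angina cost-utility data: row-stochastic
transitions, mortality and costs that rise with severity, utilities that
fall with severity, and a baseline supported on the symptomatic states.

``microsimulate`` pushes individual patients through the same event
ordering as the cohort engine (reward at cycle start, death at cycle
end from the state occupied during the cycle, survivors transition at
the end of cycle 1).  It samples transitions directly from the input
probabilities rather than reusing the cohort recursion, so it is an
independent check of the matrix arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .markov import CohortTrace, annual_to_cycle_probability
from .parameters import (
    ANGINA_STATES,
    COST_CATEGORIES,
    ModelParameters,
    StrategySpec,
)

__all__ = [
    "SyntheticConfig",
    "generate_random_parameters",
    "microsimulate",
    "MicrosimulationResult",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the generator and the microsimulation oracle."""

    seed: int = 0
    severity_monotone: bool = True
    n_patients: int = 50_000

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


def generate_random_parameters(config: SyntheticConfig | int = 0) -> ModelParameters:
    """Random, valid parameter set; identical for identical seeds."""
    if isinstance(config, int):
        config = SyntheticConfig(seed=config)
    rng = np.random.default_rng(config.seed)

    def transition_matrix() -> np.ndarray:
        # mild concentration keeps rows away from degenerate corners
        return rng.dirichlet(np.full(4, 2.0), size=4)

    utilities = rng.uniform(0.2, 0.95, size=4)
    mortality = rng.uniform(0.005, 0.3, size=4)
    if config.severity_monotone:
        utilities = np.sort(utilities)[::-1]
        mortality = np.sort(mortality)
    costs: dict[str, np.ndarray] = {}
    for cat in COST_CATEGORIES:
        draws = rng.gamma(shape=2.0, scale=150.0, size=4)
        costs[cat] = np.cumsum(draws) if config.severity_monotone else draws
    baseline = np.concatenate([[0.0], rng.dirichlet(np.full(3, 2.0))])
    return ModelParameters(
        intervention=StrategySpec(
            "synthetic-intervention", transition_matrix(),
            float(rng.uniform(5.0, 50.0)),
        ),
        comparator=StrategySpec(
            "synthetic-comparator", transition_matrix(),
            float(rng.uniform(5.0, 50.0)),
        ),
        annual_mortality=mortality,
        utilities=utilities,
        baseline=baseline,
        state_costs=costs,
        metadata={"synthetic": True, "seed": config.seed},
    )


@dataclass(frozen=True)
class MicrosimulationResult:
    """Empirical trace and per-patient reward summaries with MC errors.

    ``occupancy``/``occupancy_se`` mirror :class:`CohortTrace.occupancy`
    (start-of-cycle fractions).  Scalar rewards are per-patient means,
    each with the standard error of that mean.
    """

    trace: CohortTrace
    occupancy_se: np.ndarray
    life_years: float
    life_years_se: float
    qalys: float
    qalys_se: float
    cost_by_category: Mapping[str, float]
    total_cost: float
    total_cost_se: float
    n_patients: int


def _balanced_counts(rng: np.random.Generator, k: int, probs: np.ndarray) -> np.ndarray:
    """Allocate ``k`` individuals over outcomes with expectation ``k * probs``.

    Largest-remainder allocation with the leftover units drawn in
    proportion to the fractional parts: unbiased, but with per-outcome
    deviation O(1) instead of the O(sqrt(k)) of i.i.d. sampling.
    """
    expected = k * probs
    counts = np.floor(expected).astype(int)
    frac = expected - counts
    r = k - counts.sum()
    if r > 0:
        extra = rng.choice(len(probs), size=r, p=frac / frac.sum())
        np.add.at(counts, extra, 1)
    return counts


def _allocate(rng: np.random.Generator, members: np.ndarray, probs: np.ndarray,
              out: np.ndarray, values: np.ndarray) -> None:
    """Assign outcome ``values`` to ``members`` with balanced counts."""
    counts = _balanced_counts(rng, members.size, probs)
    shuffled = rng.permutation(members)
    out[shuffled] = np.repeat(values, counts)


def microsimulate(
    params: ModelParameters,
    strategy: StrategySpec,
    n_patients: int = 50_000,
    seed: int = 0,
    balanced: bool = True,
) -> MicrosimulationResult:
    """Simulate ``n_patients`` individual trajectories for one strategy.

    With ``balanced`` (default) every stochastic branching — initial
    state, death, cycle-1 destination — allocates patients by balanced
    (stratified, randomized-remainder) sampling, a standard
    variance-reduction device for microsimulations: each patient still
    follows a valid trajectory with the correct marginal probabilities,
    but empirical frequencies deviate from their expectations by O(1/n)
    rather than O(1/sqrt(n)), so the reported binomial/CLT standard
    errors are conservative.  ``balanced=False`` gives plain i.i.d.
    sampling.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    n_cycles = params.n_cycles
    cycle_len = params.cycle_length_years
    cycles_per_year = round(1.0 / cycle_len)
    d = annual_to_cycle_probability(params.annual_mortality, cycles_per_year)
    m_cum = np.cumsum(strategy.transition_matrix, axis=1)
    months_per_cycle = 12.0 * cycle_len

    state = np.empty(n_patients, dtype=np.int64)
    if balanced:
        _allocate(rng, np.arange(n_patients), np.asarray(params.baseline),
                  state, np.arange(4))
    else:
        state[:] = np.searchsorted(np.cumsum(params.baseline),
                                   rng.random(n_patients), side="right")
    alive = np.ones(n_patients, dtype=bool)
    occupancy = np.zeros((n_cycles, 5))
    ly = np.zeros(n_patients)
    qaly = np.zeros(n_patients)
    cost = np.zeros(n_patients)
    cost_by_cat = {cat: 0.0 for cat in list(COST_CATEGORIES) + ["drug"]}
    per_cycle_cost = {
        cat: np.asarray(params.state_costs[cat]) * cycle_len
        for cat in COST_CATEGORIES
    }

    for c in range(n_cycles):
        # start-of-cycle occupancy and rewards
        counts = np.bincount(state[alive], minlength=4)
        occupancy[c, :4] = counts / n_patients
        occupancy[c, 4] = 1.0 - alive.mean()
        s_alive = state[alive]
        ly[alive] += cycle_len
        qaly[alive] += cycle_len * params.utilities[s_alive]
        cycle_cost = np.zeros(s_alive.shape[0])
        for cat in COST_CATEGORIES:
            contrib = per_cycle_cost[cat][s_alive]
            cycle_cost += contrib
            cost_by_cat[cat] += contrib.sum()
        drug = strategy.monthly_drug_cost * months_per_cycle
        cycle_cost += drug
        cost_by_cat["drug"] += drug * s_alive.shape[0]
        cost[alive] += cycle_cost
        # end-of-cycle deaths from the state occupied during the cycle
        dies = np.zeros(n_patients, dtype=bool)
        if balanced:
            for s in range(4):
                members = np.nonzero(alive & (state == s))[0]
                if members.size:
                    flag = np.empty(members.size, dtype=np.int64)
                    _allocate(rng, np.arange(members.size),
                              np.array([1.0 - d[s], d[s]]), flag, np.arange(2))
                    dies[members] = flag.astype(bool)
        else:
            dies = alive & (rng.random(n_patients) < d[state])
        survivors = alive & ~dies
        if c == 0:
            # survivors transition once, allocated per origin state
            # (destinations read from a snapshot so nobody moves twice)
            origin = state.copy()
            u = None if balanced else rng.random(n_patients)
            for s in range(4):
                members = np.nonzero(survivors & (origin == s))[0]
                if not members.size:
                    continue
                if balanced:
                    _allocate(rng, members, strategy.transition_matrix[s],
                              state, np.arange(4))
                else:
                    state[members] = np.searchsorted(m_cum[s], u[members],
                                                     side="right")
        alive = survivors

    # final distribution after the last cycle
    final = np.zeros(5)
    final[:4] = np.bincount(state[alive], minlength=4) / n_patients
    final[4] = 1.0 - alive.mean()

    trace = CohortTrace(occupancy=occupancy, final_distribution=final)
    occ_se = np.sqrt(occupancy * (1.0 - occupancy) / n_patients)

    def mean_se(x: np.ndarray) -> tuple[float, float]:
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(n_patients))

    ly_m, ly_se = mean_se(ly)
    q_m, q_se = mean_se(qaly)
    c_m, c_se = mean_se(cost)
    return MicrosimulationResult(
        trace=trace,
        occupancy_se=occ_se,
        life_years=ly_m, life_years_se=ly_se,
        qalys=q_m, qalys_se=q_se,
        cost_by_category={k: v / n_patients for k, v in cost_by_cat.items()},
        total_cost=c_m, total_cost_se=c_se,
        n_patients=n_patients,
    )
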