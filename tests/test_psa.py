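"""Distribution assignment, Monte Carlo reproducibility and the CEAC."""

import numpy as np
import pytest

from anginacea import (
    PSAResult,
    UncertaintySpec,
    assign_distributions,
    ceac,
    evaluate_strategy,
    incremental_analysis,
    probability_cost_effective,
    run_psa,
)


@pytest.fixture(scope="module")
def default_result(params):
    return run_psa(assign_distributions(params), n_iterations=1000, seed=11)


class TestSampling:
    def test_degenerate_draws_equal_base(self, params):
        model = assign_distributions(params, UncertaintySpec.degenerate())
        rng = np.random.default_rng(0)
        drawn = model.sample(rng)
        assert drawn == params

    def test_draw_validity(self, params):
        model = assign_distributions(params)
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = model.sample(rng)
            for strat in p.strategies:
                m = strat.transition_matrix
                assert np.all(m >= 0)
                np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-9)
            assert np.all((p.utilities >= 0) & (p.utilities <= 1))
            assert np.all((p.annual_mortality >= 0) & (p.annual_mortality < 1))
            for v in p.state_costs.values():
                assert np.all(v >= 0)

    def test_structural_zeros_preserved(self, params):
        # transitions never observed in the trial stay impossible
        model = assign_distributions(params)
        rng = np.random.default_rng(9)
        for _ in range(20):
            p = model.sample(rng)
            assert p.intervention.transition_matrix[0, 3] == 0.0
            assert p.comparator.transition_matrix[0, 2] == 0.0

    def test_drug_costs_never_sampled(self, params):
        model = assign_distributions(params)
        rng = np.random.default_rng(2)
        for _ in range(10):
            p = model.sample(rng)
            assert p.intervention.monthly_drug_cost == 29.18
            assert p.comparator.monthly_drug_cost == 23.40

    def test_gamma_moments(self, params):
        # method-of-moments: mean preserved, sd = cv * mean
        model = assign_distributions(params, UncertaintySpec(cost_cv=0.102))
        rng = np.random.default_rng(123)
        draws = np.array([
            model.sample(rng).state_costs["hosp_revasc"][0] for _ in range(4000)
        ])
        assert draws.mean() == pytest.approx(586.24, rel=0.01)
        assert draws.std() == pytest.approx(0.102 * 586.24, rel=0.08)

    def test_dirichlet_concentration(self, params):
        # row draws centre on the base row with ess-driven spread
        model = assign_distributions(params, UncertaintySpec(transition_ess=100.0))
        rng = np.random.default_rng(42)
        rows = np.array([
            model.sample(rng).intervention.transition_matrix[2] for _ in range(4000)
        ])
        np.testing.assert_allclose(
            rows.mean(axis=0), params.intervention.transition_matrix[2], atol=0.01
        )

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            UncertaintySpec(cost_cv=-0.1)
        with pytest.raises(ValueError):
            UncertaintySpec(transition_ess=0.0)


class TestRunPSA:
    def test_degenerate_psa_equals_deterministic(self, params):
        a = evaluate_strategy(params, params.intervention)
        b = evaluate_strategy(params, params.comparator)
        inc = incremental_analysis(a, b)
        model = assign_distributions(params, UncertaintySpec.degenerate())
        res = run_psa(model, n_iterations=5, seed=1)
        assert np.all(res.delta_cost == inc.delta_cost)
        assert np.all(res.delta_effect == inc.delta_effect)

    def test_seed_reproducibility(self, params, default_result):
        again = run_psa(assign_distributions(params), n_iterations=1000, seed=11)
        np.testing.assert_array_equal(again.delta_cost, default_result.delta_cost)
        np.testing.assert_array_equal(again.delta_effect, default_result.delta_effect)

    def test_different_seed_differs(self, params, default_result):
        other = run_psa(assign_distributions(params), n_iterations=1000, seed=12)
        assert not np.array_equal(other.delta_cost, default_result.delta_cost)

    def test_mean_effect_near_deterministic(self, params, default_result):
        a = evaluate_strategy(params, params.intervention)
        b = evaluate_strategy(params, params.comparator)
        det = a.qalys - b.qalys
        se = default_result.delta_effect.std(ddof=1) / np.sqrt(default_result.n_iterations)
        assert abs(default_result.delta_effect.mean() - det) < 3 * se

    def test_invalid_iterations(self, params):
        with pytest.raises(ValueError):
            run_psa(assign_distributions(params), n_iterations=0, seed=1)


class TestCEAC:
    def test_wtp_zero_counts_cost_savings(self, default_result):
        p0 = probability_cost_effective(default_result, 0.0)
        assert p0 == pytest.approx(float((default_result.delta_cost < 0).mean()))

    def test_large_wtp_counts_effect_gains(self, default_result):
        p_inf = probability_cost_effective(default_result, 1e12)
        assert p_inf == pytest.approx(float((default_result.delta_effect > 0).mean()))

    def test_probabilities_in_unit_interval(self, default_result):
        pts = ceac(default_result, np.arange(0, 68_001, 1000.0))
        assert all(0.0 <= q <= 1.0 for _, q in pts)

    def test_nondecreasing_when_all_effects_positive(self, default_result):
        mask = default_result.delta_effect > 0
        sub = PSAResult(
            delta_cost=default_result.delta_cost[mask],
            delta_effect=default_result.delta_effect[mask],
            n_iterations=int(mask.sum()), seed=None,
        )
        probs = [q for _, q in ceac(sub, np.arange(0, 68_001, 500.0))]
        assert all(a <= b for a, b in zip(probs, probs[1:]))

    def test_degenerate_step_at_deterministic_icer(self, params):
        model = assign_distributions(params, UncertaintySpec.degenerate())
        res = run_psa(model, n_iterations=3, seed=1)
        a = evaluate_strategy(params, params.intervention)
        b = evaluate_strategy(params, params.comparator)
        icer = incremental_analysis(a, b).icer
        assert probability_cost_effective(res, icer * 0.99) == 0.0
        assert probability_cost_effective(res, icer * 1.01) == 1.0
        assert probability_cost_effective(res, 34_000.0) == 1.0

    def test_half_favourable_draws(self):
        res = PSAResult(
            delta_cost=np.array([-1.0, -1.0, 1.0, 1.0]),
            delta_effect=np.zeros(4), n_iterations=4, seed=None,
        )
        assert probability_cost_effective(res, 10_000.0) == 0.5

    def test_empty_grid(self, default_result):
        assert ceac(default_result, []) == []
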