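"""Perturbation mechanics, tornado ordering and rebate scenarios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anginacea import (
    ParameterHandle,
    default_handles,
    paper_fixture,
    perturb_parameter,
    rebate_scenario,
    resolve_parameter,
    run_owsa,
)
from anginacea.sensitivity import owsa_to_frame


class TestPerturbParameter:
    def test_identity_factor(self, params):
        h = ParameterHandle("utility:moderate", "clinical")
        assert perturb_parameter(params, h, 1.0) == params

    def test_input_never_mutated(self, params):
        before = params.intervention.transition_matrix.copy()
        h = ParameterHandle("transition:TMZ+SoC:moderate:mild", "clinical")
        perturb_parameter(params, h, 1.1)
        np.testing.assert_array_equal(params.intervention.transition_matrix, before)

    def test_proportional_row_renormalization(self):
        # a moderate->mild cell of 0.6117 scaled by 1.1 becomes 0.67287 and
        # the rest of the row shrinks by (1 - 0.67287) / (1 - 0.6117)
        from anginacea import StrategySpec

        p = paper_fixture()
        m = p.intervention.transition_matrix.copy()
        m[2] = [0.1942, 0.6117, 0.1553, 0.0388]
        m[2] /= m[2].sum()
        p = p.replace(intervention=StrategySpec("TMZ+SoC", m, 29.18))
        h = ParameterHandle("transition:TMZ+SoC:moderate:mild", "clinical")
        out = perturb_parameter(p, h, 1.1).intervention.transition_matrix[2]
        assert out[1] == pytest.approx(0.67287, abs=1e-4)
        scale = (1 - out[1]) / (1 - m[2][1])
        np.testing.assert_allclose(out[[0, 2, 3]], m[2][[0, 2, 3]] * scale, atol=1e-12)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_stay_cell_balancing(self, params):
        h = ParameterHandle("transition:TMZ+SoC:moderate:mild", "clinical")
        base_row = params.intervention.transition_matrix[2].copy()
        out = perturb_parameter(params, h, 1.1, row_balance="stay")
        row = out.intervention.transition_matrix[2]
        delta = row[1] - base_row[1]
        assert delta == pytest.approx(0.1 * base_row[1], abs=1e-12)
        assert row[2] == pytest.approx(base_row[2] - delta, abs=1e-12)
        np.testing.assert_array_equal(row[[0, 3]], base_row[[0, 3]])
        assert row.sum() == pytest.approx(1.0, abs=1e-9)

    def test_cost_cell_perturbs_alone(self, params):
        h = ParameterHandle("cost:hosp_revasc:severe", "cost")
        out = perturb_parameter(params, h, 1.2)
        assert resolve_parameter(out, h) == pytest.approx(1972.77 * 1.2)
        for cat in params.state_costs:
            mask = np.ones(4, bool)
            if cat == "hosp_revasc":
                mask[3] = False
            np.testing.assert_array_equal(
                out.state_costs[cat][mask], params.state_costs[cat][mask]
            )

    def test_utility_capped_at_one(self, params):
        h = ParameterHandle("utility:minimal", "clinical")
        out = perturb_parameter(params, h, 1.5)
        assert out.utilities[0] == 1.0

    def test_probability_overflow_raises_without_clamp(self, params):
        h = ParameterHandle("transition:TMZ+SoC:minimal:minimal", "clinical")
        with pytest.raises(ValueError, match="exceeds 1"):
            perturb_parameter(params, h, 1.1)
        clamped = perturb_parameter(params, h, 1.1, clamp=True)
        assert clamped.intervention.transition_matrix[0, 0] == 1.0

    @settings(max_examples=20, deadline=None)
    @given(factor=st.floats(0.5, 1.4))
    def test_rows_remain_stochastic(self, factor):
        p = paper_fixture()
        h = ParameterHandle("transition:SoC:mild:moderate", "clinical")
        out = perturb_parameter(p, h, factor, clamp=True)
        np.testing.assert_allclose(
            out.comparator.transition_matrix.sum(axis=1), 1.0, atol=1e-9
        )


@pytest.fixture(scope="module")
def entries():
    return run_owsa(paper_fixture())


class TestOWSA:
    def test_sorted_by_spread(self, entries):
        spreads = [e.spread for e in entries]
        assert spreads == sorted(spreads, reverse=True)
        assert all(s >= 0 for s in spreads)

    def test_most_influential_is_tmz_moderate_to_mild(self, entries):
        assert entries[0].handle.id == "transition:TMZ+SoC:moderate:mild"

    def test_next_ranked_are_soc_transitions_to_mild(self, entries):
        ids = [e.handle.id for e in entries[1:3]]
        assert ids == ["transition:SoC:severe:mild", "transition:SoC:moderate:mild"]

    def test_all_endpoints_cost_effective(self, entries):
        wtp = 34_000.0
        for e in entries:
            for inc, dnmb in [(e.result_low, e.nmb_low), (e.result_high, e.nmb_high)]:
                if inc.icer is not None:
                    assert inc.icer < wtp
                else:
                    assert dnmb > 0  # dominant endpoints favour the add-on

    def test_order_invariant_to_handle_order(self, entries):
        p = paper_fixture()
        handles = default_handles(p)
        rng = np.random.default_rng(3)
        shuffled = [handles[i] for i in rng.permutation(len(handles))]
        again = run_owsa(p, shuffled)
        assert [e.handle.id for e in again] == [e.handle.id for e in entries]

    def test_zero_range_zero_spread(self):
        p = paper_fixture()
        cost_handles = [h for h in default_handles(p) if h.kind == "cost"]
        out = run_owsa(p, cost_handles, cost_factor=0.0)
        assert all(e.spread == pytest.approx(0.0, abs=1e-9) for e in out)

    def test_no_effect_parameter_zero_spread(self, params):
        # nobody enters at minimal and cycle-1 occupancy is baseline, so a
        # minimal-state cost perturbation moves both arms identically only
        # through later cycles; a baseline with zero share everywhere but
        # one state isolates this: use the never-reached minimal row cost
        # under transitions that cannot reach minimal
        from anginacea import StrategySpec

        m = np.zeros((4, 4))
        m[:, 3] = 1.0  # everyone collapses to severe
        p = params.replace(
            intervention=StrategySpec("TMZ+SoC", m, 29.18),
            comparator=StrategySpec("SoC", m.copy(), 23.40),
        )
        h = ParameterHandle("cost:hosp_revasc:minimal", "cost")
        out = run_owsa(p, [h])
        assert out[0].spread == pytest.approx(0.0, abs=1e-9)

    def test_frame_export(self, entries, tmp_path):
        import pandas as pd

        frame = owsa_to_frame(entries)
        assert list(frame["rank"]) == list(range(1, len(entries) + 1))
        path = tmp_path / "owsa.csv"
        frame.to_csv(path, index=False)
        assert len(pd.read_csv(path)) == len(entries)


class TestRebateScenarios:
    def test_zero_rebate_is_base_case(self, params, base_results):
        inc = rebate_scenario(params, 0.0)
        assert inc.icer == pytest.approx(base_results[2].icer, abs=1e-9)

    def test_two_percent_rebate_lowers_icer(self, params, base_results):
        inc = rebate_scenario(params, 0.02)
        assert inc.classification == "tradeoff_icer"
        assert 0 < inc.icer < base_results[2].icer
        assert inc.delta_effect == pytest.approx(base_results[2].delta_effect, abs=1e-12)

    def test_twelve_percent_rebate_dominant(self, params):
        inc = rebate_scenario(params, 0.12)
        assert inc.classification == "intervention_dominant"
        assert inc.delta_cost < 0 < inc.delta_effect

    def test_delta_cost_strictly_decreasing_in_rebate(self, params):
        rebates = [0.0, 0.02, 0.05, 0.08, 0.12]
        dcs = [rebate_scenario(params, r).delta_cost for r in rebates]
        assert all(a > b for a, b in zip(dcs, dcs[1:]))

    def test_invalid_rebate(self, params):
        with pytest.raises(ValueError):
            rebate_scenario(params, 1.0)
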