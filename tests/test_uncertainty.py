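"""PSA, tornado analysis and scenario transforms."""

import dataclasses

import numpy as np
import pytest

from markovcea import (
    SCENARIOS,
    apply_scenario,
    run_cohort,
    run_psa,
    tornado,
)
from markovcea.evidence import ParameterDef, ParameterSet
from markovcea.uncertainty import ScenarioDef


def sorted_percentile(x, q):
    """Independent percentile oracle: sort and linearly interpolate ranks."""
    xs = np.sort(np.asarray(x, float))
    n = len(xs)
    pos = q / 100.0 * (n - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


class TestPsa:
    def test_all_fixed_reproduces_base_case_exactly(self, ankle_spec, fixed_params):
        draws, summary = run_psa(ankle_spec, fixed_params, n=5, seed=0)
        for j, s in enumerate(ankle_spec.strategies):
            base = run_cohort(ankle_spec, s)
            assert np.all(draws.cost[:, j] == base.total_cost_discounted)
            assert np.all(draws.qaly[:, j] == base.total_qaly_discounted)
        assert summary.n_rejected == 0

    def test_same_seed_identical_draw_matrix(self, ankle_spec, ankle_params):
        a, _ = run_psa(ankle_spec, ankle_params, n=50, seed=77)
        b, _ = run_psa(ankle_spec, ankle_params, n=50, seed=77)
        assert np.array_equal(a.cost, b.cost)
        assert np.array_equal(a.qaly, b.qaly)

    def test_credible_intervals_match_sort_oracle(self, ankle_psa):
        draws, summary = ankle_psa
        dc = draws.cost[:, -1] - draws.cost[:, 0]
        assert summary.delta_cost_ci[0] == pytest.approx(
            sorted_percentile(dc, 2.5), rel=1e-9)
        assert summary.delta_cost_ci[1] == pytest.approx(
            sorted_percentile(dc, 97.5), rel=1e-9)
        for name in draws.strategies:
            j = draws.column(name)
            lo, hi = summary.per_strategy[name]["cost_ci"]
            assert lo == pytest.approx(sorted_percentile(draws.cost[:, j], 2.5))
            assert hi == pytest.approx(sorted_percentile(draws.cost[:, j], 97.5))
            assert lo <= summary.per_strategy[name]["mean_cost"] <= hi

    def test_draw_means_converge_to_base_case(self, ankle_spec, ankle_psa):
        """Fitted means equal base values, so PSA means estimate the base case."""
        draws, summary = ankle_psa
        n = summary.n_iterations
        for j, s in enumerate(ankle_spec.strategies):
            base = run_cohort(ankle_spec, s)
            se_c = draws.cost[:, j].std(ddof=1) / np.sqrt(n)
            se_q = draws.qaly[:, j].std(ddof=1) / np.sqrt(n)
            assert abs(draws.cost[:, j].mean() - base.total_cost_discounted) < 3 * se_c
            assert abs(draws.qaly[:, j].mean() - base.total_qaly_discounted) < 3 * se_q

    def test_long_frame_layout(self, ankle_spec, ankle_params):
        draws, _ = run_psa(ankle_spec, ankle_params, n=10, seed=1)
        frame = draws.to_frame()
        assert list(frame.columns) == ["iteration", "strategy", "cost", "qaly"]
        assert len(frame) == 20


class TestTornado:
    def test_unused_parameter_has_zero_width(self, ankle_spec, ankle_params):
        # the permanent state's entry cost is never charged: nobody "enters"
        # stable, the whole cohort starts there
        defs = list(ankle_params.values())
        defs.append(ParameterDef("stable_entry_cost", 100.0, 0.0, 200.0, "gamma",
                                 ("states.stable.entry_cost",), "USD"))
        entries = tornado(ankle_spec, ParameterSet(defs))
        by_name = {e.parameter: e for e in entries}
        assert by_name["stable_entry_cost"].bar_width == pytest.approx(0.0, abs=1e-9)
        assert entries[-1].parameter == "stable_entry_cost"

    def test_zero_width_range_pins_endpoints_to_base(self, ankle_spec, ankle_params):
        defs = [dataclasses.replace(d, low=d.base, high=d.base)
                for d in ankle_params.values()]
        entries = tornado(ankle_spec, ParameterSet(defs))
        for e in entries:
            assert e.output_at_low == pytest.approx(e.base_output, abs=1e-9)
            assert e.output_at_high == pytest.approx(e.base_output, abs=1e-9)

    def test_ranking_matches_brute_force(self, ankle_spec, ankle_params):
        """Independent loop: re-evaluate every parameter excursion directly."""
        wtp = 100_000.0
        entries = tornado(ankle_spec, ankle_params, output="inc_nmb", wtp=wtp)

        def inc_nmb(spec):
            ref = run_cohort(spec, spec.strategy("ORIF"))
            comp = run_cohort(spec, spec.strategy("TTC"))
            return (wtp * (comp.total_qaly_discounted - ref.total_qaly_discounted)
                    - (comp.total_cost_discounted - ref.total_cost_discounted))

        widths = {}
        for name, p in ankle_params.items():
            outs = []
            for bound in (p.low, p.high):
                vals = ankle_params.base_values()
                vals[name] = bound
                outs.append(inc_nmb(ankle_params.apply(ankle_spec, vals)))
            widths[name] = abs(outs[1] - outs[0])
        for e in entries:
            assert e.bar_width == pytest.approx(widths[e.parameter], abs=1e-9)
        order = sorted(widths, key=widths.get, reverse=True)
        assert [e.parameter for e in entries] == order

    def test_endpoints_bracket_base_for_monotone_parameters(self, ankle_spec,
                                                            ankle_params):
        entries = tornado(ankle_spec, ankle_params, output="inc_cost")
        monotone = [e for e in entries if e.parameter.startswith(("p_", "index_"))]
        assert monotone
        for e in monotone:
            lo, hi = sorted((e.output_at_low, e.output_at_high))
            assert lo - 1e-9 <= e.base_output <= hi + 1e-9

    def test_unknown_output_rejected(self, ankle_spec, ankle_params):
        with pytest.raises(ValueError, match="output"):
            tornado(ankle_spec, ankle_params, output="icer")


class TestScenarios:
    def test_equal_deep_infection(self, ankle_spec):
        new = apply_scenario(ankle_spec, "equal_deep_infection")
        assert new.strategy("ORIF").p_deep == 0.025
        assert new.strategy("TTC").p_deep == 0.025

    def test_reop_plus50(self, ankle_spec):
        new = apply_scenario(ankle_spec, "reop_plus50")
        assert new.strategy("ORIF").p_nonunion == pytest.approx(0.1755)
        assert new.strategy("ORIF").p_deep == pytest.approx(0.025 * 1.5)
        assert new.strategy("TTC").p_hardware == pytest.approx(0.088 * 1.5)

    def test_horizon_3y_rebuilds_cycle_plan(self, ankle_spec):
        new = apply_scenario(ankle_spec, "horizon_3y")
        assert new.horizon_years == 3
        assert len(new.cycle_plan) == 6

    def test_base_scenario_is_identity(self, ankle_spec):
        assert apply_scenario(ankle_spec, "base") == ankle_spec

    def test_set_edits_idempotent(self, ankle_spec):
        once = apply_scenario(ankle_spec, "equal_deep_infection")
        twice = apply_scenario(once, "equal_deep_infection")
        assert once == twice

    def test_unknown_scenario_lists_registered_names(self, ankle_spec):
        with pytest.raises(KeyError, match="equal_deep_infection"):
            apply_scenario(ankle_spec, "no_such_scenario")

    def test_multiply_caps_pathway_sum_on_simplex(self, ankle_spec):
        big = ScenarioDef("big", (("mul", "strategies.*.p_nonunion", 9.0),))
        new = apply_scenario(ankle_spec, big)
        for s in new.strategies:
            assert s.p_deep + s.p_nonunion + s.p_hardware <= 1.0 + 1e-12
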