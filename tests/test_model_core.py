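"""Cohort engine: cycle plans, discounting, risk splitting, simulation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markovcea import (
    build_cycle_plan,
    discount_factor,
    generate_random_model,
    run_cohort,
    split_cumulative_probability,
)
from markovcea.model_core import HealthState, ModelSpec, Strategy, cycle_event_probs


def annuity_qaly(utility, horizon, rate):
    """Closed-form discounted QALY total for an uncomplicated cohort.

    Independent of the engine: four quarter-cycles at times k/4 plus annual
    cycles at whole years, each accruing utility x length at cycle-start
    discounting.
    """
    total = sum(utility * 0.25 * (1 + rate) ** (-k / 4) for k in range(4))
    total += sum(utility * 1.0 * (1 + rate) ** (-y) for y in range(1, int(horizon)))
    return total


def no_complication_strategy(**kw):
    base = dict(name="clean", index_cost=10_000.0, p_superficial=0.0, p_deep=0.0,
                p_nonunion=0.0, p_hardware=0.0, superficial_cost=2_500.0,
                reoperation_cost=12_000.0)
    base.update(kw)
    return Strategy(**base)


def three_states(u_stable=0.9, u_temp=0.78):
    return (
        HealthState("stable", "Stable", "permanent", u_stable),
        HealthState("superficial", "Superficial", "temporary", u_temp),
        HealthState("reoperation", "Reoperation", "temporary", u_temp),
    )


def make_spec(strategies, horizon=4, rate=0.03, u_stable=0.9, u_temp=0.78):
    return ModelSpec(
        strategies=tuple(strategies),
        states=three_states(u_stable, u_temp),
        cycle_plan=build_cycle_plan(horizon),
        horizon_years=float(horizon),
        discount_rate_annual=rate,
    )


class TestCyclePlan:
    @pytest.mark.parametrize("horizon, starts, lengths", [
        (4, (0, 0.25, 0.5, 0.75, 1, 2, 3), (0.25,) * 4 + (1.0,) * 3),
        (1, (0, 0.25, 0.5, 0.75), (0.25,) * 4),
        (3, (0, 0.25, 0.5, 0.75, 1, 2), (0.25,) * 4 + (1.0,) * 2),
    ])
    def test_quarterly_then_annual(self, horizon, starts, lengths):
        plan = build_cycle_plan(horizon)
        assert tuple(c.start_year for c in plan) == pytest.approx(starts)
        assert tuple(c.length_years for c in plan) == pytest.approx(lengths)
        assert sum(c.length_years for c in plan) == pytest.approx(horizon)

    @pytest.mark.parametrize("bad", [0, -1, 0.5, 2.5])
    def test_invalid_horizon_rejected(self, bad):
        with pytest.raises(ValueError, match="horizon_years"):
            build_cycle_plan(bad)


class TestDiscounting:
    def test_known_values(self):
        assert discount_factor(0.0, 0.03) == 1.0
        assert discount_factor(7.3, 0.0) == 1.0
        assert discount_factor(1.0, 0.03) == pytest.approx(1 / 1.03, abs=1e-9)
        assert discount_factor(1.0, 0.03) == pytest.approx(0.970874, abs=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="time_years"):
            discount_factor(-0.1, 0.03)


class TestRiskSplitting:
    @pytest.mark.parametrize("p, n, expected", [
        (0.102, 1, 0.102),
        (0.0, 4, 0.0),
        (1.0, 4, 1.0),
        (0.102, 4, 0.026538),
    ])
    def test_examples(self, p, n, expected):
        assert split_cumulative_probability(p, n) == pytest.approx(expected, abs=5e-6)

    @settings(derandomize=True, max_examples=100)
    @given(p=st.floats(0.0, 1.0), n=st.integers(1, 12))
    def test_recomposition(self, p, n):
        """The per-cycle rate recomposes to the cumulative risk exactly."""
        q = split_cumulative_probability(p, n)
        assert 0.0 <= q <= 1.0
        assert 1.0 - (1.0 - q) ** n == pytest.approx(p, abs=1e-9)


class TestRunCohort:
    def test_zero_complications_closed_form(self):
        spec = make_spec([no_complication_strategy(),
                          no_complication_strategy(name="other")])
        out = run_cohort(spec, spec.strategies[0])
        assert out.total_cost_discounted == pytest.approx(10_000.0, abs=1e-9)
        assert out.total_qaly_discounted == pytest.approx(
            annuity_qaly(0.9, 4, 0.03), abs=1e-9)
        assert out.total_qaly_discounted == pytest.approx(3.4359, abs=1e-4)

    def test_zero_rate_reproduces_undiscounted_sum(self):
        spec = make_spec([no_complication_strategy(),
                          no_complication_strategy(name="other")], rate=0.0)
        out = run_cohort(spec, spec.strategies[0])
        assert out.total_qaly_discounted == pytest.approx(0.9 * 4, abs=1e-12)

    def test_certain_superficial_forced_path(self):
        """p_superficial = 1: everyone passes through the state exactly once."""
        s = no_complication_strategy(p_superficial=1.0)
        spec = make_spec([s, no_complication_strategy(name="other")])
        out = run_cohort(spec, s)
        # split of p=1 over 4 cycles gives q=1: the whole cohort branches in
        # cycle 0 (discount factor 1) and returns to stable for good
        assert out.total_cost_discounted == pytest.approx(10_000.0 + 2_500.0)
        assert out.trajectory.sup_incidence.sum() == pytest.approx(1.0)
        assert out.trajectory.occupancy[0, 1] == pytest.approx(1.0)
        assert out.trajectory.occupancy[1:, 1] == pytest.approx(0.0)

    def test_event_costs_discounted_at_event_time(self):
        s = no_complication_strategy(p_superficial=0.2)
        spec = make_spec([s, no_complication_strategy(name="other")])
        out = run_cohort(spec, s)
        traj = out.trajectory
        # independent recomputation: incidence x cost x df(cycle start)
        expected = sum(
            inc * 2_500.0 * (1.03) ** (-t)
            for inc, t in zip(traj.sup_incidence, traj.start_years)
        )
        assert out.total_cost_discounted == pytest.approx(10_000.0 + expected, abs=1e-9)

    @pytest.mark.parametrize("field, lo, hi", [
        ("p_superficial", 0.05, 0.25),
        ("p_nonunion", 0.05, 0.25),
        ("index_cost", 8_000.0, 20_000.0),
    ])
    def test_monotone_in_risks_and_costs(self, field, lo, hi):
        """More risk or cost never increases QALYs nor decreases cost."""
        outs = []
        for v in (lo, hi):
            s = no_complication_strategy(**{field: v})
            spec = make_spec([s, no_complication_strategy(name="other")])
            outs.append(run_cohort(spec, s))
        assert outs[1].total_cost_discounted >= outs[0].total_cost_discounted
        assert outs[1].total_qaly_discounted <= outs[0].total_qaly_discounted

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_occupancy_conservation_random_specs(self, seed):
        spec = generate_random_model(seed)
        for s in spec.strategies:
            occ = run_cohort(spec, s).trajectory.occupancy
            assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-12, rtol=0)
            assert (occ >= -1e-12).all()

    def test_excess_branch_mass_rejected_before_simulation(self):
        s = Strategy(name="bad", index_cost=1.0, p_superficial=1.0, p_deep=1.0,
                     p_nonunion=0.0, p_hardware=0.0, superficial_cost=0.0,
                     reoperation_cost=0.0)
        spec = make_spec([s, no_complication_strategy(name="other")])
        with pytest.raises(ValueError, match="probability mass"):
            cycle_event_probs(spec, s)

    def test_half_cycle_discounts_qalys_at_midpoints(self):
        strategies = [no_complication_strategy(), no_complication_strategy(name="o")]
        spec = make_spec(strategies)
        spec_hc = dataclasses.replace(
            spec, options=dataclasses.replace(spec.options, half_cycle=True))
        plain = run_cohort(spec, spec.strategies[0])
        hc = run_cohort(spec_hc, spec_hc.strategies[0])
        expected = sum(0.9 * l * 1.03 ** (-(t + l / 2))
                       for t, l in zip(plain.trajectory.start_years,
                                       plain.trajectory.length_years))
        assert hc.total_qaly_discounted == pytest.approx(expected, abs=1e-12)
        assert hc.total_qaly_discounted < plain.total_qaly_discounted

    def test_trajectory_frame_layout(self):
        spec = make_spec([no_complication_strategy(),
                          no_complication_strategy(name="other")])
        frame = run_cohort(spec, spec.strategies[0]).trajectory.to_frame()
        assert list(frame.columns[:2]) == ["start_year", "length_years"]
        assert len(frame) == 7
        assert frame["discounted_qaly"].sum() == pytest.approx(
            annuity_qaly(0.9, 4, 0.03))


class TestValidation:
    def test_strategy_probability_bounds(self):
        with pytest.raises(ValueError, match="p_deep"):
            Strategy(name="x", index_cost=1.0, p_superficial=0.1, p_deep=1.4,
                     p_nonunion=0.0, p_hardware=0.0, superficial_cost=0.0)

    def test_reoperation_pathway_sum_capped(self):
        with pytest.raises(ValueError, match="p_deep \\+ p_nonunion \\+ p_hardware"):
            Strategy(name="x", index_cost=1.0, p_superficial=0.0, p_deep=0.5,
                     p_nonunion=0.4, p_hardware=0.3, superficial_cost=0.0)

    def test_exactly_one_permanent_state(self):
        states = three_states() + (HealthState("home2", "Second", "permanent", 0.8),)
        with pytest.raises(ValueError, match="permanent"):
            ModelSpec(
                strategies=(no_complication_strategy(),
                            no_complication_strategy(name="o")),
                states=states, cycle_plan=build_cycle_plan(2),
                horizon_years=2.0, discount_rate_annual=0.03)

    def test_cycle_plan_must_cover_horizon(self):
        with pytest.raises(ValueError, match="horizon_years"):
            ModelSpec(
                strategies=(no_complication_strategy(),
                            no_complication_strategy(name="o")),
                states=three_states(), cycle_plan=build_cycle_plan(2),
                horizon_years=3.0, discount_rate_annual=0.03)
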