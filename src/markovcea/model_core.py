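"""Deterministic cohort engine for a three-state Markov cost-utility model.

The decision problem is a homogeneous surgical cohort entering the model at
hospital discharge.  Three mutually exclusive health states are tracked:

* ``stable``       -- community dwelling after uncomplicated recovery
                      (the single permanent state),
* ``superficial``  -- a temporary state for superficial surgical-site
                      infection treated without reoperation,
* ``reoperation``  -- a temporary state pooling deep infection, nonunion and
                      hardware failure, which share a return-to-theatre
                      pathway with similar cost and quality-of-life impact.

Time is discretised into four quarterly cycles over the first postoperative
year (when essentially all complications occur) followed by annual cycles to
the horizon.  Each complication pathway can be experienced at most once per
patient, and within a cycle a patient follows at most one pathway; a
temporary state lasts exactly one cycle before returning to stable.  Costs
and QALYs are discounted to model entry at a constant annual rate.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HealthState",
    "Strategy",
    "Cycle",
    "ModelOptions",
    "ModelSpec",
    "Trajectory",
    "StrategyOutcome",
    "build_cycle_plan",
    "discount_factor",
    "split_cumulative_probability",
    "cycle_event_probs",
    "resolve_event_costs",
    "run_cohort",
]

_ROW_SUM_TOL = 1e-12


def _check(cond: bool, message: str) -> None:
    if not cond:
        raise ValueError(message)


@dataclass(frozen=True)
class HealthState:
    """One Markov health state.

    ``utility_annual`` is the EQ-5D weight accrued per year of occupancy
    (dimensionless, in [0, 1]); ``entry_cost`` is charged once on entry.
    ``kind`` is ``"permanent"`` for the stable state and ``"temporary"``
    for one-cycle complication states.
    """

    id: str
    name: str
    kind: str
    utility_annual: float
    entry_cost: float = 0.0

    def __post_init__(self) -> None:
        _check(self.kind in ("permanent", "temporary"),
               f"state {self.id!r}: kind must be 'permanent' or 'temporary', got {self.kind!r}")
        _check(0.0 <= self.utility_annual <= 1.0,
               f"state {self.id!r}: utility_annual must lie in [0, 1], got {self.utility_annual}")
        _check(self.entry_cost >= 0.0,
               f"state {self.id!r}: entry_cost must be >= 0, got {self.entry_cost}")


@dataclass(frozen=True)
class Strategy:
    """One treatment arm: index cost plus cumulative complication risks.

    The four probabilities are cumulative incidences over the event window
    (not per-cycle rates).  Deep infection, nonunion and hardware failure
    share the reoperation pathway, so their sum must not exceed 1.

    ``reoperation_cost`` may be left ``None``, in which case the model
    option ``reoperation_cost_rule`` decides the charge (by default the
    strategy's own index cost, the usual revision-surgery assumption).
    ``utility_stable`` optionally overrides the stable-state utility for
    this arm only; by default both arms share the stable utility.
    """

    name: str
    index_cost: float
    p_superficial: float
    p_deep: float
    p_nonunion: float
    p_hardware: float
    superficial_cost: float
    reoperation_cost: float | None = None
    utility_stable: float | None = None

    def __post_init__(self) -> None:
        for fname in ("p_superficial", "p_deep", "p_nonunion", "p_hardware"):
            p = getattr(self, fname)
            _check(0.0 <= p <= 1.0,
                   f"strategy {self.name!r}: {fname} must lie in [0, 1], got {p}")
        _check(self.p_reoperation <= 1.0 + 1e-12,
               f"strategy {self.name!r}: p_deep + p_nonunion + p_hardware must be <= 1, "
               f"got {self.p_reoperation}")
        for fname in ("index_cost", "superficial_cost"):
            c = getattr(self, fname)
            _check(c >= 0.0, f"strategy {self.name!r}: {fname} must be >= 0, got {c}")
        if self.reoperation_cost is not None:
            _check(self.reoperation_cost >= 0.0,
                   f"strategy {self.name!r}: reoperation_cost must be >= 0, "
                   f"got {self.reoperation_cost}")
        if self.utility_stable is not None:
            _check(0.0 <= self.utility_stable <= 1.0,
                   f"strategy {self.name!r}: utility_stable must lie in [0, 1], "
                   f"got {self.utility_stable}")

    @property
    def p_reoperation(self) -> float:
        """Pooled cumulative probability of the reoperation pathway."""
        return self.p_deep + self.p_nonunion + self.p_hardware


@dataclass(frozen=True)
class Cycle:
    index: int
    start_year: float
    length_years: float

    def __post_init__(self) -> None:
        _check(self.length_years > 0.0,
               f"cycle {self.index}: length_years must be > 0, got {self.length_years}")
        _check(self.start_year >= 0.0,
               f"cycle {self.index}: start_year must be >= 0, got {self.start_year}")


@dataclass(frozen=True)
class ModelOptions:
    """Switchable modelling conventions.

    half_cycle:
        If True, QALYs discount at cycle midpoints instead of cycle starts
        (event costs always discount at the cycle start, when they occur).
    event_window:
        ``"first_year"`` restricts new complications to the quarterly
        cycles; ``"all"`` spreads the cumulative risks over every cycle.
    reoperation_cost_rule:
        ``"index_cost"`` charges the strategy's own index cost for a
        reoperation when no explicit ``reoperation_cost`` is given;
        ``"explicit"`` requires one.
    """

    half_cycle: bool = False
    event_window: str = "first_year"
    reoperation_cost_rule: str = "index_cost"

    def __post_init__(self) -> None:
        _check(self.event_window in ("first_year", "all"),
               f"options: event_window must be 'first_year' or 'all', got {self.event_window!r}")
        _check(self.reoperation_cost_rule in ("index_cost", "explicit"),
               "options: reoperation_cost_rule must be 'index_cost' or 'explicit', "
               f"got {self.reoperation_cost_rule!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Full description of one decision problem."""

    strategies: tuple[Strategy, ...]
    states: tuple[HealthState, ...]
    cycle_plan: tuple[Cycle, ...]
    horizon_years: float
    discount_rate_annual: float
    cohort_label: str = ""
    options: ModelOptions = field(default_factory=ModelOptions)

    def __post_init__(self) -> None:
        object.__setattr__(self, "strategies", tuple(self.strategies))
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "cycle_plan", tuple(self.cycle_plan))
        _check(len(self.strategies) >= 2,
               f"spec: at least two strategies required, got {len(self.strategies)}")
        names = [s.name for s in self.strategies]
        _check(len(set(names)) == len(names),
               f"spec: strategy names must be unique, got {names}")
        permanent = [s for s in self.states if s.kind == "permanent"]
        _check(len(permanent) == 1,
               f"spec: exactly one permanent state required, got {len(permanent)}")
        temp_ids = {s.id for s in self.states if s.kind == "temporary"}
        _check({"superficial", "reoperation"} <= temp_ids,
               "spec: temporary states with ids 'superficial' and 'reoperation' are required, "
               f"got {sorted(temp_ids)}")
        _check(0.0 <= self.discount_rate_annual < 1.0,
               "spec: discount_rate_annual must lie in [0, 1), "
               f"got {self.discount_rate_annual}")
        # contiguity + coverage of the horizon
        t = 0.0
        for c in self.cycle_plan:
            _check(abs(c.start_year - t) < 1e-9,
                   f"spec: cycle_plan not contiguous at cycle {c.index} "
                   f"(start {c.start_year}, expected {t})")
            t += c.length_years
        _check(abs(t - self.horizon_years) < 1e-9,
               f"spec: cycle lengths sum to {t}, horizon_years is {self.horizon_years}")

    # --- lookups -------------------------------------------------------
    def strategy(self, name: str) -> Strategy:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"no strategy named {name!r}; have {[s.name for s in self.strategies]}")

    def state(self, state_id: str) -> HealthState:
        for s in self.states:
            if s.id == state_id:
                return s
        raise KeyError(f"no state with id {state_id!r}; have {[s.id for s in self.states]}")

    @property
    def permanent_state(self) -> HealthState:
        return next(s for s in self.states if s.kind == "permanent")


@dataclass(frozen=True)
class Trajectory:
    """Per-cycle cohort bookkeeping for one strategy.

    ``occupancy`` has one row per cycle and one column per state id in
    ``state_ids`` (cohort fractions; rows sum to 1).  ``sup_incidence`` and
    ``reop_incidence`` are the fractions newly entering each pathway during
    each cycle.  ``cycle_cost`` / ``cycle_qaly`` are discounted accruals per
    cycle (the index cost is included in cycle 0's cost).
    """

    state_ids: tuple[str, ...]
    start_years: np.ndarray
    length_years: np.ndarray
    occupancy: np.ndarray
    sup_incidence: np.ndarray
    reop_incidence: np.ndarray
    cycle_cost: np.ndarray
    cycle_qaly: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        _check(occ.ndim == 2 and occ.shape[1] == len(self.state_ids),
               "trajectory: occupancy must be (n_cycles, n_states)")
        _check(bool((occ >= -_ROW_SUM_TOL).all()),
               "trajectory: occupancy entries must be >= 0")
        _check(bool(np.allclose(occ.sum(axis=1), 1.0, atol=_ROW_SUM_TOL, rtol=0.0)),
               "trajectory: occupancy rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        """One row per cycle: start, length, occupancy, discounted accruals."""
        data = {"start_year": self.start_years, "length_years": self.length_years}
        for j, sid in enumerate(self.state_ids):
            data[f"occ_{sid}"] = self.occupancy[:, j]
        data["sup_incidence"] = self.sup_incidence
        data["reop_incidence"] = self.reop_incidence
        data["discounted_cost"] = self.cycle_cost
        data["discounted_qaly"] = self.cycle_qaly
        return pd.DataFrame(data)


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted totals for one strategy, with the full trajectory."""

    strategy: str
    total_cost_discounted: float
    total_qaly_discounted: float
    trajectory: Trajectory
    horizon_years: float
    discount_rate_annual: float


# ---------------------------------------------------------------------------
# primitives


def build_cycle_plan(horizon_years: float) -> tuple[Cycle, ...]:
    """Quarterly cycles over the first year, annual cycles thereafter.

    The horizon must be a whole number of years >= 1 so the plan tiles
    exactly: four cycles of 0.25 y, then ``horizon - 1`` cycles of 1 y.
    """
    _check(horizon_years > 0, f"horizon_years must be > 0, got {horizon_years}")
    _check(abs(horizon_years - round(horizon_years)) < 1e-9 and horizon_years >= 1,
           f"horizon_years must be a whole number of years >= 1, got {horizon_years}")
    n_annual = int(round(horizon_years)) - 1
    cycles = [Cycle(k, 0.25 * k, 0.25) for k in range(4)]
    cycles += [Cycle(4 + y, 1.0 + y, 1.0) for y in range(n_annual)]
    return tuple(cycles)


def discount_factor(time_years: float, rate: float) -> float:
    """Present-value multiplier ``(1 + rate) ** -time_years``."""
    _check(time_years >= 0.0, f"time_years must be >= 0, got {time_years}")
    _check(rate >= 0.0, f"rate must be >= 0, got {rate}")
    return (1.0 + rate) ** (-time_years)


def split_cumulative_probability(p_total: float, n_cycles: int) -> float:
    """Constant-rate per-cycle probability reproducing a cumulative risk.

    Returns q such that ``1 - (1 - q) ** n_cycles == p_total``, i.e. the
    per-cycle probability that spreads a cumulative incidence evenly (in
    rate terms) over ``n_cycles`` at-risk cycles.
    """
    _check(0.0 <= p_total <= 1.0, f"p_total must lie in [0, 1], got {p_total}")
    _check(n_cycles >= 1, f"n_cycles must be >= 1, got {n_cycles}")
    if p_total >= 1.0:
        return 1.0
    return 1.0 - (1.0 - p_total) ** (1.0 / n_cycles)


def cycle_event_probs(spec: ModelSpec, strategy: Strategy) -> list[tuple[float, float]]:
    """Per-cycle (q_superficial, q_reoperation) branch probabilities.

    This is the single transition builder shared by the cohort solver and
    the patient-level simulator, so the two cannot drift apart.  Outside the
    event window both probabilities are zero.  The two pathways are
    exclusive multinomial branches within a cycle, so their per-cycle sum
    must not exceed 1.
    """
    if spec.options.event_window == "first_year":
        in_window = [c.start_year < 1.0 - 1e-12 for c in spec.cycle_plan]
    else:
        in_window = [True] * len(spec.cycle_plan)
    n_ev = sum(in_window)
    _check(n_ev >= 1, "spec: cycle plan has no event-window cycles")
    q_sup = split_cumulative_probability(strategy.p_superficial, n_ev)
    q_reop = split_cumulative_probability(min(strategy.p_reoperation, 1.0), n_ev)
    _check(q_sup + q_reop <= 1.0 + 1e-12,
           f"strategy {strategy.name!r}: per-cycle branch probabilities sum to "
           f"{q_sup + q_reop:.6f} > 1; probability mass leaving the stable state exceeds 1")
    return [(q_sup, q_reop) if w else (0.0, 0.0) for w in in_window]


def resolve_event_costs(spec: ModelSpec, strategy: Strategy) -> tuple[float, float]:
    """Charges on entry to the superficial and reoperation states."""
    sup_cost = strategy.superficial_cost + spec.state("superficial").entry_cost
    if strategy.reoperation_cost is not None:
        reop = strategy.reoperation_cost
    elif spec.options.reoperation_cost_rule == "index_cost":
        reop = strategy.index_cost
    else:
        raise ValueError(
            f"strategy {strategy.name!r}: reoperation_cost is required when "
            "options.reoperation_cost_rule = 'explicit'")
    return sup_cost, reop + spec.state("reoperation").entry_cost


# ---------------------------------------------------------------------------
# cohort solver

# Compound cohort states: (location, had_superficial, had_reoperation).
# Locations: stable, or currently occupying a temporary state.  Tracking the
# event flags enforces the at-most-once rule without double counting.
_S00, _S10, _S01, _S11, _SUP_R0, _SUP_R1, _REOP_S0, _REOP_S1 = range(8)


def run_cohort(spec: ModelSpec, strategy: Strategy) -> StrategyOutcome:
    """Evaluate one strategy by deterministic cohort simulation.

    The whole cohort starts stable and complication-naive; the index cost is
    charged at time zero.  At the start of each event-window cycle the
    at-risk fraction branches into the superficial or reoperation pathway
    (exclusive, at most once each); a pathway occupies its temporary state
    for exactly that cycle, charges its event cost at the cycle start, then
    returns to stable.  QALYs accrue as occupancy-weighted utility x cycle
    length x discount factor.
    """
    probs = cycle_event_probs(spec, strategy)
    sup_cost, reop_cost = resolve_event_costs(spec, strategy)

    stable_state = spec.permanent_state
    u_stable = (strategy.utility_stable if strategy.utility_stable is not None
                else stable_state.utility_annual)
    u_sup = spec.state("superficial").utility_annual
    u_reop = spec.state("reoperation").utility_annual

    rate = spec.discount_rate_annual
    n = len(spec.cycle_plan)
    f = np.zeros(8)
    f[_S00] = 1.0

    occupancy = np.zeros((n, 3))  # columns: stable, superficial, reoperation
    sup_inc = np.zeros(n)
    reop_inc = np.zeros(n)
    cycle_cost = np.zeros(n)
    cycle_qaly = np.zeros(n)

    for i, cyc in enumerate(spec.cycle_plan):
        # temporary states resolve back to stable at the start of the next cycle
        f[_S10] += f[_SUP_R0]
        f[_S11] += f[_SUP_R1] + f[_REOP_S1]
        f[_S01] += f[_REOP_S0]
        f[_SUP_R0] = f[_SUP_R1] = f[_REOP_S0] = f[_REOP_S1] = 0.0

        q_sup, q_reop = probs[i]
        new_sup_r0 = q_sup * f[_S00]
        new_reop_s0 = q_reop * f[_S00]
        new_reop_s1 = q_reop * f[_S10]
        new_sup_r1 = q_sup * f[_S01]
        f[_S00] -= new_sup_r0 + new_reop_s0
        f[_S10] -= new_reop_s1
        f[_S01] -= new_sup_r1
        f[_SUP_R0], f[_SUP_R1] = new_sup_r0, new_sup_r1
        f[_REOP_S0], f[_REOP_S1] = new_reop_s0, new_reop_s1

        stable_frac = f[_S00] + f[_S10] + f[_S01] + f[_S11]
        sup_frac = f[_SUP_R0] + f[_SUP_R1]
        reop_frac = f[_REOP_S0] + f[_REOP_S1]
        occupancy[i] = (stable_frac, sup_frac, reop_frac)
        sup_inc[i] = new_sup_r0 + new_sup_r1
        reop_inc[i] = new_reop_s0 + new_reop_s1

        df_cost = discount_factor(cyc.start_year, rate)
        t_qaly = cyc.start_year + (0.5 * cyc.length_years if spec.options.half_cycle else 0.0)
        df_qaly = discount_factor(t_qaly, rate)
        cycle_cost[i] = (sup_inc[i] * sup_cost + reop_inc[i] * reop_cost) * df_cost
        cycle_qaly[i] = (stable_frac * u_stable + sup_frac * u_sup
                         + reop_frac * u_reop) * cyc.length_years * df_qaly

    cycle_cost[0] += strategy.index_cost  # charged at model entry, factor 1

    traj = Trajectory(
        state_ids=(stable_state.id, "superficial", "reoperation"),
        start_years=np.array([c.start_year for c in spec.cycle_plan]),
        length_years=np.array([c.length_years for c in spec.cycle_plan]),
        occupancy=occupancy,
        sup_incidence=sup_inc,
        reop_incidence=reop_inc,
        cycle_cost=cycle_cost,
        cycle_qaly=cycle_qaly,
    )
    return StrategyOutcome(
        strategy=strategy.name,
        total_cost_discounted=float(cycle_cost.sum()),
        total_qaly_discounted=float(cycle_qaly.sum()),
        trajectory=traj,
        horizon_years=spec.horizon_years,
        discount_rate_annual=rate,
    )
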