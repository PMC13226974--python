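"""Patient-level Monte Carlo twin of the cohort solver.

Each simulated patient walks the same cycle plan drawing the same per-cycle
multinomial branches as the cohort model (through the shared
:func:`~markovcea.model_core.cycle_event_probs` builder), with the same
at-most-once rule per complication pathway and the same accrual and
discounting conventions.  The sample means therefore estimate exactly the
quantities the cohort solver computes, which makes this module an
independent validation oracle for the deterministic engine: agreement is a
check of the walk logic, not of shared probability algebra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import (
    ModelSpec,
    Strategy,
    cycle_event_probs,
    discount_factor,
    resolve_event_costs,
)

__all__ = ["PatientRecord", "MicrosimResult", "simulate_patients"]

# location codes in the per-cycle state matrix
LOC_STABLE, LOC_SUP, LOC_REOP = 0, 1, 2


@dataclass(frozen=True)
class PatientRecord:
    """One simulated patient's trajectory and accruals."""

    id: int
    states: tuple[int, ...]          # location code per cycle
    had_superficial: bool
    superficial_cycle: int | None
    had_reoperation: bool
    reoperation_cycle: int | None
    cost_undiscounted: float
    cost_discounted: float
    qaly_undiscounted: float
    qaly_discounted: float


@dataclass(frozen=True)
class MicrosimResult:
    """Vectorised per-patient output plus summary statistics.

    ``state_matrix`` is (n_patients, n_cycles) of location codes.  Standard
    errors are the sample sd over patients divided by sqrt(n).
    """

    strategy: str
    n_patients: int
    seed: int
    state_matrix: np.ndarray
    sup_cycle: np.ndarray    # event cycle index, -1 if never
    reop_cycle: np.ndarray
    cost: np.ndarray         # discounted, per patient
    qaly: np.ndarray
    cost_undiscounted: np.ndarray
    qaly_undiscounted: np.ndarray

    @property
    def mean_cost(self) -> float:
        return float(self.cost.mean())

    @property
    def mean_qaly(self) -> float:
        return float(self.qaly.mean())

    @property
    def se_cost(self) -> float:
        return float(self.cost.std(ddof=1) / np.sqrt(self.n_patients))

    @property
    def se_qaly(self) -> float:
        return float(self.qaly.std(ddof=1) / np.sqrt(self.n_patients))

    def occupancy(self) -> np.ndarray:
        """Empirical per-cycle fractions in (stable, superficial, reoperation)."""
        n, m = self.state_matrix.shape
        occ = np.empty((m, 3))
        for loc in (LOC_STABLE, LOC_SUP, LOC_REOP):
            occ[:, loc] = (self.state_matrix == loc).mean(axis=0)
        return occ

    def records(self) -> list[PatientRecord]:
        """Materialise per-patient records (for export or inspection)."""
        out = []
        for i in range(self.n_patients):
            sc, rc = int(self.sup_cycle[i]), int(self.reop_cycle[i])
            out.append(PatientRecord(
                id=i,
                states=tuple(int(x) for x in self.state_matrix[i]),
                had_superficial=sc >= 0,
                superficial_cycle=sc if sc >= 0 else None,
                had_reoperation=rc >= 0,
                reoperation_cycle=rc if rc >= 0 else None,
                cost_undiscounted=float(self.cost_undiscounted[i]),
                cost_discounted=float(self.cost[i]),
                qaly_undiscounted=float(self.qaly_undiscounted[i]),
                qaly_discounted=float(self.qaly[i]),
            ))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patient": np.arange(self.n_patients),
            "superficial_cycle": self.sup_cycle,
            "reoperation_cycle": self.reop_cycle,
            "cost_discounted": self.cost,
            "qaly_discounted": self.qaly,
            "cost_undiscounted": self.cost_undiscounted,
            "qaly_undiscounted": self.qaly_undiscounted,
        })


def simulate_patients(spec: ModelSpec, strategy: Strategy, n: int,
                      seed: int) -> MicrosimResult:
    """Simulate ``n`` independent patients under one strategy.

    Reproducible from ``seed``.  The walk mirrors the cohort solver cycle
    by cycle: at the start of each event-window cycle a stable patient
    draws one uniform variate; pathway-naive patients branch superficial
    with probability q_sup and reoperation with probability q_reop
    (exclusive), patients who already used one pathway face only the
    other.  A temporary state lasts one cycle.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    probs = cycle_event_probs(spec, strategy)
    sup_cost, reop_cost = resolve_event_costs(spec, strategy)
    u_stable = (strategy.utility_stable if strategy.utility_stable is not None
                else spec.permanent_state.utility_annual)
    utilities = np.array([u_stable,
                          spec.state("superficial").utility_annual,
                          spec.state("reoperation").utility_annual])
    rate = spec.discount_rate_annual
    m = len(spec.cycle_plan)

    loc = np.zeros(n, dtype=np.int8)
    had_sup = np.zeros(n, dtype=bool)
    had_reop = np.zeros(n, dtype=bool)
    sup_cycle = np.full(n, -1, dtype=np.int32)
    reop_cycle = np.full(n, -1, dtype=np.int32)
    state_matrix = np.empty((n, m), dtype=np.int8)
    cost = np.full(n, float(strategy.index_cost))
    cost_undisc = np.full(n, float(strategy.index_cost))
    qaly = np.zeros(n)
    qaly_undisc = np.zeros(n)

    for i, cyc in enumerate(spec.cycle_plan):
        # resolve last cycle's temporary states
        had_sup |= loc == LOC_SUP
        had_reop |= loc == LOC_REOP
        loc[:] = LOC_STABLE

        q_sup, q_reop = probs[i]
        if q_sup > 0.0 or q_reop > 0.0:
            u = rng.random(n)
            naive = ~had_sup & ~had_reop
            to_sup = (naive & (u < q_sup)) | (had_reop & ~had_sup & (u < q_sup))
            to_reop = ((naive & (u >= q_sup) & (u < q_sup + q_reop))
                       | (had_sup & ~had_reop & (u < q_reop)))
            loc[to_sup] = LOC_SUP
            loc[to_reop] = LOC_REOP
            sup_cycle[to_sup] = i
            reop_cycle[to_reop] = i

            df_cost = discount_factor(cyc.start_year, rate)
            event_cost = np.where(to_sup, sup_cost, 0.0) + np.where(to_reop, reop_cost, 0.0)
            cost += event_cost * df_cost
            cost_undisc += event_cost

        state_matrix[:, i] = loc
        t_qaly = cyc.start_year + (0.5 * cyc.length_years if spec.options.half_cycle else 0.0)
        df_qaly = discount_factor(t_qaly, rate)
        u_cycle = utilities[loc] * cyc.length_years
        qaly += u_cycle * df_qaly
        qaly_undisc += u_cycle

    return MicrosimResult(
        strategy=strategy.name, n_patients=n, seed=seed,
        state_matrix=state_matrix, sup_cycle=sup_cycle, reop_cycle=reop_cycle,
        cost=cost, qaly=qaly,
        cost_undiscounted=cost_undisc, qaly_undiscounted=qaly_undisc,
    )
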