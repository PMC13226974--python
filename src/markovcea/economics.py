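"""Incremental cost-effectiveness: ICER, dominance, NMB and CEAC.

All comparisons are comparator-minus-reference.  A comparator that costs
more and yields fewer QALYs is *dominated*; cheaper and more effective is
*dominant*; otherwise the trade-off is summarised by the incremental
cost-effectiveness ratio (ICER, USD per QALY).  The net monetary benefit
NMB(lambda) = lambda * QALY - cost linearises the ICER decision rule at a
willingness-to-pay threshold lambda, and the cost-effectiveness
acceptability curve (CEAC) reports, per threshold, the fraction of
probabilistic draws in which the comparator's NMB exceeds the reference's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import StrategyOutcome

__all__ = ["ComparisonResult", "CeacCurve", "compare", "nmb", "ceac"]

#: Deltas below this magnitude are treated as zero for classification.
EQUIVALENCE_TOL = 1e-9


@dataclass(frozen=True)
class ComparisonResult:
    """Comparator-minus-reference incremental results."""

    reference: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: float | None
    label: str      # dominant | dominated | ICER | equivalent
    quadrant: str   # NE/NW/SE/SW on the (delta QALY, delta cost) plane


@dataclass(frozen=True)
class CeacCurve:
    """Probability the comparator is cost-effective per WTP threshold."""

    reference: str
    comparator: str
    wtp_grid: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        wtp = np.asarray(self.wtp_grid, dtype=float)
        prob = np.asarray(self.probability, dtype=float)
        if wtp.size == 0:
            raise ValueError("ceac: wtp_grid must be nonempty")
        if not (np.diff(wtp) > 0).all():
            raise ValueError("ceac: wtp_grid must be strictly increasing")
        if prob.shape != wtp.shape or ((prob < 0) | (prob > 1)).any():
            raise ValueError("ceac: probabilities must match the grid and lie in [0, 1]")


def _quadrant(delta_qaly: float, delta_cost: float) -> str:
    ns = "N" if delta_cost >= 0 else "S"
    ew = "E" if delta_qaly >= 0 else "W"
    return ns + ew


def compare(ref: StrategyOutcome, comp: StrategyOutcome) -> ComparisonResult:
    """Classify the comparator against the reference.

    Both outcomes must come from the same model configuration (equal
    horizon and discount rate).  Deltas within ``EQUIVALENCE_TOL`` of zero
    are treated as exact ties: both zero is *equivalent*; a tie in one
    dimension only leaves the ICER undefined and the result labelled by the
    remaining dimension's sign (reported as ``ICER`` with ``icer=None``).
    """
    if (abs(ref.horizon_years - comp.horizon_years) > 1e-9
            or abs(ref.discount_rate_annual - comp.discount_rate_annual) > 1e-9):
        raise ValueError(
            "compare: outcomes come from different model configurations "
            f"(horizons {ref.horizon_years} vs {comp.horizon_years}, "
            f"rates {ref.discount_rate_annual} vs {comp.discount_rate_annual})")

    dc = comp.total_cost_discounted - ref.total_cost_discounted
    dq = comp.total_qaly_discounted - ref.total_qaly_discounted
    tol = EQUIVALENCE_TOL
    icer: float | None = None

    if abs(dc) <= tol and abs(dq) <= tol:
        label = "equivalent"
    elif dc > tol and dq < -tol:
        label = "dominated"
    elif dc < -tol and dq > tol:
        label = "dominant"
    else:
        label = "ICER"
        if abs(dq) > tol:
            icer = dc / dq
    return ComparisonResult(
        reference=ref.strategy, comparator=comp.strategy,
        delta_cost=dc, delta_qaly=dq, icer=icer, label=label,
        quadrant=_quadrant(dq, dc),
    )


def nmb(qaly: float, cost: float, wtp: float) -> float:
    """Net monetary benefit at willingness-to-pay ``wtp`` (USD/QALY)."""
    if wtp < 0:
        raise ValueError(f"nmb: wtp must be >= 0, got {wtp}")
    return wtp * qaly - cost


def ceac(ref_cost: np.ndarray, ref_qaly: np.ndarray,
         comp_cost: np.ndarray, comp_qaly: np.ndarray,
         wtp_grid: np.ndarray,
         reference: str = "reference", comparator: str = "comparator") -> CeacCurve:
    """Acceptability curve from paired probabilistic draws.

    At each threshold the probability is the fraction of draws with
    strictly greater comparator NMB; exact NMB ties count as not
    cost-effective (conservative, and measure-zero under continuous
    parameter sampling).
    """
    rc, rq = np.asarray(ref_cost, float), np.asarray(ref_qaly, float)
    cc, cq = np.asarray(comp_cost, float), np.asarray(comp_qaly, float)
    if rc.size == 0:
        raise ValueError("ceac: at least one draw is required")
    if not (rc.shape == rq.shape == cc.shape == cq.shape):
        raise ValueError("ceac: draw arrays must share one shape (paired draws)")
    wtp = np.asarray(wtp_grid, dtype=float)
    dq = cq - rq
    dc = cc - rc
    prob = np.array([(w * dq - dc > 0).mean() for w in wtp])
    return CeacCurve(reference=reference, comparator=comparator,
                     wtp_grid=wtp, probability=prob)
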