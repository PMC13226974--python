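"""Probabilistic sensitivity analysis, tornado analysis and scenarios.

PSA resamples every non-fixed parameter from its fitted distribution
(independently; no correlation structure is imposed), rebuilds both
strategies and reruns the cohort model per iteration.  Credible intervals
are 2.5th-97.5th percentiles of the draws.  The tornado analysis is
deterministic one-way variation of each parameter to its range bounds; the
scenario registry applies declarative edits (set-value, multiply, horizon
change) to the base specification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .economics import nmb
from .evidence import ParameterSet, apply_edits
from .model_core import ModelSpec, build_cycle_plan, run_cohort

__all__ = [
    "PsaDraws",
    "PsaSummary",
    "run_psa",
    "TornadoEntry",
    "tornado",
    "ScenarioDef",
    "SCENARIOS",
    "apply_scenario",
]


@dataclass(frozen=True)
class PsaDraws:
    """Raw Monte Carlo draws: one row per iteration, one column per strategy."""

    strategies: tuple[str, ...]
    cost: np.ndarray
    qaly: np.ndarray
    seed: int
    n_rejected: int

    def column(self, strategy: str) -> int:
        return self.strategies.index(strategy)

    def to_frame(self) -> pd.DataFrame:
        """Long format: (iteration, strategy, cost, qaly)."""
        n, k = self.cost.shape
        return pd.DataFrame({
            "iteration": np.repeat(np.arange(n), k),
            "strategy": list(self.strategies) * n,
            "cost": self.cost.ravel(),
            "qaly": self.qaly.ravel(),
        })


@dataclass(frozen=True)
class PsaSummary:
    """Means and 2.5th-97.5th percentile credible intervals of PSA draws.

    ``per_strategy`` maps strategy name to a dict with keys ``mean_cost``,
    ``mean_qaly``, ``cost_ci``, ``qaly_ci``; the incremental entries are
    comparator-minus-reference (last vs first strategy).
    """

    n_iterations: int
    seed: int
    n_rejected: int
    per_strategy: dict[str, dict[str, object]]
    delta_cost_mean: float
    delta_qaly_mean: float
    delta_cost_ci: tuple[float, float]
    delta_qaly_ci: tuple[float, float]


def _ci(x: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(x, [2.5, 97.5])
    return float(lo), float(hi)


def summarize_psa(draws: PsaDraws) -> PsaSummary:
    per = {}
    for j, name in enumerate(draws.strategies):
        per[name] = {
            "mean_cost": float(draws.cost[:, j].mean()),
            "mean_qaly": float(draws.qaly[:, j].mean()),
            "cost_ci": _ci(draws.cost[:, j]),
            "qaly_ci": _ci(draws.qaly[:, j]),
        }
    dc = draws.cost[:, -1] - draws.cost[:, 0]
    dq = draws.qaly[:, -1] - draws.qaly[:, 0]
    return PsaSummary(
        n_iterations=draws.cost.shape[0], seed=draws.seed,
        n_rejected=draws.n_rejected, per_strategy=per,
        delta_cost_mean=float(dc.mean()), delta_qaly_mean=float(dq.mean()),
        delta_cost_ci=_ci(dc), delta_qaly_ci=_ci(dq),
    )


_MAX_RESAMPLE = 1000


def run_psa(spec: ModelSpec, params: ParameterSet, n: int,
            seed: int) -> tuple[PsaDraws, PsaSummary]:
    """Monte Carlo resampling of the whole parameter set.

    Per iteration every non-fixed parameter is drawn from its fitted
    distribution, the spec is rebuilt and validated, and each strategy is
    evaluated by the cohort solver.  A draw producing an invalid spec
    (e.g. reoperation-pathway probabilities summing above 1) is rejected
    and redrawn; the rejection count is reported.  Reproducible from
    ``seed``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    names = [s.name for s in spec.strategies]
    cost = np.empty((n, len(names)))
    qaly = np.empty((n, len(names)))
    n_rejected = 0
    for i in range(n):
        for attempt in range(_MAX_RESAMPLE):
            values = params.sample(rng)
            try:
                drawn_spec = params.apply(spec, values)
                outcomes = [run_cohort(drawn_spec, s) for s in drawn_spec.strategies]
            except ValueError:
                n_rejected += 1
                continue
            break
        else:
            raise RuntimeError(
                f"PSA iteration {i}: no valid parameter draw in {_MAX_RESAMPLE} attempts")
        cost[i] = [o.total_cost_discounted for o in outcomes]
        qaly[i] = [o.total_qaly_discounted for o in outcomes]
    draws = PsaDraws(strategies=tuple(names), cost=cost, qaly=qaly,
                     seed=seed, n_rejected=n_rejected)
    return draws, summarize_psa(draws)


# ---------------------------------------------------------------------------
# one-way tornado analysis


@dataclass(frozen=True)
class TornadoEntry:
    """Output swing from one parameter's low/high excursions."""

    parameter: str
    output_at_low: float
    output_at_high: float
    base_output: float

    @property
    def bar_width(self) -> float:
        return abs(self.output_at_high - self.output_at_low)


_TORNADO_OUTPUTS = ("inc_nmb", "inc_cost", "inc_qaly")


def _incremental_output(spec: ModelSpec, reference: str, comparator: str,
                        output: str, wtp: float) -> float:
    ref = run_cohort(spec, spec.strategy(reference))
    comp = run_cohort(spec, spec.strategy(comparator))
    dc = comp.total_cost_discounted - ref.total_cost_discounted
    dq = comp.total_qaly_discounted - ref.total_qaly_discounted
    if output == "inc_cost":
        return dc
    if output == "inc_qaly":
        return dq
    return nmb(dq, dc, wtp)  # incremental NMB of comparator vs reference


def tornado(spec: ModelSpec, params: ParameterSet,
            output: str = "inc_nmb", wtp: float = 100_000.0,
            reference: str | None = None,
            comparator: str | None = None) -> list[TornadoEntry]:
    """Deterministic one-way analysis over every bounded parameter.

    Each parameter is set to its low and high bound in turn with all
    others at base, the cohort model is rerun for both strategies, and the
    chosen incremental output is recorded (default: incremental net
    monetary benefit of the comparator at the headline willingness-to-pay).
    Entries are sorted by descending swing.  Zero-width parameters
    contribute zero-width bars.
    """
    if output not in _TORNADO_OUTPUTS:
        raise ValueError(f"output must be one of {_TORNADO_OUTPUTS}, got {output!r}")
    reference = reference or spec.strategies[0].name
    comparator = comparator or spec.strategies[-1].name
    base_vals = params.base_values()
    base_out = _incremental_output(params.apply(spec, base_vals),
                                   reference, comparator, output, wtp)
    entries = []
    for name, p in params.items():
        outs = []
        for bound in (p.low, p.high):
            vals = dict(base_vals)
            vals[name] = bound
            outs.append(_incremental_output(params.apply(spec, vals),
                                            reference, comparator, output, wtp))
        entries.append(TornadoEntry(name, outs[0], outs[1], base_out))
    entries.sort(key=lambda e: e.bar_width, reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([
        {"parameter": e.parameter, "output_at_low": e.output_at_low,
         "output_at_high": e.output_at_high, "base_output": e.base_output,
         "bar_width": e.bar_width}
        for e in entries
    ])


# ---------------------------------------------------------------------------
# scenario analyses


@dataclass(frozen=True)
class ScenarioDef:
    """A named, declarative transform of the base specification.

    ``edits`` is an ordered tuple of operations:
    ``("set", path, value)``, ``("mul", path, factor)`` or
    ``("horizon", years, None)``.  Paths accept the ``strategies.*``
    wildcard.  After all edits, reoperation-pathway probabilities are
    rescaled onto the simplex if an edit pushed their sum above 1.
    """

    name: str
    edits: tuple[tuple, ...]

    def apply(self, spec: ModelSpec) -> ModelSpec:
        for op, path, value in self.edits:
            if op == "set":
                spec = apply_edits(spec, [(path, value)])
            elif op == "mul":
                spec = _multiply(spec, path, value)
            elif op == "horizon":
                spec = replace(spec, horizon_years=float(path),
                               cycle_plan=build_cycle_plan(float(path)))
            else:
                raise ValueError(f"scenario {self.name!r}: unknown edit op {op!r}")
        return spec


def _multiply(spec: ModelSpec, path: str, factor: float) -> ModelSpec:
    parts = path.split(".")
    if len(parts) != 3 or parts[0] != "strategies":
        raise ValueError(f"multiply edits support strategy fields only, got {path!r}")
    names = ([s.name for s in spec.strategies] if parts[1] == "*" else [parts[1]])
    pooled = ("p_deep", "p_nonunion", "p_hardware")
    for name in names:
        s = spec.strategy(name)
        new_val = getattr(s, parts[2]) * factor
        if parts[2].startswith("p_"):
            new_val = min(new_val, 1.0)
        if parts[2] in pooled:
            # rescale the pooled pathway onto the simplex before the edited
            # strategy is rebuilt, so validation never sees a sum above 1
            vals = {f: getattr(s, f) for f in pooled}
            vals[parts[2]] = new_val
            total = sum(vals.values())
            if total > 1.0:
                vals = {f: v / total for f, v in vals.items()}
            new_strategy = replace(s, **vals)  # atomic: one validation pass
            spec = replace(spec, strategies=tuple(
                new_strategy if x.name == name else x for x in spec.strategies))
        else:
            spec = apply_edits(spec, [(f"strategies.{name}.{parts[2]}", new_val)])
    return spec


#: Registered scenario analyses for the packaged two-arm ankle model.
SCENARIOS: dict[str, ScenarioDef] = {
    "base": ScenarioDef("base", ()),
    "equal_deep_infection": ScenarioDef("equal_deep_infection", (
        ("set", "strategies.*.p_deep", 0.025),
    )),
    "horizon_3y": ScenarioDef("horizon_3y", (
        ("horizon", 3, None),
    )),
    "reop_plus50": ScenarioDef("reop_plus50", (
        ("mul", "strategies.*.p_deep", 1.5),
        ("mul", "strategies.*.p_nonunion", 1.5),
        ("mul", "strategies.*.p_hardware", 1.5),
    )),
}


def apply_scenario(spec: ModelSpec, scenario: str | ScenarioDef) -> ModelSpec:
    """Apply a registered (or ad-hoc) scenario; result is fully validated."""
    if isinstance(scenario, str):
        try:
            scenario = SCENARIOS[scenario]
        except KeyError:
            raise KeyError(
                f"unknown scenario {scenario!r}; registered: {sorted(SCENARIOS)}"
            ) from None
    return scenario.apply(spec)
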