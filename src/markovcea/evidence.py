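"""Parameter evidence: base values, sensitivity ranges and sampling fits.

A :class:`ParameterSet` names every uncertain input of a
:class:`~markovcea.model_core.ModelSpec` together with its point estimate,
sensitivity range and distribution family (beta for probabilities and
utilities, gamma for costs, log-normal for ratio-type quantities, or fixed).
Distributions are fitted by the method of moments with the range read as a
central 95% interval, i.e. sd = (high - low) / 3.92; the fitted mean always
equals the base value.

The packaged evidence set (:func:`ankle_fragility_model`) encodes a
two-strategy fragility-ankle-fracture decision problem in adults >= 75:
open reduction and internal fixation (ORIF) versus primary
tibiotalocalcaneal (TTC) nailing, with pooled meta-analytic complication
rates (McDonald 2025), CMS 2024 reimbursement costs and published EQ-5D
utilities (van Gerven et al).
"""

from __future__ import annotations

import dataclasses
import io
import warnings
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model_core import (
    Cycle,
    HealthState,
    ModelOptions,
    ModelSpec,
    Strategy,
    build_cycle_plan,
)

__all__ = [
    "ParameterDef",
    "DistributionFit",
    "ParameterSet",
    "fit_beta",
    "fit_gamma",
    "fit_lognormal",
    "fit_parameter",
    "apply_edits",
    "generate_random_model",
    "ankle_fragility_model",
    "PUBLISHED_REFERENCE",
]

#: Central-interval divisor turning a (low, high) range into a standard
#: deviation: the width of a 95% normal interval is 2 * 1.96 sd.
RANGE_TO_SD = 3.92

_FAMILIES = ("beta", "gamma", "lognormal", "fixed")


@dataclass(frozen=True)
class ParameterDef:
    """One named model input with its uncertainty description.

    ``targets`` are dotted paths into a :class:`ModelSpec` that this
    parameter drives, e.g. ``"strategies.ORIF.p_superficial"`` or
    ``"states.stable.utility_annual"``; a single evidence value may feed
    several spec fields (a shared treatment cost, a utility used by two
    temporary states).
    """

    name: str
    base: float
    low: float
    high: float
    family: str
    targets: tuple[str, ...]
    units: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        if self.family not in _FAMILIES:
            raise ValueError(
                f"parameter {self.name!r}: family must be one of {_FAMILIES}, "
                f"got {self.family!r}")
        if not (self.low <= self.base <= self.high):
            raise ValueError(
                f"parameter {self.name!r}: require low <= base <= high, "
                f"got ({self.low}, {self.base}, {self.high})")
        if self.family == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            raise ValueError(
                f"parameter {self.name!r}: beta family requires the range within [0, 1], "
                f"got ({self.low}, {self.high})")
        if self.family in ("gamma", "lognormal") and self.low < 0.0:
            raise ValueError(
                f"parameter {self.name!r}: {self.family} family requires low >= 0, "
                f"got {self.low}")
        if not self.targets:
            raise ValueError(f"parameter {self.name!r}: at least one target path required")


@dataclass(frozen=True)
class DistributionFit:
    """A fitted sampling distribution.

    ``a``/``b`` are the family's shape parameters: (alpha, beta) for beta,
    (shape, scale) for gamma, (mu, sigma) of log-values for lognormal, and
    (value, 0) for a point mass.
    """

    family: str
    a: float
    b: float
    fitted_mean: float
    fitted_sd: float

    def rvs(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        if self.family == "fixed" or self.fitted_sd == 0.0:
            return np.full(size, self.fitted_mean) if size is not None else self.fitted_mean
        if self.family == "beta":
            return rng.beta(self.a, self.b, size=size)
        if self.family == "gamma":
            return rng.gamma(self.a, self.b, size=size)
        if self.family == "lognormal":
            return rng.lognormal(self.a, self.b, size=size)
        raise AssertionError(self.family)


def _range_sd(low: float, high: float) -> float:
    if high < low:
        raise ValueError(f"range bounds out of order: ({low}, {high})")
    return (high - low) / RANGE_TO_SD


def fit_beta(mean: float, low: float, high: float) -> DistributionFit:
    """Method-of-moments beta fit from a mean and a 95%-interval range.

    If the range implies a variance at or beyond the beta maximum
    ``mean * (1 - mean)``, the fit falls back to 99% of that maximum and
    warns: the resulting distribution is extremely dispersed but proper.
    A zero-width range degenerates to a point mass.
    """
    if not (0.0 < mean < 1.0):
        raise ValueError(f"beta fit: mean must lie strictly in (0, 1), got {mean}")
    sd = _range_sd(low, high)
    if sd == 0.0:
        return DistributionFit("fixed", mean, 0.0, mean, 0.0)
    var = sd * sd
    vmax = mean * (1.0 - mean)
    if var >= vmax:
        warnings.warn(
            f"beta fit: range-implied sd {sd:.4g} infeasible for mean {mean:.4g}; "
            "falling back to 99% of the maximum variance", stacklevel=2)
        var = 0.99 * vmax
    k = mean * (1.0 - mean) / var - 1.0
    return DistributionFit("beta", mean * k, (1.0 - mean) * k, mean, float(np.sqrt(var)))


def fit_gamma(mean: float, low: float, high: float) -> DistributionFit:
    """Method-of-moments gamma fit (shape-scale); samples strictly positive."""
    if mean <= 0.0:
        raise ValueError(f"gamma fit: mean must be > 0, got {mean}")
    sd = _range_sd(low, high)
    if sd == 0.0:
        return DistributionFit("fixed", mean, 0.0, mean, 0.0)
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return DistributionFit("gamma", shape, scale, mean, sd)


def fit_lognormal(mean: float, low: float, high: float) -> DistributionFit:
    """Log-normal fit matching the arithmetic mean and range-implied sd.

    Provided for ratio-type parameters (e.g. hazard ratios); the packaged
    ankle model contains none, so this family is exercised only by tests.
    """
    if mean <= 0.0:
        raise ValueError(f"lognormal fit: mean must be > 0, got {mean}")
    sd = _range_sd(low, high)
    if sd == 0.0:
        return DistributionFit("fixed", mean, 0.0, mean, 0.0)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return DistributionFit("lognormal", float(mu), float(np.sqrt(sigma2)), mean, sd)


def fit_parameter(p: ParameterDef) -> DistributionFit:
    if p.family == "fixed":
        return DistributionFit("fixed", p.base, 0.0, p.base, 0.0)
    if p.family == "beta":
        return fit_beta(p.base, p.low, p.high)
    if p.family == "gamma":
        return fit_gamma(p.base, p.low, p.high)
    return fit_lognormal(p.base, p.low, p.high)


# ---------------------------------------------------------------------------
# applying parameter values to a ModelSpec


def _set_path(spec: ModelSpec, path: str, value: float) -> ModelSpec:
    parts = path.split(".")
    if parts[0] == "strategies" and len(parts) == 3:
        _, name, fname = parts
        target = spec.strategy(name)  # raises KeyError with names listed
        if not hasattr(target, fname):
            raise ValueError(f"unknown strategy field {fname!r} in target {path!r}")
        new = replace(target, **{fname: value})
        strategies = tuple(new if s.name == name else s for s in spec.strategies)
        return replace(spec, strategies=strategies)
    if parts[0] == "states" and len(parts) == 3:
        _, sid, fname = parts
        target = spec.state(sid)
        if not hasattr(target, fname):
            raise ValueError(f"unknown state field {fname!r} in target {path!r}")
        new = replace(target, **{fname: value})
        states = tuple(new if s.id == sid else s for s in spec.states)
        return replace(spec, states=states)
    if len(parts) == 1 and parts[0] in ("discount_rate_annual",):
        return replace(spec, **{parts[0]: value})
    if len(parts) == 1 and parts[0] == "horizon_years":
        return replace(spec, horizon_years=value, cycle_plan=build_cycle_plan(value))
    raise ValueError(f"unrecognised target path {path!r}")


def apply_edits(spec: ModelSpec, edits: Iterable[tuple[str, float]]) -> ModelSpec:
    """Return a new validated spec with ``(path, value)`` edits applied.

    Paths support a ``*`` wildcard in the strategy position,
    e.g. ``"strategies.*.p_deep"`` edits every arm.
    """
    for path, value in edits:
        parts = path.split(".")
        if len(parts) == 3 and parts[0] == "strategies" and parts[1] == "*":
            for s in spec.strategies:
                spec = _set_path(spec, f"strategies.{s.name}.{parts[2]}", value)
        else:
            spec = _set_path(spec, path, value)
    return spec


class ParameterSet(Mapping):
    """An ordered, named collection of :class:`ParameterDef`.

    Behaves as a mapping from parameter name to definition, fits and caches
    sampling distributions, draws correlated-free Monte Carlo samples, and
    rebuilds model specs from sampled values.
    """

    def __init__(self, defs: Iterable[ParameterDef]):
        self._defs: dict[str, ParameterDef] = {}
        for d in defs:
            if d.name in self._defs:
                raise ValueError(f"duplicate parameter name {d.name!r}")
            self._defs[d.name] = d
        self._fits: dict[str, DistributionFit] = {}

    # Mapping protocol
    def __getitem__(self, name: str) -> ParameterDef:
        return self._defs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._defs)

    def __len__(self) -> int:
        return len(self._defs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return list(self._defs.values()) == list(other._defs.values())

    def fit(self, name: str) -> DistributionFit:
        if name not in self._fits:
            self._fits[name] = fit_parameter(self._defs[name])
        return self._fits[name]

    def base_values(self) -> dict[str, float]:
        return {n: d.base for n, d in self._defs.items()}

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        """One joint draw; fixed parameters stay at their base value."""
        return {n: float(self.fit(n).rvs(rng)) for n in self._defs}

    def apply(self, spec: ModelSpec, values: Mapping[str, float]) -> ModelSpec:
        """Rebuild a spec with every parameter set to ``values[name]``."""
        edits = []
        for name, value in values.items():
            for path in self._defs[name].targets:
                edits.append((path, value))
        return apply_edits(spec, edits)

    # --- serialization -------------------------------------------------
    _COLUMNS = ("name", "base", "low", "high", "family", "units", "source", "targets")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": d.name, "base": d.base, "low": d.low, "high": d.high,
                "family": d.family, "units": d.units, "source": d.source,
                "targets": ";".join(d.targets),
            }
            for d in self._defs.values()
        ]
        return pd.DataFrame(rows, columns=list(self._COLUMNS))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ParameterSet":
        defs = []
        for row in frame.itertuples(index=False):
            defs.append(ParameterDef(
                name=row.name, base=float(row.base), low=float(row.low),
                high=float(row.high), family=row.family,
                targets=tuple(str(row.targets).split(";")),
                units="" if pd.isna(row.units) else str(row.units),
                source="" if pd.isna(row.source) else str(row.source),
            ))
        return cls(defs)

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "ParameterSet":
        return cls.from_frame(pd.read_csv(path_or_buf, keep_default_na=False))


# ---------------------------------------------------------------------------
# packaged evidence: fragility ankle fracture, ORIF vs TTC nailing


def _ankle_states() -> tuple[HealthState, ...]:
    return (
        HealthState("stable", "Stable community dwelling", "permanent", 0.90),
        HealthState("superficial", "Superficial infection", "temporary", 0.78),
        HealthState("reoperation", "Reoperation", "temporary", 0.78),
    )


def ankle_fragility_model() -> tuple[ModelSpec, ParameterSet]:
    """The packaged base case: ORIF vs primary TTC nailing, age >= 75.

    Cumulative complication probabilities are pooled meta-analytic
    estimates; costs are 2024 USD from CMS reimbursement (DRG 509/511 for
    the index admissions, CPT 10060/10061 for superficial-infection care);
    utilities are EQ-5D weights (0.90 stable at age 75, 0.78 for a
    temporary complication quarter).  Four-year horizon, 3% annual
    discounting.  Sensitivity ranges are approximately +/-20% of base.

    The reoperation event cost is not published for this problem; the
    default model option charges the strategy's own index cost (flagged in
    reports), and ``reoperation_cost`` may be set explicitly instead.
    """
    orif = Strategy(
        name="ORIF", index_cost=25_000.0,
        p_superficial=0.102, p_deep=0.025, p_nonunion=0.117, p_hardware=0.066,
        superficial_cost=2_500.0,
    )
    ttc = Strategy(
        name="TTC", index_cost=28_000.0,
        p_superficial=0.021, p_deep=0.0343, p_nonunion=0.053, p_hardware=0.088,
        superficial_cost=2_500.0,
    )
    spec = ModelSpec(
        strategies=(orif, ttc),
        states=_ankle_states(),
        cycle_plan=build_cycle_plan(4),
        horizon_years=4.0,
        discount_rate_annual=0.03,
        cohort_label="fragility ankle fracture, age >=75",
    )

    src_meta = "McDonald 2025 meta-analysis"
    src_cms = "CMS 2024 reimbursement"
    src_util = "van Gerven et al"
    defs = [
        ParameterDef("p_superficial_ORIF", 0.102, 0.082, 0.122, "beta",
                     ("strategies.ORIF.p_superficial",), "probability", src_meta),
        ParameterDef("p_superficial_TTC", 0.021, 0.017, 0.025, "beta",
                     ("strategies.TTC.p_superficial",), "probability", src_meta),
        ParameterDef("p_deep_ORIF", 0.025, 0.020, 0.030, "beta",
                     ("strategies.ORIF.p_deep",), "probability", src_meta),
        ParameterDef("p_deep_TTC", 0.0343, 0.027, 0.041, "beta",
                     ("strategies.TTC.p_deep",), "probability", src_meta),
        ParameterDef("p_nonunion_ORIF", 0.117, 0.084, 0.150, "beta",
                     ("strategies.ORIF.p_nonunion",), "probability", src_meta),
        ParameterDef("p_nonunion_TTC", 0.053, 0.038, 0.068, "beta",
                     ("strategies.TTC.p_nonunion",), "probability", src_meta),
        ParameterDef("p_hardware_ORIF", 0.066, 0.048, 0.084, "beta",
                     ("strategies.ORIF.p_hardware",), "probability", src_meta),
        ParameterDef("p_hardware_TTC", 0.088, 0.068, 0.108, "beta",
                     ("strategies.TTC.p_hardware",), "probability", src_meta),
        ParameterDef("index_cost_ORIF", 25_000.0, 20_000.0, 30_000.0, "gamma",
                     ("strategies.ORIF.index_cost",), "USD 2024", src_cms),
        ParameterDef("index_cost_TTC", 28_000.0, 22_400.0, 33_600.0, "gamma",
                     ("strategies.TTC.index_cost",), "USD 2024",
                     src_cms + " + implant premium"),
        ParameterDef("superficial_cost", 2_500.0, 2_000.0, 3_000.0, "gamma",
                     ("strategies.ORIF.superficial_cost",
                      "strategies.TTC.superficial_cost"), "USD 2024", src_cms),
        ParameterDef("utility_stable", 0.90, 0.80, 1.00, "fixed",
                     ("states.stable.utility_annual",), "EQ-5D", src_util),
        ParameterDef("utility_temporary", 0.78, 0.68, 0.88, "beta",
                     ("states.superficial.utility_annual",
                      "states.reoperation.utility_annual"), "EQ-5D", src_util),
    ]
    return spec, ParameterSet(defs)


#: Published base-case results for the packaged ankle decision problem, kept
#: for external cross-checks (e.g. per-1000-patient aggregate projections).
#: These are reference constants, not model output.
PUBLISHED_REFERENCE = {
    "incremental_cost_ttc_vs_orif": 3492.0,   # USD per patient
    "incremental_qaly_ttc_vs_orif": -0.003,   # QALY per patient
}


# ---------------------------------------------------------------------------
# synthetic decision problems


def generate_random_model(seed: int, n_strategies: int = 2) -> ModelSpec:
    """A random valid two-plus-strategy decision problem for testing.

    Reproducible from ``seed``.  Complication probabilities are drawn in
    (0, 0.3) so the reoperation pathway sum stays below 1 by construction;
    costs lie in (1 000, 50 000) USD; the stable utility is in (0.6, 1)
    with the temporary utility strictly below it; horizon 1-6 years with
    the standard quarterly/annual cycle plan.
    """
    if n_strategies < 2:
        raise ValueError(f"n_strategies must be >= 2, got {n_strategies}")
    rng = np.random.default_rng(seed)
    u_stable = float(rng.uniform(0.6, 1.0))
    u_temp = float(rng.uniform(0.2, u_stable))
    states = (
        HealthState("stable", "Stable", "permanent", u_stable),
        HealthState("superficial", "Superficial infection", "temporary", u_temp),
        HealthState("reoperation", "Reoperation", "temporary", u_temp),
    )
    strategies = []
    for k in range(n_strategies):
        strategies.append(Strategy(
            name=f"S{k + 1}",
            index_cost=float(rng.uniform(1_000.0, 50_000.0)),
            p_superficial=float(rng.uniform(0.0, 0.3)),
            p_deep=float(rng.uniform(0.0, 0.3)),
            p_nonunion=float(rng.uniform(0.0, 0.3)),
            p_hardware=float(rng.uniform(0.0, 0.3)),
            superficial_cost=float(rng.uniform(1_000.0, 50_000.0)),
            reoperation_cost=float(rng.uniform(1_000.0, 50_000.0)),
        ))
    horizon = int(rng.integers(1, 7))
    return ModelSpec(
        strategies=tuple(strategies),
        states=states,
        cycle_plan=build_cycle_plan(horizon),
        horizon_years=float(horizon),
        discount_rate_annual=float(rng.uniform(0.0, 0.05)),
        cohort_label=f"synthetic decision problem (seed {seed})",
    )
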