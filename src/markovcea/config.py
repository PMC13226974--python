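"""Configuration loading, the analysis pipeline and report writing.

A model configuration is one human-editable YAML document with sections
``states``, ``strategies``, ``parameters``, cycle-plan shorthand
(``horizon_years``), ``discount_rate_annual``, ``options`` and ``run``.
Unknown keys are rejected with location-bearing messages and every failing
field is reported at once.  Reports are flat CSV tables plus one
machine-readable JSON bundle carrying the seed and package version, so any
probabilistic result can be replayed bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .economics import CeacCurve, ComparisonResult, ceac, compare
from .evidence import ParameterDef, ParameterSet
from .model_core import (
    Cycle,
    HealthState,
    ModelOptions,
    ModelSpec,
    Strategy,
    StrategyOutcome,
    build_cycle_plan,
    run_cohort,
)
from .uncertainty import (
    SCENARIOS,
    PsaDraws,
    PsaSummary,
    TornadoEntry,
    apply_scenario,
    run_psa,
    tornado,
    tornado_frame,
)

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "dump_config",
    "ResultsBundle",
    "run_analyses",
    "write_report",
]

log = logging.getLogger("markovcea")

ANALYSES = ("base", "psa", "tornado", "ceac", "scenarios", "all")


class ConfigError(ValueError):
    """Raised with every schema violation enumerated, one per line."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings; the defaults are the standard study settings.

    10 000 probabilistic iterations; willingness-to-pay grid $0-$300 000
    per QALY in $1 000 steps with a $100 000 headline threshold.
    """

    analysis: str = "all"
    n_iterations: int = 10_000
    seed: int = 20_240
    wtp_max: float = 300_000.0
    wtp_step: float = 1_000.0
    wtp_headline: float = 100_000.0
    output_dir: str = "results"

    def wtp_grid(self) -> np.ndarray:
        return np.arange(0.0, self.wtp_max + self.wtp_step / 2, self.wtp_step)


_STATE_KEYS = {"id", "name", "kind", "utility_annual", "entry_cost"}
_STRATEGY_KEYS = {"name", "index_cost", "p_superficial", "p_deep", "p_nonunion",
                  "p_hardware", "superficial_cost", "reoperation_cost",
                  "utility_stable"}
_PARAM_KEYS = {"name", "base", "low", "high", "family", "targets", "units", "source"}
_OPTION_KEYS = {"half_cycle", "event_window", "reoperation_cost_rule"}
_RUN_KEYS = {"analysis", "n_iterations", "seed", "wtp_max", "wtp_step",
             "wtp_headline", "output_dir"}
_TOP_KEYS = {"cohort_label", "horizon_years", "discount_rate_annual", "states",
             "strategies", "parameters", "options", "run"}


def _check_keys(mapping: dict, allowed: set[str], where: str, errors: list[str]) -> None:
    for key in mapping:
        if key not in allowed:
            errors.append(f"{where}: unknown key {key!r} (allowed: {sorted(allowed)})")


def load_config(path: str | Path) -> tuple[ModelSpec, ParameterSet, RunConfig]:
    """Parse and fully validate a YAML model configuration."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError([f"{path}: top level must be a mapping"])

    errors: list[str] = []
    _check_keys(doc, _TOP_KEYS, str(path), errors)

    states: list[HealthState] = []
    for i, raw in enumerate(doc.get("states", [])):
        where = f"states[{i}]"
        _check_keys(raw, _STATE_KEYS, where, errors)
        try:
            states.append(HealthState(**{k: v for k, v in raw.items() if k in _STATE_KEYS}))
        except (TypeError, ValueError) as exc:
            errors.append(f"{where}: {exc}")

    strategies: list[Strategy] = []
    for i, raw in enumerate(doc.get("strategies", [])):
        where = f"strategies[{i}]"
        _check_keys(raw, _STRATEGY_KEYS, where, errors)
        try:
            strategies.append(Strategy(**{k: v for k, v in raw.items()
                                          if k in _STRATEGY_KEYS}))
        except (TypeError, ValueError) as exc:
            errors.append(f"{where}: {exc}")

    defs: list[ParameterDef] = []
    for i, raw in enumerate(doc.get("parameters", [])):
        where = f"parameters[{i}]"
        _check_keys(raw, _PARAM_KEYS, where, errors)
        try:
            raw = dict(raw)
            raw["targets"] = tuple(raw.get("targets", ()))
            defs.append(ParameterDef(**{k: v for k, v in raw.items() if k in _PARAM_KEYS}))
        except (TypeError, ValueError) as exc:
            errors.append(f"{where}: {exc}")

    opt_raw = doc.get("options", {}) or {}
    _check_keys(opt_raw, _OPTION_KEYS, "options", errors)
    try:
        options = ModelOptions(**{k: v for k, v in opt_raw.items() if k in _OPTION_KEYS})
    except (TypeError, ValueError) as exc:
        errors.append(f"options: {exc}")
        options = ModelOptions()

    run_raw = doc.get("run", {}) or {}
    _check_keys(run_raw, _RUN_KEYS, "run", errors)
    try:
        run_config = RunConfig(**{k: v for k, v in run_raw.items() if k in _RUN_KEYS})
        if run_config.analysis not in ANALYSES:
            errors.append(f"run.analysis: must be one of {ANALYSES}, "
                          f"got {run_config.analysis!r}")
    except TypeError as exc:
        errors.append(f"run: {exc}")
        run_config = RunConfig()

    if errors:
        raise ConfigError(errors)

    try:
        horizon = float(doc.get("horizon_years", 4))
        spec = ModelSpec(
            strategies=tuple(strategies),
            states=tuple(states),
            cycle_plan=build_cycle_plan(horizon),
            horizon_years=horizon,
            discount_rate_annual=float(doc.get("discount_rate_annual", 0.03)),
            cohort_label=str(doc.get("cohort_label", "")),
            options=options,
        )
    except ValueError as exc:
        raise ConfigError([str(exc)]) from None

    if (options.reoperation_cost_rule == "index_cost"
            and any(s.reoperation_cost is None for s in spec.strategies)):
        log.warning(
            "reoperation_cost not given for %s; defaulting to each strategy's "
            "own index cost (reoperation_cost_rule = 'index_cost')",
            [s.name for s in spec.strategies if s.reoperation_cost is None])

    return spec, ParameterSet(defs), run_config


def dump_config(spec: ModelSpec, params: ParameterSet, run_config: RunConfig,
                path: str | Path) -> None:
    """Serialize a model back to the YAML schema (round-trips loadable)."""
    def _clean(d: dict) -> dict:
        return {k: v for k, v in d.items() if v is not None}

    doc = {
        "cohort_label": spec.cohort_label,
        "horizon_years": spec.horizon_years,
        "discount_rate_annual": spec.discount_rate_annual,
        "options": dataclasses.asdict(spec.options),
        "states": [_clean(dataclasses.asdict(s)) for s in spec.states],
        "strategies": [_clean(dataclasses.asdict(s)) for s in spec.strategies],
        "parameters": [
            {**{k: v for k, v in dataclasses.asdict(d).items() if v != ""},
             "targets": list(d.targets)}
            for d in params.values()
        ],
        "run": dataclasses.asdict(run_config),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def packaged_config_path() -> Path:
    """Path of the packaged ankle-fragility YAML configuration."""
    return Path(__file__).parent / "data" / "ankle_fragility.yaml"


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class ResultsBundle:
    """Everything one run produced, ready for report writing."""

    spec: ModelSpec
    run_config: RunConfig
    base_outcomes: list[StrategyOutcome] = field(default_factory=list)
    base_comparison: ComparisonResult | None = None
    psa_draws: PsaDraws | None = None
    psa_summary: PsaSummary | None = None
    tornado_entries: list[TornadoEntry] | None = None
    ceac_curve: CeacCurve | None = None
    scenario_results: dict[str, ComparisonResult] | None = None
    reoperation_cost_defaulted: bool = False


def run_analyses(spec: ModelSpec, params: ParameterSet,
                 run_config: RunConfig) -> ResultsBundle:
    """Execute the selected analyses on one model configuration.

    The base case always runs (every other stage is relative to it).  The
    reference strategy is the first in the spec, the comparator the last.
    """
    which = run_config.analysis
    bundle = ResultsBundle(spec=spec, run_config=run_config)
    bundle.reoperation_cost_defaulted = (
        spec.options.reoperation_cost_rule == "index_cost"
        and any(s.reoperation_cost is None for s in spec.strategies))

    bundle.base_outcomes = [run_cohort(spec, s) for s in spec.strategies]
    bundle.base_comparison = compare(bundle.base_outcomes[0], bundle.base_outcomes[-1])

    if which in ("psa", "ceac", "all"):
        log.info("running PSA: %d iterations, seed %d",
                 run_config.n_iterations, run_config.seed)
        bundle.psa_draws, bundle.psa_summary = run_psa(
            spec, params, run_config.n_iterations, run_config.seed)

    if which in ("ceac", "all"):
        d = bundle.psa_draws
        bundle.ceac_curve = ceac(
            d.cost[:, 0], d.qaly[:, 0], d.cost[:, -1], d.qaly[:, -1],
            run_config.wtp_grid(),
            reference=d.strategies[0], comparator=d.strategies[-1])

    if which in ("tornado", "all"):
        bundle.tornado_entries = tornado(spec, params, wtp=run_config.wtp_headline)

    if which in ("scenarios", "all"):
        bundle.scenario_results = {}
        for name in SCENARIOS:
            sspec = apply_scenario(spec, name)
            outs = [run_cohort(sspec, s) for s in sspec.strategies]
            bundle.scenario_results[name] = compare(outs[0], outs[-1])
    return bundle


# ---------------------------------------------------------------------------
# report writing


def _comparison_row(c: ComparisonResult) -> dict:
    return {
        "reference": c.reference, "comparator": c.comparator,
        "delta_cost": c.delta_cost, "delta_qaly": c.delta_qaly,
        "icer": c.icer, "label": c.label, "quadrant": c.quadrant,
    }


def write_report(bundle: ResultsBundle, directory: str | Path) -> list[Path]:
    """Write CSV tables and the JSON bundle; returns the files written.

    Emits ``base_case.csv`` (per-strategy totals plus the comparison row),
    ``psa_summary.csv``, ``tornado.csv``, ``ceac.csv`` and
    ``scenarios.csv`` for whichever analyses ran, plus ``bundle.json``
    with the seed and package version for exact replay.  CSV values are
    full precision; round for presentation, not storage.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    probe = directory / ".write_probe"
    try:  # fail before computing anything if the directory is unwritable
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {directory} is not writable: {exc}") from exc

    written: list[Path] = []

    def _emit(name: str, frame: pd.DataFrame) -> None:
        p = directory / name
        frame.to_csv(p, index=False)
        written.append(p)

    rows = [
        {"strategy": o.strategy, "total_cost_discounted": o.total_cost_discounted,
         "total_qaly_discounted": o.total_qaly_discounted}
        for o in bundle.base_outcomes
    ]
    base = pd.DataFrame(rows)
    cmp_row = _comparison_row(bundle.base_comparison)
    base = base.assign(**{k: [None] * (len(base) - 1) + [v]
                          for k, v in cmp_row.items() if k not in ("reference",)})
    _emit("base_case.csv", base)

    for o in bundle.base_outcomes:
        _emit(f"trajectory_{o.strategy}.csv", o.trajectory.to_frame())

    if bundle.psa_summary is not None:
        s = bundle.psa_summary
        rows = []
        for name, d in s.per_strategy.items():
            rows.append({
                "strategy": name, "mean_cost": d["mean_cost"],
                "mean_qaly": d["mean_qaly"],
                "cost_ci_low": d["cost_ci"][0], "cost_ci_high": d["cost_ci"][1],
                "qaly_ci_low": d["qaly_ci"][0], "qaly_ci_high": d["qaly_ci"][1],
            })
        rows.append({
            "strategy": "incremental", "mean_cost": s.delta_cost_mean,
            "mean_qaly": s.delta_qaly_mean,
            "cost_ci_low": s.delta_cost_ci[0], "cost_ci_high": s.delta_cost_ci[1],
            "qaly_ci_low": s.delta_qaly_ci[0], "qaly_ci_high": s.delta_qaly_ci[1],
        })
        _emit("psa_summary.csv", pd.DataFrame(rows))
        _emit("psa_draws.csv", bundle.psa_draws.to_frame())

    if bundle.tornado_entries is not None:
        _emit("tornado.csv", tornado_frame(bundle.tornado_entries))

    if bundle.ceac_curve is not None:
        c = bundle.ceac_curve
        _emit("ceac.csv", pd.DataFrame({"wtp": c.wtp_grid, "probability": c.probability}))

    if bundle.scenario_results is not None:
        _emit("scenarios.csv", pd.DataFrame([
            {"scenario": name, **_comparison_row(c)}
            for name, c in bundle.scenario_results.items()
        ]))

    meta = {
        "version": __version__,
        "seed": bundle.run_config.seed,
        "n_iterations": bundle.run_config.n_iterations,
        "analysis": bundle.run_config.analysis,
        "cohort_label": bundle.spec.cohort_label,
        "reoperation_cost_defaulted_to_index_cost": bundle.reoperation_cost_defaulted,
        "base_case": {
            "outcomes": {o.strategy: {"cost": o.total_cost_discounted,
                                      "qaly": o.total_qaly_discounted}
                         for o in bundle.base_outcomes},
            "comparison": _comparison_row(bundle.base_comparison),
        },
    }
    if bundle.psa_summary is not None:
        s = bundle.psa_summary
        meta["psa"] = {
            "n_iterations": s.n_iterations, "seed": s.seed,
            "n_rejected": s.n_rejected,
            "delta_cost_mean": s.delta_cost_mean,
            "delta_qaly_mean": s.delta_qaly_mean,
            "delta_cost_ci": list(s.delta_cost_ci),
            "delta_qaly_ci": list(s.delta_qaly_ci),
        }
    if bundle.scenario_results is not None:
        meta["scenarios"] = {name: _comparison_row(c)
                             for name, c in bundle.scenario_results.items()}
    bundle_path = directory / "bundle.json"
    with open(bundle_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(bundle_path)
    return written
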