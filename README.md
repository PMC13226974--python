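# markovcea

Markov cohort cost-utility analysis for two-strategy surgical decision
problems, built around a packaged model of operative treatment for
**fragility ankle fractures in adults aged 75 and over**: open reduction and
internal fixation (ORIF) versus primary tibiotalocalcaneal (TTC) nailing.

The package is aimed at health-economics and orthopaedic-outcomes
researchers who want a small, fully scriptable alternative to spreadsheet or
GUI decision-tree tools: every stage — deterministic base case,
probabilistic sensitivity analysis (PSA), tornado analysis,
cost-effectiveness acceptability curves (CEAC) and scenario analyses — is a
plain Python function over immutable, validated model objects, and every
probabilistic result is reproducible from a seed.

## The model

A cohort enters at hospital discharge and moves among three mutually
exclusive health states: **stable community dwelling** (permanent),
**superficial infection** and **reoperation** (temporary, one cycle each).
Deep infection, nonunion and hardware failure are pooled into the
reoperation pathway. Time runs in four quarterly cycles over the first
postoperative year — when the complications occur — followed by annual
cycles to the horizon (4 years by default). Cumulative complication risks
*p* are spread over the quarterly cycles at a constant rate,
*q* = 1 − (1 − *p*)^(1/4); each pathway can occur at most once per patient
and at most one pathway per cycle.

Each strategy accrues discounted costs and quality-adjusted life years
(QALYs, EQ-5D-weighted years at 3% annual discounting):

- ICER = ΔC / ΔE between two strategies (USD per QALY); a strategy that is
  cheaper *and* more effective **dominates** its comparator;
- NMB(λ) = λ·E − C at willingness-to-pay λ (default $100 000/QALY);
- the CEAC reports Pr[NMB_TTC > NMB_ORIF] over λ ∈ [$0, $300 000]/QALY
  across 10 000 PSA iterations, with probabilities/utilities drawn from
  method-of-moments beta fits and costs from gamma fits.

A patient-level microsimulation of the identical process
(`markovcea.microsim`) serves as an independent validation oracle for the
cohort solver.

## Worked example

```bash
cea run --analysis base --out results/ --quiet
```

prints

```
cohort: fragility ankle fracture, age >=75
  ORIF: $30,398, 3.427 QALYs
  TTC: $32,909, 3.430 QALYs
  TTC vs ORIF: +2,511 USD, +0.003 QALY, ICER $743,846/QALY -> ICER
  note: reoperation event cost defaulted to each strategy's index cost (not an evidence-based input)
wrote 4 files to results/
```

Reading: under the packaged evidence, TTC nailing costs $2 511 more per
patient — its $3 000 implant premium is only partly offset by fewer
superficial infections (2.1% vs 10.2%) — while the QALY difference is
essentially nil (+0.003, from TTC's lower total complication burden under
the default equal stable utilities). At $743 846 per QALY gained, TTC is
far above any conventional willingness-to-pay threshold. The note flags
that the reoperation event cost has no published value for this problem and
defaults to each arm's index cost (see `docs/methods.md`).

The same pipeline is available as a library:

```python
from markovcea import ankle_fragility_model, run_cohort, compare, run_psa

spec, params = ankle_fragility_model()
orif, ttc = (run_cohort(spec, s) for s in spec.strategies)
print(compare(orif, ttc))
draws, summary = run_psa(spec, params, n=10_000, seed=1)
```

Custom decision problems are plain YAML files (see
`src/markovcea/data/ankle_fragility.yaml` for the schema) passed as
`cea run --config my_model.yaml`.

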