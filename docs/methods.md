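# Methods

## Decision problem and state structure

The packaged model compares two definitive-fixation strategies for
fragility ankle fractures in community-dwelling adults aged 75 and over:
open reduction and internal fixation (ORIF) and primary tibiotalocalcaneal
(TTC) nailing. The cohort is homogeneous and enters at hospital discharge.
Three mutually exclusive health states are modelled:

| state | kind | EQ-5D utility (default) |
|---|---|---|
| stable community dwelling | permanent | 0.90 |
| superficial infection | temporary (one cycle) | 0.78 |
| reoperation | temporary (one cycle) | 0.78 |

Deep infection, nonunion and hardware failure are pooled into the single
reoperation pathway: clinically they share the need for a return to
theatre and have similar downstream cost and quality-of-life impact, and
the pooled evidence does not support separate downstream paths. There is
no death state: over a 4-year horizon in this population the comparison of
strategies is driven by complications and costs, and adding background
mortality equal in both arms would shrink both arms' totals without
changing increments. This is a deliberate structural simplification and a
known limitation — absolute QALY totals are "mortality-free" and should
not be compared across models that do include survival.

## Cycle plan and event timing

Time is discretised into four quarterly cycles covering the first
postoperative year, then annual cycles to the horizon (default 4 years, so
7 cycles). Complications after fixation of these fractures occur almost
entirely in the early postoperative months, which is what the quarterly
resolution is for; accordingly, new complications arise **only in the
first-year cycles** (option `event_window`, default `first_year`).

The evidence supplies *cumulative* incidences over follow-up, not
per-cycle rates. Each cumulative risk *p* is converted to a per-cycle
branch probability by the constant-rate split q = 1 − (1 − p)^(1/4).
Within a cycle a stable, pathway-naive patient takes the superficial
branch with probability q_sup, the reoperation branch with q_reop
(exclusive multinomial branches; their per-cycle sum must not exceed 1),
or stays stable. Each pathway can be experienced **at most once per
patient**; the cohort solver tracks (state × had-superficial ×
had-reoperation) compound occupancies so cumulative inputs are never
double-counted. Temporary states resolve back to stable at the start of
the next cycle, *before* that cycle's branching — a patient therefore
faces the per-cycle draw in every quarter and the expected realised
incidence of each pathway equals its cumulative input exactly.

## Accrual and discounting

The index procedure cost is charged at model entry (time 0). Event costs
are charged once on entry into a temporary state, discounted at the cycle
start (when the event happens). QALYs accrue per cycle as
occupancy-weighted utility × cycle length × discount factor at the cycle
start; an optional half-cycle correction (`half_cycle: true`) moves QALY
discounting to cycle midpoints. It is off by default: with quarterly
cycles over the event-dense first year, the residual error is small, and
the plain cycle-start convention keeps the closed-form zero-complication
check exact. Costs and QALYs are both discounted at 3%/year
(`discount_rate_annual`), i.e. multiplied by (1.03)^(−t).

## Evidence and parameter uncertainty

Inputs (packaged in `data/ankle_fragility.yaml` and
`evidence.ankle_fragility_model()`):

- cumulative complication probabilities per arm (superficial infection
  ORIF 10.2% / TTC 2.1%; deep infection 2.5% / 3.43%; nonunion 11.7% /
  5.3%; hardware failure 6.6% / 8.8%), pooled meta-analytic estimates
  (McDonald 2025);
- index procedure costs $25 000 (ORIF) and $28 000 (TTC) and
  superficial-infection treatment $2 500, 2024 USD from CMS reimbursement;
- EQ-5D utilities 0.90 (stable, age-adjusted) and 0.78 (temporary
  complication quarter), from van Gerven et al.

Each parameter carries a sensitivity range of roughly ±20% of base (the
printed evidence ranges are stored verbatim where they deviate slightly,
e.g. nonunion 8.4–15%). For probabilistic sampling the range is read as a
central 95% interval, sd = (high − low)/3.92, and distributions are fitted
by the method of moments: beta for probabilities and utilities, gamma for
costs, log-normal available for ratio-type parameters (none in the
packaged set). The fitted mean always equals the base value; a beta fit
whose implied variance reaches the feasibility bound mean·(1 − mean)
falls back to 99% of that bound with a warning. The stable utility is
marked `fixed` and is never sampled in PSA (it is still varied in the
deterministic tornado, which uses the range bounds directly). Zero-width
ranges degenerate to point masses.

Two evidence gaps are handled explicitly rather than silently:

- **Reoperation event cost** has no published value. Default rule: charge
  the strategy's own index cost per reoperation (a standard
  revision-surgery assumption); every report carries a flag when this rule
  is active, and `reoperation_cost` can be set per arm.
- **Stable utility after TTC hindfoot fusion** may plausibly differ from
  ORIF's, but no comparative estimate exists; both arms share the stable
  utility by default, with a per-strategy `utility_stable` override
  exposed. Under equal utilities the arm with fewer total complications
  (TTC) necessarily accrues marginally more QALYs; an external utility
  decrement for TTC would reverse that sign. The superficial-infection
  utility is likewise unpublished and defaults to the temporary utility
  0.78.

## Analyses

**Base case.** Deterministic cohort run per strategy; comparator-minus-
reference increments; dominance classified strictly (dominated ⇔ ΔC > 0 and
ΔE < 0, dominant the mirror image, both |Δ| < 10⁻⁹ equivalent, otherwise
ICER = ΔC/ΔE).

**PSA.** 10 000 iterations by default. Every non-fixed parameter is drawn
independently from its fitted distribution (no correlation structure is
imposed — none is estimable from the published evidence), both strategies
are rebuilt and re-solved, and draws failing validation (e.g. a sampled
reoperation-pathway sum above 1) are rejected, redrawn and counted.
Credible intervals are 2.5th–97.5th percentiles of the draws. All
sampling flows from one `numpy` generator seeded by the user, so runs are
bit-reproducible.

**CEAC.** At each willingness-to-pay λ on a $0–$300 000/QALY grid ($1 000
steps), the probability that the comparator is cost-effective is the
fraction of paired draws with strictly greater net monetary benefit; exact
NMB ties count as *not* cost-effective (conservative; measure-zero under
continuous sampling).

**Tornado.** One-way deterministic variation of every bounded parameter to
its low and high bound with all others at base, ranked by output swing.
The default output is incremental NMB at $100 000/QALY; incremental cost
and incremental QALY are selectable.

**Scenarios.** Declarative spec transforms, validated after application:
`equal_deep_infection` (both arms 2.5%), `horizon_3y` (rebuilt cycle
plan), `reop_plus50` (all three reoperation-pathway probabilities ×1.5 in
both arms, rescaled onto the simplex if a product exceeds feasibility),
and `base` (identity).

## Validation oracle

`microsim.simulate_patients` walks individual patients through the same
cycle plan using the same per-cycle branch probabilities via the shared
transition builder (`model_core.cycle_event_probs`) — deliberately shared,
so equivalence tests exercise the stochastic walk and accrual logic rather
than re-deriving the probability algebra. The cohort solver's totals are
the exact expectations of the microsimulation, and the test suite checks
agreement within 3 standard errors at 50 000 patients on the packaged
model and on 20 random synthetic problems.

## Synthetic decision problems

`evidence.generate_random_model(seed)` draws structurally valid random
two-(or more-)strategy problems: complication probabilities uniform on
(0, 0.3) (so the pooled pathway sum stays below 0.9), costs uniform on
(1 000, 50 000) USD, stable utility in (0.6, 1) with the temporary utility
below it, horizons of 1–6 years and discount rates up to 5%. These cover
the invariant space (conservation, monotonicity, oracle agreement) but are
*not* calibrated to any clinical population: they contain no correlation
between arms, no cost-risk relationships and no realistic effect sizes, so
passing property tests demonstrates engine correctness, not clinical
validity of any particular parameterisation.

## Numerical choices

- Occupancy conservation is enforced at 10⁻¹²; spec construction validates
  probability bounds, pathway sums, cycle-plan contiguity and
  horizon coverage at 10⁻⁹.
- Dominance/equivalence tie tolerance is 10⁻⁹ on both deltas; with one
  delta tied and the other not, the ICER is undefined (`None`) and the
  result is labelled by the remaining dimension.
- Report CSVs store full precision; rounding (whole dollars, QALYs to
  three decimals) is applied only at presentation in the CLI summary, so
  written tables reload to identical comparisons.
- PSA re-sampling of invalid draws retries up to 1 000 times per iteration
  before failing loudly; the packaged model's rejection rate is zero.

## Problem sizes

Default analyses run 10 000 PSA iterations and 50 000-patient
microsimulation checks; both complete in seconds on a single CPU, and the
sizes were chosen so Monte Carlo error is well below every tolerance used
in the tests (e.g. the CEAC probability has a standard error of about half
a percentage point at 10 000 iterations).

## Limitations

No mortality, no hospital length-of-stay, discharge-disposition or
early-weight-bearing effects, and no societal-perspective costs are
modelled. Costs are CMS reimbursements and generalise imperfectly across
institutions. The absolute cost totals depend materially on the
reoperation-cost rule described above, and the sign of the (tiny) QALY
increment depends on the equal-stable-utility default; both are exposed as
configuration, and conclusions should be read against the wide
probabilistic intervals rather than the point estimates.
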