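# Methods

## Model structure and assumptions

The model is a two-arm decision tree over a single birth episode; the time
horizon is the postpartum hospitalization, plus a lifetime tail only for
valuing maternal death. Each birth is assigned a delivery mode (C-section
with probability `p_csection`, otherwise vaginal) and then passes, per arm,
through at most four chance nodes: PPH ≥500 mL, escalation to massive PPH
≥1,500 mL, emergency hysterectomy, and death. The five terminal states per
mode are mutually exclusive and exhaustive; their probabilities are chain
products of the conditional inputs and sum to one by construction.

Structural assumptions:

* the carbetocin arm differs from oxytocin only in the PPH probability
  (multiplied by the relative risk, capped at 1) and the prophylaxis drug
  cost; the cascade below the PPH node is arm-independent. Consequently
  every expected PPH-downstream quantity scales exactly linearly in the
  relative risk — an identity the engine exploits for closed-form
  cross-checks of the bisection threshold search;
* death occurs only through emergency hysterectomy (the only mortality
  input in the model); PPH without hysterectomy is non-fatal;
* no treatment-failure branching beyond the two blood-loss thresholds.

## Costing rule

The published per-arm totals constrain but do not fully specify how stay
costs combine with procedure costs. The package adopts one explicit rule,
held in a single costing table (`cost_model.path_cost`) so alternatives can
be swapped in:

| terminal state    | components |
|-------------------|-----------|
| no PPH            | prophylaxis only (the baseline delivery stay is not PPH-related) |
| non-massive PPH   | prophylaxis + first-line uterotonics + (mode base LOS × PPH stay multiplier 1.264) × day rate |
| massive, no hysterectomy | prophylaxis + uterotonics + second-line procedure + 6-day second-line stay × day rate |
| hysterectomy (survive or death) | prophylaxis + uterotonics + second-line procedure + hysterectomy procedure + 6.7-day stay × day rate |

Escalated paths pay their dedicated stay *instead of* the multiplied base
stay; hysterectomy paths also pay the second-line procedure (escalation
passes through second-line therapy); death paths cost the same as
surviving hysterectomy (no early-death offset). This is the unique simple
rule we found that reproduces both published arm totals (USD 190 and 161)
from the printed unit costs; whether massive paths should additionally
accrue the multiplied base stay cannot be decided from the published
totals (they fit better without it) and is flagged as a known open point.

Day rates: the general-ward rate (USD 654/day) applies to every path at
base case. Two path-specific day-rate parameters (`cost_day_pph_no_hyst`,
`cost_day_pph_hyst`) default to it and carry the sensitivity ranges up to
the high-dependency (USD 1,750) and intensive-care (USD 3,128) rates. The
oxytocin prophylaxis cost uses the single-dose 10 IU price (USD 1.03) as
base case — the printed dose range implies USD 1.03–4.10, exposed as its
sensitivity range — because the single-dose price reproduces the published
oxytocin total.

## QALY model

QALY loss = morbidity + mortality.

* Morbidity: disutility × stay/365 per PPH path, with the same stays as
  the costing rule and disutilities 0.347 (no hysterectomy) / 0.435
  (hysterectomy). Stays are far below one year, so no within-stay
  discounting is applied. Death paths keep their hysterectomy-stay
  disutility (nothing extra).
* Mortality: death probability × baseline utility (0.92) ×
  discounted remaining life expectancy at the maternal age (33). Annual
  discounting at 3%/year with end-of-year payments,
  `sum_{t=1..floor(L)} (1+r)^-t`, fractional final year prorated at
  `(1+r)^-ceil(L)`; at r = 0 the undiscounted L is returned exactly.

The remaining-life-expectancy input is not published. The packaged
synthetic life table pins female remaining LE at age 33 to 55.0 years
(current Hong Kong female life tables imply ≈55); with it the oxytocin
QALY loss computes to 0.00206/birth against the published 0.00212 — a ≈3%
residual attributable to the unrecoverable LE figure and possible
half-cycle conventions, documented rather than calibrated away. QALY
checks therefore carry a ±5% band; the relative-risk scaling between arms
is asserted exactly.

## Sensitivity analyses

* **One-way DSA** evaluates both arms at each parameter's low/high range
  end, all others at base. The decision can flip only for the relative
  risk (its high end 0.93 exceeds the WTP threshold value ≈0.915);
  carbetocin saves QALYs at every range end, so no QALY threshold exists.
* **Threshold search** bisects the signed criterion margin (negative
  incremental cost for `cost_saving`; net monetary benefit
  `WTP·ΔQALY − ΔCost` for `cost_effective_at_wtp`) to an absolute
  parameter tolerance of 1e-6. An interval without a sign change returns a
  no-threshold result carrying the constant decision. For the relative
  risk the margin is linear, and the bisection root is cross-validated
  against `rr* = 1 − Δprev/(T + WTP·Q)` (T: oxytocin treatment-cost
  component; Q: oxytocin QALY loss; Δprev: prophylaxis cost difference).
* **Two-way curve** solves the relative-risk threshold on a grid of
  C-section proportions; the curve rises monotonically because a higher
  C-section share raises baseline hemorrhage risk and hence the value of
  prevention.
* **PSA** redraws every distributed input independently per iteration
  (no correlation structure is published), 10,000 draws by default,
  seeded through `numpy.random.default_rng` and bit-reproducible.
  Probabilities use beta distributions, everything else triangular, per
  the input table. The exact published distribution parameters are not
  available; beta shapes are re-derived deterministically by moment
  matching — mean = base value, sd = range width / 3.92 (the range read as
  a central 95% interval) — falling back to a triangular over the range if
  the implied variance is infeasible. With these specs the PSA reproduces
  the published qualitative findings (QALY-saving in 100% of draws since
  the relative-risk support lies below 1; cost-saving in ≈99.5% vs the
  published 99.7%; mean saving ≈USD 74 vs 75), and the PSA acceptance
  checks are property-based (>95% cost-saving) rather than exact.
  Ties at ICER = WTP resolve to acceptance.

## Synthetic data

The generator provides every input the analysis needs without downloads:

* **Life table**: remaining LE follows a power law in years-to-`max_age`,
  `LE(a) = c·(110 − a)^g`, with c, g solved so LE(0) = 87.7 and
  LE(33) = 55.0 exactly; strictly decreasing and positive by construction.
  It emulates the shape of a modern female life table but not cohort
  effects or old-age mortality plateaus — adequate here because the model
  reads a single interpolated LE value at the maternal age (18–45 in
  sensitivity draws).
* **Microsimulation oracle**: each birth draws mode and cascade steps as
  independent Bernoulli variables and is costed/QALY-scored by the *same*
  per-path functions as the analytic modules (one source of truth), so
  agreement of cohort means with analytic expectations (asserted within 3
  Monte Carlo standard errors, using analytic variances since rare death
  paths can draw zero events) tests the expectation engine's probability
  wiring, not formula divergence. The suite runs it at n = 10^5 on the
  base case and ten parameter sets fuzzed uniformly within the sensitivity
  ranges — seconds on one CPU and ample power for the 3-SE bands; larger
  cohorts are available through the API.
* **Parameter fuzzing**: uniform draws within each sensitivity range,
  valid by construction of the ranges.

What passing these tests shows: the expectation engine, costing table and
QALY formulas are internally consistent and reproduce the published
aggregates. What they do not show: that the tree, its inputs, or the
synthetic life table match any real obstetric population beyond the
published Hong Kong aggregates.

## Numerical choices and limitations

* Internal computation is unrounded; display rounding (integer USD,
  per-1,000 rates to 1–2 decimals, QALY loss to 5 decimals) happens only
  in the reporting layer.
* Bisection tolerance 1e-6 on the parameter; path probabilities sum to 1
  to 1e-12; exact linear identities asserted at relative 1e-12.
* Degenerate inputs are legal where meaningful: all-zero probabilities
  collapse to the no-PPH state; zero-width ranges yield point-mass
  distributions; a zero discount rate disables discounting.
* Not modelled (out of scope by design): indirect/productivity costs,
  long-term post-hysterectomy and psychological sequelae, currency or
  inflation adjustment, budget impact, EVPI, and continuous blood-loss
  volumes (the model is state-based).
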