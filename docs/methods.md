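# Methods

## The model

`pompesim` simulates, month by month over a claim year, what a household
pays for enzyme replacement therapy (alglucosidase alfa) under three
reimbursement schemes, and summarizes the population burden with two
financial-protection indicators.

### Drug cost

The guideline regimen is 20 mg per kg body weight, infused twice a month,
dispensed in 50 mg vials at 5 645 RMB per vial (all four constants are
`DrugParams` fields).  The per-infusion dose is scaled by the patient's
*adherence fraction* — 1 for children, 1/8 to 1/4 for adults, reflecting
the widespread partial dosing among adult patients — and rounded **up**
to whole vials: partial vials cannot be dispensed.  A guard of 1e-9 keeps
exactly divisible doses (e.g. 12.5 kg × 20 mg/kg = 5.0 vials) from being
pushed over the next vial by float noise.

### Dosage-based scheme

A stateless monthly schedule: vials are reimbursed block by block
(`tier_width` = 5) at the plan's tier rates, nothing beyond the last
tier.  Plans are written as hyphenated percent strings ("70-60-50",
"100-90-80-70").

### Cost-based scheme

Monthly, with three annual accumulators (`AnnualClaimState`: BMI paid,
CI paid, CI deductible consumed) reset each January:

1. `insured = bill × (1 − deductible_share)`; the deductible share is the
   patient's own, always.
2. BMI pays `insured × bmi_copay`, capped by the room left under its
   annual ceiling.
3. The CI base is the insured cost BMI did not pay — including any amount
   BMI could not pay because its ceiling was exhausted.  The CI base first
   consumes what is left of the annual CI deductible line (cumulative
   across months, not re-applied monthly — the scheme's language is
   annual throughout); the remainder is reimbursed at the base CI rate up
   to the point where the year's CI payout reaches the tier threshold and
   at the boosted rate (base + 10 points) beyond it, capped by the CI
   annual ceiling.

Two design points deserve justification because the scheme description
does not pin them down:

- **BMI-ceiling overflow flows to CI.**  Reading the split as "BMI pays
  its co-pay share, CI covers the rest of the insured cost", the natural
  treatment of a binding BMI ceiling is that the unpaid remainder stays
  in the CI base — which is also how critical-illness insurance operates
  in practice (it picks up high out-of-pocket costs left after basic
  insurance).  The alternative (overflow borne by the patient) has a
  perverse consequence: raising the BMI co-pay under a binding ceiling
  *starves* the CI base and increases the patient's bill, so plan
  generosity would not be monotone.
- **The tier switch splits the claim that crosses the threshold.**  The
  boosted rate applies to payout beyond the threshold within a claim, not
  only from the next claim.  With the split, the year's CI payout is a
  fixed piecewise-linear function of the year's eligible CI base,
  independent of how the base is distributed over months; without it,
  shifting CI claims later in the year (e.g. by raising the BMI co-pay)
  defers the boost and can raise the annual bill — another monotonicity
  violation, found by randomized property testing.

With both choices, annual out-of-pocket cost is non-increasing in every
direction of plan generosity (lower deductibles, higher co-pays, higher
ceilings, lower tier threshold), which the test suite verifies on
thousands of randomized cases alongside exact conservation
(total = BMI + CI + OOP every month).

### Combined scheme

The month first runs through the dosage schedule; the residual self-paid
amount becomes the CI base (annual deductible line, base/boosted rate, CI
ceiling).  The BMI arm is not involved.  This models layering the
nationally available critical-illness insurance on top of a local
dosage-based pilot.

### Burden indicators

- **CHE**: out-of-pocket health spending strictly *exceeds*
  `che_income_share` (default 0.10) of annual household income.  Zero
  income with positive spending counts as catastrophic; spending at
  exactly the threshold does not ("exceeding" is strict).
- **IDI**: `(income − net health spend) / household_size` strictly
  *below* the poverty line (default 4 978 RMB/person/year, the $1.90/day
  line at the study-period exchange rate).  Net income may go negative.
  The baseline step counts households already below the line before any
  health spending, so IDI is an absolute post-payment poverty head count.
  A household with zero income and zero spending is therefore IDI-true
  and CHE-false.

The stepwise decomposition introduces expenses payer by payer — direct
medical cost; minus BMI reimbursement; minus CI reimbursement; plus
direct non-medical cost — and reports n/N and the rate per group at each
step (percentages printed to one decimal place).

The policy simulation replaces each household's *observed* medical
expense with the scheme's simulated annual out-of-pocket drug cost;
observed non-medical expense is added only on request
(`include_nonmedical`), since the simulation is deliberately restricted
to the drug cost.

## Synthetic cohorts

The survey behind the study (92 households) is not public, so all
population-level results run on a seeded synthetic stand-in whose
group-level moments match the published summary table (in thousand RMB:
pediatric income 37.9 (32.4), medical 120.1 (231.6), BMI reimbursed 7.3
(10.9), CI reimbursed 0.1 (0.4), non-medical 73.8 (152.2); adult income
66.1 (103.5), medical 66.4 (245.2), BMI 8.4 (21.6), CI 0.03 (0.2),
non-medical 13.1 (37.6)), with n = 24 pediatric / 68 adult by default.

- **Distributions.**  Monetary variables are log-normal — positive
  support and right skew, consistent with every published SD exceeding
  its mean — parameterized by moment matching (σ² = ln(1 + SD²/mean²)).
  Ages are truncated normal: pediatric mean 5.9, SD 5.6 on [1, 18];
  adult mean 30, SD 7.4 on (18, 60].  Infants under 1 year are excluded,
  as in the survey.
- **Mean calibration.**  After drawing, each variable is multiplicatively
  rescaled so the realized group mean equals its target exactly.  This is
  standard scenario-generation practice and matters here because some
  targets are extremely heavy-tailed: the adult CI-reimbursement target
  has SD/mean ≈ 6.7, so an uncalibrated sample mean at n = 10 000 still
  carries a ~7% relative standard error.  SDs are left to fall where the
  fitted distribution puts them; heavy-tailed sample SDs are noisy and
  are further shrunk by the accounting cap below, so only means are
  guaranteed.
- **Accounting cap.**  `bmi_reimbursed + ci_reimbursed ≤ direct_medical`
  is enforced by proportionally shrinking the two reimbursements of
  violating records, alternated with re-calibration of the group means
  (up to 100 sweeps); unsatisfiable targets raise an error.
- **Weight.**  No weights are published.  Pediatric weight uses the
  standard clinical approximation 2 × age + 8 kg with multiplicative 10%
  noise; adult weight is truncated normal, mean 60 kg, SD 10, bounds
  [40, 100].
- **Household size.**  Not published; fixed at 3 persons (configurable
  per group).  Required for per-capita income in IDI.
- **Adherence.**  Pediatric 1; adult uniform on [1/8, 1/4] per patient,
  with CLI overrides to fix either endpoint for sensitivity runs.
- **Independence.**  Variables are drawn independently; the survey's
  joint distribution (e.g. income–expense correlation) is unknown and
  not emulated.

What passing tests on this cohort do and do not show: the engine
arithmetic, indicator definitions and sweep machinery are exercised
exactly; population rates, however, inherit the independence assumption
and the log-normal tails, so they approximate the published observed
rates only loosely and should not be read as estimates for the real
cohort.

## Simulation machinery

- **Bootstrap.**  Percentile bootstrap on per-patient burden flags: point
  estimate is the flag mean; the 95% interval is the 2.5/97.5 percentile
  of B resampled means (B defaults to 1 000; not a published choice).
  Flags are sorted before resampling so results are invariant to cohort
  row order at a fixed seed; degenerate all-equal flags short-circuit to
  a zero-width interval.  Resampling happens after simulation, on the
  per-patient flags.
- **Grids.**  Eleven dosage plans (pilot + three three-tier + seven
  four-tier variants) and one-parameter-at-a-time cost-plan variants
  around the pilot (deductible share ∈ {0.3, 0.2, 0.1}; BMI co-pay up to
  1.0; BMI ceiling up to 200k; CI co-pay up to 0.9; tier threshold
  50k–125k; CI ceiling 400k–600k), with a `--factorial` escape hatch for
  the full product.
- **Stagnation point.**  For results ordered by increasing generosity,
  the first plan after which the metric never again improves by at least
  `tolerance` (default 0.005 absolute rate change — the published
  description of the policy ceiling is qualitative only); `None` if
  improvement continues to the grid end.
- **Seeding.**  All randomness flows through `numpy` Generators seeded
  from user-supplied integers; child seeds are derived with
  `SeedSequence` and kept below 2³¹.

## Numerical choices

Currency arithmetic is double-precision floating point with no
intermediate rounding; the worked-example quantities are reproduced to
well under 0.005 RMB, the tolerance used throughout the tests.  The
boosted CI rate defaults to min(base + 0.10, 1.0) so degenerate plans
with base > 0.9 remain valid.  Monthly outcomes satisfy conservation by
construction (OOP is computed as total minus reimbursements).

## Problem sizes used in the checks

Moment recovery is verified at n = 10 000 per group (every targeted mean
within 5%).  The directional findings — pilot plans never worsen CHE and
strictly cut mean out-of-pocket cost; dosage-plan sweeps move the burden
rates far more than cost-plan sweeps; simulated guideline-dosing IDI
exceeds the observed-expense IDI — are averaged over 20 generator seeds
at the default 24/68 cohort size.  A caveat the simulation itself makes
visible: at the published income levels, simulated drug costs are so far
above the 10%-of-income line that CHE saturates near 100% under *every*
scheme, so the policy effect on CHE appears mostly through mean
out-of-pocket cost and IDI, and at the real study size the rates vary
noticeably across seeds.

## Known limitations

Only the ERT drug cost enters the policy simulation (no other
medications, hospitalization or indirect/productivity costs); no
health-state or survival modelling of treatment effect; independence of
the synthetic variables as noted above; household size and weights are
assumptions surfaced in the configuration, not data.
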