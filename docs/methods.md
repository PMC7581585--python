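# Methods

## The decision problem

Acute coronary syndrome (ACS) — myocardial infarction with or without
ST-elevation, and unstable angina — carries elevated risks of
re-hospitalization and death for years after the initial event, and large
direct and indirect costs in working-age patients. Person-centred care
(PCC), in which care is co-planned with the patient as a partner, has shown
short-term clinical benefit and lower costs in trial settings. This package
implements a cohort state-transition model that projects trial-derived
two-year evidence to a five-year horizon and asks whether PCC remains
cost-effective relative to usual care for patients under 65, and how robust
that conclusion is to parameter uncertainty.

## Model structure

The disease process is a time-inhomogeneous Markov chain over seven states:

    InitialEvent → Remission1 ⇄ Relapse1 → Remission2 ⇄ Relapse2 → Remission3 → Dead

A relapse (a hospitalized ACS event) occupies exactly one monthly cycle,
after which the cohort moves to the next remission or dies. Up to two
relapses and three remissions are tracked; the numbered states encode the
relapse count so the process is Markov despite the "memory" in relapse
history. From the third remission, patients remain or die. Dead is
absorbing.

The cycle length is one month. For cycles 0–23 the transition risks are
treatment-specific (estimated from two-year trial-linked register data);
from cycle 24 onward the treatment-independent 2–5 year risks apply
(literature-sourced). Monthly transition probabilities are stored exactly
as given in the base-case table; the `switch_month` boundary is the
half-open interval convention `[0, 24)` → two-year risks.

The cohort starts fully in Remission1. The initial hospitalization is
common to both arms and its inclusion would not change any increment, so
the initial-event month is excluded by default; setting
`include_initial_event_month=True` starts the cohort in InitialEvent,
costed and utility-weighted as a relapse month.

## Rewards

Per cycle, on the accrual-basis occupancy (see conventions below):

- **QALYs**: Σ occupancy × state utility / 12 (relapse 0.67, remission
  0.82, dead 0).
- **Life-years**: alive occupancy / 12.
- **Direct costs**: relapse states accrue the arm's mean inpatient cost per
  ACS event (one event = one relapse month); remission states accrue the
  arm's monthly non-inpatient healthcare cost. Fixed and per-month
  intervention-delivery costs are supported and default to zero: PCC is
  assumed to consume no tangible resources beyond usual care, and any
  introductory fixed cost amortizes toward zero per patient.
- **Sick leave**: every alive patient-month accrues the arm's monthly
  absenteeism cost (absenteeism is not a model state; the register data do
  not support one).
- **Mortality-related productivity losses** (human-capital method): a death
  during cycle m loses the gross monthly wage (46,400 SEK, labour-tax
  adjusted) for every remaining cycle up to the horizon, each discounted at
  the cost rate.

Effects are discounted at 3%/year and costs at 3%/year in the base case,
with the per-cycle factor (1 + r)^(−m/12). Three costing perspectives are
reported throughout: direct only; direct + sick leave; societal (adding
mortality-related productivity losses).

## Cycle-accounting conventions and the replication mode

The published base-case results this package re-implements were produced in
a spreadsheet whose exact cycle accounting was not documented. Standard
textbook conventions (start-of-cycle accrual, each monthly cost accrued in
full each cycle) are this package's defaults. They reproduce the published
QALY increments to within 8% but yield cost increments one to four orders
of magnitude larger than the published ones, so the original accounting
must have differed. Structural probing of the alternatives identified a
convention set under which the package reproduces every published base-case
and discount-scenario cell to within ~4% (ICERs within ~2%); it is exposed
as `publication_conventions()` /
`MarkovCEAModel.with_publication_conventions()` and consists of:

1. **End-of-cycle accrual**: rewards are computed on the occupancy after
   each transition (discount exponent m+1), not before it.
2. **Annualized cost accrual**: every cost stream — state costs and the
   wage used for productivity losses — enters at 1/12 of its monthly value
   per cycle, i.e. the original model spread monthly amounts over annual
   cycles while effects were correctly divided by 12.
3. **No sick-leave stream in the increments**: the published sick-leave
   cost increments (−2,217 and −5,176 SEK per 1000 patients) are roughly
   three orders of magnitude smaller than any monthly application of the
   stated per-month absenteeism costs (−1.9M and −4.1M under convention 2);
   whatever the original spreadsheet applied this stream to, its
   contribution was numerically negligible, and the replication mode
   therefore excludes it (its `direct_plus_sick_leave` perspective equals
   `direct_only`).

The acceptance script (`scripts/acceptance.py`) and the quantitative
acceptance tests use the replication mode, because their purpose is to
recompute the published numbers; all other defaults remain the textbook
conventions. A half-cycle-correction flag (average of start- and
end-of-cycle occupancy, discount exponent m+0.5) is also available and off
by default.

Deaths during cycle m are costed with the productivity-loss window
[m, horizon) under start-of-cycle accrual and [m+1, horizon) under
end-of-cycle accrual, matching the timing of the other streams.

## Incremental comparison

`compare_arms` runs both cohorts under identical settings and reports
increments (PCC − usual care) scaled to 1000 patients. ICERs carry
dominance semantics: when the intervention adds QALYs and saves costs the
ratio is negative and labelled *dominant*, and no threshold comparison is
made on the raw ratio. All decision rules — threshold search and the CEAC —
are evaluated on net monetary benefit, NMB(λ) = λ·ΔE − ΔC, whose sign is
well-defined in every quadrant of the cost-effectiveness plane.

## Deterministic sensitivity analysis

- **Discount scenarios**: the four {0%, 5%} × {effects, costs} combinations
  plus the 3%/3% base case.
- **One-way sweeps** address any scalar parameter by dotted path
  (`pcc.risks_2y.relapse1`); several paths can be tied to move together
  (e.g. the three remission-cost rows, which share one underlying
  estimate).
- **Threshold search** bisects the addressed parameter to the value where
  per-patient NMB at the willingness-to-pay threshold (500,000 SEK/QALY)
  crosses zero, stopping at |NMB| < 1e-6 SEK or a bracket width below
  1e-10 of its scale. Bisection is used because NMB is continuous and
  monotone in each swept parameter but not analytically differentiable
  through the cohort recursion; the search is deterministic and seed-free.

Threshold analyses default to the five-year horizon and societal
perspective; under the replication conventions this reproduces the four
published threshold values (first-relapse risk 1.13%, second-relapse risk
5.86%, remission cost 2,741 SEK, relapse cost 107,302 SEK) to within
0.4–4.5%. Two conventions were genuinely open and were resolved by
replication fit: (a) the relapse-cost threshold treats the *first-relapse
cost row* as the swept parameter (sweeping both relapse-cost rows tied
gives 96,030 SEK, ~10% below the published value; sweeping the single row
gives 105,208 SEK); (b) the published sick-leave-cost threshold
(342,290 SEK/month) cannot be recomputed in the replication mode because
that mode carries no sick-leave stream — it is reproducible only under the
intermediate convention in which the stream is scaled to match the
published sick-leave increments, and is therefore not reported.

## Probabilistic sensitivity analysis

Each parameter-table row is assigned a distribution: beta for risks and
utilities, log-normal for costs, moment-matched so the base-case value is
the arithmetic mean:

- beta: α = m(m(1−m)/v − 1), β = (1−m)(m(1−m)/v − 1), requiring
  v < m(1−m);
- log-normal: σ² = ln(1 + v/m²), μ = ln m − σ²/2.

The default dispersion rule is **SD = 20% of the mean**. The alternative
literal rule *variance = 20% of the mean* is implemented but infeasible for
the remission utility (v = 0.164 > 0.82 × 0.18 = 0.1476) and raises rather
than clipping; the SD reading keeps every table row feasible and is the
default.

Each row consumes one uniform percentile per replicate, mapped through each
arm's own inverse CDF (**comonotone arms**). Rows whose base values
coincide in both arms (death risks, 2–5 year risks, utilities) therefore
receive identical draws, and arm-specific rows (two-year relapse risks,
costs) receive draws that preserve the between-arm ordering. This row-wise
structure mirrors the parameter table, which annotates one distribution per
row, and it is the structure under which the Monte Carlo probability of
cost-effectiveness falls inside the published ranges (87% at two years
vs the published 80–99%; 76% at five years vs 75–90%, societal perspective,
1000 draws). Fully independent per-arm draws are available
(`default_distribution_specs(arm_correlation="independent")`) and yield
~62–66% instead — the published likelihoods are only consistent with
correlated arms. Draw ordering is replicate-major, spec-order within a
replicate; a fixed seed reproduces samples bit-identically. The default is
1000 draws.

The CEAC reports, for each willingness-to-pay value, the fraction of
replicates with positive NMB; the CE plane is the scatter of incremental
(effect, cost) pairs.

## Parameter estimation from register-like data

`fit_parameters` re-derives the arm-specific parameters from patient-level
records: two-year relapse risks, mean inpatient cost per ACS event (total
event costs / number of events), monthly remission cost (non-inpatient
costs / remission patient-months, a relapse lasting one month), and the
monthly sick-leave cost by the human-capital method — each reimbursed spell
contributes (reimbursed days + 14) × (gross monthly wage / 20 working
days), since reimbursement starts only after 14 days; months of permanent
sick leave beginning after the initial event are valued at the full wage,
and patients already on permanent sick leave beforehand contribute nothing.
All registered absenteeism is attributed to the ACS condition. Death risks,
2–5 year risks and utilities are literature-sourced constants and pass
through from the defaults.

Two relapse-risk estimators are provided. The cumulative procedure
(`total_risk` + `monthly_risk`) divides patients-with-events by patients
and converts to a monthly probability by constant hazard
(1 − (1−p_total)^(1/24)) or linearly (p_total/24). Because deaths censor
follow-up, this inversion is biased low (≈ −12% for the first-relapse risk
at the base-case mortality). The default fit method (`at_risk`) instead
divides events by reconstructed person-months at risk (time in Remission1
before the first event for relapse 1; time in Remission2 for relapse 2),
the maximum-likelihood estimate of the monthly transition probability,
which is unbiased under censoring and passes parameter recovery against the
generating values at n = 10,000/arm within 3 standard errors. Relapse
events are filtered by a configurable ICD prefix list, default
{I20, I21, I22, I25, I50}, applied when records carry per-event codes.

## Synthetic register data

`generate_cohort` simulates each patient's monthly state path (starting in
Remission1, two-year follow-up by default) under the ground-truth
parameters, then dresses it: inpatient cost per event ~ log-normal with the
arm's relapse cost as mean (CV 0.5 by default, consistent with the
log-normal cost model of the PSA); non-inpatient cost per alive
non-relapse month ~ log-normal around the remission cost; sick-leave spell
onsets ~ Bernoulli per alive month with geometric reimbursed-day counts
(mean 10 days), the monthly onset probability calibrated per arm so the
expected absenteeism cost per patient-month equals the arm's base-case
value. All generated spells are reimbursed spells, matching the register's
">14 days" visibility. `make_trial_fixture` produces a 117-patient cohort
(59/58 split) shaped like the source trial. The same transition rules power
`microsimulate`, a multinomial count-based individual-level oracle whose
occupancies converge to the deterministic cohort trace at the Monte Carlo
rate; the test suite checks agreement at n = 10⁶ within 3 binomial standard
errors.

What the generator does **not** emulate: DRG-weighted costing of real
visits, ICD-coded diagnoses on events (supported in records but not
generated), permanent sick-leave spells (supported by the estimator, not
generated by default), seasonal or time-varying costs, and any correlation
between a patient's event risk and their costs. Passing recovery tests
therefore show the estimators invert this generative structure, not that
they are robust to the messiness of real registers.

## Numerical choices

- Occupancy conservation is maintained to 1e-12 per cycle (closed-form row
  construction; no renormalization).
- Probabilities and costs are validated on construction and after every
  dotted-path update; out-of-range values raise naming the field.
- Bisection: 200 iteration cap, convergence by per-patient |NMB| < 1e-6 SEK
  or bracket collapse; a missing sign change raises a `NoCrossingError`
  rather than returning a boundary value.
- Degenerate inputs: zero variance in a distribution spec yields the mean;
  a zero effect increment yields an `undefined` ICER label, never a
  division; an empty patient group or a group without events raises.
- Problem sizes used by the shipped checks: cohort runs are exact
  (deterministic) at horizons 24 and 60; the microsimulation oracle uses
  10⁶ patients; sampler moment recovery uses 10⁵ draws; estimator recovery
  uses 10,000 patients per arm; the PSA uses 1000 draws.

## Known limitations

- The two relapse-cost rows and three remission-cost rows are stored
  separately but estimated jointly (the registers do not distinguish
  them); sweeps may address them individually.
- Mortality-related productivity losses assume full labour-force
  participation to the horizon for every patient, the standard
  human-capital upper bound.
- The replication conventions reproduce the published results but are not
  recommended for new analyses; the defaults (full monthly cost accrual,
  sick leave included) are the economically meaningful ones, and under
  them PCC still dominates usual care at both horizons — by a wider cost
  margin, since the sick-leave saving then enters at full scale.
- Risks beyond five years, treatment effects beyond two years, and
  co-morbidity states are outside the model by construction.
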