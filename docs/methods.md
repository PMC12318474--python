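# Methods

## Model structure

`fallsim` is a discrete individual simulation with annual cycles over a
default 40-cycle horizon.  The simulated population is community-dwelling
adults aged 60+ at baseline (default 20 000), refreshed by an entry cohort
of 60-year-olds each cycle (default 3 % of the baseline size, which
approximately offsets deaths under the default mortality schedule and keeps
the 60+ population near-stationary).

Each person carries: age; sex; SES quartile (1 = least deprived, 4 = most
deprived); falls history in the previous year; a 0–100 cumulative-deficit
frailty index; and binary low-physical-activity, cognitive-impairment,
fear-of-falling and abnormal-gait/balance states.  Within a cycle, events
occur in a fixed order:

1. **Intervention assignment.**  Reactive (R) eligibility requires at least
   one medically attended (MA) fall recorded in the immediately preceding
   cycle (annual cycles make the next decision point the natural referral
   window).  Proactive (P) eligibility requires a GP-contact draw at the
   SES-adjusted access rate plus a positive screen; the screen is the
   *conjunction* of falls history and abnormal gait/balance by default
   (`access_params.screening_rule` switches to disjunction).  Self-referral
   (SR) is open to every community-dwelling person.  A pathway is received
   iff eligible AND a supply draw AND a demand draw succeed; when several
   qualify, precedence is R > P > SR (clinical urgency; configurable).  At
   the recommended provision level supply is 1 by construction ("no
   supply-side constraint").  At most one pathway per cycle; a new receipt
   resets the active effect.
2. **Mortality**: a fatal-fall draw (logistic in age and frailty), then
   other-cause death from a Gompertz-style age/sex schedule multiplied by a
   frailty factor and the SES mortality gradient.
3. **Nonfatal fall classification** for survivors: fall probability is
   logistic in the person's characteristics, with SES and any active
   intervention effect applied as odds multipliers.  Fallers split into
   single/recurrent × non-MA/MA types; a recurrent-with-MA cycle carries 1
   or 2 MA falls (probability of 2: 0.35).  Each MA fall is hospitalised
   with probability 0.28.
4. **Outcome accrual**, discounted by `(1+r)^-t` with r = 0.035 and cycle 0
   undiscounted (no half-cycle correction; annual accrual at cycle start):
   EQ-5D-3L utility = SES-scaled age/sex baseline − frailty decrement −
   acute faller-type loss − per-hospitalisation loss, floored at 0
   (configurable down to −0.594); public all-cause cost (age/frailty
   gradient) + directly fall-related cost (faller type, plus a
   hip-fracture-level cost per hospitalised MA fall), recorded separately
   inside the public total; out-of-pocket expenditure; paid and unpaid
   productivity value (positive value streams); informal care cost; and
   intervention costs by payer (public, copayment, participant time,
   caregiver time).
5. **Frailty and characteristic updates**: frailty += (age-band base
   increment + faller-type add-on) × scenario multiplier, clamped to
   [0, 100]; falls history is set by this cycle's faller type; cognitive
   impairment, fear of falling and gait/balance onset are absorbing annual
   logistic risks; activity declines/recovers; age += 1.
6. **LTC admission** (logistic in updated age and frailty).  Death and LTC
   admission are absorbing exits; nothing accrues afterwards.  Whether LTC
   entrants accrue a terminal-cycle cost is an open modelling choice; none
   is accrued here (their final community cycle accrues normally).

### Common random numbers

All within-simulation draws are counter-based: a splitmix64-style hash of
`(seed, person id, cycle, event)` mapped to a uniform.  A draw therefore
never depends on how many draws preceded it, and identical tuples give
identical values in every strategy.  Consequences: strategy comparisons are
variance-reduced by construction, and a null intervention (relative risk 1,
zero costs) makes all eight strategies *bit-identical* — an exact
equivalence the test suite asserts.  Cohort generation and PSA draws use
separate named streams, so adding one draw never perturbs another.

## Key parameters

All defaults are synthetic stand-ins with realistic orders of magnitude for
a UK urban 60+ population (GBP at 2023 prices); every one is overridable
via YAML/JSON.  The load-bearing choices:

| parameter | default | rationale |
| --- | --- | --- |
| fall-risk logistic | intercept −1.85; age +0.03/yr; frailty +1.6 per unit frailty/100; history +0.85 | ≈25–30 % annual fall probability, rising with age/frailty; ≈30 % baseline falls-history prevalence |
| faller-type split | 0.45/0.20/0.20/0.15 (single non-MA/single MA/recurrent non-MA/recurrent MA) | ≈35 % of faller-cycles involve medical attention |
| hospitalisation per MA fall | 0.28 | fixed study condition |
| frailty add-ons per faller type | 0.3/1.5/1.2/3.0 index points | injurious (MA) falls cause lasting functional decline — hip fracture at the severe end — which is what gives prevention its long-term QALY and cost leverage |
| intervention cost / effect | R £650, P £500, SR £150+£50 copay; odds RR 0.76/0.82/0.88 for 3/3/2 cycles | programme costs in the range of published UK falls-service costings; effects at guideline meta-analysis magnitudes, applied as fall-odds multipliers from the cycle of receipt, no decay |
| access | GP rate 0.72; usual supply 0.45/0.25/0.55 and demand 0.55/0.45/0.12; recommended supply 1 and demand 0.70/0.60/0.20 | usual care reaches a minority; recommended care removes supply constraints |
| SES gradients (Q1→Q4 multipliers) | frailty 0.85→1.25; fall odds 0.90→1.20; utility 1.02→0.94; mortality 0.88→1.25; GP access 1.05→0.88 | deprivation monotonically worsens health and access, giving the DCEA genuine inequality to measure |
| economics | 3.5 %/yr discount; horizon 40; λ_pub {20 000, 30 000}; λ_soc 60 000 | fixed study conditions |

Under these defaults the package's worked example lands where the field's
trial evidence typically does: cheap self-referral is clearly
cost-effective (≈£15 000/QALY), professional-referral pathways sit near the
£30 000 margin, and full concurrent scale-up is not cost-effective on
efficiency alone.

## Synthetic cohorts

Baseline ages follow an exponential decay (scale 8 years) truncated to
60–95; entry cohorts are exactly 60.  SES quartiles are equally sized ±1
within each cohort.  Baseline frailty is Beta(2, 9)×55 with a proportional
age trend, scaled by the SES gradient and the baseline-frailty scenario
multiplier, clamped to [0, 100].  Binary characteristics are drawn from
logistic prevalence models in age and frailty, so the SES frailty gradient
propagates into falls history, impairments and activity.

What the generator does *not* emulate: real joint dependence between
characteristics beyond the frailty channel, secular trends in cohort
health, regional heterogeneity, and the calibration targets of any real
locality.  Passing tests therefore demonstrate internal consistency,
correct accounting and the model's qualitative mechanics — not predictive
validity for any real population, whose parameterisation would have to be
supplied via the configuration interface.

## Analysis layers

**CEA.**  Societal QALYs = health QALYs − (net nonpublic cost)/λ_soc, where
net nonpublic cost = out-of-pocket + informal care + copayments + time
costs − productivity value (productivity enters the societal ledger as a
negative cost).  The public-cost basis is all-cause by default
(fall-related available); intervention public spend is included in both.
The frontier removes strong dominance pairwise (exact cost-and-QALY ties
keep the lexicographically first name, for deterministic output), then
peels extendedly dominated points until sequential ICERs strictly increase.
ICERs are reported to the nearest pound; full precision is kept internally.
The layer also accepts externally supplied (cost, QALY) tables, so
published incremental tables can be analysed without the simulator.

**PSA.**  Second-order uncertainty uses standard families — beta for
probabilities, gamma for costs, lognormal for positive multiplicative
parameters, normal for log-odds coefficients — with hyperparameters derived
from the point estimate and a coefficient of variation (default 0.2) such
that the distribution mean equals the point estimate exactly.  Relative
risks use a beta family so draws respect the (0, 1] bound.  Every run draws
one parameter set; *all* runs and strategies share a single simulation
seed, so run-to-run variation isolates parameter uncertainty (with CV = 0
the PSA degenerates to identical runs, a property the tests assert).  CEAC
ties within a run split the count equally, keeping each row summing to 1;
the CEAF maximises mean NMB on the same matrix.  The λ grid defaults to
£0–£50 000 in £500 steps.  Per-run population sizes may be scaled down
relative to deterministic runs via `PopulationSpec`.

**DCEA.**  Per-capita societal NHB by quartile feeds the Atkinson EDE
(ε = 0 mean; ε = 1 geometric-mean limit, handled explicitly to avoid the
1/(1−ε) singularity; general form `(Σ w x^{1−ε})^{1/(1−ε)}`) and the Kolm
EDE (`−ln(Σ w e^{−αx})/α`, evaluated with a max-shift for numerical
stability; exactly translation-equivariant).  Non-positive values under
Atkinson with ε > 0 raise a hard error directing users to the Kolm index —
any silent shift would change relative-inequality rankings.  Quartile
weights default to ¼ each (configurable to person-count shares).  Which
nonpublic items enter the *level* (not just increments) of NHB is a
documented choice: all of them, as in the per-capita formula above.

**Scenarios.**  "Baseline frailty ±20 %" multiplicatively scales each
individual's baseline frailty draw (clamped), not the distribution's
parameters — the simplest reading, applied identically across strategies.
Demand scenarios scale recommended-level demand only; usual-care access is
bit-identical across demand scenarios.  Scenario runs use point-estimate
parameters averaged over 10 seeds; the seed list derives only from the
master seed, so every scenario re-uses the main analysis's seeds.  Scenario
outputs default to the relative-inequality (Atkinson) DCEA.

## Numerical choices

* Logits are clipped to ±60 before exponentiation (the sigmoid is saturated
  beyond ±37 in double precision); probabilities are exact within double
  rounding elsewhere.
* Other-cause death probabilities are capped at 0.995 by default.
* Discounting uses `(1+r)^-t` with t the model cycle index, for entrants as
  for the baseline cohort.
* ICER display rounds to the nearest pound; EDE ties resolve
  lexicographically with a logged warning.
* Every generator is a pure function of its arguments and seed; identical
  seeds yield byte-identical output files.

## Problem sizes used by the test suite

Unit tests run at hundreds of individuals; the structural end-to-end checks
use the sizes the analyses are designed around: null-intervention
equivalence at 5000 baseline individuals × 40 cycles, the scenario
direction check at 50 000 × 10 seeds × all eight strategies, and a 50-run ×
2000-individual PSA demonstration.  A single 50 000-person, 40-cycle
strategy run takes under a second on one CPU core.

## Limitations

* All default parameter values are synthetic; absolute outcome levels
  (QALYs, costs, EDE NHB) are not calibrated to any real locality and
  should not be quoted as estimates for one.
* No intra-year event timing, no supply-capacity queuing, no decay of
  intervention effects, and no terminal-cycle LTC costs.
* Equity subgroups are SES quartiles only; other equity-relevant
  delineators (e.g. living alone) are out of scope.
* Discount-rate and time-horizon sweeps are not part of the scenario
  catalogue.
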