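# fallsim

Model-based economic evaluation of community falls-prevention strategies
for adults aged 60+, for health-economics researchers and commissioning
analysts. `fallsim` combines:

* an **annual-cycle individual microsimulation** of falls, frailty
  progression, long-term care (LTC) admission and death in a 60+
  community-dwelling population, under eight commissioning strategies that
  scale up none, one, two or all three falls-prevention pathways —
  reactive (**R**, referral after a medically attended fall), proactive
  (**P**, risk screening at GP contact) and self-referred (**SR**) — giving
  strategies UC, R, P, SR, R+P, R+SR, P+SR and RC (recommended care);
* a **societal cost-utility analysis** with strong/extended dominance
  frontier, ICERs and net-benefit measures;
* **probabilistic sensitivity analysis** (PSA) with cost-effectiveness
  acceptability curves (CEAC) and frontier (CEAF);
* **distributional cost-effectiveness analysis** (DCEA) of per-capita
  societal net health benefit across socioeconomic-status (SES) quartiles,
  using Atkinson and Kolm equally-distributed-equivalent (EDE) levels;
* ±20 % **alternative scenarios** for baseline frailty, frailty
  progression, cognitive-impairment incidence, intervention demand and GP
  access.

## The model in brief

Each simulated person carries age, sex, SES quartile (1 = least deprived),
falls history, a 0–100 frailty index, and binary physical-activity,
cognitive-impairment, fear-of-falling and gait/balance states.  Per annual
cycle: intervention assignment (eligibility × supply × demand), mortality
(fatal fall, then other-cause), nonfatal fall classification into faller
types (single/recurrent × medically attended or not; each MA fall carries a
28 % hospitalisation probability), accrual of EQ-5D-3L utility and costs
discounted at 3.5 %/year, frailty and characteristic updates, then LTC
admission.  Death and LTC are absorbing.  All draws are counter-based on
`(seed, person, cycle, event)`, so strategies are compared under common
random numbers.

Nonpublic costs (out-of-pocket, informal care, copayments, time costs, net
of productivity value) are converted to QALY equivalents at the societal
threshold λ_soc = £60 000/QALY and added to health QALYs:

    societal QALYs = QALYs − net nonpublic cost / λ_soc
    ICER           = Δ public cost / Δ societal QALYs   (frontier pairs)
    INMB           = λ_pub·ΔQ − ΔC,  INHB = ΔQ − ΔC/λ_pub

For the DCEA, per-capita societal NHB by quartile g is
`(Q_g − NPC_g/λ_soc − C_g/λ_pub)/n_g`, collapsed by the Atkinson EDE
`(Σ w_g x_g^{1−ε})^{1/(1−ε)}` (relative inequality aversion ε; ε=11 as
elicited from the English general public) or the Kolm EDE
`−ln(Σ w_g e^{−α x_g})/α` (absolute aversion α, e.g. 0.15).

All numeric defaults are synthetic but chosen to be realistic for a UK
urban 60+ population (≈30 % with falls history; fall risk rising with age
and frailty; the most deprived quartile worse off on frailty, fall risk and
utility).  Every value can be overridden from a YAML/JSON configuration.

## Worked example

```python
import fallsim as fs

params = fs.build_default_parameters()
spec = fs.PopulationSpec(n_baseline=20000)          # + 600 entrants/cycle
summaries = fs.run_all_strategies(params, spec, master_seed=1)
cea = fs.dominance_frontier(
    fs.points_from_summaries(summaries, fs.CEAConfig(lambda_public=30000)))
print(cea.table().to_string(index=False))
```

prints (40-year horizon, default synthetic parameterisation):

```
strategy  incremental_public_cost  incremental_societal_qalys     icer comparator       classification
      UC                        0                      0.0000      NaN       None          on-frontier
      SR                  2197898                    142.8576  15385.0         UC          on-frontier
       R                  8192773                    314.9885  34827.0         SR          on-frontier
       P                 10644661                    172.7729      NaN       None   strongly dominated
    R+SR                 10935858                    393.4386  34966.0          R          on-frontier
    P+SR                 13025121                    274.9578      NaN       None   strongly dominated
     R+P                 17427062                    405.3425      NaN       None extendedly dominated
      RC                 20173563                    464.6737 129679.0       R+SR          on-frontier
```

Reading: relative to usual care, scaling up self-referral costs £2.2 m more
public money and gains 142.9 societal QALYs (£15 385 per QALY gained —
cost-effective at the usual £20 000–£30 000 thresholds); the reactive
pathway and R+SR sit near the £30 000 margin; full recommended care costs
£129 679 per additional QALY versus R+SR under these synthetic inputs.
Strategies containing P are dominated here.  The distributional layer
(`fallsim.dcea.dcea_table(summaries, ...)`) then reports EDE NHB per
inequality-aversion level; under the defaults SR is optimal on efficiency
and equity combined at both thresholds.

The same analyses are scriptable from the shell:

```sh
fallsim evaluate --n-individuals 20000 --seed 1 --out results/
fallsim psa --runs 50 --n-individuals 2000 --out results/psa/
fallsim scenario --name frailty_baseline_up20 --n-seeds 10 --out results/scen/
fallsim table1-check          # frontier on the bundled incremental table
```

## Layout

| module | contents |
| --- | --- |
| `fallsim.parameters` | every numeric input, validation, YAML/JSON I/O |
| `fallsim.sampling`   | PSA distribution spec and mean-preserving draws |
| `fallsim.population` | baseline and annual-entry cohort generators |
| `fallsim.microsim`   | per-person operations + vectorised strategy engine |
| `fallsim.cea`        | societal QALYs, ICERs, net benefits, dominance frontier |
| `fallsim.psa`        | PSA orchestration, expected outcomes, CEAC/CEAF, scatter |
| `fallsim.dcea`       | per-quartile NHB, Atkinson/Kolm EDE, optimal strategy |
| `fallsim.scenarios`  | ±20 % scenario modifiers, multi-seed deterministic runs |
| `fallsim.cli`        | `fallsim` command-line entry point |

See `docs/methods.md` for modelling assumptions, parameter rationale and
known limitations.
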