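# acscea

A Markov cohort model of the mid-term cost-effectiveness of person-centred
care (PCC) versus usual care for patients under 65 with acute coronary
syndrome (ACS), for health economists and HTA analysts who want a
reproducible, scriptable re-implementation of a published spreadsheet
analysis — including its deterministic threshold analyses and Monte Carlo
probabilistic sensitivity analysis — plus the register-style estimation
procedures that produced its parameters.

## The model

Patients move monthly through seven states that encode relapse history:

    InitialEvent → Remission1 ⇄ Relapse1 → Remission2 ⇄ Relapse2 → Remission3 → Dead

A relapse (hospitalized ACS event) lasts one cycle. Transition risks are
treatment-specific for the first 24 cycles (trial-linked register data) and
treatment-independent thereafter (literature). Each cycle accrues QALYs
(utility 0.82 in remission, 0.67 in relapse), direct healthcare costs,
sick-leave costs, and — via the human-capital method — the gross wage
(46,400 SEK/month) for every cycle lost to death before the horizon.
Outcomes are discounted at 3%/year and compared as increments per 1000
patients:

- ΔE, ΔC by costing perspective (direct / + sick leave / societal),
- ICER = ΔC/ΔE with dominance labels,
- NMB(λ) = λ·ΔE − ΔC at λ = 500,000 SEK/QALY.

One-way threshold analyses bisect a PCC-arm parameter to the value where
NMB crosses zero; the PSA draws each parameter-table row from a
moment-matched beta (risks, utilities) or log-normal (costs) distribution
with SD = 20% of the mean and reports the CE plane and CEAC. A synthetic
register-data generator and the corresponding estimators close the loop
from patient-level records back to model parameters. See
`docs/methods.md` for the full specification, including the
publication-replication cycle-accounting conventions.

## Worked example

```python
from acscea import MarkovCEAModel, probability_cost_effective

model = MarkovCEAModel().with_publication_conventions()  # 5-year horizon
results = model.fit()
print(results)

th = results.threshold_search("pcc.risks_2y.relapse1", bracket=(0.0093, 0.5))
print(f"PCC first-relapse risk threshold: {th.threshold_value:.4%} per month")

sample = results.run_psa(n_draws=1000, seed=20200907)
print(f"P(cost-effective at 500,000 SEK/QALY): "
      f"{probability_cost_effective(sample, 500_000):.2f}")
```

prints

```
Markov cohort CEA — horizon 60 months, increments per 1000 patients
                        delta_qalys  delta_life_years  delta_cost_sek  icer_sek_per_qaly dominance  nmb_at_wtp_sek
perspective
direct_only                    2.64              2.70      -91,739.78         -34,763.26  dominant    1,411,233.20
direct_plus_sick_leave         2.64              2.70      -91,739.78         -34,763.26  dominant    1,411,233.20
societal                       2.64              2.70     -214,901.42         -81,433.31  dominant    1,534,394.84

PCC first-relapse risk threshold: 1.1343% per month
P(cost-effective at 500,000 SEK/QALY): 0.78
```

Over five years, PCC yields 2.64 additional QALYs and saves 214,901 SEK
per 1000 patients from the societal perspective — it *dominates* usual care
(the negative ICER is a label, not a price), and remains cost-effective
until the PCC arm's monthly first-relapse risk would rise from 0.93% to
1.13%. Across 1000 parameter draws it stays cost-effective in 78% of
replicates at the 500,000 SEK/QALY threshold.

The same analyses are available from the shell:

```sh
acscea run --horizon 60 -o out/base           # CEResult JSON + trace CSVs
acscea sens threshold --param pcc.risks_2y.relapse1 \
       --bracket 0.0093 0.5 --publication-conventions -o out/th
acscea psa --draws 1000 --seed 42 -o out/psa  # CE pairs + CEAC CSVs
acscea synth --n-per-arm 59 --seed 7 -o out/synth
acscea estimate out/synth/patients.csv -o out/fit
```

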