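# afib-cea

A Markov cohort cost-effectiveness model comparing four oral anticoagulation
strategies for stroke prevention in non-valvular atrial fibrillation (NVAF):
adjusted-dose **warfarin**, **rivaroxaban** 20 mg qd, and **dabigatran** at
110 mg and 150 mg bid. It is written for health-economics analysts who want a
scriptable, testable alternative to spreadsheet or GUI decision-tree tools:
every input is a plain YAML file, every output a CSV/JSON/PNG, and every
analysis step a library function.

## The model

Patients start event-free (*Min*) and each annual cycle face a
competing-risk partition over five clinical events — ischemic stroke (IS),
intracranial hemorrhage (ICH), extracranial hemorrhage (ECH), myocardial
infarction (MI), and all-cause death — or no event. Stroke and ICH outcomes
follow a severity split into no sequelae / moderate disability (*Mod*) /
severe disability (*Sev*) / fatal; ECH and MI are either fatal or fully
recovered. *Sev* is an absorbing disability state (maintenance or death
only), and event rates are time-constant. The cohort runs for 30 one-year
cycles with costs and QALYs discounted at 3% per year.

For strategies *i* and *j* with discounted totals *(C, E)*, the incremental
cost-effectiveness ratio is

    ICER = (C_i − C_j) / (E_i − E_j)   [$ per QALY]

and strategy choice at a willingness-to-pay threshold λ (default
3 × 9481.88 = 28 445.64 $/QALY, three times 2018 China GDP per capita)
maximizes net monetary benefit NMB = λ·E − C. The analysis layer classifies
strategies by strict and extended dominance and reports the efficiency
frontier with its ICERs.

Uncertainty is handled two ways:

- **One-way (tornado) analysis** — each parameter moves to the low/high end
  of its plausible range while everything else stays at base; bars rank
  parameters by ICER swing.
- **Probabilistic sensitivity analysis (PSA)** — second-order Monte Carlo
  (1000 draws by default): probabilities and utilities follow beta
  distributions and costs log-normal distributions, fitted by the method of
  moments with mean = base value and sd = range/3.92 (the range read as a
  95% interval). Outputs are the cost-effectiveness acceptability curve
  (CEAC) and the incremental cost-effectiveness plane scatter with a 95%
  covariance ellipse.

An individual-level microsimulation (`run_microsim`) shares the cohort
engine's branch tables, so the cohort totals are its exact expectation —
used as a cross-check, with Monte Carlo standard errors reported.

## Worked example

```python
import afib_cea as ac

inputs = ac.base_case_inputs()           # shipped base-case parameter set
outcomes = ac.run_all_strategies(inputs)
table = ac.incremental_analysis(list(outcomes.values()), "warfarin",
                                inputs.run.wtp)
print(table.to_frame().to_string(index=False))
print("frontier:", table.frontier, "| recommended:", table.recommended)
```

prints

```
     strategy         cost      qaly  ...               status  on_frontier  frontier_icer
     warfarin  5046.932560  8.190078  ...           comparator         True            NaN
dabigatran110 23858.637514  9.034397  ... extendedly_dominated        False            NaN
  rivaroxaban 29962.032321 10.588989  ...          on_frontier         True   10386.002606
dabigatran150 34518.178763 10.409731  ...   strictly_dominated        False            NaN
frontier: ['warfarin', 'rivaroxaban'] | recommended: rivaroxaban
```

Warfarin is by far the cheapest strategy but yields the fewest QALYs;
rivaroxaban buys the most health and completes the efficiency frontier at
about 10 386 $/QALY vs warfarin — well under the 28 445.64 $/QALY threshold,
so rivaroxaban is the recommended strategy. Dabigatran 150 mg is strictly
dominated by rivaroxaban (costs more, yields fewer QALYs) and dabigatran
110 mg is extendedly dominated (a warfarin/rivaroxaban mix beats it).

The same analyses are available from the shell:

```bash
afib-cea base-case --config config.yaml --out results/base
afib-cea owsa      --config config.yaml --out results/owsa
afib-cea psa       --config config.yaml --out results/psa --draws 1000 --seed 7
```

Each command validates the config, writes CSV/JSON tables and PNG plots
(tornado, CEAC, ICE scatter), and records a `manifest.json` with the seed so
runs are auditable and reproducible. `afib_cea.synthetic_data` generates
randomized-but-valid parameter sets and analytic two-state toy models used
throughout the test suite.

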