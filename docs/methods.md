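# Methods

## Model structure

The model is a four-state discrete-time Markov cohort: event-free (*Min*),
moderate disability (*Mod*), severe disability (*Sev*), and *Death*. The
whole cohort starts in *Min*. Each one-year cycle, a patient in *Min* faces
a competing-risk partition over ischemic stroke (IS), intracranial
hemorrhage (ICH), extracranial hemorrhage (ECH), myocardial infarction (MI),
all-cause death, and "no event"; at most one clinical event occurs per
cycle, so the all-cause mortality probability enters the partition
additively rather than multiplicatively, which keeps row sums exact. Stroke
and ICH outcomes follow a four-way severity split (no sequelae / moderate /
severe / fatal); ECH and MI are two-outcome events (fatal or full recovery).
*Sev* is an irreversible disability state whose only exits are maintenance
and death. By default *Mod* likewise faces only all-cause mortality; setting
`events_from_moderate = true` lets moderate patients experience the same
event partition, with nonfatal destinations promoted to
`max(current, destination)` severity so a disability never improves. All
rates are constant over time (no age trend), and treatment never switches or
stops after an event.

## Accrual and discounting conventions

A patient occupies one state for a whole cycle and transitions at cycle end;
there is no half-cycle correction. Per cycle:

- **Costs** = (annual treatment cost for every alive state) + (one-time
  acute-event cost for each incident event). Fatal events are charged their
  acute cost by default (`charge_fatal_event_cost`), on the reasoning that
  acute care precedes death.
- **QALYs**: survivors of a nonfatal event accrue the utility of their
  *destination* state for that cycle, multiplied by the event's within-cycle
  multiplier (`m_ich`, `m_ech`, `m_mi`; IS has no multiplier — its utility
  loss is carried entirely by the destination state). Patients without an
  event accrue their state utility; patients whose cycle ends in death
  accrue their pre-event state utility (`accrue_fatal_cycle_utility`, on by
  default). The multipliers are interpreted as *multipliers* on the state
  utility rather than substitute utilities: a substitute reading would make
  an ICH year (0.80) better than an ordinary event-free year (0.76).
- **Discounting**: cycle *t* carries the factor (1 + r)^−(t−1) — the first
  cycle is undiscounted — applied to costs and effects at the same rate
  (3%/yr default). `discount_first_cycle`, `discount_costs`, and
  `discount_effects` expose the alternatives, because published summary
  totals for this decision problem are not reproducible bit-for-bit under
  any single stated convention (the printed QALY totals slightly exceed the
  discounted annuity bound, suggesting effects may not have been
  discounted). This package therefore targets the *qualitative* base-case
  structure — orderings, dominance pattern, frontier membership — rather
  than the absolute printed totals, and the test suite asserts exactly
  that.
- No ongoing disability-care cost beyond the annual treatment cost is
  modelled; the input table provides none, so long-run disability affects
  results through utilities and mortality only.

The cohort engine and the individual-level microsimulation share one
branch-table representation of the cycle (probability, destination, event
tag, per-branch cost and utility), which makes the cohort run the exact
expectation of the microsimulation; agreement at 100 000 patients within
3 Monte Carlo standard errors is part of the test suite, as is exact
(1e-9) agreement with the closed-form geometric-series solution of a
degenerate two-state (alive/dead) configuration.

## Parameters

All inputs live in one YAML file (shipped fixture:
`src/afib_cea/data/table1_base_case.yaml`) with sections `strategies`
(five annual event probabilities per strategy), `event_outcomes` (severity
splits and fatalities), `costs` (annual treatment cost per strategy, $;
one-time event costs, $), `utilities` (state weights and event
multipliers), and `run`. Parameters without a published plausible range are
stored as degenerate ranges (low = base = high) and held fixed in both
sensitivity analyses. The aggregate "annual treatment cost" row is taken as
authoritative rather than recomputed from unit drug prices and monitoring
frequencies, which disagree with the aggregates at the sub-percent level.
Strategy labels are canonical lowercase identifiers with case-insensitive
aliases accepted on load. Money is plain dollars; no currency conversion.

Key run defaults: 30 annual cycles; 3% discount rate; willingness-to-pay
threshold 28 445.64 $/QALY (three times 2018 China per-capita GDP);
1000 PSA draws.

## Incremental analysis

Strategies are sorted by discounted total cost. Strict dominance removes any
strategy that is no cheaper and no more effective than another (strict on at
least one axis); exact ties are flagged *indifferent* rather than dominated.
Extended dominance then iterates: whenever consecutive frontier ICERs fail
to increase strictly, the middle strategy is removed. The resulting frontier
ICERs are strictly increasing, and the classification is property-tested
against an exhaustive O(n³) convex-blend oracle on random instances. The
result table carries both pairwise-vs-comparator increments (the common
presentation in applied work, warfarin as comparator) and frontier status.
The recommended strategy maximizes net monetary benefit at the threshold;
ties break toward lower cost, then label order.

## Sensitivity analyses

**One-way (tornado).** Each ranged parameter is set to its low and high
bound with everything else at base, the cohort model re-run for the
reference and comparator strategies (rivaroxaban vs warfarin by default),
and the ICER recorded. Entries sort by absolute ICER swing; a dominance
flag at either bound is treated as maximal (infinite) swing. Degenerate
ranges produce zero-swing entries.

**Probabilistic (second-order Monte Carlo).** Each non-fixed parameter is
drawn independently: beta for probabilities and utilities, log-normal for
costs, fitted by the method of moments with mean = base and
sd = (high − low)/3.92, i.e. the published range is read as a central 95%
interval (ranges here are literature-derived plausibility intervals, not
hard supports). Severity-split components are drawn marginally and the
vector renormalized to sum to 1; a draw that still fails validation (e.g.
inverted state utilities from overlapping ranges) is redrawn, with a cap of
100 attempts. The deterministic cohort engine runs once per draw per
strategy — parameter uncertainty only, no patient-level noise. The CEAC
reports, per willingness-to-pay grid point, the fraction of draws in which
each strategy attains maximal net monetary benefit, ties split equally (so
columns sum exactly to 1). The ICE scatter returns per-draw
(ΔQALY, Δcost) pairs with the mean-centred covariance ellipse at the
chi-square(2) quantile of the requested coverage; empirical coverage is
verified at 0.95 ± 0.01 on synthetic bivariate-normal draws.

## Synthetic data

`generate_inputs` perturbs every base-case scalar multiplicatively
(log-scale jitter), truncates into each parameter's legal domain
(probabilities capped at 0.19 so five competing risks always leave positive
stay-well probability), renormalizes splits, re-sorts state utilities, and
regenerates ranges around the new bases — so generated sets always validate
and always run. Jitter 0 returns the fixture exactly. These sets exercise
the machinery across the parameter space; they do not emulate features of
real trial data such as correlated risks across strategies, age-dependent
hazards, or adherence, so passing tests on them demonstrates numerical and
structural correctness, not clinical calibration.

## Numerical notes and limitations

- Transition rows are validated to sum to 1 within 1e-9; severity splits to
  1 within 1e-9; the two-state oracle agreement tolerance is 1e-9.
- Equal-QALY ICERs always return a flag (dominant / dominated /
  indifferent), never a division.
- Problem sizes used in the shipped checks — a 45-point closed-form grid,
  100 000 microsimulated patients, 1000 PSA draws, 100 000-draw moment
  checks — run in seconds and were chosen to make Monte Carlo tolerances
  (3 SE, 1%) comfortably discriminating.
- Known limitations: no age-dependent background mortality, no treatment
  discontinuation or switching, no disability-care costs, no correlated
  parameter sampling, no EVPI, and no attempt to reproduce the published
  absolute totals bit-for-bit (see the discounting note above). Apixaban is
  out of scope.
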