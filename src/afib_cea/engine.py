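"""Markov cohort engine: cycle kernel, cohort trace, and microsimulation.

Four health states: event-free (``Min``), moderate disability (``Mod``),
severe disability (``Sev``) and ``Death``.  Each annual cycle a patient in
``Min`` faces a competing-event partition: ischemic stroke, intracranial
hemorrhage, extracranial hemorrhage, myocardial infarction, all-cause
death, or no event.  Stroke and ICH outcomes follow a severity split
(light / moderate / severe / fatal); ECH and MI are either fatal or fully
recovered.  ``Sev`` is absorbing up to death; ``Mod`` faces only all-cause
mortality unless ``events_from_moderate`` is enabled.

Accrual convention: a patient occupies one state for the whole cycle and
transitions at cycle end.  Survivors of a nonfatal event accrue, for that
cycle, the utility of their destination state times the event's
within-cycle multiplier; patients whose cycle ends in death accrue their
pre-event state utility (switchable via ``accrue_fatal_cycle_utility``).
Acute-event costs are charged in the event cycle, fatal or not
(``charge_fatal_event_cost``).  No half-cycle correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .parameters import (
    EVENTS,
    CostInputs,
    Event,
    EventRisks,
    ModelInputs,
    RunConfig,
    SeveritySplit,
    SimpleFatality,
    Strategy,
    UtilityInputs,
    canonical_strategy,
)

# state indices
MIN, MOD, SEV, DEATH = 0, 1, 2, 3
STATE_LABELS = ("Min", "Mod", "Sev", "Death")
N_STATES = 4
ALIVE = (MIN, MOD, SEV)

_EVENT_INDEX = {e: i for i, e in enumerate(EVENTS)}
_ROW_TOL = 1e-12


class KernelError(ValueError):
    """Raised when per-cycle competing probabilities are inconsistent."""


@dataclass(frozen=True)
class Branch:
    """One outcome branch of a cycle: probability, destination, event tag."""

    prob: float
    next_state: int
    event: int | None = None   # index into EVENTS, None for no acute event
    fatal: bool = False        # cycle ends in death


@dataclass
class CycleKernel:
    """One strategy's per-cycle transition structure.

    ``branches[s]`` enumerates the mutually exclusive outcomes of a cycle
    spent in state ``s``; ``transition`` and ``event_incidence`` are the
    implied state-to-state matrix and per-state acute-event probabilities.
    """

    branches: tuple[tuple[Branch, ...], ...]
    transition: np.ndarray       # (4, 4)
    event_incidence: np.ndarray  # (4, n_events), origin state x event
    strategy: str | None = None

    def __post_init__(self):
        rows = self.transition.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise KernelError(f"transition rows do not sum to 1: {rows}")


def _event_branches(risks: EventRisks, is_split: SeveritySplit,
                    ich_split: SeveritySplit, ech_fate: SimpleFatality,
                    mi_fate: SimpleFatality, origin: int) -> list[Branch]:
    """Competing-event branches for an at-risk origin state.

    Nonfatal light/moderate stroke outcomes never improve on the origin
    state: destinations are promoted to ``max(origin, destination)``.
    """
    def dest(state: int) -> int:
        return max(origin, state)

    br: list[Branch] = []
    iis = _EVENT_INDEX[Event.IS]
    iich = _EVENT_INDEX[Event.ICH]
    iech = _EVENT_INDEX[Event.ECH]
    imi = _EVENT_INDEX[Event.MI]
    for ev, p, split in ((iis, risks.p_is, is_split), (iich, risks.p_ich, ich_split)):
        if p == 0:
            continue
        br.append(Branch(p * split.f_light, dest(MIN), ev))
        br.append(Branch(p * split.f_moderate, dest(MOD), ev))
        br.append(Branch(p * split.f_severe, dest(SEV), ev))
        br.append(Branch(p * split.f_die, DEATH, ev, fatal=True))
    for ev, p, fate in ((iech, risks.p_ech, ech_fate), (imi, risks.p_mi, mi_fate)):
        if p == 0:
            continue
        br.append(Branch(p * (1.0 - fate.f_die), dest(MIN), ev))
        br.append(Branch(p * fate.f_die, DEATH, ev, fatal=True))
    if risks.p_death > 0:
        br.append(Branch(risks.p_death, DEATH, None, fatal=True))
    return [b for b in br if b.prob > 0]


def build_cycle_kernel(risks: EventRisks, is_split: SeveritySplit,
                       ich_split: SeveritySplit, ech_fate: SimpleFatality,
                       mi_fate: SimpleFatality, config: RunConfig,
                       strategy: str | None = None) -> CycleKernel:
    """Assemble the one-cycle branch structure for one strategy.

    Raises :class:`KernelError` when the competing probabilities from an
    at-risk state sum above 1.
    """
    total = risks.total()
    if total > 1.0 + _ROW_TOL:
        raise KernelError(
            f"competing event probabilities sum to {total:.6f} > 1"
            + (f" for strategy {strategy!r}" if strategy else ""))

    branches: list[list[Branch]] = [[] for _ in range(N_STATES)]

    min_events = _event_branches(risks, is_split, ich_split, ech_fate, mi_fate, MIN)
    stay = 1.0 - sum(b.prob for b in min_events)
    branches[MIN] = min_events + ([Branch(stay, MIN)] if stay > 0 else [])

    if config.events_from_moderate:
        mod_events = _event_branches(risks, is_split, ich_split, ech_fate, mi_fate, MOD)
        stay = 1.0 - sum(b.prob for b in mod_events)
        branches[MOD] = mod_events + ([Branch(stay, MOD)] if stay > 0 else [])
    else:
        branches[MOD] = ([Branch(risks.p_death, DEATH, None, fatal=True)]
                         if risks.p_death > 0 else [])
        if risks.p_death < 1:
            branches[MOD].append(Branch(1.0 - risks.p_death, MOD))

    branches[SEV] = ([Branch(risks.p_death, DEATH, None, fatal=True)]
                     if risks.p_death > 0 else [])
    if risks.p_death < 1:
        branches[SEV].append(Branch(1.0 - risks.p_death, SEV))

    branches[DEATH] = [Branch(1.0, DEATH)]

    transition = np.zeros((N_STATES, N_STATES))
    incidence = np.zeros((N_STATES, len(EVENTS)))
    for s in range(N_STATES):
        for b in branches[s]:
            transition[s, b.next_state] += b.prob
            if b.event is not None:
                incidence[s, b.event] += b.prob

    return CycleKernel(
        branches=tuple(tuple(bs) for bs in branches),
        transition=transition,
        event_incidence=incidence,
        strategy=strategy,
    )


def build_strategy_kernels(inputs: ModelInputs) -> dict[str, CycleKernel]:
    """Build the cycle kernel of every strategy in a parameter set."""
    return {
        s.value: build_cycle_kernel(inputs.risks[s], inputs.is_split,
                                    inputs.ich_split, inputs.ech_fate,
                                    inputs.mi_fate, inputs.run,
                                    strategy=s.value)
        for s in Strategy
    }


# ---------------------------------------------------------------------------
# Per-branch accruals
# ---------------------------------------------------------------------------

def _accrual_tables(kernel: CycleKernel, costs: CostInputs,
                    utilities: UtilityInputs, config: RunConfig):
    """Per-origin-state branch arrays: (cumprob, next_state, utility, cost).

    Branch utility: survivors of a nonfatal event take the destination-state
    utility times the event multiplier; every other branch (no event, fatal
    event, background death) takes the origin-state utility for the cycle.
    Branch cost: the annual treatment cost (any alive origin) plus the acute
    event cost when an event occurs.
    """
    u_state = np.array([utilities.u_min, utilities.u_mod, utilities.u_sev, 0.0])
    mult = {
        _EVENT_INDEX[Event.IS]: 1.0,
        _EVENT_INDEX[Event.ICH]: utilities.m_ich,
        _EVENT_INDEX[Event.ECH]: utilities.m_ech,
        _EVENT_INDEX[Event.MI]: utilities.m_mi,
    }
    if kernel.strategy is not None:
        annual = costs.annual_treatment[canonical_strategy(kernel.strategy)]
    else:
        annual = 0.0
    event_cost = np.array([costs.event[e] for e in EVENTS])

    tables = []
    for origin in range(N_STATES):
        brs = kernel.branches[origin]
        if origin == DEATH or not brs:
            tables.append(None)
            continue
        probs = np.array([b.prob for b in brs])
        nxt = np.array([b.next_state for b in brs])
        util = np.empty(len(brs))
        cost = np.full(len(brs), float(annual))
        ev = np.full(len(brs), -1)
        for i, b in enumerate(brs):
            if b.event is not None and not b.fatal:
                util[i] = u_state[b.next_state] * mult[b.event]
            elif b.fatal and not config.accrue_fatal_cycle_utility:
                util[i] = 0.0
            else:
                util[i] = u_state[origin]
            if b.event is not None:
                ev[i] = b.event
                if config.charge_fatal_event_cost or not b.fatal:
                    cost[i] += event_cost[b.event]
        tables.append({
            "prob": probs, "cum": np.cumsum(probs), "next": nxt,
            "util": util, "cost": cost, "event": ev,
        })
    return tables


# ---------------------------------------------------------------------------
# Cohort model
# ---------------------------------------------------------------------------

@dataclass
class CohortTrace:
    """Cycle-by-cycle expectations of the cohort model.

    ``occupancy`` has ``horizon + 1`` rows; row 0 is the initial
    distribution (everyone event-free).  Per-cycle accruals are
    undiscounted; discounting happens in :func:`summarize_trace`.
    """

    occupancy: np.ndarray        # (T + 1, 4)
    events_per_cycle: np.ndarray  # (T, n_events)
    cost_per_cycle: np.ndarray   # (T,)
    qaly_per_cycle: np.ndarray   # (T,)
    strategy: str | None = None

    def to_frame(self) -> pd.DataFrame:
        """One row per cycle with occupancy, incidence and accruals."""
        T = len(self.cost_per_cycle)
        df = pd.DataFrame(self.occupancy[1:], columns=[f"occ_{s}" for s in STATE_LABELS])
        for j, e in enumerate(EVENTS):
            df[f"events_{e.value}"] = self.events_per_cycle[:, j]
        df["cost"] = self.cost_per_cycle
        df["qaly"] = self.qaly_per_cycle
        df.insert(0, "cycle", np.arange(1, T + 1))
        return df


@dataclass
class StrategyOutcome:
    """Discounted totals for one strategy."""

    strategy: str
    total_cost: float
    total_qaly: float
    life_years: float
    event_totals: dict[str, float] = field(default_factory=dict)
    mc_stderr: dict[str, float] | None = None


def _discount_factors(config: RunConfig) -> np.ndarray:
    t = np.arange(1, config.horizon_cycles + 1, dtype=float)
    exponent = t if config.discount_first_cycle else t - 1.0
    return (1.0 + config.discount_rate) ** (-exponent)


def run_cohort(kernel: CycleKernel, costs: CostInputs, utilities: UtilityInputs,
               config: RunConfig) -> CohortTrace:
    """Propagate the full cohort through ``horizon_cycles`` annual cycles.

    The cohort starts 100% in the event-free state.  Expected per-cycle
    accruals are the branch-probability-weighted accruals of
    :func:`_accrual_tables`, which makes the cohort model the exact
    expectation of :func:`run_microsim`.
    """
    T = config.horizon_cycles
    tables = _accrual_tables(kernel, costs, utilities, config)

    occupancy = np.zeros((T + 1, N_STATES))
    occupancy[0, MIN] = 1.0
    events = np.zeros((T, len(EVENTS)))
    cost = np.zeros(T)
    qaly = np.zeros(T)

    x = occupancy[0]
    for t in range(T):
        for s in ALIVE:
            tab = tables[s]
            if tab is None or x[s] == 0:
                continue
            w = x[s] * tab["prob"]
            cost[t] += float(w @ tab["cost"])
            qaly[t] += float(w @ tab["util"])
            for i, e in enumerate(tab["event"]):
                if e >= 0:
                    events[t, e] += w[i]
        x = x @ kernel.transition
        occupancy[t + 1] = x

    return CohortTrace(occupancy=occupancy, events_per_cycle=events,
                       cost_per_cycle=cost, qaly_per_cycle=qaly,
                       strategy=kernel.strategy)


def summarize_trace(trace: CohortTrace, config: RunConfig) -> StrategyOutcome:
    """Discount the per-cycle accruals into strategy totals.

    With ``discount_first_cycle = False`` (default) cycle ``t`` carries the
    factor ``(1 + r)^-(t - 1)``; life-years discount with the effect stream.
    """
    disc = _discount_factors(config)
    cdisc = disc if config.discount_costs else np.ones_like(disc)
    edisc = disc if config.discount_effects else np.ones_like(disc)
    alive = trace.occupancy[:-1, :3].sum(axis=1)
    return StrategyOutcome(
        strategy=trace.strategy or "",
        total_cost=float(trace.cost_per_cycle @ cdisc),
        total_qaly=float(trace.qaly_per_cycle @ edisc),
        life_years=float(alive @ edisc),
        event_totals={e.value: float(trace.events_per_cycle[:, j].sum())
                      for j, e in enumerate(EVENTS)},
    )


def run_strategy(inputs: ModelInputs, strategy) -> StrategyOutcome:
    """Convenience: kernel + cohort + summary for one strategy."""
    s = canonical_strategy(strategy)
    kernel = build_cycle_kernel(inputs.risks[s], inputs.is_split, inputs.ich_split,
                                inputs.ech_fate, inputs.mi_fate, inputs.run,
                                strategy=s.value)
    trace = run_cohort(kernel, inputs.costs, inputs.utilities, inputs.run)
    return summarize_trace(trace, inputs.run)


def run_all_strategies(inputs: ModelInputs) -> dict[str, StrategyOutcome]:
    return {s.value: run_strategy(inputs, s) for s in Strategy}


# ---------------------------------------------------------------------------
# Individual-level microsimulation
# ---------------------------------------------------------------------------

def run_microsim(kernel: CycleKernel, costs: CostInputs, utilities: UtilityInputs,
                 config: RunConfig, n_patients: int, seed: int) -> StrategyOutcome:
    """First-order Monte Carlo: ``n_patients`` independent trajectories.

    Uses the same branch tables (and therefore the same accrual rules) as
    the cohort model, so cohort totals are the exact expectation of the
    microsimulation.  Returns per-patient means with Monte Carlo standard
    errors under ``mc_stderr`` (keys ``"cost"`` and ``"qaly"``).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    tables = _accrual_tables(kernel, costs, utilities, config)
    disc = _discount_factors(config)
    cdisc = disc if config.discount_costs else np.ones_like(disc)
    edisc = disc if config.discount_effects else np.ones_like(disc)

    state = np.full(n_patients, MIN, dtype=np.int64)
    cost = np.zeros(n_patients)
    qaly = np.zeros(n_patients)
    ly = np.zeros(n_patients)
    event_counts = np.zeros(len(EVENTS))

    for t in range(config.horizon_cycles):
        # snapshot start-of-cycle states so nobody transitions twice per cycle
        new_state = state.copy()
        for s in ALIVE:
            tab = tables[s]
            if tab is None:
                continue
            idx = np.nonzero(state == s)[0]
            if idx.size == 0:
                continue
            u = rng.random(idx.size)
            b = np.searchsorted(tab["cum"], u, side="right")
            b = np.minimum(b, len(tab["cum"]) - 1)  # guard fp edge
            cost[idx] += cdisc[t] * tab["cost"][b]
            qaly[idx] += edisc[t] * tab["util"][b]
            ly[idx] += edisc[t]
            ev = tab["event"][b]
            for j in range(len(EVENTS)):
                event_counts[j] += int(np.count_nonzero(ev == j))
            new_state[idx] = tab["next"][b]
        state = new_state
        if not np.any(state != DEATH):
            break

    n = float(n_patients)
    se = {
        "cost": float(cost.std(ddof=1) / np.sqrt(n)) if n_patients > 1 else 0.0,
        "qaly": float(qaly.std(ddof=1) / np.sqrt(n)) if n_patients > 1 else 0.0,
    }
    return StrategyOutcome(
        strategy=kernel.strategy or "",
        total_cost=float(cost.mean()),
        total_qaly=float(qaly.mean()),
        life_years=float(ly.mean()),
        event_totals={e.value: float(event_counts[j] / n)
                      for j, e in enumerate(EVENTS)},
        mc_stderr=se,
    )
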