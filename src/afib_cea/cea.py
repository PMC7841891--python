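"""Incremental cost-effectiveness analysis.

Sorting by cost, strict and extended dominance, frontier ICERs, pairwise
comparisons against a named comparator, net monetary benefit (NMB) and the
willingness-to-pay (WTP) decision rule.  The functions here are generic:
they work on any collection of (cost, QALY) outcomes, not only the four
anticoagulation strategies.

The result table carries both pairwise-vs-comparator increments (the usual
presentation in applied work) and frontier status/ICERs (the standard
decision-analytic summary).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

# dominance / degeneracy flags returned instead of a numeric ICER
DOMINANT = "dominant"        # cheaper and more effective
DOMINATED = "dominated"      # costlier and less effective
INDIFFERENT = "indifferent"  # identical cost and effect

STATUS_COMPARATOR = "comparator"
STATUS_ON_FRONTIER = "on_frontier"
STATUS_STRICTLY_DOMINATED = "strictly_dominated"
STATUS_EXTENDEDLY_DOMINATED = "extendedly_dominated"
STATUS_INDIFFERENT = "indifferent"


def _cost_qaly(outcome) -> tuple[float, float]:
    """Accept a StrategyOutcome-like object or a (cost, qaly) pair."""
    if hasattr(outcome, "total_cost"):
        return float(outcome.total_cost), float(outcome.total_qaly)
    c, q = outcome
    return float(c), float(q)


def icer(reference, comparator, round_to: int | None = None):
    """ICER of ``reference`` vs ``comparator``: Δcost / ΔQALY.

    Returns a float when the QALY difference is nonzero and the point is in
    a trade-off quadrant; otherwise one of the flags :data:`DOMINANT`
    (reference cheaper and more effective), :data:`DOMINATED` (costlier and
    less effective) or :data:`INDIFFERENT` (identical outcomes).  Equal-QALY
    comparisons always yield a flag, never a division.

    ``round_to`` rounds the increments before dividing, which matches how
    ratios computed from rounded published tables are reproduced.
    """
    cr, qr = _cost_qaly(reference)
    cc, qc = _cost_qaly(comparator)
    dc, dq = cr - cc, qr - qc
    if round_to is not None:
        dc, dq = round(dc, round_to), round(dq, round_to)
    if dq == 0:
        if dc > 0:
            return DOMINATED
        if dc < 0:
            return DOMINANT
        return INDIFFERENT
    if dq > 0 and dc <= 0:
        return DOMINANT
    if dq < 0 and dc >= 0:
        return DOMINATED
    return dc / dq


def net_monetary_benefit(outcome, wtp: float) -> float:
    """NMB = wtp x QALYs - cost."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    c, q = _cost_qaly(outcome)
    return wtp * q - c


def optimal_strategy(outcomes: Sequence, wtp: float) -> str:
    """Label of the max-NMB strategy; ties go to the cheaper strategy, then
    to label sort order."""
    if not outcomes:
        raise ValueError("need at least one strategy")
    best = None
    for o in outcomes:
        nmb = net_monetary_benefit(o, wtp)
        c, _ = _cost_qaly(o)
        key = (-nmb, c, str(o.strategy))
        if best is None or key < best[0]:
            best = (key, str(o.strategy))
    return best[1]


@dataclass
class CEAEntry:
    strategy: str
    total_cost: float
    total_qaly: float
    delta_cost: float | None      # vs comparator (None for the comparator row)
    delta_qaly: float | None
    icer_vs_comparator: float | str | None
    status: str
    frontier: bool = False
    frontier_icer: float | None = None  # vs previous frontier strategy


@dataclass
class CEATable:
    """Strategies ordered by total cost with dominance classification."""

    entries: list[CEAEntry]
    comparator: str
    wtp: float
    recommended: str

    @property
    def frontier(self) -> list[str]:
        return [e.strategy for e in self.entries if e.frontier]

    def entry(self, strategy: str) -> CEAEntry:
        for e in self.entries:
            if e.strategy == strategy:
                return e
        raise KeyError(strategy)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "strategy": e.strategy,
            "cost": e.total_cost,
            "qaly": e.total_qaly,
            "delta_cost_vs_comparator": e.delta_cost,
            "delta_qaly_vs_comparator": e.delta_qaly,
            "icer_vs_comparator": e.icer_vs_comparator,
            "status": e.status,
            "on_frontier": e.frontier,
            "frontier_icer": e.frontier_icer,
        } for e in self.entries])


def incremental_analysis(outcomes: Sequence, comparator: str,
                         wtp: float) -> CEATable:
    """Full incremental analysis of a set of strategy outcomes.

    Strategies are sorted by total cost; strictly dominated strategies
    (another strategy is no costlier and strictly more effective, or
    cheaper and no less effective) are removed first, then extendedly
    dominated strategies are removed iteratively until the frontier ICERs
    strictly increase with cost.  Pairwise increments against
    ``comparator`` are reported for every strategy regardless of status.
    """
    pts = [(str(o.strategy), *_cost_qaly(o)) for o in outcomes]
    labels = [p[0] for p in pts]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate strategy labels: {sorted(labels)}")
    if len(pts) < 2:
        raise ValueError("need at least two strategies")
    comparator = str(comparator)
    if comparator not in labels:
        raise ValueError(f"comparator {comparator!r} not among strategies")

    pts.sort(key=lambda p: (p[1], -p[2], p[0]))

    status: dict[str, str] = {}
    # exact duplicates: the first occurrence competes, later ones are
    # flagged indifferent (not dominated)
    seen: dict[tuple[float, float], str] = {}
    for lab, c, q in pts:
        if (c, q) in seen:
            status[lab] = STATUS_INDIFFERENT
        else:
            seen[(c, q)] = lab

    candidates = [p for p in pts if p[0] not in status]

    # strict dominance
    for lab, c, q in candidates:
        for lab2, c2, q2 in candidates:
            if lab2 == lab:
                continue
            if (c2 <= c and q2 >= q) and (c2 < c or q2 > q):
                status[lab] = STATUS_STRICTLY_DOMINATED
                break
    candidates = [p for p in candidates if p[0] not in status]

    # extended dominance: frontier ICERs must strictly increase
    while len(candidates) > 2:
        removed = False
        for i in range(1, len(candidates) - 1):
            _, c0, q0 = candidates[i - 1]
            lab, c1, q1 = candidates[i]
            _, c2, q2 = candidates[i + 1]
            icer_in = (c1 - c0) / (q1 - q0)
            icer_out = (c2 - c1) / (q2 - q1)
            if icer_in >= icer_out:
                status[lab] = STATUS_EXTENDEDLY_DOMINATED
                candidates.pop(i)
                removed = True
                break
        if not removed:
            break

    frontier_labels = [p[0] for p in candidates]
    frontier_icers: dict[str, float | None] = {}
    for i, (lab, c, q) in enumerate(candidates):
        if i == 0:
            frontier_icers[lab] = None
        else:
            _, c0, q0 = candidates[i - 1]
            frontier_icers[lab] = (c - c0) / (q - q0)

    comp_point = next(p for p in pts if p[0] == comparator)
    entries = []
    for lab, c, q in pts:
        on_frontier = lab in frontier_labels
        if lab == comparator:
            st = STATUS_COMPARATOR
            dc = dq = ic = None
        else:
            st = status.get(lab, STATUS_ON_FRONTIER)
            dc = c - comp_point[1]
            dq = q - comp_point[2]
            ic = icer((c, q), (comp_point[1], comp_point[2]))
        entries.append(CEAEntry(
            strategy=lab, total_cost=c, total_qaly=q,
            delta_cost=dc, delta_qaly=dq, icer_vs_comparator=ic,
            status=st, frontier=on_frontier,
            frontier_icer=frontier_icers.get(lab),
        ))

    recommended = optimal_strategy(list(outcomes), wtp)
    return CEATable(entries=entries, comparator=comparator, wtp=wtp,
                    recommended=recommended)
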