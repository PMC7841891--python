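"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations


def min_row_enumeration(risks, is_split, ich_split, ech_fate, mi_fate):
    """One-cycle distribution from the event-free state by explicitly
    enumerating every event branch (independent of the engine)."""
    p = {"Min": 0.0, "Mod": 0.0, "Sev": 0.0, "Death": 0.0}
    # ischemic stroke and intracranial hemorrhage
    for prob, split in ((risks.p_is, is_split), (risks.p_ich, ich_split)):
        p["Min"] += prob * split.f_light
        p["Mod"] += prob * split.f_moderate
        p["Sev"] += prob * split.f_severe
        p["Death"] += prob * split.f_die
    # two-outcome events
    for prob, fate in ((risks.p_ech, ech_fate), (risks.p_mi, mi_fate)):
        p["Min"] += prob * (1 - fate.f_die)
        p["Death"] += prob * fate.f_die
    # background mortality and staying well
    p["Death"] += risks.p_death
    p["Min"] += 1.0 - (risks.p_is + risks.p_ich + risks.p_ech
                       + risks.p_mi + risks.p_death)
    return p


def bruteforce_dominance(points: dict[str, tuple[float, float]]) -> dict[str, str]:
    """Classify each (cost, qaly) point by exhaustive search.

    Strictly dominated: another point is no worse on both axes and better
    on one.  Extendedly dominated: a convex blend of two other points
    attains the same QALYs at strictly lower cost.  Everything else is on
    the frontier.
    """
    out = {}
    items = list(points.items())
    for lab, (c, q) in items:
        strict = any(
            (c2 <= c and q2 >= q) and (c2 < c or q2 > q)
            for lab2, (c2, q2) in items if lab2 != lab
        )
        if strict:
            out[lab] = "strictly_dominated"
            continue
        extended = False
        for lab_j, (cj, qj) in items:
            if lab_j == lab:
                continue
            for lab_k, (ck, qk) in items:
                if lab_k in (lab, lab_j) or qk == qj:
                    continue
                t = (q - qj) / (qk - qj)
                if 0.0 <= t <= 1.0:
                    blend_cost = cj + t * (ck - cj)
                    if blend_cost < c:
                        extended = True
                        break
            if extended:
                break
        out[lab] = "extendedly_dominated" if extended else "on_frontier"
    return out
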