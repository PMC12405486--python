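"""Cost-effectiveness frontier: ICERs, dominance and net monetary benefit.

Strategies are sorted by cost; a strategy is absolutely dominated if some
other strategy is at most as costly and at least as effective (strictly
better on one margin), and extendedly dominated if its incremental
cost-effectiveness ratio against the previous frontier member exceeds that of
the next more effective frontier member. Along the resulting frontier, costs,
effects and ICERs all strictly increase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .engine import StrategyOutcome

ON_FRONTIER = "on_frontier"
ABSOLUTELY_DOMINATED = "absolutely_dominated"
EXTENDED_DOMINATED = "extended_dominated"


def icer(a: StrategyOutcome, b: StrategyOutcome) -> float:
    """Incremental cost per QALY of ``b`` relative to ``a``.

    Undefined (NaN) when the two strategies have equal effects; dominance
    logic, not this ratio, handles that case.
    """
    d_qalys = b.qalys - a.qalys
    d_cost = b.cost - a.cost
    if d_qalys == 0.0:
        return math.nan
    return d_cost / d_qalys


def nmb(outcome: StrategyOutcome, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold (USD/QALY)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return outcome.qalys * wtp - outcome.cost


def optimal_at_wtp(outcomes: Sequence[StrategyOutcome], wtp: float) -> int:
    """Strategy id maximizing net monetary benefit; ties go to the lower
    cost, then the lower id."""
    best = max(outcomes, key=lambda o: (nmb(o, wtp), -o.cost, -o.strategy_id))
    return best.strategy_id


@dataclass
class FrontierEntry:
    strategy_id: int
    label: str
    cost: float
    qalys: float
    classification: str
    icer: float | None  # vs previous frontier strategy; None for the cheapest

    @property
    def on_frontier(self) -> bool:
        return self.classification == ON_FRONTIER


def build_frontier(outcomes: Sequence[StrategyOutcome]) -> list[FrontierEntry]:
    """Classify strategies into frontier members and dominated strategies and
    compute frontier ICERs."""
    if len(outcomes) < 1:
        raise ValueError("need at least one outcome")
    ordered = sorted(outcomes, key=lambda o: (o.cost, -o.qalys, o.strategy_id))

    classification: dict[int, str] = {}
    for o in ordered:
        dominated = any(
            (p.cost <= o.cost and p.qalys >= o.qalys)
            and (p.cost < o.cost or p.qalys > o.qalys)
            for p in ordered
            if p is not o
        )
        if dominated:
            classification[o.strategy_id] = ABSOLUTELY_DOMINATED

    # Extended dominance: iteratively drop candidates whose incremental ratio
    # against the previous survivor exceeds the next survivor's.
    candidates = [o for o in ordered if o.strategy_id not in classification]
    while True:
        removed = False
        for j in range(1, len(candidates) - 1):
            prev, cur, nxt = candidates[j - 1], candidates[j], candidates[j + 1]
            icer_cur = icer(prev, cur)
            icer_nxt = icer(cur, nxt)
            if icer_cur > icer_nxt:
                classification[cur.strategy_id] = EXTENDED_DOMINATED
                candidates.pop(j)
                removed = True
                break
        if not removed:
            break

    entries: list[FrontierEntry] = []
    prev_front: StrategyOutcome | None = None
    for o in ordered:
        cls = classification.get(o.strategy_id, ON_FRONTIER)
        ratio: float | None = None
        if cls == ON_FRONTIER:
            if prev_front is not None and o.qalys != prev_front.qalys:
                ratio = icer(prev_front, o)
            if prev_front is None or o.qalys != prev_front.qalys:
                prev_front = o
        entries.append(
            FrontierEntry(
                strategy_id=o.strategy_id,
                label=o.label,
                cost=o.cost,
                qalys=o.qalys,
                classification=cls,
                icer=ratio,
            )
        )
    return entries


def cea_table(outcomes: Sequence[StrategyOutcome]) -> "pd.DataFrame":
    """Cost-effectiveness table: per strategy (cost-sorted) the discounted
    totals, increments against the previous non-dominated strategy, the ICER
    for frontier members and the dominance label."""
    import pandas as pd

    entries = build_frontier(outcomes)
    by_id = {o.strategy_id: o for o in outcomes}
    rows = []
    prev_front: FrontierEntry | None = None
    for e in entries:
        o = by_id[e.strategy_id]
        inc_cost = inc_q = None
        if prev_front is not None:
            inc_cost = e.cost - prev_front.cost
            inc_q = e.qalys - prev_front.qalys
        rows.append(
            {
                "strategy": e.strategy_id,
                "label": o.label,
                "cost": e.cost,
                "incremental_cost": inc_cost,
                "qalys": e.qalys,
                "incremental_qalys": inc_q,
                "icer": e.icer,
                "classification": e.classification,
            }
        )
        if e.on_frontier:
            prev_front = e
    return pd.DataFrame(rows)


def max_frontier_icer(entries: Sequence[FrontierEntry]) -> float:
    """Largest ICER along the frontier (the most effective frontier strategy
    against its frontier predecessor)."""
    icers = [e.icer for e in entries if e.on_frontier and e.icer is not None]
    if not icers:
        raise ValueError("frontier has no incremental comparisons")
    return max(icers)
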