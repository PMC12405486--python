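"""Markov cohort engine for one treat-to-target drug sequence.

The cohort is tracked on an expanded state space: disease-activity health
state crossed with treatment position. Positions are ``(line k, just_started)``
for the first cycle on drug line ``k``, ``(line k, at_target)`` for patients
who reached remission/LDA on that line and stay on it, plus the rescue-therapy
positions (off target / at target) and the absorbing dead state.

Cycle dynamics (6-month cycles):

* Death strikes first, with a per-cycle probability derived from the annual
  background rate under a constant hazard, multiplied by a disease-activity
  mortality multiplier.
* Survivors who just started line ``k`` are distributed over the four live
  states by that line's transition profile; remission/LDA landers move to the
  line's at-target position, moderate/high landers start the next line (or
  rescue after the last line).
* Survivors at target remain there with probability ``p_stay_target``
  (re-split remission:LDA 1:2) and otherwise relapse (split MDA:HDA 2:1) and
  start the next line.
* Patients who exhaust every line of a strategy move to rescue therapy
  (methotrexate + low-dose prednisolone). In the default ``one_shot`` mode
  they get a single chance (43% per base case) of reaching the target at the
  end of their first rescue cycle and are then categorized as at target or
  not for the remaining cycles, both categories absorbing (apart from
  death). The ``per_cycle`` mode instead re-applies the rescue response
  probability every cycle, optionally with relapse from the rescue target
  state.

Costs (drugs, investigations, clinic visits, one-off diagnosis/bridging and
biologic start-up panels) are billed on start-of-cycle occupancy — the
people occupying a treatment position during a cycle. QALYs accrue on the
half-cycle-corrected occupancy (trapezoid average of adjacent cycle starts).
Both are discounted at the annual rate, evaluated at cycle midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ModelConfig, StrategySpec
from .states import LIVE_STATES, HealthState

COST_CATEGORIES = ("drugs", "investigations", "visits", "diagnosis_bridging")


def annual_to_cycle_prob(p_annual: float, cycle_length: float) -> float:
    """Convert an annual event probability to a per-cycle probability under a
    constant hazard: ``1 - (1 - p)**cycle_length``."""
    if not (0.0 <= p_annual <= 1.0):
        raise ValueError(f"annual probability out of [0,1]: {p_annual}")
    return 1.0 - (1.0 - p_annual) ** cycle_length


def death_prob(state: HealthState, base_cycle_prob: float, mortality) -> float:
    """Per-cycle death probability in a live state: background cycle
    probability times the state's excess-mortality multiplier, capped at 1."""
    if state is HealthState.DEAD:
        raise ValueError("death_prob is undefined for the dead state")
    return min(1.0, mortality.smr[state] * base_cycle_prob)


# ---------------------------------------------------------------------------
# Expanded state space
# ---------------------------------------------------------------------------

JUST_STARTED = "just_started"
AT_TARGET = "at_target"
RESCUE_OFF = "rescue_off"
RESCUE_AT = "rescue_at"
RESCUE_EXHAUSTED = "rescue_exhausted"  # categorized off-target for good


@dataclass(frozen=True)
class ExpandedState:
    """Health state plus treatment position; ``line`` is None for rescue and
    for the dead state."""

    position: str  # JUST_STARTED / AT_TARGET / RESCUE_OFF / RESCUE_AT / "dead"
    line: int | None
    health: HealthState

    @property
    def at_target(self) -> bool:
        return self.position in (AT_TARGET, RESCUE_AT)


def _state_space(n_lines: int) -> list[ExpandedState]:
    states: list[ExpandedState] = []
    for k in range(n_lines):
        for h in (HealthState.MDA, HealthState.HDA):
            states.append(ExpandedState(JUST_STARTED, k, h))
        for h in (HealthState.REMISSION, HealthState.LDA):
            states.append(ExpandedState(AT_TARGET, k, h))
    for h in (HealthState.MDA, HealthState.HDA):
        states.append(ExpandedState(RESCUE_OFF, None, h))
    for h in (HealthState.REMISSION, HealthState.LDA):
        states.append(ExpandedState(RESCUE_AT, None, h))
    for h in (HealthState.MDA, HealthState.HDA):
        states.append(ExpandedState(RESCUE_EXHAUSTED, None, h))
    states.append(ExpandedState("dead", None, HealthState.DEAD))
    return states


@dataclass
class _Resolved:
    """Strategy-specific quantities resolved from the config once."""

    states: list[ExpandedState]
    index: dict[ExpandedState, int]
    dead: int
    matrix: np.ndarray
    drug_cost: np.ndarray  # per live state, USD/cycle
    continuation_cost: np.ndarray
    startup_cost: np.ndarray  # one-off, billed on just-started biologic mass
    utility: np.ndarray
    at_target_mask: np.ndarray
    cycle_death: np.ndarray


def _resolve(strategy: StrategySpec, config: ModelConfig) -> _Resolved:
    states = _state_space(len(strategy.lines))
    index = {s: i for i, s in enumerate(states)}
    dead = index[ExpandedState("dead", None, HealthState.DEAD)]
    n = len(states)

    base_q = annual_to_cycle_prob(
        config.mortality.baseline_annual_mortality.value,
        config.econ.cycle_length_years,
    )
    q = np.zeros(n)
    for s in states[:-1]:
        q[index[s]] = death_prob(s.health, base_q, config.mortality)

    p_stay = config.rules.p_stay_target.value
    w_rem, w_lda = config.rules.target_weights
    w_mda, w_hda = config.rules.nontarget_weights
    p_rescue = strategy.rescue.p_reach_target_per_cycle.value

    def next_js(k_next: int | None) -> dict[HealthState, int]:
        """Index of the off-target landing state per health, for the position
        after line ``k`` (rescue when the sequence is exhausted)."""
        out = {}
        for h in (HealthState.MDA, HealthState.HDA):
            if k_next is None:
                out[h] = index[ExpandedState(RESCUE_OFF, None, h)]
            else:
                out[h] = index[ExpandedState(JUST_STARTED, k_next, h)]
        return out

    m = np.zeros((n, n))
    m[dead, dead] = 1.0
    n_lines = len(strategy.lines)
    for s in states[:-1]:
        i = index[s]
        qi = q[i]
        m[i, dead] += qi
        live = 1.0 - qi
        if s.position == JUST_STARTED:
            k = s.line
            prof = config.drugs[strategy.lines[k].drug].profile(
                strategy.lines[k].variant
            )
            p = prof.by_state()
            m[i, index[ExpandedState(AT_TARGET, k, HealthState.REMISSION)]] += (
                live * p[HealthState.REMISSION]
            )
            m[i, index[ExpandedState(AT_TARGET, k, HealthState.LDA)]] += (
                live * p[HealthState.LDA]
            )
            nxt = next_js(k + 1 if k + 1 < n_lines else None)
            m[i, nxt[HealthState.MDA]] += live * p[HealthState.MDA]
            m[i, nxt[HealthState.HDA]] += live * p[HealthState.HDA]
        elif s.position == AT_TARGET:
            k = s.line
            m[i, index[ExpandedState(AT_TARGET, k, HealthState.REMISSION)]] += (
                live * p_stay * w_rem
            )
            m[i, index[ExpandedState(AT_TARGET, k, HealthState.LDA)]] += (
                live * p_stay * w_lda
            )
            nxt = next_js(k + 1 if k + 1 < n_lines else None)
            m[i, nxt[HealthState.MDA]] += live * (1 - p_stay) * w_mda
            m[i, nxt[HealthState.HDA]] += live * (1 - p_stay) * w_hda
        elif s.position == RESCUE_OFF:
            # End of the first rescue cycle: reach the target or (one_shot
            # mode) be categorized off-target for the remaining cycles.
            fail_pos = (
                RESCUE_EXHAUSTED
                if config.rules.rescue_mode == "one_shot"
                else RESCUE_OFF
            )
            m[i, index[ExpandedState(RESCUE_AT, None, HealthState.REMISSION)]] += (
                live * p_rescue * w_rem
            )
            m[i, index[ExpandedState(RESCUE_AT, None, HealthState.LDA)]] += (
                live * p_rescue * w_lda
            )
            m[i, index[ExpandedState(fail_pos, None, HealthState.MDA)]] += (
                live * (1 - p_rescue) * w_mda
            )
            m[i, index[ExpandedState(fail_pos, None, HealthState.HDA)]] += (
                live * (1 - p_rescue) * w_hda
            )
        elif s.position == RESCUE_AT:
            if config.rules.rescue_at_relapse:
                p_keep = p_stay
                fail_pos = (
                    RESCUE_EXHAUSTED
                    if config.rules.rescue_mode == "one_shot"
                    else RESCUE_OFF
                )
                m[i, index[ExpandedState(fail_pos, None, HealthState.MDA)]] += (
                    live * (1 - p_keep) * w_mda
                )
                m[i, index[ExpandedState(fail_pos, None, HealthState.HDA)]] += (
                    live * (1 - p_keep) * w_hda
                )
            else:
                p_keep = 1.0
            m[i, index[ExpandedState(RESCUE_AT, None, HealthState.REMISSION)]] += (
                live * p_keep * w_rem
            )
            m[i, index[ExpandedState(RESCUE_AT, None, HealthState.LDA)]] += (
                live * p_keep * w_lda
            )
        elif s.position == RESCUE_EXHAUSTED:
            m[i, index[ExpandedState(RESCUE_EXHAUSTED, None, HealthState.MDA)]] += (
                live * w_mda
            )
            m[i, index[ExpandedState(RESCUE_EXHAUSTED, None, HealthState.HDA)]] += (
                live * w_hda
            )

    drug_cost = np.zeros(n)
    contin = np.zeros(n)
    startup = np.zeros(n)
    utility = np.zeros(n)
    at_target = np.zeros(n, dtype=bool)
    cs_contin = config.costs.cs_continuation.value
    bts_contin = config.costs.bts_continuation.value
    bts_startup = config.costs.bts_startup_investigations.value
    for s in states[:-1]:
        i = index[s]
        utility[i] = config.utilities.for_state(s.health)
        at_target[i] = s.at_target
        if s.line is not None:
            drug = config.drugs[strategy.lines[s.line].drug]
            drug_cost[i] = config.line_drug_cost(drug.name)
            contin[i] = bts_contin if drug.is_biologic else cs_contin
            if drug.is_biologic and s.position == JUST_STARTED:
                startup[i] = bts_startup
        else:
            drug_cost[i] = config.rescue_drug_cost
            contin[i] = cs_contin

    return _Resolved(
        states=states,
        index=index,
        dead=dead,
        matrix=m,
        drug_cost=drug_cost,
        continuation_cost=contin,
        startup_cost=startup,
        utility=utility,
        at_target_mask=at_target,
        cycle_death=q,
    )


# ---------------------------------------------------------------------------
# Public stepping / accrual API
# ---------------------------------------------------------------------------


def initial_occupancy(strategy: StrategySpec, config: ModelConfig) -> np.ndarray:
    """Cohort start: everyone with moderate disease activity, just starting
    the first-line drug (methotrexate)."""
    res = _resolve(strategy, config)
    occ = np.zeros(len(res.states))
    occ[res.index[ExpandedState(JUST_STARTED, 0, HealthState.MDA)]] = 1.0
    return occ


def step(
    occupancy: np.ndarray,
    cycle_index: int,
    strategy: StrategySpec,
    config: ModelConfig,
) -> np.ndarray:
    """Advance the cohort one cycle (death, then transition, then switching)."""
    if cycle_index >= config.econ.n_cycles:
        raise ValueError(f"cycle_index {cycle_index} beyond horizon")
    total = float(np.sum(occupancy))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"occupancy must sum to 1, got {total!r}")
    res = _resolve(strategy, config)
    return occupancy @ res.matrix


@dataclass
class CycleLedger:
    """Undiscounted per-cycle flows, by cost category, plus QALYs."""

    cycle: int
    drugs: float
    investigations: float
    visits: float
    diagnosis_bridging: float
    qalys: float

    @property
    def cost(self) -> float:
        return self.drugs + self.investigations + self.visits + self.diagnosis_bridging


def _accrue(
    occ_start: np.ndarray,
    occ_eff: np.ndarray,
    cycle_index: int,
    res: _Resolved,
    config: ModelConfig,
) -> CycleLedger:
    """Flows for one cycle. All costs are billed on the start-of-cycle
    occupancy ``occ_start`` (the people on each treatment position during the
    cycle); QALYs accrue on the half-cycle-corrected occupancy ``occ_eff``."""
    costs = config.costs
    cycle_years = config.econ.cycle_length_years
    live_eff = occ_eff.copy()
    live_eff[res.dead] = 0.0
    live_start = occ_start.copy()
    live_start[res.dead] = 0.0

    drugs = float(live_start @ res.drug_cost)
    investigations = float(live_start @ res.continuation_cost)
    diagnosis_bridging = 0.0
    if cycle_index == 0:
        # Diagnosis work-up, bridging steroids and the first-cycle csDMARD
        # investigation panel replace the routine continuation charge.
        investigations = costs.cs_first_cycle_investigations.value * float(
            live_start.sum()
        )
        diagnosis_bridging = (costs.diagnosis.value + costs.bridging.value) * float(
            live_start.sum()
        )
    else:
        # Start-up panel for every patient newly on a biologic line this cycle.
        investigations += float(live_start @ res.startup_cost)

    visit_cost = costs.clinic_visit.value
    if cycle_index == 0:
        visits = costs.visits_first_cycle * visit_cost * float(live_start.sum())
    else:
        n_at = float(live_start[res.at_target_mask].sum())
        n_off = float(live_start.sum()) - n_at
        visits = visit_cost * (
            costs.visits_at_target * n_at + costs.visits_off_target * n_off
        )

    qalys = float(live_eff @ res.utility) * cycle_years
    return CycleLedger(
        cycle=cycle_index,
        drugs=drugs,
        investigations=investigations,
        visits=visits,
        diagnosis_bridging=diagnosis_bridging,
        qalys=qalys,
    )


def accrue_cycle(
    occupancy: np.ndarray,
    cycle_index: int,
    strategy: StrategySpec,
    config: ModelConfig,
) -> tuple[float, float]:
    """Undiscounted (cost, qalys) for one cycle evaluated on a single
    occupancy vector (no half-cycle averaging); exposed for testing and
    trace inspection."""
    res = _resolve(strategy, config)
    ledger = _accrue(occupancy, occupancy, cycle_index, res, config)
    return ledger.cost, ledger.qalys


@dataclass
class CohortTrace:
    """Cycle-start occupancy snapshots and per-cycle ledgers."""

    states: list[ExpandedState]
    occupancies: list[np.ndarray]  # length n_cycles + 1
    ledgers: list[CycleLedger]
    discount_factors: list[float]

    def occupancy_frame(self) -> pd.DataFrame:
        rows = []
        for t, occ in enumerate(self.occupancies):
            for s, mass in zip(self.states, occ):
                if mass > 0:
                    rows.append(
                        {
                            "cycle": t,
                            "position": s.position,
                            "line": -1 if s.line is None else s.line,
                            "health": s.health.value,
                            "occupancy": mass,
                        }
                    )
        return pd.DataFrame(rows)

    def ledger_frame(self) -> pd.DataFrame:
        rows = []
        for ledger, df in zip(self.ledgers, self.discount_factors):
            for cat in COST_CATEGORIES:
                rows.append(
                    {
                        "cycle": ledger.cycle,
                        "component": cat,
                        "amount": getattr(ledger, cat),
                        "discount_factor": df,
                    }
                )
            rows.append(
                {
                    "cycle": ledger.cycle,
                    "component": "qalys",
                    "amount": ledger.qalys,
                    "discount_factor": df,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class StrategyOutcome:
    """Discounted totals for one strategy over the model horizon."""

    strategy_id: int
    label: str
    cost: float
    qalys: float
    undiscounted_cost: float
    undiscounted_qalys: float
    trace: CohortTrace | None = None


def evaluate_strategy(
    strategy: StrategySpec,
    config: ModelConfig,
    keep_trace: bool = True,
) -> StrategyOutcome:
    """Run the deterministic cohort for one strategy over the full horizon."""
    res = _resolve(strategy, config)
    n_cycles = config.econ.n_cycles
    rate = config.econ.annual_discount_rate
    cycle_years = config.econ.cycle_length_years

    occ = np.zeros(len(res.states))
    occ[res.index[ExpandedState(JUST_STARTED, 0, HealthState.MDA)]] = 1.0

    occupancies = [occ]
    for _ in range(n_cycles):
        occupancies.append(occupancies[-1] @ res.matrix)

    ledgers: list[CycleLedger] = []
    dfs: list[float] = []
    cost = qalys = u_cost = u_qalys = 0.0
    for t in range(n_cycles):
        occ_start = occupancies[t]
        if config.econ.half_cycle_correction:
            occ_eff = 0.5 * (occupancies[t] + occupancies[t + 1])
        else:
            occ_eff = occ_start
        ledger = _accrue(occ_start, occ_eff, t, res, config)
        midpoint_years = (t + 0.5) * cycle_years
        df = (1.0 + rate) ** (-midpoint_years)
        ledgers.append(ledger)
        dfs.append(df)
        cost += df * ledger.cost
        qalys += df * ledger.qalys
        u_cost += ledger.cost
        u_qalys += ledger.qalys

    trace = (
        CohortTrace(res.states, occupancies, ledgers, dfs) if keep_trace else None
    )
    return StrategyOutcome(
        strategy_id=strategy.id,
        label=strategy.label,
        cost=cost,
        qalys=qalys,
        undiscounted_cost=u_cost,
        undiscounted_qalys=u_qalys,
        trace=trace,
    )


def evaluate_all(config: ModelConfig, keep_trace: bool = False) -> list[StrategyOutcome]:
    """Deterministic outcomes for every strategy in the configuration."""
    return [
        evaluate_strategy(s, config, keep_trace=keep_trace) for s in config.strategies
    ]
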