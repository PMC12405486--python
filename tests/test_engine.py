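"""Markov engine: rate conversions, cycle dynamics, accrual conventions and
a brute-force path-enumeration oracle."""

import numpy as np
import pytest

from rheumcea import (
    HealthState,
    annual_to_cycle_prob,
    death_prob,
    evaluate_all,
    evaluate_strategy,
    step,
)
from rheumcea.engine import initial_occupancy
from rheumcea.parameters import config_from_dict, config_to_dict


class TestRateConversion:
    @pytest.mark.parametrize(
        "annual,cycle,expected",
        [
            (0.0, 0.5, 0.0),
            (1.0, 0.5, 1.0),
            (0.04, 0.5, 1 - 0.96**0.5),
            (0.004, 0.5, 1 - 0.996**0.5),
        ],
    )
    def test_constant_hazard_closed_form(self, annual, cycle, expected):
        assert annual_to_cycle_prob(annual, cycle) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            annual_to_cycle_prob(1.2, 0.5)


class TestDeathProb:
    def test_activity_multipliers(self, zanzibar):
        mort = zanzibar.mortality
        assert death_prob(HealthState.LDA, 0.01, mort) == pytest.approx(0.0129)
        assert death_prob(HealthState.MDA, 0.01, mort) == pytest.approx(0.0142)
        assert death_prob(HealthState.REMISSION, 0.01, mort) == pytest.approx(0.01)

    def test_zero_base_gives_zero(self, zanzibar):
        for state in (HealthState.REMISSION, HealthState.HDA):
            assert death_prob(state, 0.0, zanzibar.mortality) == 0.0

    def test_capped_at_one(self, zanzibar):
        assert death_prob(HealthState.MDA, 0.9, zanzibar.mortality) == 1.0

    def test_dead_state_rejected(self, zanzibar):
        with pytest.raises(ValueError):
            death_prob(HealthState.DEAD, 0.01, zanzibar.mortality)


class TestStep:
    def test_first_cycle_distributes_by_methotrexate_profile(
        self, zero_mortality_config
    ):
        """From the all-moderate start, the live cohort lands on the
        first-line transition profile (0.09/0.34/0.38/0.19)."""
        cfg = zero_mortality_config
        strat = cfg.strategy(1)
        occ = initial_occupancy(strat, cfg)
        nxt = step(occ, 0, strat, cfg)
        from rheumcea.engine import _resolve

        res = _resolve(strat, cfg)
        by_health = {}
        for s, mass in zip(res.states, nxt):
            by_health[s.health] = by_health.get(s.health, 0.0) + mass
        assert by_health[HealthState.REMISSION] == pytest.approx(0.09)
        assert by_health[HealthState.LDA] == pytest.approx(0.34)
        assert by_health[HealthState.MDA] == pytest.approx(0.38)
        assert by_health[HealthState.HDA] == pytest.approx(0.19)

    def test_dead_mass_is_absorbing(self, config):
        strat = config.strategy(1)
        occ = initial_occupancy(strat, config)
        occ[:] = 0.0
        occ[-1] = 1.0  # everyone dead
        nxt = step(occ, 0, strat, config)
        assert nxt[-1] == pytest.approx(1.0)
        assert np.sum(nxt[:-1]) == pytest.approx(0.0)

    def test_invalid_occupancy_rejected(self, config):
        strat = config.strategy(1)
        occ = initial_occupancy(strat, config)
        with pytest.raises(ValueError, match="sum to 1"):
            step(occ * 0.5, 0, strat, config)

    def test_occupancy_conserved_every_cycle(self, config):
        for strat in config.strategies:
            outcome = evaluate_strategy(strat, config)
            for occ in outcome.trace.occupancies:
                assert np.sum(occ) == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Brute-force path-enumeration oracle on a two-line toy model
# ---------------------------------------------------------------------------


def _toy_config(zanzibar, n_cycles=2):
    raw = config_to_dict(zanzibar)
    raw["economics"]["horizon_years"] = n_cycles * 0.5
    raw["mortality"]["baseline_annual_mortality"]["value"] = 0.1
    raw["mortality"]["baseline_annual_mortality"]["low"] = 0.1
    raw["mortality"]["baseline_annual_mortality"]["high"] = 0.1
    raw["strategies"] = [
        {
            "id": 1,
            "label": "toy",
            "lines": [
                {"drug": "methotrexate", "profile": "early"},
                {"drug": "btsdmard1", "profile": "early"},
            ],
        }
    ]
    return config_from_dict(raw)


def _oracle_totals(cfg):
    """Independent evaluation of the toy strategy by exhaustive enumeration
    of every branch path, written directly from the stated cycle rules."""
    smr = {s: cfg.mortality.smr[s] for s in cfg.mortality.smr}
    q_base = 1 - (1 - cfg.mortality.baseline_annual_mortality.value) ** 0.5
    mtx_p = dict(
        zip("rlmh", cfg.drugs["methotrexate"].profile_early.values())
    )
    b1_p = dict(zip("rlmh", cfg.drugs["btsdmard1"].profile_early.values()))
    p_stay = cfg.rules.p_stay_target.value
    p_resc = cfg.rescue.p_reach_target_per_cycle.value
    H = {
        "r": HealthState.REMISSION,
        "l": HealthState.LDA,
        "m": HealthState.MDA,
        "h": HealthState.HDA,
    }

    def branches(state):
        """(next_state, prob) pairs; states are (position, health-letter)."""
        if state == "dead":
            return [("dead", 1.0)]
        pos, h = state
        q = min(1.0, smr[H[h]] * q_base)
        out = [("dead", q)]
        live = 1 - q

        def land_target(pos_at, pr, pl):
            return [((pos_at, "r"), live * pr), ((pos_at, "l"), live * pl)]

        def land_off(pos_next, pm, ph):
            return [((pos_next, "m"), live * pm), ((pos_next, "h"), live * ph)]

        if pos == "js0":
            out += land_target("at0", mtx_p["r"], mtx_p["l"])
            out += land_off("js1", mtx_p["m"], mtx_p["h"])
        elif pos == "at0":
            out += land_target("at0", p_stay / 3, 2 * p_stay / 3)
            out += land_off("js1", 2 * (1 - p_stay) / 3, (1 - p_stay) / 3)
        elif pos == "js1":
            out += land_target("at1", b1_p["r"], b1_p["l"])
            out += land_off("roff", b1_p["m"], b1_p["h"])
        elif pos == "at1":
            out += land_target("at1", p_stay / 3, 2 * p_stay / 3)
            out += land_off("roff", 2 * (1 - p_stay) / 3, (1 - p_stay) / 3)
        elif pos == "roff":
            out += land_target("rat", p_resc / 3, 2 * p_resc / 3)
            out += land_off("rx", 2 * (1 - p_resc) / 3, (1 - p_resc) / 3)
        elif pos == "rat":
            out += land_target("rat", 1 / 3, 2 / 3)
        elif pos == "rx":
            out += land_off("rx", 2 / 3, 1 / 3)
        return out

    costs = cfg.costs
    mtx_cost = cfg.line_drug_cost("methotrexate")
    b1_cost = cfg.line_drug_cost("btsdmard1")
    rescue_cost = cfg.rescue_drug_cost

    def cycle_cost(state, t):
        if state == "dead":
            return 0.0
        pos, _h = state
        if pos in ("js0", "at0"):
            drug, contin, bio = mtx_cost, costs.cs_continuation.value, False
        elif pos in ("js1", "at1"):
            drug, contin, bio = b1_cost, costs.bts_continuation.value, True
        else:
            drug, contin, bio = rescue_cost, costs.cs_continuation.value, False
        total = drug
        if t == 0:
            total += (
                costs.cs_first_cycle_investigations.value
                + costs.diagnosis.value
                + costs.bridging.value
                + costs.visits_first_cycle * costs.clinic_visit.value
            )
        else:
            total += contin
            if bio and pos == "js1":
                total += costs.bts_startup_investigations.value
            at = pos in ("at0", "at1", "rat")
            visits = costs.visits_at_target if at else costs.visits_off_target
            total += visits * costs.clinic_visit.value
        return total

    def utility(state):
        if state == "dead":
            return 0.0
        return cfg.utilities.for_state(H[state[1]])

    n_cycles = cfg.econ.n_cycles
    rate = cfg.econ.annual_discount_rate
    dfs = [(1 + rate) ** (-(t + 0.5) * 0.5) for t in range(n_cycles)]

    total_cost = total_qalys = 0.0

    def walk(state, t, prob):
        nonlocal total_cost, total_qalys
        if t < n_cycles:
            total_cost += prob * dfs[t] * cycle_cost(state, t)
        if t == n_cycles:
            return
        for nxt, p in branches(state):
            if p <= 0:
                continue
            # trapezoid half-cycle correction on utilities
            total_qalys += (
                prob * p * dfs[t] * 0.5 * (utility(state) + utility(nxt)) * 0.5
            )
            walk(nxt, t + 1, prob * p)

    walk(("js0", "m"), 0, 1.0)
    return total_cost, total_qalys


class TestPathEnumerationOracle:
    @pytest.mark.parametrize("n_cycles", [2, 3])
    def test_engine_matches_exhaustive_path_sum(self, zanzibar, n_cycles):
        cfg = _toy_config(zanzibar, n_cycles)
        outcome = evaluate_strategy(cfg.strategies[0], cfg, keep_trace=False)
        oracle_cost, oracle_qalys = _oracle_totals(cfg)
        assert outcome.cost == pytest.approx(oracle_cost, rel=1e-12)
        assert outcome.qalys == pytest.approx(oracle_qalys, rel=1e-12)


class TestAccrualConventions:
    def test_first_cycle_visit_component(self, config):
        """Four first-cycle visits at 4 USD each: 16 USD per patient."""
        outcome = evaluate_strategy(config.strategy(1), config)
        assert outcome.trace.ledgers[0].visits == pytest.approx(16.0)

    def test_remission_cycle_qaly_contribution(self, config):
        assert config.utilities.for_state(HealthState.REMISSION) * 0.5 == pytest.approx(
            0.435
        )

    def test_discount_factors_evaluated_at_cycle_midpoints(self, config):
        outcome = evaluate_strategy(config.strategy(1), config)
        # cycle 5 spans years 2.5-3.0; its midpoint discount is 1.03^-2.75
        assert outcome.trace.discount_factors[5] == pytest.approx(1.03**-2.75)
        assert outcome.trace.discount_factors[0] == pytest.approx(1.03**-0.25)

    def test_zero_utilities_give_zero_qalys(self, config):
        for name in ("remission", "lda", "mda", "hda", "target", "nontarget"):
            p = getattr(config.utilities, name)
            p.value = p.low = p.high = 0.0
        for o in evaluate_all(config):
            assert o.qalys == 0.0

    def test_discounted_not_above_undiscounted(self, config):
        for o in evaluate_all(config):
            assert o.cost <= o.undiscounted_cost
            assert o.qalys <= o.undiscounted_qalys

    def test_zero_discount_never_decreases_totals(self, config):
        base = evaluate_all(config)
        config.econ.annual_discount_rate = 0.0
        undisc = evaluate_all(config)
        for a, b in zip(base, undisc):
            assert b.cost >= a.cost
            assert b.qalys >= a.qalys

    def test_removing_excess_mortality_never_decreases_qalys(self, config):
        base = evaluate_all(config)
        config.mortality.smr = {s: 1.0 for s in config.mortality.smr}
        flat = evaluate_all(config)
        for a, b in zip(base, flat):
            assert b.qalys >= a.qalys


class TestStrategyOrdering:
    def test_qaly_and_cost_ordering(self, zanzibar):
        """More/earlier treatment options never hurt effectiveness; the
        two-biologic strategy is the costliest."""
        out = {o.strategy_id: o for o in evaluate_all(zanzibar)}
        assert out[6].qalys >= out[3].qalys >= out[1].qalys
        assert all(out[6].cost >= o.cost for o in out.values())

    def test_per_cycle_rescue_mode_runs_and_conserves(self, config):
        config.rules.rescue_mode = "per_cycle"
        config.rules.rescue_at_relapse = True
        for o in evaluate_all(config, keep_trace=True):
            for occ in o.trace.occupancies:
                assert np.sum(occ) == pytest.approx(1.0, abs=1e-9)
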