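"""Deterministic and probabilistic sensitivity analyses.

* One-way (tornado) analysis: re-evaluate a strategy pair with one parameter
  at its low / high bound, all else at base, and report the ICER swing.
* Probabilistic sensitivity analysis: joint independent parameter draws —
  costs from gamma, probabilities from beta, utilities from (truncated)
  normal distributions, each matched by method of moments to the point
  estimate and its deterministic range interpreted as a 95% interval — with
  all six strategies evaluated per draw under common random numbers.
* CEAC and pairwise incremental scatter summaries of the PSA samples.
* Price-threshold search: bisection on one drug's per-cycle price until the
  pairwise ICER equals the willingness-to-pay threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import StrategyOutcome, evaluate_all, evaluate_strategy
from .frontier import icer as icer_of
from .parameters import (
    ModelConfig,
    UncertainParameter,
    uncertainty_parameters,
)
_Z95 = 1.959963984540054  # normal 97.5% quantile


# ---------------------------------------------------------------------------
# Distribution fitting
# ---------------------------------------------------------------------------


@dataclass
class FittedDistribution:
    """Seeded sampler for one uncertain parameter.

    Gamma and beta are parameterized by matching the mean to the point
    estimate and the SD to (high - low) / (2 * 1.96); normal uses the same
    moments directly. A degenerate range yields a point mass.
    """

    name: str
    family: str  # gamma / beta / normal / point
    mean: float
    sd: float
    shape_a: float = 0.0
    shape_b: float = 0.0

    def rvs(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        if self.family == "point":
            return np.full(size, self.mean) if size else self.mean
        if self.family == "gamma":
            return rng.gamma(self.shape_a, self.shape_b, size=size)
        if self.family == "beta":
            return rng.beta(self.shape_a, self.shape_b, size=size)
        return rng.normal(self.mean, self.sd, size=size)


def fit_distribution(
    point: float, low: float, high: float, family: str, name: str = ""
) -> FittedDistribution:
    """Fit the PSA sampling distribution for one parameter."""
    if high < low:
        raise ValueError(f"{name}: high < low")
    sd = (high - low) / (2 * _Z95)
    if sd == 0.0 or point == 0.0 and family in ("gamma", "beta"):
        return FittedDistribution(name, "point", point, 0.0)
    if family == "gamma":
        if point < 0:
            raise ValueError(f"{name}: gamma requires a non-negative point estimate")
        shape = (point / sd) ** 2
        scale = sd**2 / point
        return FittedDistribution(name, "gamma", point, sd, shape, scale)
    if family == "beta":
        if not (0.0 < point < 1.0):
            raise ValueError(f"{name}: beta requires a point estimate in (0,1)")
        nu = point * (1 - point) / sd**2 - 1.0
        if nu <= 0:
            raise ValueError(
                f"{name}: SD {sd:.4g} too large for a beta with mean {point:.4g}"
            )
        return FittedDistribution(name, "beta", point, sd, point * nu, (1 - point) * nu)
    if family == "normal":
        return FittedDistribution(name, "normal", point, sd)
    raise ValueError(f"{name}: unknown distribution family {family!r}")


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity (tornado)
# ---------------------------------------------------------------------------


@dataclass
class TornadoEntry:
    parameter: str
    pair: tuple[int, int]
    icer_base: float
    icer_at_low: float
    icer_at_high: float
    non_monotone: bool

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _pair_icer(config: ModelConfig, pair: tuple[int, int]) -> float:
    a = evaluate_strategy(config.strategy(pair[0]), config, keep_trace=False)
    b = evaluate_strategy(config.strategy(pair[1]), config, keep_trace=False)
    return icer_of(a, b)


def owsa(
    config: ModelConfig,
    params: Sequence[str],
    pair: tuple[int, int],
) -> list[TornadoEntry]:
    """One-way sensitivity of a pairwise ICER to each named parameter.

    Each parameter is set to its low and high bound in turn (everything else
    at base); entries come back sorted by ICER swing, largest first.
    """
    registry = uncertainty_parameters(config)
    base_icer = _pair_icer(config, pair)
    entries = []
    for name in params:
        try:
            p = registry[name]
        except KeyError:
            raise KeyError(f"unknown uncertain parameter {name!r}") from None
        low, high = p.bounds(config)
        icers = []
        for bound in (low, high):
            cfg = config.copy()
            uncertainty_parameters(cfg)[name].set(cfg, bound)
            icers.append(_pair_icer(cfg, pair))
        lo_icer, hi_icer = icers
        non_monotone = not (
            min(lo_icer, hi_icer) - 1e-9 <= base_icer <= max(lo_icer, hi_icer) + 1e-9
        )
        entries.append(
            TornadoEntry(
                parameter=name,
                pair=pair,
                icer_base=base_icer,
                icer_at_low=lo_icer,
                icer_at_high=hi_icer,
                non_monotone=non_monotone,
            )
        )
    entries.sort(key=lambda e: e.spread, reverse=True)
    return entries


def default_owsa_parameters(config: ModelConfig) -> list[str]:
    """The key inputs varied in the tornado: drug prices, other unit costs,
    band utilities and the sequencing probabilities."""
    names = [f"cost.{c}" for c in config.drug_prices]
    names += [
        "cost.diagnosis",
        "cost.bridging",
        "cost.cs_first_cycle_investigations",
        "cost.cs_continuation",
        "cost.bts_startup_investigations",
        "cost.bts_continuation",
        "cost.clinic_visit",
        "utility.remission",
        "utility.lda",
        "utility.mda",
        "utility.hda",
        "prob.p_stay_target",
        "prob.rescue_target",
    ]
    return names


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "icer_base": e.icer_base,
                "icer_at_low": e.icer_at_low,
                "icer_at_high": e.icer_at_high,
                "spread": e.spread,
                "non_monotone": e.non_monotone,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PSAResult:
    """Per-iteration (cost, QALY) outcomes for every strategy."""

    strategy_ids: list[int]
    costs: np.ndarray  # (n_iterations, n_strategies)
    qalys: np.ndarray
    seed: int

    @property
    def n_iterations(self) -> int:
        return self.costs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it in range(self.n_iterations):
            for j, sid in enumerate(self.strategy_ids):
                rows.append(
                    {
                        "iteration": it,
                        "strategy": sid,
                        "cost": self.costs[it, j],
                        "qalys": self.qalys[it, j],
                    }
                )
        return pd.DataFrame(rows)

    def optimal_share(self, wtp: float) -> dict[int, float]:
        """Fraction of iterations each strategy maximizes net monetary
        benefit at the given threshold (ties go to the column listed first,
        i.e. to the cheaper base-case strategy)."""
        nmb_matrix = self.qalys * wtp - self.costs
        winners = np.argmax(nmb_matrix, axis=1)
        return {
            sid: float(np.mean(winners == j))
            for j, sid in enumerate(self.strategy_ids)
        }


def _scalar_draw_params(
    registry: dict[str, UncertainParameter],
) -> list[str]:
    # Profile cells are drawn jointly per profile (then renormalized), not
    # through the scalar pass.
    return [n for n in registry if not n.startswith("prob.profile.")]


def run_psa(
    config: ModelConfig,
    n_iterations: int = 10_000,
    seed: int = 1,
    profile_sampling: str = "independent_beta",
) -> PSAResult:
    """Monte-Carlo PSA: draw all parameters jointly and independently,
    evaluate all strategies deterministically per draw.

    Transition profiles are sampled per state from beta distributions and
    renormalized to sum to one (``profile_sampling='dirichlet'`` draws the
    whole row from a moment-matched Dirichlet instead). Utility draws are
    truncated to [0, 1]. Reproducible given the seed.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if profile_sampling not in ("independent_beta", "dirichlet"):
        raise ValueError(f"unknown profile_sampling {profile_sampling!r}")
    rng = np.random.default_rng(seed)
    registry = uncertainty_parameters(config)
    scalar_names = _scalar_draw_params(registry)

    # Pre-draw all scalar parameters as (n_iterations,) arrays.
    draws: dict[str, np.ndarray] = {}
    for name in scalar_names:
        p = registry[name]
        low, high = p.bounds(config)
        dist = fit_distribution(p.point(config), low, high, p.family, name)
        values = np.asarray(dist.rvs(rng, n_iterations), dtype=float)
        if name.startswith("utility."):
            values = np.clip(values, 0.0, 1.0)
        elif p.family == "beta":
            values = np.clip(values, 0.0, 1.0)
        draws[name] = values

    # Pre-draw transition profiles per drug/variant.
    profile_keys: list[tuple[str, str]] = []
    for drug_name, drug in config.drugs.items():
        variants = ["early"]
        if drug.profile_late.values() != drug.profile_early.values():
            variants.append("late")
        for v in variants:
            profile_keys.append((drug_name, v))
    profile_draws: dict[tuple[str, str], np.ndarray] = {}
    for drug_name, variant in profile_keys:
        prof = config.drugs[drug_name].profile(variant)
        cells = np.empty((n_iterations, 4))
        if profile_sampling == "dirichlet":
            mean = np.array(prof.values())
            sd0 = (prof.probs()[0].high - prof.probs()[0].low) / (2 * _Z95)
            conc = mean[0] * (1 - mean[0]) / sd0**2 - 1.0
            cells = rng.dirichlet(mean * conc, size=n_iterations)
        else:
            for j, p in enumerate(prof.probs()):
                dist = fit_distribution(
                    p.value, p.low, p.high, "beta",
                    f"profile.{drug_name}.{variant}",
                )
                cells[:, j] = np.asarray(dist.rvs(rng, n_iterations), dtype=float)
            cells /= cells.sum(axis=1, keepdims=True)
        profile_draws[(drug_name, variant)] = cells

    # Order strategies by base-case cost so that argmax tie-breaking in
    # optimal_share favors the cheaper strategy.
    base = evaluate_all(config)
    order = sorted(range(len(base)), key=lambda j: (base[j].cost, base[j].strategy_id))
    strategies = [config.strategies[j] for j in order]
    ids = [s.id for s in strategies]

    costs = np.empty((n_iterations, len(strategies)))
    qalys = np.empty((n_iterations, len(strategies)))
    for it in range(n_iterations):
        cfg = config.copy()
        reg = uncertainty_parameters(cfg)
        for name in scalar_names:
            reg[name].set(cfg, float(draws[name][it]))
        for (drug_name, variant), cells in profile_draws.items():
            prof = cfg.drugs[drug_name].profile(variant)
            row = cells[it]
            for p, v in zip(prof.probs(), row):
                p.value = float(v)
        for j, strat in enumerate(strategies):
            out = evaluate_strategy(cfg.strategy(strat.id), cfg, keep_trace=False)
            costs[it, j] = out.cost
            qalys[it, j] = out.qalys
    return PSAResult(strategy_ids=ids, costs=costs, qalys=qalys, seed=seed)


# ---------------------------------------------------------------------------
# CEAC and pairwise scatter
# ---------------------------------------------------------------------------


def ceac(samples: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: probability each strategy is
    optimal (max net monetary benefit) at each willingness-to-pay value."""
    if samples.n_iterations == 0:
        raise ValueError("empty PSA sample")
    rows = []
    for wtp in wtp_grid:
        share = samples.optimal_share(wtp)
        for sid, prob in share.items():
            rows.append({"wtp": wtp, "strategy": sid, "p_optimal": prob})
    return pd.DataFrame(rows)


def ceac_crossover(
    frame: pd.DataFrame, a: int, b: int
) -> float | None:
    """Smallest WTP on the grid where strategy ``b`` overtakes ``a`` on the
    acceptability curve, or None if it never does."""
    for wtp, sub in frame.groupby("wtp"):
        pa = float(sub.loc[sub["strategy"] == a, "p_optimal"].iloc[0])
        pb = float(sub.loc[sub["strategy"] == b, "p_optimal"].iloc[0])
        if pb > pa:
            return float(wtp)
    return None


@dataclass
class ScatterSummary:
    pair: tuple[int, int]
    wtp: float
    points: pd.DataFrame  # columns d_cost, d_qalys
    share_favoring: float  # fraction of iterations with positive incremental NMB


def pairwise_scatter(
    samples: PSAResult, pair: tuple[int, int], wtp: float
) -> ScatterSummary:
    """Incremental (cost, QALY) cloud of ``pair[1]`` vs ``pair[0]`` and the
    share of iterations in which the second strategy is cost-effective at the
    threshold (incremental net monetary benefit > 0)."""
    ja = samples.strategy_ids.index(pair[0])
    jb = samples.strategy_ids.index(pair[1])
    d_cost = samples.costs[:, jb] - samples.costs[:, ja]
    d_q = samples.qalys[:, jb] - samples.qalys[:, ja]
    inmb = d_q * wtp - d_cost
    return ScatterSummary(
        pair=pair,
        wtp=wtp,
        points=pd.DataFrame({"d_cost": d_cost, "d_qalys": d_q}),
        share_favoring=float(np.mean(inmb > 0)),
    )


# ---------------------------------------------------------------------------
# Price-threshold analysis
# ---------------------------------------------------------------------------


@dataclass
class PriceThresholdResult:
    drug: str
    pair: tuple[int, int]
    wtp: float
    threshold_price: float | None  # USD per 6 months; None if unattainable
    icer_at_threshold: float | None
    base_price: float


def _with_line_price(config: ModelConfig, drug: str, price: float) -> ModelConfig:
    """Clone the config with one drug line's per-cycle cost set to ``price``
    (components scaled proportionally; other lines sharing a component keep
    their base prices via an override)."""
    cfg = config.copy()
    cfg.drugs[drug].cost_override = price
    return cfg


def price_threshold(
    config: ModelConfig,
    drug: str,
    pair: tuple[int, int],
    wtp: float,
    tol: float = 0.5,
    max_iter: int = 200,
) -> PriceThresholdResult:
    """Bisection on one drug's per-cycle price until the pairwise ICER equals
    the willingness-to-pay threshold (within ``tol`` USD/QALY).

    Returns ``threshold_price=None`` when even a free drug leaves the ICER
    above the threshold.
    """
    if drug not in config.drugs:
        raise KeyError(f"unknown drug {drug!r}")
    base_outs = {
        sid: evaluate_strategy(config.strategy(sid), config, keep_trace=False)
        for sid in pair
    }
    more_effective = max(pair, key=lambda sid: base_outs[sid].qalys)
    uses = any(
        ln.drug == drug for ln in config.strategy(more_effective).lines
    )
    if not uses:
        raise ValueError(
            f"drug {drug!r} is not used by the more effective strategy "
            f"{more_effective} of pair {pair}"
        )
    base_price = config.line_drug_cost(drug)

    def icer_at(price: float) -> float:
        cfg = _with_line_price(config, drug, price)
        a = evaluate_strategy(cfg.strategy(pair[0]), cfg, keep_trace=False)
        b = evaluate_strategy(cfg.strategy(pair[1]), cfg, keep_trace=False)
        return icer_of(a, b)

    lo, hi = 0.0, base_price
    icer_lo = icer_at(lo)
    if icer_lo > wtp:
        return PriceThresholdResult(drug, pair, wtp, None, None, base_price)
    icer_hi = icer_at(hi)
    while icer_hi < wtp:  # threshold above the current price: expand bracket
        hi *= 2.0
        icer_hi = icer_at(hi)
        if hi > 1e7:
            raise RuntimeError("price bracket expansion failed")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        icer_mid = icer_at(mid)
        if abs(icer_mid - wtp) <= tol:
            return PriceThresholdResult(drug, pair, wtp, mid, icer_mid, base_price)
        if icer_mid < wtp:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    return PriceThresholdResult(drug, pair, wtp, mid, icer_at(mid), base_price)
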