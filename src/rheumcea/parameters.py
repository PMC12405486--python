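"""Model parameters: schema, validation, YAML I/O and bundled parameter sets.

The model is parameterized by

* component drug prices (USD per 6-month cycle) from which per-line drug
  costs are assembled (triple therapy = methotrexate + sulfasalazine +
  hydroxychloroquine; rescue = methotrexate + low-dose prednisolone bundle),
* non-drug unit costs (diagnosis work-up, bridging steroids, investigation
  panels, clinic visits),
* per-drug transition profiles: the distribution over the four live
  disease-activity states reached six months after starting that drug,
* CDAI-band utility weights derived from EQ-5D-5L,
* background mortality with disease-activity mortality multipliers,
* treat-to-target sequencing rules (probability of remaining at target,
  remission:LDA and MDA:HDA split ratios), and
* economic settings (cycle length, horizon, discount rate, WTP thresholds).

Every uncertain scalar carries a (value, low, high) triple; the registry in
:func:`uncertainty_parameters` maps flat parameter names onto config slots so
one-way and probabilistic sensitivity analyses can perturb them uniformly.

Three parameter sets ship with the package: ``zanzibar`` (base case) and the
``india`` / ``scandinavia`` price scenarios, which differ from the base case
only in component drug prices.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Literal

import yaml

from .states import LIVE_STATES, HealthState

BUNDLED_SCENARIOS = ("zanzibar", "india", "scandinavia")

_PROB_SUM_TOL = 1e-9


class ConfigError(ValueError):
    """Raised when a parameter file violates the documented schema."""


@dataclass
class Param:
    """A scalar parameter with its deterministic sensitivity range."""

    value: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.value <= self.high):
            raise ConfigError(
                f"range must satisfy low <= value <= high, got "
                f"({self.low}, {self.value}, {self.high})"
            )

    @classmethod
    def fixed(cls, value: float) -> "Param":
        return cls(value, value, value)

    @classmethod
    def pct(cls, value: float, rel: float) -> "Param":
        """Symmetric relative range, e.g. ``pct(45, 0.5)`` for +/-50%."""
        return cls(value, value * (1 - rel), value * (1 + rel))


@dataclass
class TransitionProfile:
    """Distribution over live disease-activity states 6 months after
    starting a drug line (one row of the effectiveness table)."""

    p_remission: Param
    p_lda: Param
    p_mda: Param
    p_hda: Param

    def __post_init__(self) -> None:
        total = sum(p.value for p in self.probs())
        if abs(total - 1.0) > _PROB_SUM_TOL:
            raise ConfigError(
                f"transition profile probabilities must sum to 1, got {total!r}"
            )
        for p in self.probs():
            if not (0.0 <= p.value <= 1.0):
                raise ConfigError(f"transition probability out of [0,1]: {p.value}")

    def probs(self) -> tuple[Param, Param, Param, Param]:
        return (self.p_remission, self.p_lda, self.p_mda, self.p_hda)

    def values(self) -> tuple[float, float, float, float]:
        return tuple(p.value for p in self.probs())  # type: ignore[return-value]

    @property
    def p_target(self) -> float:
        return self.p_remission.value + self.p_lda.value

    def by_state(self) -> dict[HealthState, float]:
        return dict(zip(LIVE_STATES, self.values()))


@dataclass
class DrugLine:
    """One drug line of a strategy.

    ``price_components`` name entries of ``ModelConfig.drug_prices`` whose sum
    is the per-cycle drug cost; ``profile_late`` applies when the line comes
    after triple-therapy failure and equals ``profile_early`` for csDMARDs.
    ``cost_override`` pins the line's total per-cycle cost regardless of
    component prices (used by the price-threshold search).
    """

    name: str
    price_components: list[str]
    is_biologic: bool
    profile_early: TransitionProfile
    profile_late: TransitionProfile
    cost_override: float | None = None

    def profile(self, variant: str) -> TransitionProfile:
        if variant == "early":
            return self.profile_early
        if variant == "late":
            return self.profile_late
        raise ConfigError(f"unknown profile variant {variant!r} for drug {self.name}")


@dataclass
class StrategyLine:
    drug: str
    variant: Literal["early", "late"] = "early"


@dataclass
class RescueSpec:
    """Rescue therapy (methotrexate + low-dose prednisolone) taken after all
    strategy lines have failed."""

    price_components: list[str]
    p_reach_target_per_cycle: Param

    def __post_init__(self) -> None:
        p = self.p_reach_target_per_cycle
        if not (0.0 <= p.value <= 1.0):
            raise ConfigError(f"rescue target probability out of [0,1]: {p.value}")


@dataclass
class StrategySpec:
    id: int
    label: str
    lines: list[StrategyLine]
    rescue: RescueSpec

    def __post_init__(self) -> None:
        if not self.lines:
            raise ConfigError(f"strategy {self.id}: line list must be non-empty")
        if self.lines[0].drug != "methotrexate":
            raise ConfigError(
                f"strategy {self.id}: first line must be methotrexate, "
                f"got {self.lines[0].drug!r}"
            )


@dataclass
class CostSet:
    """Non-drug unit costs (USD) and the clinic visit schedule."""

    diagnosis: Param
    bridging: Param
    cs_first_cycle_investigations: Param
    cs_continuation: Param
    bts_startup_investigations: Param
    bts_continuation: Param
    clinic_visit: Param
    visits_first_cycle: int
    visits_at_target: int
    visits_off_target: int

    def __post_init__(self) -> None:
        for name in (
            "diagnosis",
            "bridging",
            "cs_first_cycle_investigations",
            "cs_continuation",
            "bts_startup_investigations",
            "bts_continuation",
            "clinic_visit",
        ):
            if getattr(self, name).value < 0:
                raise ConfigError(f"cost {name!r} must be >= 0")
        if self.visits_first_cycle < self.visits_off_target:
            raise ConfigError(
                "visits_first_cycle must be >= visits_off_target "
                f"({self.visits_first_cycle} < {self.visits_off_target})"
            )


@dataclass
class UtilitySet:
    """Utility weights per CDAI band (QALY/year); dead is fixed at 0.

    ``target`` / ``nontarget`` are the pooled two-level alternatives; the
    engine uses the four band utilities unless ``use_pooled_target_utilities``
    is set.
    """

    remission: Param
    lda: Param
    mda: Param
    hda: Param
    target: Param
    nontarget: Param
    use_pooled_target_utilities: bool = False

    def __post_init__(self) -> None:
        vals = [self.hda.value, self.mda.value, self.lda.value, self.remission.value]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ConfigError(
                "utilities must be ordered hda <= mda <= lda <= remission, "
                f"got {vals}"
            )

    def for_state(self, state: HealthState) -> float:
        if state is HealthState.DEAD:
            return 0.0
        if self.use_pooled_target_utilities:
            return self.target.value if state.at_target else self.nontarget.value
        return getattr(self, state.value).value


@dataclass
class MortalitySpec:
    """Background mortality plus excess-mortality multipliers by band."""

    baseline_annual_mortality: Param
    smr: dict[HealthState, float]

    def __post_init__(self) -> None:
        if not (0.0 <= self.baseline_annual_mortality.value < 1.0):
            raise ConfigError("baseline_annual_mortality must lie in [0, 1)")
        for state in LIVE_STATES:
            if state not in self.smr:
                raise ConfigError(f"mortality multiplier missing for state {state.value}")
            if self.smr[state] < 1.0:
                raise ConfigError(
                    f"mortality multiplier for {state.value} must be >= 1"
                )


@dataclass
class SequencingRules:
    """Treat-to-target sequencing assumptions.

    ``rescue_mode`` controls what happens after all strategy lines fail:
    ``one_shot`` (default) gives patients entering rescue therapy a single
    chance (``p_reach_target_per_cycle``) at the end of their first rescue
    cycle, after which they are categorized as at target or not for the
    remaining cycles; ``per_cycle`` re-applies that probability every cycle.
    ``rescue_at_relapse`` lets at-target rescue patients relapse with
    probability ``1 - p_stay_target`` (default: the at-target category is
    absorbing once options are exhausted).
    """

    p_stay_target: Param
    target_split: tuple[float, float]  # remission : LDA
    nontarget_split: tuple[float, float]  # MDA : HDA
    rescue_mode: str = "one_shot"
    rescue_at_relapse: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_stay_target.value <= 1.0):
            raise ConfigError("p_stay_target must lie in [0,1]")
        if self.rescue_mode not in ("one_shot", "per_cycle"):
            raise ConfigError(
                f"rescue_mode must be 'one_shot' or 'per_cycle', got "
                f"{self.rescue_mode!r}"
            )
        for name in ("target_split", "nontarget_split"):
            ratio = getattr(self, name)
            if len(ratio) != 2 or min(ratio) <= 0:
                raise ConfigError(f"{name} must be two positive weights, got {ratio}")

    @property
    def target_weights(self) -> tuple[float, float]:
        a, b = self.target_split
        return a / (a + b), b / (a + b)

    @property
    def nontarget_weights(self) -> tuple[float, float]:
        a, b = self.nontarget_split
        return a / (a + b), b / (a + b)


@dataclass
class EconSettings:
    cycle_length_years: float = 0.5
    horizon_years: float = 3.0
    annual_discount_rate: float = 0.03
    wtp_thresholds: list[float] = field(default_factory=lambda: [282.0, 1136.0, 2272.0])
    half_cycle_correction: bool = True

    def __post_init__(self) -> None:
        if self.annual_discount_rate < 0:
            raise ConfigError("annual_discount_rate must be >= 0")
        n = self.horizon_years / self.cycle_length_years
        if abs(n - round(n)) > 1e-9:
            raise ConfigError(
                "horizon_years must be an integer multiple of cycle_length_years"
            )

    @property
    def n_cycles(self) -> int:
        return round(self.horizon_years / self.cycle_length_years)


@dataclass
class ModelConfig:
    """Complete, validated parameter set for the six-strategy model."""

    drug_prices: dict[str, Param]
    drugs: dict[str, DrugLine]
    rescue: RescueSpec
    strategies: list[StrategySpec]
    costs: CostSet
    utilities: UtilitySet
    mortality: MortalitySpec
    rules: SequencingRules
    econ: EconSettings

    def __post_init__(self) -> None:
        for drug in self.drugs.values():
            for comp in drug.price_components:
                if comp not in self.drug_prices:
                    raise ConfigError(
                        f"drug {drug.name!r} references unknown price component {comp!r}"
                    )
        for comp in self.rescue.price_components:
            if comp not in self.drug_prices:
                raise ConfigError(f"rescue references unknown price component {comp!r}")
        for strat in self.strategies:
            for line in strat.lines:
                if line.drug not in self.drugs:
                    raise ConfigError(
                        f"strategy {strat.id} references undefined drug {line.drug!r}"
                    )

    # -- derived costs ----------------------------------------------------
    def line_drug_cost(self, drug: str) -> float:
        line = self.drugs[drug]
        if line.cost_override is not None:
            return line.cost_override
        return sum(self.drug_prices[c].value for c in line.price_components)

    @property
    def rescue_drug_cost(self) -> float:
        return sum(self.drug_prices[c].value for c in self.rescue.price_components)

    def strategy(self, strategy_id: int) -> StrategySpec:
        for s in self.strategies:
            if s.id == strategy_id:
                return s
        raise KeyError(f"no strategy with id {strategy_id}")

    def copy(self) -> "ModelConfig":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# YAML (de)serialization
# ---------------------------------------------------------------------------


def _param(node: object, key: str) -> Param:
    if isinstance(node, (int, float)):
        return Param.fixed(float(node))
    if isinstance(node, dict):
        try:
            return Param(float(node["value"]), float(node["low"]), float(node["high"]))
        except KeyError as exc:
            raise ConfigError(f"{key}: missing field {exc.args[0]!r}") from None
        except ConfigError as exc:
            raise ConfigError(f"{key}: {exc}") from None
    raise ConfigError(f"{key}: expected number or {{value, low, high}}, got {node!r}")


def _profile(node: dict, key: str) -> TransitionProfile:
    try:
        probs = {
            s: _param(node[s.value], f"{key}.{s.value}")
            for s in LIVE_STATES
        }
    except KeyError as exc:
        raise ConfigError(f"{key}: missing state {exc.args[0]!r}") from None
    try:
        return TransitionProfile(
            probs[HealthState.REMISSION],
            probs[HealthState.LDA],
            probs[HealthState.MDA],
            probs[HealthState.HDA],
        )
    except ConfigError as exc:
        raise ConfigError(f"{key}: {exc}") from None


def config_from_dict(raw: dict) -> ModelConfig:
    """Build and validate a :class:`ModelConfig` from parsed YAML."""

    def section(name: str) -> dict:
        try:
            node = raw[name]
        except KeyError:
            raise ConfigError(f"missing config section {name!r}") from None
        if not isinstance(node, dict) and name != "strategies":
            raise ConfigError(f"section {name!r} must be a mapping")
        return node

    drug_prices = {
        name: _param(node, f"drug_prices.{name}")
        for name, node in section("drug_prices").items()
    }

    drugs: dict[str, DrugLine] = {}
    for name, node in section("drugs").items():
        key = f"drugs.{name}"
        if "profile" in node:
            early = late = _profile(node["profile"], f"{key}.profile")
        else:
            try:
                early = _profile(node["profile_early"], f"{key}.profile_early")
                late = _profile(node["profile_late"], f"{key}.profile_late")
            except KeyError as exc:
                raise ConfigError(f"{key}: missing {exc.args[0]!r}") from None
        drugs[name] = DrugLine(
            name=name,
            price_components=list(node["price_components"]),
            is_biologic=bool(node.get("is_biologic", False)),
            profile_early=early,
            profile_late=late,
        )

    rnode = section("rescue")
    rescue = RescueSpec(
        price_components=list(rnode["price_components"]),
        p_reach_target_per_cycle=_param(
            rnode["p_reach_target_per_cycle"], "rescue.p_reach_target_per_cycle"
        ),
    )

    strategies = []
    for snode in raw.get("strategies", []):
        lines = [
            StrategyLine(drug=ln["drug"], variant=ln.get("profile", "early"))
            for ln in snode["lines"]
        ]
        strategies.append(
            StrategySpec(
                id=int(snode["id"]),
                label=str(snode["label"]),
                lines=lines,
                rescue=rescue,
            )
        )
    if not strategies:
        raise ConfigError("config defines no strategies")

    cnode = section("costs")
    costs = CostSet(
        diagnosis=_param(cnode["diagnosis"], "costs.diagnosis"),
        bridging=_param(cnode["bridging"], "costs.bridging"),
        cs_first_cycle_investigations=_param(
            cnode["cs_first_cycle_investigations"],
            "costs.cs_first_cycle_investigations",
        ),
        cs_continuation=_param(cnode["cs_continuation"], "costs.cs_continuation"),
        bts_startup_investigations=_param(
            cnode["bts_startup_investigations"], "costs.bts_startup_investigations"
        ),
        bts_continuation=_param(cnode["bts_continuation"], "costs.bts_continuation"),
        clinic_visit=_param(cnode["clinic_visit"], "costs.clinic_visit"),
        visits_first_cycle=int(cnode["visits_first_cycle"]),
        visits_at_target=int(cnode["visits_at_target"]),
        visits_off_target=int(cnode["visits_off_target"]),
    )

    unode = section("utilities")
    utilities = UtilitySet(
        remission=_param(unode["remission"], "utilities.remission"),
        lda=_param(unode["lda"], "utilities.lda"),
        mda=_param(unode["mda"], "utilities.mda"),
        hda=_param(unode["hda"], "utilities.hda"),
        target=_param(unode["target"], "utilities.target"),
        nontarget=_param(unode["nontarget"], "utilities.nontarget"),
        use_pooled_target_utilities=bool(
            unode.get("use_pooled_target_utilities", False)
        ),
    )

    mnode = section("mortality")
    mortality = MortalitySpec(
        baseline_annual_mortality=_param(
            mnode["baseline_annual_mortality"], "mortality.baseline_annual_mortality"
        ),
        smr={HealthState(k): float(v) for k, v in mnode["smr"].items()},
    )

    rlnode = section("rules")
    rules = SequencingRules(
        p_stay_target=_param(rlnode["p_stay_target"], "rules.p_stay_target"),
        target_split=tuple(rlnode.get("target_split", [1, 2])),
        nontarget_split=tuple(rlnode.get("nontarget_split", [2, 1])),
        rescue_mode=str(rlnode.get("rescue_mode", "one_shot")),
        rescue_at_relapse=bool(rlnode.get("rescue_at_relapse", False)),
    )

    enode = raw.get("economics", {})
    econ = EconSettings(
        cycle_length_years=float(enode.get("cycle_length_years", 0.5)),
        horizon_years=float(enode.get("horizon_years", 3.0)),
        annual_discount_rate=float(enode.get("annual_discount_rate", 0.03)),
        wtp_thresholds=[float(w) for w in enode.get("wtp_thresholds", [282, 1136, 2272])],
        half_cycle_correction=bool(enode.get("half_cycle_correction", True)),
    )

    return ModelConfig(
        drug_prices=drug_prices,
        drugs=drugs,
        rescue=rescue,
        strategies=strategies,
        costs=costs,
        utilities=utilities,
        mortality=mortality,
        rules=rules,
        econ=econ,
    )


def _param_dict(p: Param) -> dict:
    return {"value": p.value, "low": p.low, "high": p.high}


def _profile_dict(pr: TransitionProfile) -> dict:
    return {s.value: _param_dict(p) for s, p in zip(LIVE_STATES, pr.probs())}


def config_to_dict(config: ModelConfig) -> dict:
    drugs = {}
    for name, d in config.drugs.items():
        node: dict = {
            "price_components": list(d.price_components),
            "is_biologic": d.is_biologic,
        }
        if d.profile_early is d.profile_late or (
            d.profile_early.values() == d.profile_late.values()
        ):
            node["profile"] = _profile_dict(d.profile_early)
        else:
            node["profile_early"] = _profile_dict(d.profile_early)
            node["profile_late"] = _profile_dict(d.profile_late)
        drugs[name] = node
    return {
        "drug_prices": {k: _param_dict(v) for k, v in config.drug_prices.items()},
        "drugs": drugs,
        "rescue": {
            "price_components": list(config.rescue.price_components),
            "p_reach_target_per_cycle": _param_dict(
                config.rescue.p_reach_target_per_cycle
            ),
        },
        "strategies": [
            {
                "id": s.id,
                "label": s.label,
                "lines": [{"drug": ln.drug, "profile": ln.variant} for ln in s.lines],
            }
            for s in config.strategies
        ],
        "costs": {
            "diagnosis": _param_dict(config.costs.diagnosis),
            "bridging": _param_dict(config.costs.bridging),
            "cs_first_cycle_investigations": _param_dict(
                config.costs.cs_first_cycle_investigations
            ),
            "cs_continuation": _param_dict(config.costs.cs_continuation),
            "bts_startup_investigations": _param_dict(
                config.costs.bts_startup_investigations
            ),
            "bts_continuation": _param_dict(config.costs.bts_continuation),
            "clinic_visit": _param_dict(config.costs.clinic_visit),
            "visits_first_cycle": config.costs.visits_first_cycle,
            "visits_at_target": config.costs.visits_at_target,
            "visits_off_target": config.costs.visits_off_target,
        },
        "utilities": {
            "remission": _param_dict(config.utilities.remission),
            "lda": _param_dict(config.utilities.lda),
            "mda": _param_dict(config.utilities.mda),
            "hda": _param_dict(config.utilities.hda),
            "target": _param_dict(config.utilities.target),
            "nontarget": _param_dict(config.utilities.nontarget),
            "use_pooled_target_utilities": config.utilities.use_pooled_target_utilities,
        },
        "mortality": {
            "baseline_annual_mortality": _param_dict(
                config.mortality.baseline_annual_mortality
            ),
            "smr": {s.value: config.mortality.smr[s] for s in LIVE_STATES},
        },
        "rules": {
            "p_stay_target": _param_dict(config.rules.p_stay_target),
            "target_split": list(config.rules.target_split),
            "nontarget_split": list(config.rules.nontarget_split),
            "rescue_mode": config.rules.rescue_mode,
            "rescue_at_relapse": config.rules.rescue_at_relapse,
        },
        "economics": {
            "cycle_length_years": config.econ.cycle_length_years,
            "horizon_years": config.econ.horizon_years,
            "annual_discount_rate": config.econ.annual_discount_rate,
            "wtp_thresholds": list(config.econ.wtp_thresholds),
            "half_cycle_correction": config.econ.half_cycle_correction,
        },
    }


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a model configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return config_from_dict(raw)


def write_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (round-trips all numeric values)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def bundled_config_path(scenario: str = "zanzibar") -> Path:
    if scenario not in BUNDLED_SCENARIOS:
        raise ConfigError(
            f"unknown scenario {scenario!r}; expected one of {BUNDLED_SCENARIOS}"
        )
    return Path(str(resources.files("rheumcea").joinpath(f"data/{scenario}.yaml")))


def load_bundled_config(scenario: str = "zanzibar") -> ModelConfig:
    """Load one of the bundled parameter sets (zanzibar, india, scandinavia)."""
    return load_config(bundled_config_path(scenario))


def scenario_config(base: ModelConfig, scenario: str) -> ModelConfig:
    """Return a copy of ``base`` with drug prices swapped to a price scenario.

    Only the component drug prices change; investigation, visit and overhead
    costs, effectiveness and utilities stay as in ``base``.
    """
    out = base.copy()
    out.drug_prices = copy.deepcopy(load_bundled_config(scenario).drug_prices)
    return out


# ---------------------------------------------------------------------------
# Uncertainty-parameter registry
# ---------------------------------------------------------------------------

Family = Literal["gamma", "beta", "normal"]


@dataclass
class UncertainParameter:
    """One named uncertain scalar: where it lives, its range and its PSA
    distribution family."""

    name: str
    family: Family
    get: Callable[[ModelConfig], Param]
    set: Callable[[ModelConfig, float], None]

    def point(self, config: ModelConfig) -> float:
        return self.get(config).value

    def bounds(self, config: ModelConfig) -> tuple[float, float]:
        p = self.get(config)
        return p.low, p.high


def _price_param(component: str) -> UncertainParameter:
    def setter(cfg: ModelConfig, v: float) -> None:
        cfg.drug_prices[component].value = v

    return UncertainParameter(
        name=f"cost.{component}",
        family="gamma",
        get=lambda cfg: cfg.drug_prices[component],
        set=setter,
    )


def _cost_param(attr: str) -> UncertainParameter:
    def setter(cfg: ModelConfig, v: float) -> None:
        getattr(cfg.costs, attr).value = v

    return UncertainParameter(
        name=f"cost.{attr}",
        family="gamma",
        get=lambda cfg, a=attr: getattr(cfg.costs, a),
        set=setter,
    )


def _utility_param(attr: str) -> UncertainParameter:
    def setter(cfg: ModelConfig, v: float) -> None:
        getattr(cfg.utilities, attr).value = v

    return UncertainParameter(
        name=f"utility.{attr}",
        family="normal",
        get=lambda cfg, a=attr: getattr(cfg.utilities, a),
        set=setter,
    )


def _profile_cell_param(drug: str, variant: str, state: HealthState) -> UncertainParameter:
    """A single transition probability; setting it rescales the other three
    states of the profile so the row still sums to 1."""

    attr = f"p_{state.value}" if state is not HealthState.REMISSION else "p_remission"

    def get(cfg: ModelConfig) -> Param:
        return getattr(cfg.drugs[drug].profile(variant), attr)

    def setter(cfg: ModelConfig, v: float) -> None:
        prof = cfg.drugs[drug].profile(variant)
        old = getattr(prof, attr).value
        rest = 1.0 - old
        v = min(max(v, 0.0), 1.0)
        scale = (1.0 - v) / rest if rest > 0 else 0.0
        for s in LIVE_STATES:
            a = f"p_{s.value}"
            p = getattr(prof, a)
            p.value = v if s is state else p.value * scale

    return UncertainParameter(
        name=f"prob.profile.{drug}.{variant}.{state.value}",
        family="beta",
        get=get,
        set=setter,
    )


def uncertainty_parameters(config: ModelConfig) -> dict[str, UncertainParameter]:
    """The full registry of uncertain scalars for a configuration.

    Each entry resolves to exactly one numeric slot of the config; names are
    stable identifiers used by OWSA, PSA and the CLI.
    """
    params: list[UncertainParameter] = []
    for component in config.drug_prices:
        params.append(_price_param(component))
    for attr in (
        "diagnosis",
        "bridging",
        "cs_first_cycle_investigations",
        "cs_continuation",
        "bts_startup_investigations",
        "bts_continuation",
        "clinic_visit",
    ):
        params.append(_cost_param(attr))
    for attr in ("remission", "lda", "mda", "hda", "target", "nontarget"):
        params.append(_utility_param(attr))

    def set_stay(cfg: ModelConfig, v: float) -> None:
        cfg.rules.p_stay_target.value = min(max(v, 0.0), 1.0)

    params.append(
        UncertainParameter(
            "prob.p_stay_target", "beta", lambda cfg: cfg.rules.p_stay_target, set_stay
        )
    )

    def set_rescue(cfg: ModelConfig, v: float) -> None:
        cfg.rescue.p_reach_target_per_cycle.value = min(max(v, 0.0), 1.0)

    params.append(
        UncertainParameter(
            "prob.rescue_target",
            "beta",
            lambda cfg: cfg.rescue.p_reach_target_per_cycle,
            set_rescue,
        )
    )

    def set_mort(cfg: ModelConfig, v: float) -> None:
        cfg.mortality.baseline_annual_mortality.value = min(max(v, 0.0), 1.0)

    params.append(
        UncertainParameter(
            "prob.baseline_mortality",
            "beta",
            lambda cfg: cfg.mortality.baseline_annual_mortality,
            set_mort,
        )
    )

    for drug_name, drug in config.drugs.items():
        variants = ["early"]
        if drug.profile_late.values() != drug.profile_early.values():
            variants.append("late")
        for variant in variants:
            for state in LIVE_STATES:
                params.append(_profile_cell_param(drug_name, variant, state))

    registry = {p.name: p for p in params}
    if len(registry) != len(params):
        raise ConfigError("duplicate parameter names in uncertainty registry")
    return registry


def resolve_parameter(
    config: ModelConfig, name: str
) -> UncertainParameter:
    registry = uncertainty_parameters(config)
    try:
        return registry[name]
    except KeyError:
        raise KeyError(
            f"unknown uncertain parameter {name!r}; known names include "
            f"{sorted(registry)[:8]}..."
        ) from None
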