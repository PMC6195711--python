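"""Domain types, configuration I/O and validation.

Every quantity used by the model lives here: the eight-state structure
(composite asthma-control x medication-adherence states plus exacerbation and
death states), the monthly base transition probabilities, effectiveness odds
ratios, exacerbation hazard ratios, utilities, costs, the background-mortality
life table and the in-hospital case-fatality table.

Configurations are single YAML documents (see ``asthmacea/config/``); a
scenario file may ``inherit`` another file and override blocks.
"""

from __future__ import annotations

import copy
import dataclasses
import enum
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "HealthState",
    "CHRONIC_STATES",
    "STATE_ORDER",
    "Quantity",
    "ClassificationCutoffs",
    "BaseTransitions",
    "ExacerbationRisks",
    "EffectivenessFactor",
    "UtilitySet",
    "CostModel",
    "LifeTable",
    "CaseFatalityTable",
    "ModelConfig",
    "EffectRule",
    "ParameterSet",
    "ValidationReport",
    "load_parameters",
    "validate_parameters",
    "packaged_config_path",
]


class HealthState(enum.Enum):
    """The eight health states of the model.

    A  good control - high adherence      B  good control - low adherence
    C  poor control - high adherence      D  poor control - low adherence
    E  exacerbation, urgent/ED visit      F  exacerbation, hospitalization
    G  death due to asthma                H  death due to other causes
    """

    A = 0
    B = 1
    C = 2
    D = 3
    E = 4
    F = 5
    G = 6
    H = 7

    @property
    def is_absorbing(self) -> bool:
        return self in (HealthState.G, HealthState.H)

    @property
    def is_alive(self) -> bool:
        return not self.is_absorbing


#: States in matrix order.
STATE_ORDER: tuple[HealthState, ...] = tuple(HealthState)
#: The four chronic control-adherence states.
CHRONIC_STATES: tuple[HealthState, ...] = tuple(HealthState)[:4]
CHRONIC_NAMES: tuple[str, ...] = ("A", "B", "C", "D")


@dataclass(frozen=True)
class Quantity:
    """A model input: point value, (low, high) range and distribution tag."""

    value: float
    low: float
    high: float
    dist: str = "fixed"

    def brackets(self) -> bool:
        return self.low <= self.value <= self.high

    def to_dict(self) -> dict:
        d = {"value": self.value, "low": self.low, "high": self.high}
        if self.dist != "fixed":
            d["dist"] = self.dist
        return d

    @classmethod
    def from_dict(cls, d: Mapping, dist: str | None = None) -> "Quantity":
        return cls(
            value=float(d["value"]),
            low=float(d["low"]),
            high=float(d["high"]),
            dist=str(d.get("dist", dist or "fixed")),
        )


@dataclass
class ClassificationCutoffs:
    """Score cutoffs mapping (ACT, adherence) to the A-D states.

    ACT scores of ``act_poor_max`` and below mean poor control; adherence
    scores strictly below ``adherence_low_below`` mean low adherence.
    """

    act_poor_max: int = 19
    adherence_low_below: float = 6.0

    def validate(self) -> None:
        if not (5 <= self.act_poor_max <= 24):
            raise ValueError(f"act_poor_max out of [5, 24]: {self.act_poor_max}")
        if not (0 < self.adherence_low_below <= 8):
            raise ValueError(
                f"adherence_low_below out of (0, 8]: {self.adherence_low_below}"
            )


@dataclass
class BaseTransitions:
    """Monthly A-D transition probabilities for the intervention arm.

    ``cells[origin][dest]`` holds the 12 off-diagonal quantities; the
    self-loop of each row is the residual 1 - sum(off-diagonals). Rows are
    sampled as Dirichlet vectors in the PSA with ``dirichlet_n_eff``
    pseudo-observations.
    """

    cells: dict[str, dict[str, Quantity]]
    dirichlet_n_eff: float = 16.0

    def matrix(self) -> np.ndarray:
        """4x4 row-stochastic matrix (self-loops on the diagonal)."""
        m = np.zeros((4, 4))
        for i, o in enumerate(CHRONIC_NAMES):
            for j, d in enumerate(CHRONIC_NAMES):
                if d in self.cells.get(o, {}):
                    m[i, j] = self.cells[o][d].value
            m[i, i] = 1.0 - m[i].sum()
        return m

    def off_diagonal(self, origin: str, dest: str) -> Quantity:
        return self.cells[origin][dest]

    def to_dict(self) -> dict:
        d: dict = {"distribution": "dirichlet", "dirichlet_n_eff": self.dirichlet_n_eff}
        for o in CHRONIC_NAMES:
            d[o] = {dst: q.to_dict() for dst, q in self.cells[o].items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "BaseTransitions":
        cells = {}
        for o in CHRONIC_NAMES:
            if o not in d:
                raise KeyError(f"base_transitions missing row {o!r}")
            cells[o] = {
                dst: Quantity.from_dict(q, dist="dirichlet")
                for dst, q in d[o].items()
            }
        return cls(cells=cells, dirichlet_n_eff=float(d.get("dirichlet_n_eff", 16)))


_EXAC_FIELDS = (
    "p_BE", "p_BF", "p_DE", "p_DF",
    "hr_good_control", "hr_poor_control",
    "p_EA", "p_EC", "p_FA", "p_FC",
    "p_EF", "p_FE", "p_EG",
)


@dataclass
class ExacerbationRisks:
    """Exacerbation entry, recovery, re-exacerbation and E-state mortality.

    ``p_BE``..``p_DF`` are the low-adherence monthly exacerbation
    probabilities; ``hr_good_control``/``hr_poor_control`` are the hazard
    ratios applied (on the rate scale) to obtain the high-adherence rows A/C.
    """

    p_BE: Quantity
    p_BF: Quantity
    p_DE: Quantity
    p_DF: Quantity
    hr_good_control: Quantity
    hr_poor_control: Quantity
    p_EA: Quantity
    p_EC: Quantity
    p_FA: Quantity
    p_FC: Quantity
    p_EF: Quantity
    p_FE: Quantity
    p_EG: Quantity

    def to_dict(self) -> dict:
        return {f: getattr(self, f).to_dict() | {"dist": getattr(self, f).dist}
                for f in _EXAC_FIELDS}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExacerbationRisks":
        missing = [f for f in _EXAC_FIELDS if f not in d]
        if missing:
            raise KeyError(f"exacerbation block missing fields: {missing}")
        return cls(**{f: Quantity.from_dict(d[f]) for f in _EXAC_FIELDS})


@dataclass
class EffectivenessFactor:
    """An intervention effect: odds ratio promoting entry into target states."""

    name: str
    odds_ratio: Quantity
    target_states: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "odds_ratio": self.odds_ratio.to_dict() | {"dist": self.odds_ratio.dist},
            "target_states": list(self.target_states),
        }

    @classmethod
    def from_dict(cls, name: str, d: Mapping) -> "EffectivenessFactor":
        return cls(
            name=name,
            odds_ratio=Quantity.from_dict(d["odds_ratio"]),
            target_states=tuple(d["target_states"]),
        )


_UTIL_STATES = ("A", "B", "C", "D", "E", "F")


@dataclass
class UtilitySet:
    """Utility weights for the six alive states (death states weigh 0)."""

    name: str
    values: dict[str, Quantity]

    def vector(self) -> np.ndarray:
        return np.array([self.values[s].value for s in _UTIL_STATES])

    def to_dict(self) -> dict:
        return {s: self.values[s].to_dict() | {"dist": self.values[s].dist}
                for s in _UTIL_STATES}

    @classmethod
    def from_dict(cls, name: str, d: Mapping) -> "UtilitySet":
        missing = [s for s in _UTIL_STATES if s not in d]
        if missing:
            raise KeyError(f"utility set {name!r} missing states: {missing}")
        return cls(name=name, values={s: Quantity.from_dict(d[s]) for s in _UTIL_STATES})


_COST_FIELDS = (
    "c_A", "c_B", "c_C", "c_D", "c_E", "c_F",
    "rmtac_recruitment", "rmtac_followup_q", "rmtac_followup_biannual",
)


@dataclass
class CostModel:
    """Monthly direct costs (2014 USD).

    ``c_A``..``c_F`` are per-state monthly costs. The clinic (RMTAC) costs are
    charged only in the intervention arm, weighted by the fraction of the
    cohort alive: recruitment at cycle 0, the quarterly-follow-up rate per
    cycle for cycles 1-15, the biannual rate for cycles >= 16.
    """

    c_A: Quantity
    c_B: Quantity
    c_C: Quantity
    c_D: Quantity
    c_E: Quantity
    c_F: Quantity
    rmtac_recruitment: Quantity
    rmtac_followup_q: Quantity
    rmtac_followup_biannual: Quantity

    def state_vector(self) -> np.ndarray:
        return np.array([getattr(self, f"c_{s}").value for s in _UTIL_STATES])

    def rmtac_vector(self) -> np.ndarray:
        return np.array([
            self.rmtac_recruitment.value,
            self.rmtac_followup_q.value,
            self.rmtac_followup_biannual.value,
        ])

    def to_dict(self) -> dict:
        return {f: getattr(self, f).to_dict() | {"dist": getattr(self, f).dist}
                for f in _COST_FIELDS}

    @classmethod
    def from_dict(cls, d: Mapping) -> "CostModel":
        missing = [f for f in _COST_FIELDS if f not in d]
        if missing:
            raise KeyError(f"costs block missing fields: {missing}")
        return cls(**{f: Quantity.from_dict(d[f]) for f in _COST_FIELDS})


class LifeTable:
    """Age-indexed monthly all-cause death probability q(a).

    Defined for every integer age in [age_min, age_max]. The analytic life
    expectancy uses the same discrete monthly convention as the cohort engine
    (12 cycles per age row), so the engine reproduces it exactly when state
    dynamics do not affect mortality.
    """

    def __init__(self, q_monthly: Mapping[int, float]):
        ages = sorted(int(a) for a in q_monthly)
        if ages != list(range(ages[0], ages[-1] + 1)):
            raise ValueError("life table ages must be contiguous integers")
        self.age_min = ages[0]
        self.age_max = ages[-1]
        self._q = np.array([float(q_monthly[a]) for a in ages])
        if np.any((self._q < 0) | (self._q > 1)):
            raise ValueError("life table probabilities must lie in [0, 1]")

    def q(self, age: int) -> float:
        if not (self.age_min <= age <= self.age_max):
            raise KeyError(f"age {age} outside life table [{self.age_min}, {self.age_max}]")
        return float(self._q[int(age) - self.age_min])

    def covers(self, age_low: int, age_high: int) -> bool:
        return self.age_min <= age_low and age_high <= self.age_max

    def life_expectancy(self, from_age: int, to_age: int | None = None) -> float:
        """Discrete monthly life expectancy in years from ``from_age``."""
        to_age = self.age_max if to_age is None else to_age
        months = (to_age - from_age) * 12
        ages = from_age + (np.arange(months) // 12)
        surv = np.cumprod(1.0 - self._q[ages - self.age_min])
        return float(surv.sum() / 12.0)

    def to_dict(self) -> dict:
        return {"mode": "table",
                "q_monthly": {int(a): float(q)
                              for a, q in zip(range(self.age_min, self.age_max + 1), self._q)}}


class CaseFatalityTable:
    """Monthly asthma-death probability from the hospitalized state, by age band."""

    def __init__(self, bands: Iterable[tuple[int, int, float]]):
        self.bands = sorted((int(lo), int(hi), float(q)) for lo, hi, q in bands)
        for lo, hi, q in self.bands:
            if lo > hi:
                raise ValueError(f"band {lo}-{hi} reversed")
            if not (0.0 <= q <= 1.0):
                raise ValueError(f"case fatality {q} outside [0, 1]")
        for (l1, h1, _), (l2, _, _) in zip(self.bands, self.bands[1:]):
            if l2 != h1 + 1:
                raise ValueError("case fatality bands must be contiguous")

    def q(self, age: int) -> float:
        for lo, hi, q in self.bands:
            if lo <= age <= hi:
                return q
        raise KeyError(f"age {age} not covered by case fatality table")

    def covers(self, age_low: int, age_high: int) -> bool:
        return self.bands[0][0] <= age_low and age_high <= self.bands[-1][1]

    def to_dict(self) -> dict:
        return {"bands": [{"age_low": lo, "age_high": hi, "q_monthly": q}
                          for lo, hi, q in self.bands]}


@dataclass
class ModelConfig:
    """Structural settings of the cohort simulation."""

    start_age: int = 50
    max_age: int = 105
    cycle_length_months: int = 1
    annual_discount_rate: float = 0.03
    willingness_to_pay: float = 9006.0
    initial_distribution: dict[str, float] = field(
        default_factory=lambda: {"B": 1 / 3, "C": 1 / 3, "D": 1 / 3}
    )
    psa_draws: int = 10000
    random_seed: int = 20140322
    utility_set: str = "base_case"
    effectiveness: str = "asthma_control"
    half_cycle_correction: bool = False
    hospitalization_metric: str = "entries"

    @property
    def n_cycles(self) -> int:
        return (self.max_age - self.start_age) * 12

    def initial_vector(self) -> np.ndarray:
        v = np.zeros(8)
        for s, p in self.initial_distribution.items():
            v[HealthState[s].value] = p
        return v / v.sum()

    def to_dict(self) -> dict:
        return {
            "start_age": self.start_age,
            "max_age": self.max_age,
            "cycle_length_months": self.cycle_length_months,
            "annual_discount_rate": self.annual_discount_rate,
            "willingness_to_pay": self.willingness_to_pay,
            "initial_distribution": dict(self.initial_distribution),
            "psa_draws": self.psa_draws,
            "random_seed": self.random_seed,
            "utility_set": self.utility_set,
            "effectiveness": self.effectiveness,
            "half_cycle_correction": self.half_cycle_correction,
            "hospitalization_metric": self.hospitalization_metric,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        return cls(
            start_age=int(d.get("start_age", 50)),
            max_age=int(d.get("max_age", 105)),
            cycle_length_months=int(d.get("cycle_length_months", 1)),
            annual_discount_rate=float(d.get("annual_discount_rate", 0.03)),
            willingness_to_pay=float(d.get("willingness_to_pay", 9006.0)),
            initial_distribution={k: float(v)
                                  for k, v in d.get("initial_distribution",
                                                    {"B": 1 / 3, "C": 1 / 3, "D": 1 / 3}).items()},
            psa_draws=int(d.get("psa_draws", 10000)),
            random_seed=int(d.get("random_seed", 20140322)),
            utility_set=str(d.get("utility_set", "base_case")),
            effectiveness=str(d.get("effectiveness", "asthma_control")),
            half_cycle_correction=bool(d.get("half_cycle_correction", False)),
            hospitalization_metric=str(d.get("hospitalization_metric", "entries")),
        )


@dataclass
class EffectRule:
    """How the effectiveness odds ratio maps onto transition probabilities."""

    mode: str = "zhang_yu_rr"          # zhang_yu_rr | exact_odds
    reference_risk: str = "rmtac_row_probability"
    fixed_value: float | None = None

    def to_dict(self) -> dict:
        d = {"mode": self.mode, "reference_risk": self.reference_risk}
        if self.fixed_value is not None:
            d["fixed_value"] = self.fixed_value
        return d


@dataclass
class ParameterSet:
    """Everything the model needs, fully resolved."""

    config: ModelConfig
    effect_rule: EffectRule
    cutoffs: ClassificationCutoffs
    base_transitions: BaseTransitions
    effectiveness_factors: dict[str, EffectivenessFactor]
    exacerbation: ExacerbationRisks
    utility_sets: dict[str, UtilitySet]
    costs: CostModel
    life_table: LifeTable
    case_fatality: CaseFatalityTable
    life_table_spec: dict = field(default_factory=dict)
    case_fatality_spec: str | dict = "default"

    @property
    def active_utilities(self) -> UtilitySet:
        return self.utility_sets[self.config.utility_set]

    @property
    def active_effectiveness(self) -> EffectivenessFactor:
        return self.effectiveness_factors[self.config.effectiveness]

    def copy(self) -> "ParameterSet":
        # life table / case fatality are immutable in practice; share them
        return ParameterSet(
            config=copy.deepcopy(self.config),
            effect_rule=copy.deepcopy(self.effect_rule),
            cutoffs=copy.deepcopy(self.cutoffs),
            base_transitions=copy.deepcopy(self.base_transitions),
            effectiveness_factors=copy.deepcopy(self.effectiveness_factors),
            exacerbation=copy.deepcopy(self.exacerbation),
            utility_sets=copy.deepcopy(self.utility_sets),
            costs=copy.deepcopy(self.costs),
            life_table=self.life_table,
            case_fatality=self.case_fatality,
            life_table_spec=copy.deepcopy(self.life_table_spec),
            case_fatality_spec=copy.deepcopy(self.case_fatality_spec),
        )

    def to_dict(self) -> dict:
        return {
            "model": self.config.to_dict(),
            "effect": self.effect_rule.to_dict(),
            "classification": {
                "act_poor_max": self.cutoffs.act_poor_max,
                "adherence_low_below": self.cutoffs.adherence_low_below,
            },
            "base_transitions": self.base_transitions.to_dict(),
            "effectiveness_factors": {n: f.to_dict()
                                      for n, f in self.effectiveness_factors.items()},
            "exacerbation": self.exacerbation.to_dict(),
            "utilities": {n: u.to_dict() for n, u in self.utility_sets.items()},
            "costs": self.costs.to_dict(),
            "life_table": self.life_table_spec or self.life_table.to_dict(),
            "case_fatality": self.case_fatality_spec,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: Mapping, *, life_table: LifeTable | None = None,
                  case_fatality: CaseFatalityTable | None = None) -> "ParameterSet":
        for block in ("model", "base_transitions", "exacerbation", "utilities", "costs"):
            if block not in d:
                raise KeyError(f"configuration missing block {block!r}")
        cfg = ModelConfig.from_dict(d["model"])
        eff_d = d.get("effect", {})
        rule = EffectRule(
            mode=str(eff_d.get("mode", "zhang_yu_rr")),
            reference_risk=str(eff_d.get("reference_risk", "rmtac_row_probability")),
            fixed_value=eff_d.get("fixed_value"),
        )
        cls_d = d.get("classification", {})
        cutoffs = ClassificationCutoffs(
            act_poor_max=int(cls_d.get("act_poor_max", 19)),
            adherence_low_below=float(cls_d.get("adherence_low_below", 6.0)),
        )
        factors = {n: EffectivenessFactor.from_dict(n, fd)
                   for n, fd in d.get("effectiveness_factors", {}).items()}
        utils = {n: UtilitySet.from_dict(n, ud) for n, ud in d["utilities"].items()}

        lt_spec = d.get("life_table", {"mode": "makeham_calibrated",
                                       "calibrate_age": 50,
                                       "target_life_expectancy": 27.8})
        if life_table is None:
            life_table = _resolve_life_table(lt_spec, cfg)
        cf_spec = d.get("case_fatality", "default")
        if case_fatality is None:
            case_fatality = _resolve_case_fatality(cf_spec)

        return cls(
            config=cfg,
            effect_rule=rule,
            cutoffs=cutoffs,
            base_transitions=BaseTransitions.from_dict(d["base_transitions"]),
            effectiveness_factors=factors,
            exacerbation=ExacerbationRisks.from_dict(d["exacerbation"]),
            utility_sets=utils,
            costs=CostModel.from_dict(d["costs"]),
            life_table=life_table,
            case_fatality=case_fatality,
            life_table_spec=dict(lt_spec) if isinstance(lt_spec, Mapping) else lt_spec,
            case_fatality_spec=cf_spec,
        )


def _resolve_life_table(spec: Mapping, cfg: ModelConfig) -> LifeTable:
    from . import synthdata  # local import to avoid a cycle

    mode = spec.get("mode", "makeham_calibrated")
    if mode == "table":
        return LifeTable({int(a): float(q) for a, q in spec["q_monthly"].items()})
    if mode == "makeham_calibrated":
        return synthdata.make_life_table(
            calibrate_age=int(spec.get("calibrate_age", cfg.start_age)),
            target_le=float(spec.get("target_life_expectancy", 27.8)),
            age_min=cfg.start_age,
            age_max=cfg.max_age,
        )
    if mode == "makeham":
        return synthdata.make_life_table(
            makeham=synthdata.MakehamParams(
                alpha=float(spec["alpha"]), beta=float(spec["beta"]),
                gamma=float(spec["gamma"])),
            age_min=cfg.start_age, age_max=cfg.max_age,
        )
    raise ValueError(f"unknown life_table mode {mode!r}")


def _resolve_case_fatality(spec) -> CaseFatalityTable:
    from . import synthdata

    if spec == "default":
        return synthdata.default_case_fatality()
    if isinstance(spec, Mapping) and "bands" in spec:
        return CaseFatalityTable(
            (b["age_low"], b["age_high"], b["q_monthly"]) for b in spec["bands"]
        )
    raise ValueError(f"unrecognised case_fatality spec: {spec!r}")


def packaged_config_path(name: str) -> Path:
    """Path of a configuration file shipped inside the package."""
    res = importlib.resources.files("asthmacea") / "config" / name
    return Path(str(res))


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config_dict(path: str | Path) -> dict:
    """Read a YAML configuration, resolving ``inherit`` chains."""
    path = Path(path)
    if not path.exists():
        candidate = packaged_config_path(path.name)
        if candidate.exists():
            path = candidate
        else:
            raise FileNotFoundError(path)
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError(f"{path} does not contain a mapping")
    if "inherit" in d:
        parent_name = d.pop("inherit")
        parent_path = (path.parent / parent_name)
        if not parent_path.exists():
            parent_path = packaged_config_path(parent_name)
        parent = load_config_dict(parent_path)
        d = _deep_merge(parent, d)
    return d


def load_parameters(path: str | Path = "base_case.yaml") -> ParameterSet:
    """Load and resolve a full parameter set from a YAML configuration."""
    return ParameterSet.from_dict(load_config_dict(path))


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_parameters`: one entry per rule."""

    checks: list[tuple[str, bool, str]] = field(default_factory=list)

    def add(self, rule: str, ok: bool, message: str = "") -> None:
        self.checks.append((rule, bool(ok), message))

    @property
    def ok(self) -> bool:
        return all(ok for _, ok, _ in self.checks)

    @property
    def failures(self) -> list[tuple[str, str]]:
        return [(rule, msg) for rule, ok, msg in self.checks if not ok]

    def raise_if_failed(self) -> None:
        if not self.ok:
            lines = "; ".join(f"{r}: {m}" for r, m in self.failures)
            raise ValueError(f"parameter validation failed: {lines}")


def validate_parameters(params: ParameterSet) -> ValidationReport:
    """Check every numeric rule; structural absences raise earlier, at parse."""
    rep = ValidationReport()
    cfg = params.config

    # probabilities in [0, 1] and ranges bracket point values
    def check_prob(name: str, q: Quantity) -> None:
        rep.add(f"{name} in [0,1]", 0.0 <= q.value <= 1.0, f"value {q.value}")
        rep.add(f"{name} range brackets value", q.low <= q.value <= q.high,
                f"({q.low}, {q.value}, {q.high})")

    for o in CHRONIC_NAMES:
        row_sum = 0.0
        for dst, q in params.base_transitions.cells[o].items():
            check_prob(f"base {o}->{dst}", q)
            row_sum += q.value
        rep.add(f"base row {o} off-diagonal sum <= 1", row_sum <= 1.0 + 1e-12,
                f"sum {row_sum}")

    ex = params.exacerbation
    for f in _EXAC_FIELDS:
        q = getattr(ex, f)
        if f.startswith("hr_"):
            rep.add(f"{f} > 0", q.value > 0, f"value {q.value}")
            rep.add(f"{f} range brackets value", q.low <= q.value <= q.high,
                    f"({q.low}, {q.value}, {q.high})")
        else:
            check_prob(f, q)

    for name, fac in params.effectiveness_factors.items():
        rep.add(f"OR[{name}] > 0", fac.odds_ratio.value > 0,
                f"value {fac.odds_ratio.value}")
        rep.add(f"OR[{name}] CI brackets value", fac.odds_ratio.brackets(),
                f"({fac.odds_ratio.low}, {fac.odds_ratio.value}, {fac.odds_ratio.high})")
        ok_targets = (len(fac.target_states) > 0
                      and set(fac.target_states) <= set(CHRONIC_NAMES))
        rep.add(f"OR[{name}] target states valid", ok_targets,
                f"{fac.target_states}")

    for uname, uset in params.utility_sets.items():
        for s in _UTIL_STATES:
            check_prob(f"u_{s}[{uname}]", uset.values[s])

    for f in _COST_FIELDS:
        q = getattr(params.costs, f)
        rep.add(f"{f} >= 0", q.value >= 0, f"value {q.value}")
        rep.add(f"{f} range brackets value", q.low <= q.value <= q.high,
                f"({q.low}, {q.value}, {q.high})")

    rep.add("life table covers horizon",
            params.life_table.covers(cfg.start_age, cfg.max_age),
            f"[{params.life_table.age_min}, {params.life_table.age_max}]")
    rep.add("case fatality covers horizon",
            params.case_fatality.covers(cfg.start_age, cfg.max_age), "")

    init = params.config.initial_distribution
    rep.add("initial distribution sums to 1",
            abs(sum(init.values()) - 1.0) < 1e-9, f"sum {sum(init.values())}")
    rep.add("initial distribution support within {B, C, D}",
            set(init) <= {"B", "C", "D"}, f"{sorted(init)}")

    rep.add("discount rate >= 0", cfg.annual_discount_rate >= 0,
            f"{cfg.annual_discount_rate}")
    rep.add("horizon positive", cfg.n_cycles > 0, f"{cfg.n_cycles} cycles")
    return rep
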