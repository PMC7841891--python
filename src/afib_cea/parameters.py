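"""Model parameters: domain types, base-case fixture, config I/O and validation.

The model compares four oral anticoagulation strategies for stroke
prevention in non-valvular atrial fibrillation.  Each strategy carries
annual probabilities of five competing clinical events (ischemic stroke,
intracranial hemorrhage, extracranial hemorrhage, myocardial infarction,
all-cause death), shared event-outcome severity splits, an annual
treatment cost, one-time acute-event costs, and health-state utilities.

Every tunable scalar is addressable by a string identifier (for example
``"p_is.warfarin"`` or ``"cost_event.ICH"``) through
:func:`get_parameter` / :func:`set_parameter`; plausible ranges for the
sensitivity analyses are stored per identifier in
:attr:`ModelInputs.ranges`.
"""

from __future__ import annotations

import copy
import enum
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import yaml


class Strategy(str, enum.Enum):
    """The four anticoagulation strategies the model compares."""

    WARFARIN = "warfarin"
    RIVAROXABAN = "rivaroxaban"
    DABIGATRAN110 = "dabigatran110"
    DABIGATRAN150 = "dabigatran150"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Event(str, enum.Enum):
    """Acute clinical events a patient can experience in a cycle."""

    IS = "IS"
    ICH = "ICH"
    ECH = "ECH"
    MI = "MI"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


STRATEGIES: tuple[Strategy, ...] = tuple(Strategy)
EVENTS: tuple[Event, ...] = tuple(Event)

# case-insensitive aliases accepted in config files
_STRATEGY_ALIASES = {
    "warfarin": Strategy.WARFARIN,
    "rivaroxaban": Strategy.RIVAROXABAN,
    "dabigatran110": Strategy.DABIGATRAN110,
    "dabigatran110mg": Strategy.DABIGATRAN110,
    "dabigatran150": Strategy.DABIGATRAN150,
    "dabigatran150mg": Strategy.DABIGATRAN150,
}


def canonical_strategy(label: str | Strategy) -> Strategy:
    """Resolve a (case-insensitive) strategy label to its canonical enum."""
    if isinstance(label, Strategy):
        return label
    key = str(label).strip().lower().replace(" ", "").replace("_", "")
    # tolerate an underscore style like "dabigatran_110"
    key = key.replace("dabigatran110", "dabigatran110").replace("dabigatran150", "dabigatran150")
    if key not in _STRATEGY_ALIASES:
        raise SchemaError(f"unknown strategy label {label!r}; expected one of "
                          f"{[s.value for s in STRATEGIES]}")
    return _STRATEGY_ALIASES[key]


class ConfigError(Exception):
    """A configuration file could not be parsed."""


class SchemaError(ConfigError):
    """A configuration file parsed but is missing or misusing keys."""


@dataclass
class ValidationIssue:
    code: str
    message: str

    def __str__(self) -> str:
        return f"[{self.code}] {self.message}"


@dataclass
class ValidationReport:
    """Outcome of :func:`validate`; empty ``issues`` means all invariants hold."""

    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, code: str, message: str) -> None:
        self.issues.append(ValidationIssue(code, message))

    def __str__(self) -> str:
        if self.ok:
            return "valid: no issues"
        return "\n".join(str(i) for i in self.issues)


class ValidationError(Exception):
    """Raised when a loaded parameter set violates a model invariant."""

    def __init__(self, report: ValidationReport):
        self.report = report
        super().__init__(str(report))


@dataclass
class EventRisks:
    """Annual probabilities of the competing clinical events for one strategy."""

    p_is: float
    p_ich: float
    p_ech: float
    p_mi: float
    p_death: float

    def total(self) -> float:
        return self.p_is + self.p_ich + self.p_ech + self.p_mi + self.p_death


@dataclass
class SeveritySplit:
    """Outcome distribution of an acute event (stroke or ICH).

    ``f_light`` survivors return to the event-free state, ``f_moderate`` and
    ``f_severe`` move to the corresponding disability states, and ``f_die``
    is the short-term case fatality.
    """

    f_light: float
    f_moderate: float
    f_severe: float
    f_die: float

    def total(self) -> float:
        return self.f_light + self.f_moderate + self.f_severe + self.f_die

    def normalize(self) -> None:
        s = self.total()
        if s > 0:
            self.f_light /= s
            self.f_moderate /= s
            self.f_severe /= s
            self.f_die /= s


@dataclass
class SimpleFatality:
    """Two-outcome event: fatal with ``f_die``, otherwise full recovery."""

    f_die: float


@dataclass
class CostInputs:
    """Annual treatment costs per strategy and one-time acute-event costs ($)."""

    annual_treatment: dict[Strategy, float]
    event: dict[Event, float]


@dataclass
class UtilityInputs:
    """Health-state utility weights and within-cycle event multipliers.

    ``u_min``/``u_mod``/``u_sev`` weight a year lived in the event-free,
    moderate-disability, and severe-disability states.  ``m_ich``, ``m_ech``
    and ``m_mi`` multiply the survivor's state utility in the cycle a
    nonfatal hemorrhage or infarction occurs.
    """

    u_min: float
    u_mod: float
    u_sev: float
    m_ich: float
    m_ech: float
    m_mi: float


@dataclass
class ParameterRange:
    """Base value plus the plausible (low, high) bounds used in sensitivity
    analyses.  Parameters without a published range are stored as degenerate
    ranges (low == base == high) and are held fixed."""

    base: float
    low: float
    high: float

    @property
    def degenerate(self) -> bool:
        return self.low == self.high

    @property
    def width(self) -> float:
        return self.high - self.low


@dataclass
class RunConfig:
    """Run settings: horizon, discounting, decision threshold, PSA size.

    The default willingness-to-pay threshold is three times the 2018 China
    GDP per capita (3 x 9481.88 = 28445.64 $/QALY).  By default the first
    cycle is undiscounted and both costs and effects are discounted at the
    same annual rate.
    """

    horizon_cycles: int = 30
    discount_rate: float = 0.03
    wtp: float = 3 * 9481.88
    discount_first_cycle: bool = False
    events_from_moderate: bool = False
    psa_draws: int = 1000
    seed: int = 12345
    # accrual/discounting switches (see docs/methods.md)
    discount_costs: bool = True
    discount_effects: bool = True
    charge_fatal_event_cost: bool = True
    accrue_fatal_cycle_utility: bool = True


@dataclass
class ModelInputs:
    """The complete parameter set driving the model."""

    risks: dict[Strategy, EventRisks]
    is_split: SeveritySplit
    ich_split: SeveritySplit
    ech_fate: SimpleFatality
    mi_fate: SimpleFatality
    costs: CostInputs
    utilities: UtilityInputs
    ranges: dict[str, ParameterRange]
    run: RunConfig = field(default_factory=RunConfig)

    def copy(self) -> "ModelInputs":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Parameter registry: string identifier -> (kind, getter, setter)
# ---------------------------------------------------------------------------

_SPLIT_FIELDS = {"light": "f_light", "moderate": "f_moderate",
                 "severe": "f_severe", "die": "f_die"}
_RISK_FIELDS = ("p_is", "p_ich", "p_ech", "p_mi", "p_death")
_UTILITY_FIELDS = ("u_min", "u_mod", "u_sev", "m_ich", "m_ech", "m_mi")


def _build_registry():
    reg: dict[str, tuple[str, callable, callable]] = {}

    def risk_acc(strategy, fld):
        return (lambda mi: getattr(mi.risks[strategy], fld),
                lambda mi, v: setattr(mi.risks[strategy], fld, v))

    for s in STRATEGIES:
        for fld in _RISK_FIELDS:
            g, st = risk_acc(s, fld)
            reg[f"{fld}.{s.value}"] = ("probability", g, st)

    def split_acc(attr, fld):
        return (lambda mi: getattr(getattr(mi, attr), fld),
                lambda mi, v: setattr(getattr(mi, attr), fld, v))

    for name, fld in _SPLIT_FIELDS.items():
        g, st = split_acc("is_split", fld)
        reg[f"is_split.{name}"] = ("probability", g, st)
        g, st = split_acc("ich_split", fld)
        reg[f"ich_split.{name}"] = ("probability", g, st)

    reg["ech_fatality"] = ("probability",
                           lambda mi: mi.ech_fate.f_die,
                           lambda mi, v: setattr(mi.ech_fate, "f_die", v))
    reg["mi_fatality"] = ("probability",
                          lambda mi: mi.mi_fate.f_die,
                          lambda mi, v: setattr(mi.mi_fate, "f_die", v))

    def annual_acc(strategy):
        return (lambda mi: mi.costs.annual_treatment[strategy],
                lambda mi, v: mi.costs.annual_treatment.__setitem__(strategy, v))

    for s in STRATEGIES:
        g, st = annual_acc(s)
        reg[f"cost_annual.{s.value}"] = ("cost", g, st)

    def event_acc(ev):
        return (lambda mi: mi.costs.event[ev],
                lambda mi, v: mi.costs.event.__setitem__(ev, v))

    for e in EVENTS:
        g, st = event_acc(e)
        reg[f"cost_event.{e.value}"] = ("cost", g, st)

    def util_acc(fld):
        return (lambda mi: getattr(mi.utilities, fld),
                lambda mi, v: setattr(mi.utilities, fld, v))

    for fld in _UTILITY_FIELDS:
        g, st = util_acc(fld)
        reg[fld] = ("utility", g, st)

    return reg


_REGISTRY = _build_registry()

PARAMETER_IDS: tuple[str, ...] = tuple(_REGISTRY)


def parameter_kind(pid: str) -> str:
    """Return ``"probability"``, ``"utility"`` or ``"cost"`` for an identifier."""
    if pid not in _REGISTRY:
        raise KeyError(f"unknown parameter identifier {pid!r}; "
                       f"known identifiers: {sorted(_REGISTRY)}")
    return _REGISTRY[pid][0]


def get_parameter(inputs: ModelInputs, pid: str) -> float:
    if pid not in _REGISTRY:
        raise KeyError(f"unknown parameter identifier {pid!r}")
    return _REGISTRY[pid][1](inputs)


def set_parameter(inputs: ModelInputs, pid: str, value: float) -> None:
    if pid not in _REGISTRY:
        raise KeyError(f"unknown parameter identifier {pid!r}")
    _REGISTRY[pid][2](inputs, float(value))


def ranged_parameter_ids(inputs: ModelInputs) -> list[str]:
    """Identifiers with a non-degenerate plausible range."""
    return [pid for pid in PARAMETER_IDS
            if pid in inputs.ranges and not inputs.ranges[pid].degenerate]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

_SPLIT_TOL = 1e-9


def validate(inputs: ModelInputs) -> ValidationReport:
    """Check every model invariant; issues are reported, never raised."""
    rep = ValidationReport()

    for s in STRATEGIES:
        if s not in inputs.risks:
            rep.add("missing_strategy", f"strategy {s.value!r} has no event risks")
            continue
        r = inputs.risks[s]
        for fld in _RISK_FIELDS:
            v = getattr(r, fld)
            if not (0.0 <= v <= 1.0):
                rep.add("prob_out_of_range",
                        f"{fld}.{s.value} = {v} probability outside [0,1]")
        if r.total() > 1.0 + 1e-12:
            rep.add("prob_sum_exceeds_1",
                    f"competing event probabilities for {s.value} sum to "
                    f"{r.total():.6f} > 1")

    for name, split in (("ischemic stroke", inputs.is_split),
                        ("intracranial hemorrhage", inputs.ich_split)):
        for fld in ("f_light", "f_moderate", "f_severe", "f_die"):
            v = getattr(split, fld)
            if not (0.0 <= v <= 1.0):
                rep.add("prob_out_of_range",
                        f"{name} split {fld} = {v} outside [0,1]")
        if abs(split.total() - 1.0) > _SPLIT_TOL:
            rep.add("split_not_normalized",
                    f"{name} severity split not normalized (sum = {split.total():.9f})")

    for name, fate in (("ECH", inputs.ech_fate), ("MI", inputs.mi_fate)):
        if not (0.0 <= fate.f_die <= 1.0):
            rep.add("prob_out_of_range",
                    f"{name} fatality {fate.f_die} outside [0,1]")

    for s in STRATEGIES:
        if s not in inputs.costs.annual_treatment:
            rep.add("missing_strategy", f"no annual treatment cost for {s.value!r}")
        elif inputs.costs.annual_treatment[s] < 0:
            rep.add("cost_negative",
                    f"annual treatment cost for {s.value} is negative")
    for e in EVENTS:
        if e not in inputs.costs.event:
            rep.add("missing_event", f"no event cost for {e.value!r}")
        elif inputs.costs.event[e] < 0:
            rep.add("cost_negative", f"event cost for {e.value} is negative")

    u = inputs.utilities
    for fld in _UTILITY_FIELDS:
        v = getattr(u, fld)
        if not (0.0 <= v <= 1.0):
            rep.add("utility_out_of_range", f"{fld} = {v} outside [0,1]")
    if not (u.u_min >= u.u_mod >= u.u_sev):
        rep.add("utility_order",
                f"state utilities not ordered: u_min={u.u_min}, "
                f"u_mod={u.u_mod}, u_sev={u.u_sev}")

    for pid, rng in inputs.ranges.items():
        if pid not in _REGISTRY:
            rep.add("range_unknown_parameter",
                    f"range given for unknown parameter {pid!r}")
            continue
        if not (rng.low <= rng.base <= rng.high):
            rep.add("range_invalid",
                    f"range for {pid} violates low <= base <= high "
                    f"({rng.low}, {rng.base}, {rng.high})")

    rc = inputs.run
    if rc.horizon_cycles < 1:
        rep.add("run_config_invalid", "horizon_cycles must be >= 1")
    if rc.discount_rate < 0:
        rep.add("run_config_invalid", "discount_rate must be >= 0")
    if rc.wtp < 0:
        rep.add("run_config_invalid", "wtp must be >= 0")
    if rc.psa_draws < 1:
        rep.add("run_config_invalid", "psa_draws must be >= 1")

    return rep


# ---------------------------------------------------------------------------
# Configuration I/O
# ---------------------------------------------------------------------------

_EVENT_OUTCOME_KEYS = {
    "ischemic_stroke": "is_split",
    "intracranial_hemorrhage": "ich_split",
    "extracranial_hemorrhage": "ech_fate",
    "myocardial_infarction": "mi_fate",
}

_RUN_FIELDS = set(RunConfig.__dataclass_fields__)


def _read_scalar(node, context: str) -> tuple[float, ParameterRange]:
    """Parse a number or a ``{value, range}`` mapping into (value, range)."""
    if isinstance(node, (int, float)) and not isinstance(node, bool):
        v = float(node)
        return v, ParameterRange(v, v, v)
    if isinstance(node, Mapping):
        unknown = set(node) - {"value", "range"}
        if unknown:
            raise SchemaError(f"unknown key {sorted(unknown)[0]!r} in {context}")
        if "value" not in node:
            raise SchemaError(f"missing 'value' in {context}")
        v = float(node["value"])
        if "range" in node and node["range"] is not None:
            rng = node["range"]
            if not (isinstance(rng, (list, tuple)) and len(rng) == 2):
                raise SchemaError(f"'range' in {context} must be [low, high]")
            return v, ParameterRange(v, float(rng[0]), float(rng[1]))
        return v, ParameterRange(v, v, v)
    raise SchemaError(f"cannot interpret {node!r} as a scalar in {context}")


def _from_dict(data: Mapping) -> ModelInputs:
    if not isinstance(data, Mapping):
        raise SchemaError("configuration root must be a mapping")
    for section in ("strategies", "event_outcomes", "costs", "utilities"):
        if section not in data:
            raise SchemaError(f"missing top-level section {section!r}")

    ranges: dict[str, ParameterRange] = {}

    risks: dict[Strategy, EventRisks] = {}
    for label, block in data["strategies"].items():
        s = canonical_strategy(label)
        if not isinstance(block, Mapping):
            raise SchemaError(f"strategy block {label!r} must be a mapping")
        unknown = set(block) - set(_RISK_FIELDS)
        if unknown:
            raise SchemaError(f"unknown key {sorted(unknown)[0]!r} in strategy {label!r}")
        vals = {}
        for fld in _RISK_FIELDS:
            if fld not in block:
                raise SchemaError(f"strategy {label!r} is missing field {fld!r}")
            v, rng = _read_scalar(block[fld], f"strategies.{label}.{fld}")
            vals[fld] = v
            ranges[f"{fld}.{s.value}"] = rng
        risks[s] = EventRisks(**vals)
    missing = [s.value for s in STRATEGIES if s not in risks]
    if missing:
        raise SchemaError(f"missing strategy block(s): {missing}")

    eo = data["event_outcomes"]
    splits: dict[str, object] = {}
    for key, attr in _EVENT_OUTCOME_KEYS.items():
        if key not in eo:
            raise SchemaError(f"missing event_outcomes block {key!r}")
        block = eo[key]
        if attr in ("is_split", "ich_split"):
            prefix = "is_split" if attr == "is_split" else "ich_split"
            vals = {}
            for name, fld in _SPLIT_FIELDS.items():
                if name not in block:
                    raise SchemaError(f"event_outcomes.{key} is missing {name!r}")
                v, rng = _read_scalar(block[name], f"event_outcomes.{key}.{name}")
                vals[fld] = v
                ranges[f"{prefix}.{name}"] = rng
            splits[attr] = SeveritySplit(**vals)
        else:
            if "die" not in block:
                raise SchemaError(f"event_outcomes.{key} is missing 'die'")
            v, rng = _read_scalar(block["die"], f"event_outcomes.{key}.die")
            splits[attr] = SimpleFatality(v)
            ranges["ech_fatality" if attr == "ech_fate" else "mi_fatality"] = rng

    cblock = data["costs"]
    for sub in ("annual_treatment", "event"):
        if sub not in cblock:
            raise SchemaError(f"missing costs block {sub!r}")
    annual: dict[Strategy, float] = {}
    for label, node in cblock["annual_treatment"].items():
        s = canonical_strategy(label)
        v, rng = _read_scalar(node, f"costs.annual_treatment.{label}")
        annual[s] = v
        ranges[f"cost_annual.{s.value}"] = rng
    missing = [s.value for s in STRATEGIES if s not in annual]
    if missing:
        raise SchemaError(f"missing annual treatment cost for: {missing}")
    event_costs: dict[Event, float] = {}
    for label, node in cblock["event"].items():
        try:
            e = Event(str(label).upper())
        except ValueError:
            raise SchemaError(f"unknown event label {label!r} in costs.event")
        v, rng = _read_scalar(node, f"costs.event.{label}")
        event_costs[e] = v
        ranges[f"cost_event.{e.value}"] = rng
    missing = [e.value for e in EVENTS if e not in event_costs]
    if missing:
        raise SchemaError(f"missing event cost for: {missing}")

    ublock = data["utilities"]
    uvals = {}
    for fld in _UTILITY_FIELDS:
        if fld not in ublock:
            raise SchemaError(f"utilities section is missing {fld!r}")
        v, rng = _read_scalar(ublock[fld], f"utilities.{fld}")
        uvals[fld] = v
        ranges[fld] = rng

    run_kwargs = {}
    for key, v in (data.get("run") or {}).items():
        if key not in _RUN_FIELDS:
            raise SchemaError(f"unknown key {key!r} in run section")
        run_kwargs[key] = v
    run = RunConfig(**run_kwargs)

    inputs = ModelInputs(
        risks=risks,
        is_split=splits["is_split"],
        ich_split=splits["ich_split"],
        ech_fate=splits["ech_fate"],
        mi_fate=splits["mi_fate"],
        costs=CostInputs(annual_treatment=annual, event=event_costs),
        utilities=UtilityInputs(**uvals),
        ranges=ranges,
        run=run,
    )
    report = validate(inputs)
    if not report.ok:
        raise ValidationError(report)
    return inputs


def load_model_inputs(source) -> ModelInputs:
    """Load and validate a parameter set.

    ``source`` may be a mapping, a path to a YAML/JSON file, or YAML text.
    Raises :class:`ConfigError` on parse failure, :class:`SchemaError` on a
    missing or unknown key, and :class:`ValidationError` when a parsed set
    violates a model invariant.
    """
    if isinstance(source, Mapping):
        return _from_dict(source)
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).exists()):
        text = Path(source).read_text()
    elif hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str):
        text = source
    else:
        raise ConfigError(f"cannot load model inputs from {type(source).__name__}")
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse configuration: {exc}") from exc
    if data is None:
        raise SchemaError("configuration file is empty")
    return _from_dict(data)


def _scalar_node(value: float, rng: ParameterRange | None):
    if rng is None or rng.degenerate:
        return {"value": value}
    return {"value": value, "range": [rng.low, rng.high]}


def to_dict(inputs: ModelInputs) -> dict:
    """Serialize a parameter set to the configuration-file schema."""
    R = inputs.ranges.get
    out: dict = {"strategies": {}, "event_outcomes": {}, "costs": {}, "utilities": {}}
    for s in STRATEGIES:
        r = inputs.risks[s]
        out["strategies"][s.value] = {
            fld: _scalar_node(getattr(r, fld), R(f"{fld}.{s.value}"))
            for fld in _RISK_FIELDS
        }
    for key, attr in _EVENT_OUTCOME_KEYS.items():
        obj = getattr(inputs, attr)
        if isinstance(obj, SeveritySplit):
            prefix = "is_split" if attr == "is_split" else "ich_split"
            out["event_outcomes"][key] = {
                name: _scalar_node(getattr(obj, fld), R(f"{prefix}.{name}"))
                for name, fld in _SPLIT_FIELDS.items()
            }
        else:
            pid = "ech_fatality" if attr == "ech_fate" else "mi_fatality"
            out["event_outcomes"][key] = {"die": _scalar_node(obj.f_die, R(pid))}
    out["costs"]["annual_treatment"] = {
        s.value: _scalar_node(inputs.costs.annual_treatment[s], R(f"cost_annual.{s.value}"))
        for s in STRATEGIES
    }
    out["costs"]["event"] = {
        e.value: _scalar_node(inputs.costs.event[e], R(f"cost_event.{e.value}"))
        for e in EVENTS
    }
    out["utilities"] = {
        fld: _scalar_node(getattr(inputs.utilities, fld), R(fld))
        for fld in _UTILITY_FIELDS
    }
    out["run"] = asdict(inputs.run)
    return out


def save_model_inputs(inputs: ModelInputs, path) -> None:
    Path(path).write_text(yaml.safe_dump(to_dict(inputs), sort_keys=False))


_BASE_CASE_CACHE: ModelInputs | None = None


def base_case_inputs() -> ModelInputs:
    """The shipped base-case parameter set (a fresh, mutable copy)."""
    global _BASE_CASE_CACHE
    if _BASE_CASE_CACHE is None:
        from importlib import resources
        text = resources.files("afib_cea").joinpath(
            "data/table1_base_case.yaml").read_text()
        _BASE_CASE_CACHE = load_model_inputs(text)
    return _BASE_CASE_CACHE.copy()


def reference_results() -> dict[str, tuple[float, float]]:
    """Published base-case totals per strategy as ``{label: (cost, QALY)}``.

    These are the reference summary results for this decision problem; the
    incremental-analysis layer reproduces the published increments and
    ICERs from them, and tests use them as a regression anchor.  They are
    not produced by this package's engine.
    """
    return {
        Strategy.WARFARIN.value: (5317.31, 11.07),
        Strategy.RIVAROXABAN.value: (29673.33, 15.46),
        Strategy.DABIGATRAN110.value: (23615.48, 12.40),
        Strategy.DABIGATRAN150.value: (34324.91, 15.00),
    }
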