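"""Protocol definitions, selection, and traffic-light constraint evaluation.

Protocols ship as editable text files (``data/protocols/*.txt``): a header
block with the selection rule followed by one constraint line per rule.
Comparisons are inclusive and applied to values rounded to one decimal,
matching the clinical reading of limits like "<= 20".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources

from .dvhcore import DVHCurve, MetricSpec, format_metric, metric_value, parse_metric
from .exceptions import FormatError, NoMatchError, UnitError, ValidationError
from .planmodel import PlanProperties, StructureMapping
from .rtio import PlanInfo

DISPLAY_DECIMALS = 1

PROTOCOL_NAMES = ("RTOG1005", "FAST_FORWARD", "FAST", "EUROPA_PBI", "EUROPA_WBI")


class Comparator(str, Enum):
    LE = "<="
    GE = ">="


class Status(str, Enum):
    GREEN = "GREEN"
    YELLOW = "YELLOW"
    RED = "RED"
    NOT_EVALUATED = "NOT_EVALUATED"


class ConstraintGroup(str, Enum):
    PTV = "PTV"
    MAIN_OAR = "MAIN_OAR"
    OTHER_OAR = "OTHER_OAR"


NOT_EVALUATED = None  # sentinel for a value that could not be computed


@dataclass(frozen=True)
class DoseConstraint:
    role: str
    metric: MetricSpec
    comparator: Comparator
    mandatory_limit: float
    optimal_limit: float | None = None
    is_extra: bool = False
    group: ConstraintGroup = ConstraintGroup.MAIN_OAR

    def __post_init__(self) -> None:
        if self.mandatory_limit < 0:
            raise ValidationError("constraint limits must be >= 0")
        if self.optimal_limit is not None:
            stricter = (
                self.optimal_limit < self.mandatory_limit
                if self.comparator == Comparator.LE
                else self.optimal_limit > self.mandatory_limit
            )
            if not stricter:
                raise ValidationError(
                    f"optimal limit {self.optimal_limit} is not stricter than "
                    f"mandatory {self.mandatory_limit} under {self.comparator.value}"
                )

    @property
    def label(self) -> str:
        return f"{self.role} {format_metric(self.metric)}"


@dataclass(frozen=True)
class SelectionRule:
    fractions: frozenset[int]
    dose_per_fraction: tuple[float, float]  # inclusive window, Gy
    min_ptvs: int = 1
    max_ptvs: int = 3

    def matches(self, dose_per_fraction: float, n_fractions: int, n_ptvs: int) -> bool:
        lo, hi = self.dose_per_fraction
        return (
            n_fractions in self.fractions
            and lo <= round(dose_per_fraction, 3) <= hi
            and self.min_ptvs <= n_ptvs <= self.max_ptvs
        )


@dataclass
class Protocol:
    name: str
    selection: list[SelectionRule]
    constraints: list[DoseConstraint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.name not in PROTOCOL_NAMES:
            raise ValidationError(f"unknown protocol name {self.name!r}")
        if not self.selection:
            raise ValidationError(f"protocol {self.name}: at least one selection rule")

    def matches(self, dose_per_fraction: float, n_fractions: int, n_ptvs: int) -> bool:
        return any(
            r.matches(dose_per_fraction, n_fractions, n_ptvs) for r in self.selection
        )


@dataclass
class ConstraintResult:
    constraint: DoseConstraint
    value: float | None
    status: Status

    @property
    def display_tier(self) -> str:
        return "EXTRA" if self.constraint.is_extra else "STANDARD"


@dataclass
class PlanEvaluation:
    protocol: Protocol
    properties: PlanProperties
    mapping: StructureMapping
    results: list[ConstraintResult]
    bw_score: int | None = None


# ---------------------------------------------------------------------------
# protocol file format

def _parse_selection(value: str) -> SelectionRule:
    # "5 fx @ 5.0-5.4 Gy/fx, 1-3 ptvs"
    try:
        fx_part, rest = value.split("@")
        dose_part, ptv_part = rest.split(",")
        fractions = frozenset(int(v) for v in fx_part.replace("fx", "").split("/"))
        lo, hi = (float(v) for v in dose_part.replace("Gy/fx", "").strip().split("-"))
        p_lo, p_hi = (int(v) for v in ptv_part.replace("ptvs", "").strip().split("-"))
    except ValueError as exc:
        raise FormatError(f"cannot parse selection rule {value!r}") from exc
    return SelectionRule(fractions, (lo, hi), p_lo, p_hi)


def _format_selection(rule: SelectionRule) -> str:
    fx = "/".join(str(f) for f in sorted(rule.fractions))
    lo, hi = rule.dose_per_fraction
    return f"{fx} fx @ {lo:g}-{hi:g} Gy/fx, {rule.min_ptvs}-{rule.max_ptvs} ptvs"


def parse_protocol(text: str) -> Protocol:
    """Parse the text protocol format (see :func:`format_protocol`)."""
    name: str | None = None
    rules: list[SelectionRule] = []
    constraints: list[DoseConstraint] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "|" in line:
            parts = [p.strip() for p in line.split("|")]
            if len(parts) != 7:
                raise FormatError(
                    f"protocol line {lineno}: expected 7 '|'-separated fields"
                )
            role, metric_s, cmp_s, mand_s, opt_s, extra_s, group_s = parts
            constraints.append(DoseConstraint(
                role=role,
                metric=parse_metric(metric_s),
                comparator=Comparator(cmp_s),
                mandatory_limit=float(mand_s),
                optimal_limit=float(opt_s) if opt_s not in ("", "-") else None,
                is_extra=extra_s.lower() in ("extra", "true", "yes", "1", "*"),
                group=ConstraintGroup(group_s),
            ))
        elif "=" in line:
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "name":
                name = value
            elif key == "selection":
                rules.append(_parse_selection(value))
            else:
                raise FormatError(f"protocol line {lineno}: unknown key {key!r}")
        else:
            raise FormatError(f"protocol line {lineno}: cannot parse {raw!r}")
    if name is None:
        raise FormatError("protocol file missing 'name ='")
    return Protocol(name=name, selection=rules, constraints=constraints)


def format_protocol(protocol: Protocol) -> str:
    """Serialize to the text format; ``parse_protocol(format_protocol(p)) == p``."""
    lines = [f"name = {protocol.name}"]
    lines += [f"selection = {_format_selection(r)}" for r in protocol.selection]
    for c in protocol.constraints:
        opt = f"{c.optimal_limit:g}" if c.optimal_limit is not None else "-"
        lines.append(
            f"{c.role} | {format_metric(c.metric)} | {c.comparator.value} | "
            f"{c.mandatory_limit:g} | {opt} | {'extra' if c.is_extra else 'std'} | "
            f"{c.group.value}"
        )
    return "\n".join(lines) + "\n"


def load_protocol(name_or_path: str) -> Protocol:
    """Load a shipped protocol by name, or any protocol file by path."""
    if name_or_path in PROTOCOL_NAMES:
        text = (
            resources.files("planwatch.data.protocols")
            .joinpath(f"{name_or_path}.txt").read_text("utf-8")
        )
    else:
        with open(name_or_path, "r", encoding="utf-8") as fh:
            text = fh.read()
    return parse_protocol(text)


def load_all_protocols() -> list[Protocol]:
    return [load_protocol(name) for name in PROTOCOL_NAMES]


# ---------------------------------------------------------------------------
# selection & evaluation

def select_protocol(
    plan: PlanInfo,
    n_ptvs: int,
    override: str | None = None,
    protocols: list[Protocol] | None = None,
) -> Protocol:
    """Pick the protocol whose selection rule matches the plan's prescription."""
    protocols = protocols if protocols is not None else load_all_protocols()
    if override is not None:
        for p in protocols:
            if p.name == override:
                return p
        raise NoMatchError(f"no protocol named {override!r}")
    dpf = plan.dose_per_fraction
    matches = [p for p in protocols if p.matches(dpf, plan.n_fractions, n_ptvs)]
    if len(matches) == 1:
        return matches[0]
    if len(matches) > 1:
        raise NoMatchError(
            f"ambiguous protocol selection: {[p.name for p in matches]} all match "
            f"{dpf:.2f} Gy/fx x {plan.n_fractions}"
        )
    near = ", ".join(
        f"{p.name} ({'; '.join(_format_selection(r) for r in p.selection)})"
        for p in protocols
    )
    raise NoMatchError(
        f"no protocol matches {dpf:.2f} Gy/fx x {plan.n_fractions} fx with "
        f"{n_ptvs} PTV(s); shipped rules: {near}"
    )


def evaluate_constraint(value: float | None, c: DoseConstraint) -> ConstraintResult:
    """Traffic-light a single value (inclusive comparison at display precision)."""
    if value is None:
        return ConstraintResult(c, None, Status.NOT_EVALUATED)
    v = round(float(value), DISPLAY_DECIMALS)

    def passes(limit: float) -> bool:
        return v <= limit if c.comparator == Comparator.LE else v >= limit

    if not passes(c.mandatory_limit):
        return ConstraintResult(c, float(value), Status.RED)
    if c.optimal_limit is not None and not passes(c.optimal_limit):
        return ConstraintResult(c, float(value), Status.YELLOW)
    return ConstraintResult(c, float(value), Status.GREEN)


_GROUP_ORDER = {ConstraintGroup.PTV: 0, ConstraintGroup.MAIN_OAR: 1, ConstraintGroup.OTHER_OAR: 2}


def evaluate_plan(
    curves: list[DVHCurve],
    mapping: StructureMapping,
    protocol: Protocol,
    properties: PlanProperties,
) -> PlanEvaluation:
    """Evaluate every protocol constraint against the mapped structures' curves."""
    if mapping.name_for("PTV_BREAST") is None:
        raise ValidationError("structure mapping must cover PTV_BREAST")
    by_name = {c.structure_name: c for c in curves}
    results: list[ConstraintResult] = []
    for c in sorted(protocol.constraints, key=lambda c: _GROUP_ORDER[c.group]):
        structure_name = mapping.name_for(c.role)
        curve = by_name.get(structure_name) if structure_name else None
        if curve is None:
            results.append(ConstraintResult(c, None, Status.NOT_EVALUATED))
            continue
        try:
            value = metric_value(curve, c.metric)
        except UnitError:
            results.append(ConstraintResult(c, None, Status.NOT_EVALUATED))
            continue
        results.append(evaluate_constraint(value, c))
    evaluation = PlanEvaluation(protocol, properties, mapping, results)
    from .scoring import bw_score  # deferred: scoring depends on this module
    try:
        evaluation.bw_score = bw_score(evaluation)
    except ValidationError:
        evaluation.bw_score = None
    return evaluation
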