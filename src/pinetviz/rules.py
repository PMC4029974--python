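"""Declarative styling rules: target + condition + action.

A rule names a target (proteins or interactions), an optional condition
(the same predicates as prefilters, extended with ``degree``,
``betweenness`` and expression conditions), and an action such as
"paint green", "show label", "size by betweenness" or "color by
functional class".  Rules are plain data — serializable, replayable —
and are applied in list order on top of the documented defaults, so a
later rule overrides earlier values of the same attribute.

Category colors come from a fixed 12-color qualitative palette
(:data:`PALETTE12`); assignment depends only on the first-seen order of
category values over proteins in accession order, making legends
deterministic.  Quantitative coloring interpolates linearly per RGB
channel with round-half-down, so the midpoint of black-to-white is
``#7f7f7f`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import RuleError
from .io import Dataset, InteractionRecord, ProteinRecord
from .metrics import MetricTable, compute_metrics
from .query import (
    NUMERIC_OPS,
    FilterCondition,
    Subnetwork,
    interaction_matches,
    protein_matches,
)

__all__ = [
    "Action",
    "Rule",
    "StyleState",
    "PALETTE12",
    "DEFAULT_NODE_STYLE",
    "DEFAULT_EDGE_STYLE",
    "UNANNOTATED_COLOR",
    "evaluate_condition",
    "apply_rules",
    "quantitative_color",
    "contextual_rule_for",
]

# 12-class qualitative palette (ColorBrewer Set3 hues).
PALETTE12 = [
    "#8dd3c7", "#ffffb3", "#bebada", "#fb8072", "#80b1d3", "#fdb462",
    "#b3de69", "#fccde5", "#d9d9d9", "#bc80bd", "#ccebc5", "#ffed6f",
]
UNANNOTATED_COLOR = "#bdbdbd"
UNANNOTATED_LABEL = "unannotated"

DEFAULT_NODE_STYLE = {"color": "#888888", "size": 5.0, "label": None, "visible": True}
DEFAULT_EDGE_STYLE = {"color": "#999999", "width": 1.0, "visible": True}

_ACTION_KINDS = {
    "set_color": {"color"},
    "color_by_category": {"feature"},
    "color_by_value": {"feature", "vmin", "vmax", "color_low", "color_high"},
    "show_label": {"feature"},
    "hide_label": set(),
    "set_size": {"size"},
    "size_by_value": {"feature", "vmin", "vmax", "size_min", "size_max"},
    "hide": set(),
    "show": set(),
}

_NODE_METRIC_FIELDS = {"degree", "betweenness"}


def _parse_hex(color: str) -> tuple[int, int, int]:
    if not (isinstance(color, str) and color.startswith("#") and len(color) == 7):
        raise RuleError(f"expected '#rrggbb' hex color, got {color!r}")
    try:
        return tuple(int(color[i : i + 2], 16) for i in (1, 3, 5))  # type: ignore[return-value]
    except ValueError:
        raise RuleError(f"expected '#rrggbb' hex color, got {color!r}")


@dataclass(frozen=True)
class Action:
    """A visual action with its typed parameters."""

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _ACTION_KINDS:
            raise RuleError(
                f"unknown action kind {self.kind!r}; expected one of {sorted(_ACTION_KINDS)}"
            )
        missing = _ACTION_KINDS[self.kind] - set(self.params)
        if missing:
            raise RuleError(f"action {self.kind!r} missing params: {sorted(missing)}")
        if self.kind == "set_color":
            _parse_hex(self.params["color"])
        if self.kind == "color_by_value":
            _parse_hex(self.params["color_low"])
            _parse_hex(self.params["color_high"])
        if self.kind in ("color_by_value", "size_by_value"):
            if not self.params["vmin"] < self.params["vmax"]:
                raise RuleError("vmin must be < vmax")
        if self.kind == "set_size" and self.params["size"] <= 0:
            raise RuleError("size must be positive")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "Action":
        return cls(d["kind"], dict(d.get("params", {})))


@dataclass(frozen=True)
class Rule:
    """target + condition + action.  ``condition=None`` matches everything."""

    target: str
    condition: FilterCondition | None
    action: Action

    def __post_init__(self):
        if self.target not in ("protein", "interaction"):
            raise RuleError(f"rule target must be 'protein' or 'interaction', got {self.target!r}")
        if self.condition is not None and self.condition.scope != self.target:
            raise RuleError(
                f"condition scope {self.condition.scope!r} does not match target {self.target!r}"
            )
        if self.target == "interaction" and self.action.kind == "color_by_category":
            raise RuleError("color_by_category applies to protein targets only")

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "condition": self.condition.to_dict() if self.condition else None,
            "action": self.action.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Rule":
        cond = d.get("condition")
        return cls(
            d["target"],
            FilterCondition.from_dict(cond) if cond else None,
            Action.from_dict(d["action"]),
        )


@dataclass
class StyleState:
    """Resolved per-element visual attributes plus the category legend."""

    node_style: dict[str, dict]
    edge_style: dict[tuple[str, str], dict]
    legend: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _numeric_value(
    cond_field: str,
    element: ProteinRecord | InteractionRecord,
    metrics: MetricTable | None,
) -> float | None:
    """Numeric lookup used by rule conditions and *_by_value actions."""
    if isinstance(element, ProteinRecord):
        if cond_field in _NODE_METRIC_FIELDS:
            if metrics is None or element.accession not in metrics:
                raise RuleError(f"metrics required for field {cond_field!r}")
            return float(metrics[element.accession][cond_field])
        if element.expression and cond_field in element.expression:
            return element.expression[cond_field]
        value = element.features.get(cond_field)
        if value is not None:
            try:
                return float(value)
            except ValueError:
                return None
        return None
    if cond_field == "score":
        return element.score
    return element.evidence.get(cond_field)


def compile_rules(rules: list[Rule], dataset: Dataset) -> None:
    """Type-check rule conditions up front (numeric ops on numeric fields)."""
    numeric_protein = _NODE_METRIC_FIELDS | set(dataset.expression_columns)
    numeric_interaction = {"score"} | set(dataset.evidence_columns)
    for i, rule in enumerate(rules):
        cond = rule.condition
        if cond is None:
            continue
        numeric_fields = numeric_protein if rule.target == "protein" else numeric_interaction
        if cond.operator in NUMERIC_OPS and cond.field not in numeric_fields:
            raise RuleError(
                f"rule {i}: numeric operator {cond.operator!r} on non-numeric "
                f"field {cond.field!r}"
            )


def evaluate_condition(
    condition: FilterCondition | None,
    element: ProteinRecord | InteractionRecord,
    subnetwork: Subnetwork,
    dataset: Dataset,
    metrics: MetricTable | None = None,
) -> bool:
    """Pure predicate deciding whether a rule condition holds for an element."""
    if condition is None:
        return True
    if isinstance(element, ProteinRecord):
        if condition.field in _NODE_METRIC_FIELDS:
            value = _numeric_value(condition.field, element, metrics)
            if condition.operator == "present":
                return value is not None
            if condition.operator in NUMERIC_OPS or condition.operator == "equals":
                ref = float(condition.value)
                return {
                    "gt": value > ref,
                    "ge": value >= ref,
                    "lt": value < ref,
                    "le": value <= ref,
                    "equals": value == ref,
                }[condition.operator]
            raise RuleError(f"operator {condition.operator!r} invalid for {condition.field!r}")
        return protein_matches(condition, element)
    return interaction_matches(condition, element)


def quantitative_color(
    value: float, vmin: float, vmax: float, color_low: str, color_high: str
) -> str:
    """Linear two-color gradient, clamped to [vmin, vmax].

    Channels are interpolated in RGB and rounded *half down* to integers
    (midpoint of #000000..#ffffff is 127 = #7f7f7f), keeping output
    bit-stable across platforms.
    """
    if not vmin < vmax:
        raise RuleError(f"vmin must be < vmax (got {vmin!r}, {vmax!r})")
    lo = _parse_hex(color_low)
    hi = _parse_hex(color_high)
    t = (value - vmin) / (vmax - vmin)
    t = min(1.0, max(0.0, t))
    channels = []
    for a, b in zip(lo, hi):
        x = a + t * (b - a)
        channels.append(int(math.ceil(x - 0.5)))  # round half down
    return "#{:02x}{:02x}{:02x}".format(*channels)


def _lerp_size(value, vmin, vmax, size_min, size_max) -> float:
    t = (value - vmin) / (vmax - vmin)
    t = min(1.0, max(0.0, t))
    return size_min + t * (size_max - size_min)


def apply_rules(
    subnetwork: Subnetwork,
    rules: list[Rule],
    dataset: Dataset,
    metrics: MetricTable | None = None,
) -> StyleState:
    """Resolve defaults + ordered rules into one StyleState.

    Every displayed protein and interaction gets a style entry; later
    rules override earlier attribute writes on the same element.  The
    legend reflects the categories of the *last* ``color_by_category``
    rule applied.
    """
    compile_rules(rules, dataset)
    if metrics is None:
        metrics = compute_metrics(subnetwork)
    nodes = sorted(subnetwork.proteins)
    edges = subnetwork.sorted_interactions()
    state = StyleState(
        node_style={acc: dict(DEFAULT_NODE_STYLE) for acc in nodes},
        edge_style={rec.key: dict(DEFAULT_EDGE_STYLE) for rec in edges},
    )
    for rule in rules:
        if rule.target == "protein":
            matched = [
                acc
                for acc in nodes
                if evaluate_condition(
                    rule.condition, dataset.proteins[acc], subnetwork, dataset, metrics
                )
            ]
            _apply_to_nodes(state, rule.action, matched, dataset, metrics)
        else:
            matched_edges = [
                rec
                for rec in edges
                if evaluate_condition(rule.condition, rec, subnetwork, dataset, metrics)
            ]
            _apply_to_edges(state, rule.action, matched_edges)
    return state


def _apply_to_nodes(
    state: StyleState,
    action: Action,
    matched: list[str],
    dataset: Dataset,
    metrics: MetricTable,
) -> None:
    kind, params = action.kind, action.params
    if kind == "set_color":
        for acc in matched:
            state.node_style[acc]["color"] = params["color"]
    elif kind == "color_by_category":
        feature = params["feature"]
        assignment: dict[str, str] = {}
        has_unannotated = False
        for acc in matched:
            p = dataset.proteins[acc]
            value = p.organism if feature == "organism" else p.features.get(feature)
            if value is None:
                has_unannotated = True
                state.node_style[acc]["color"] = UNANNOTATED_COLOR
                continue
            if value not in assignment:
                idx = len(assignment)
                if idx == len(PALETTE12):
                    state.warnings.append(
                        f"more than {len(PALETTE12)} categories for {feature!r}: palette cycling"
                    )
                assignment[value] = PALETTE12[idx % len(PALETTE12)]
            state.node_style[acc]["color"] = assignment[value]
        state.legend = list(assignment.items())
        if has_unannotated:
            state.legend.append((UNANNOTATED_LABEL, UNANNOTATED_COLOR))
    elif kind == "color_by_value":
        for acc in matched:
            value = _numeric_value(params["feature"], dataset.proteins[acc], metrics)
            if value is None:
                continue
            state.node_style[acc]["color"] = quantitative_color(
                value, params["vmin"], params["vmax"], params["color_low"], params["color_high"]
            )
    elif kind == "show_label":
        feature = params["feature"]
        for acc in matched:
            p = dataset.proteins[acc]
            if feature == "accession":
                text = acc
            else:
                # fall back to the accession when the annotation is absent
                text = p.features.get(feature, acc)
            state.node_style[acc]["label"] = text
    elif kind == "hide_label":
        for acc in matched:
            state.node_style[acc]["label"] = None
    elif kind == "set_size":
        for acc in matched:
            state.node_style[acc]["size"] = float(params["size"])
    elif kind == "size_by_value":
        for acc in matched:
            value = _numeric_value(params["feature"], dataset.proteins[acc], metrics)
            if value is None:
                continue
            state.node_style[acc]["size"] = _lerp_size(
                value, params["vmin"], params["vmax"], params["size_min"], params["size_max"]
            )
    elif kind == "hide":
        for acc in matched:
            state.node_style[acc]["visible"] = False
    elif kind == "show":
        for acc in matched:
            state.node_style[acc]["visible"] = True


def _apply_to_edges(
    state: StyleState, action: Action, matched: list[InteractionRecord]
) -> None:
    kind, params = action.kind, action.params
    if kind == "set_color":
        for rec in matched:
            state.edge_style[rec.key]["color"] = params["color"]
    elif kind == "color_by_value":
        for rec in matched:
            value = rec.score if params["feature"] == "score" else rec.evidence.get(params["feature"])
            if value is None:
                continue
            state.edge_style[rec.key]["color"] = quantitative_color(
                value, params["vmin"], params["vmax"], params["color_low"], params["color_high"]
            )
    elif kind == "set_size":
        for rec in matched:
            state.edge_style[rec.key]["width"] = float(params["size"])
    elif kind == "size_by_value":
        for rec in matched:
            value = rec.score if params["feature"] == "score" else rec.evidence.get(params["feature"])
            if value is None:
                continue
            state.edge_style[rec.key]["width"] = _lerp_size(
                value, params["vmin"], params["vmax"], params["size_min"], params["size_max"]
            )
    elif kind == "hide":
        for rec in matched:
            state.edge_style[rec.key]["visible"] = False
    elif kind == "show":
        for rec in matched:
            state.edge_style[rec.key]["visible"] = True
    elif kind in ("show_label", "hide_label", "color_by_category"):
        raise RuleError(f"action {kind!r} does not apply to interactions")


def contextual_rule_for(
    subnetwork: Subnetwork, accession: str, action: Action
) -> Rule:
    """Build the single-protein rule the contextual menu would create."""
    if accession not in subnetwork.proteins:
        raise RuleError(f"accession {accession!r} is not displayed")
    return Rule(
        "protein",
        FilterCondition("protein", "accession", "equals", accession),
        action,
    )
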