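"""Prefilters, the three search modes, and accession autocomplete.

A *prefilter* is an ordered conjunction of conditions applied to the
whole dataset before anything is displayed; the running interaction
count after each condition is reported so the user can see how each
filter shrinks the network.

The three search modes, given a list of query accessions Q and the
currently displayed subnetwork D:

* **normal** — Q plus every interaction with at least one endpoint in Q;
* **explicit** — only interactions among Q itself, plus interactions
  between Q and proteins already in D;
* **recursive** — the induced subgraph on Q and all its neighbors, so
  every interaction between displayed proteins becomes visible.

All three are additive: they never remove anything already displayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import QueryError
from .io import Dataset, InteractionRecord, ProteinRecord

__all__ = [
    "FilterCondition",
    "FilterSummary",
    "Subnetwork",
    "full_subnetwork",
    "apply_prefilters",
    "search",
    "autocomplete",
    "get_protein_card",
    "parse_condition",
]

NUMERIC_OPS = {"gt", "ge", "lt", "le"}
STRING_OPS = {"contains", "equals"}
ALL_OPS = NUMERIC_OPS | STRING_OPS | {"present"}
SEARCH_MODES = ("normal", "explicit", "recursive")


@dataclass(frozen=True)
class FilterCondition:
    """A single predicate on proteins or interactions.

    ``scope`` is ``"protein"`` or ``"interaction"``; ``field`` names what
    is tested (organism/accession/any feature for proteins; score, an
    evidence source, or the endpoint ``accession`` for interactions —
    rules additionally allow degree/betweenness/expression conditions).
    """

    scope: str
    field: str
    operator: str
    value: str | float | None = None

    def __post_init__(self):
        if self.scope not in ("protein", "interaction"):
            raise QueryError(f"unknown condition scope {self.scope!r}")
        if self.operator not in ALL_OPS:
            raise QueryError(f"unknown operator {self.operator!r}")
        if self.operator == "present":
            if self.value is not None:
                raise QueryError("'present' takes no value")
        elif self.value is None:
            raise QueryError(f"operator {self.operator!r} requires a value")
        if self.operator in NUMERIC_OPS and not isinstance(self.value, (int, float)):
            raise QueryError(
                f"operator {self.operator!r} requires a numeric value, got {self.value!r}"
            )

    def to_dict(self) -> dict:
        d = {"scope": self.scope, "field": self.field, "op": self.operator}
        if self.value is not None:
            d["value"] = self.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FilterCondition":
        return cls(d["scope"], d["field"], d["op"], d.get("value"))


@dataclass
class Subnetwork:
    """The displayed selection: a closed set of proteins and interactions."""

    proteins: set[str] = field(default_factory=set)
    interactions: list[InteractionRecord] = field(default_factory=list)

    def __post_init__(self):
        for rec in self.interactions:
            for acc in rec.key:
                if acc not in self.proteins:
                    raise QueryError(
                        f"subnetwork not closed: endpoint {acc!r} missing from proteins"
                    )

    @property
    def edge_keys(self) -> set[tuple[str, str]]:
        return {rec.key for rec in self.interactions}

    def __eq__(self, other) -> bool:
        if not isinstance(other, Subnetwork):
            return NotImplemented
        return self.proteins == other.proteins and self.edge_keys == other.edge_keys

    def sorted_interactions(self) -> list[InteractionRecord]:
        return sorted(self.interactions, key=lambda r: r.key)

    @classmethod
    def from_edges(
        cls, interactions: list[InteractionRecord], extra_proteins: set[str] = frozenset()
    ) -> "Subnetwork":
        by_key = {rec.key: rec for rec in interactions}
        prots = set(extra_proteins)
        for key in by_key:
            prots.update(key)
        return cls(prots, sorted(by_key.values(), key=lambda r: r.key))


def full_subnetwork(dataset: Dataset) -> Subnetwork:
    """The whole dataset as a subnetwork (isolated proteins included)."""
    return Subnetwork.from_edges(list(dataset.interactions), set(dataset.proteins))


@dataclass
class FilterSummary:
    """Prefilter outcome: per-step cumulative counts plus the subnetwork.

    ``total`` is the implicit step 0 — the dataset-wide interaction
    count before any condition is applied.
    """

    total: int
    steps: list[tuple[FilterCondition, int]]
    result: Subnetwork

    @property
    def counts(self) -> list[int]:
        return [c for _, c in self.steps]


def _protein_fields(dataset: Dataset) -> list[str]:
    return ["accession", "organism"] + dataset.feature_columns + dataset.expression_columns


def _interaction_fields(dataset: Dataset) -> list[str]:
    return ["score", "accession"] + dataset.evidence_columns


def _check_field(dataset: Dataset, cond: FilterCondition) -> None:
    known = (
        _protein_fields(dataset) if cond.scope == "protein" else _interaction_fields(dataset)
    )
    if cond.field not in known:
        raise QueryError(
            f"unknown {cond.scope} field {cond.field!r}; available: {', '.join(known)}"
        )


def _compare_number(op: str, left: float, right: float) -> bool:
    return {
        "gt": left > right,
        "ge": left >= right,
        "lt": left < right,
        "le": left <= right,
        "equals": left == right,
    }[op]


def protein_matches(cond: FilterCondition, protein: ProteinRecord) -> bool:
    """Evaluate a protein-scope condition against one protein."""
    f = cond.field
    if f == "accession":
        actual: str | float | None = protein.accession
    elif f == "organism":
        actual = protein.organism
    elif protein.expression is not None and f in protein.expression:
        actual = protein.expression[f]
    elif f in protein.features:
        actual = protein.features[f]
    else:
        actual = None
    if cond.operator == "present":
        return actual is not None
    if actual is None:
        return False
    if cond.operator in NUMERIC_OPS:
        try:
            return _compare_number(cond.operator, float(actual), float(cond.value))
        except (TypeError, ValueError):
            raise QueryError(
                f"numeric operator {cond.operator!r} on non-numeric field {f!r}"
            )
    if cond.operator == "contains":
        return str(cond.value).lower() in str(actual).lower()
    if isinstance(actual, float) and isinstance(cond.value, (int, float)):
        return actual == float(cond.value)
    return str(actual) == str(cond.value)


def interaction_matches(cond: FilterCondition, rec: InteractionRecord) -> bool:
    """Evaluate an interaction-scope condition against one edge."""
    f = cond.field
    if f == "accession":
        # "with protein Y": either endpoint
        if cond.operator == "equals":
            return str(cond.value) in rec.key
        if cond.operator == "contains":
            needle = str(cond.value).lower()
            return any(needle in acc.lower() for acc in rec.key)
        raise QueryError("endpoint accession supports equals/contains only")
    if f == "score":
        actual: float | None = rec.score
    else:
        actual = rec.evidence.get(f)
    if cond.operator == "present":
        return actual is not None
    if actual is None:
        return False
    if cond.operator in NUMERIC_OPS or cond.operator == "equals":
        return _compare_number(cond.operator, actual, float(cond.value))
    return str(cond.value).lower() in repr(actual).lower()


def _edge_passes(
    cond: FilterCondition,
    rec: InteractionRecord,
    dataset: Dataset,
    protein_match: str,
) -> bool:
    if cond.scope == "interaction":
        return interaction_matches(cond, rec)
    results = [protein_matches(cond, dataset.proteins[acc]) for acc in rec.key]
    return all(results) if protein_match == "all" else any(results)


def apply_prefilters(
    dataset: Dataset,
    conditions: list[FilterCondition],
    protein_match: str = "any",
) -> FilterSummary:
    """AND the conditions in order over all interactions of the dataset.

    A protein-scope condition passes an interaction when at least one
    endpoint satisfies it (``protein_match="any"``, the default, which
    keeps host-pathogen edges visible) or when both do
    (``protein_match="all"``).
    """
    if protein_match not in ("any", "all"):
        raise QueryError("protein_match must be 'any' or 'all'")
    for cond in conditions:
        _check_field(dataset, cond)
    current = list(dataset.interactions)
    steps: list[tuple[FilterCondition, int]] = []
    for cond in conditions:
        current = [rec for rec in current if _edge_passes(cond, rec, dataset, protein_match)]
        steps.append((cond, len(current)))
    return FilterSummary(
        total=len(dataset.interactions),
        steps=steps,
        result=Subnetwork.from_edges(current),
    )


def _adjacency(dataset: Dataset) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {acc: set() for acc in dataset.proteins}
    for rec in dataset.interactions:
        if rec.is_self_loop:
            continue
        adj[rec.endpoint_a].add(rec.endpoint_b)
        adj[rec.endpoint_b].add(rec.endpoint_a)
    return adj


def search(
    dataset: Dataset,
    query: list[str],
    mode: str,
    displayed: Subnetwork | None = None,
    warnings: list[str] | None = None,
) -> Subnetwork:
    """Run one search in the given mode and merge into ``displayed``.

    Unknown accessions are reported through the optional ``warnings``
    list rather than failing the whole search; an empty query returns
    ``displayed`` unchanged with a warning.
    """
    if mode not in SEARCH_MODES:
        raise QueryError(f"unknown search mode {mode!r}; expected one of {SEARCH_MODES}")
    displayed = displayed if displayed is not None else Subnetwork()
    sink = warnings if warnings is not None else []
    known = []
    for acc in query:
        if acc in dataset.proteins:
            known.append(acc)
        else:
            sink.append(f"unknown accession {acc!r} ignored")
    if not query:
        sink.append("empty query: displayed selection unchanged")
        return displayed
    qset = set(known)

    if mode == "normal":
        new_edges = [rec for rec in dataset.interactions if qset & set(rec.key)]
    elif mode == "explicit":
        base = displayed.proteins
        new_edges = [
            rec
            for rec in dataset.interactions
            if set(rec.key) <= qset
            or (qset & set(rec.key) and (set(rec.key) - qset) <= base)
        ]
    else:  # recursive
        adj = _adjacency(dataset)
        closure = set(qset)
        for acc in qset:
            closure |= adj[acc]
        new_edges = [rec for rec in dataset.interactions if set(rec.key) <= closure]

    return Subnetwork.from_edges(
        displayed.interactions + new_edges, displayed.proteins | qset
    )


def autocomplete(dataset: Dataset, prefix: str, limit: int) -> list[tuple[str, str]]:
    """Case-insensitive accession-prefix completion, sorted, truncated."""
    if limit < 1:
        raise QueryError("limit must be >= 1")
    low = prefix.lower()
    hits = sorted(acc for acc in dataset.proteins if acc.lower().startswith(low))
    return [(acc, dataset.proteins[acc].organism) for acc in hits[:limit]]


def get_protein_card(dataset: Dataset, accession: str) -> dict[str, str | float]:
    """The feature card shown for one protein: organism, features, expression."""
    if accession not in dataset.proteins:
        raise QueryError(f"unknown accession {accession!r}")
    p = dataset.proteins[accession]
    card: dict[str, str | float] = {"organism": p.organism}
    for col in dataset.feature_columns:
        if col in p.features:
            card[col] = p.features[col]
    for col, value in (p.expression or {}).items():
        card[col] = value
    return card


def parse_condition(text: str) -> FilterCondition:
    """Parse ``"<scope>.<field> <op> [value]"`` into a FilterCondition.

    Examples: ``protein.organism contains tuberculosis``,
    ``interaction.score ge 0.6``, ``interaction.string present``.
    """
    parts = text.strip().split(None, 2)
    if len(parts) < 2:
        raise QueryError(f"cannot parse condition {text!r}: expected '<scope>.<field> <op> [value]'")
    target, op = parts[0], parts[1]
    if "." not in target:
        raise QueryError(f"condition target {target!r} must be '<scope>.<field>'")
    scope, fieldname = target.split(".", 1)
    if op == "present":
        if len(parts) > 2:
            raise QueryError("'present' takes no value")
        return FilterCondition(scope, fieldname, op)
    if len(parts) < 3:
        raise QueryError(f"operator {op!r} requires a value")
    raw = parts[2]
    value: str | float = raw
    if op in NUMERIC_OPS:
        try:
            value = float(raw)
        except ValueError:
            raise QueryError(f"operator {op!r} requires a numeric value, got {raw!r}")
    return FilterCondition(scope, fieldname, op, value)
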