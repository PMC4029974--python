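"""Provenance history, deterministic replay, and shareable state JSON.

Every user-level action (load, prefilter, search, add_rule, remove_rule,
set_layout, export) is recorded with its *parameters*, not its results;
replaying the history against the same dataset reconstructs the
displayed subnetwork, the rule list and the layout settings exactly.
The serialized JSON (schema ``pinv-state-v1``) is itself the share
payload; it references the dataset by id plus a content hash so a
collaborator opening the state against a different dataset gets a clear
mismatch error instead of a silently wrong picture.
"""

from __future__ import annotations

import html
import json
from dataclasses import dataclass, field, replace

from .errors import SessionError
from .io import Dataset, content_hash
from .layout import LayoutParams
from .query import FilterCondition, Subnetwork, apply_prefilters, search
from .rules import Rule

__all__ = [
    "HistoryEntry",
    "SessionState",
    "initial_state",
    "record",
    "replay",
    "serialize",
    "deserialize",
    "embed_snippet",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "pinv-state-v1"
VALID_OPS = ("load", "prefilter", "search", "add_rule", "remove_rule", "set_layout", "export")
LAYOUT_ENGINES = ("force", "circle")


@dataclass(frozen=True)
class HistoryEntry:
    index: int
    op: str
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"index": self.index, "op": self.op, "params": self.params}


@dataclass
class SessionState:
    """Replayable view state; holds no dataset content, only its identity."""

    dataset_id: str
    dataset_hash: str
    displayed: Subnetwork = field(default_factory=Subnetwork)
    rules: list[Rule] = field(default_factory=list)
    layout_engine: str = "force"
    layout_params: LayoutParams = field(default_factory=LayoutParams)
    history: list[HistoryEntry] = field(default_factory=list)

    def equivalent(self, other: "SessionState") -> bool:
        """State equality modulo history bookkeeping."""
        return (
            self.dataset_id == other.dataset_id
            and self.dataset_hash == other.dataset_hash
            and self.displayed == other.displayed
            and self.rules == other.rules
            and self.layout_engine == other.layout_engine
            and self.layout_params == other.layout_params
        )


def initial_state(dataset: Dataset, dataset_id: str) -> SessionState:
    """A fresh, empty session bound to one dataset."""
    return SessionState(dataset_id=dataset_id, dataset_hash=content_hash(dataset))


def _apply(state: SessionState, dataset: Dataset, op: str, params: dict) -> SessionState:
    """Apply one operation, returning a new state (history untouched)."""
    if op == "load":
        return replace(
            state,
            dataset_id=params.get("dataset_id", state.dataset_id),
            displayed=Subnetwork(),
            rules=[],
        )
    if op == "prefilter":
        conds = [FilterCondition.from_dict(c) for c in params.get("conditions", [])]
        summary = apply_prefilters(dataset, conds, params.get("protein_match", "any"))
        return replace(state, displayed=summary.result)
    if op == "search":
        displayed = search(
            dataset, list(params["query"]), params["mode"], state.displayed
        )
        return replace(state, displayed=displayed)
    if op == "add_rule":
        rule = Rule.from_dict(params["rule"])
        return replace(state, rules=state.rules + [rule])
    if op == "remove_rule":
        idx = params["index"]
        if not 0 <= idx < len(state.rules):
            raise SessionError(f"remove_rule: no rule at index {idx}")
        return replace(state, rules=state.rules[:idx] + state.rules[idx + 1 :])
    if op == "set_layout":
        engine = params.get("engine", state.layout_engine)
        if engine not in LAYOUT_ENGINES:
            raise SessionError(f"unknown layout engine {engine!r}")
        lp = (
            LayoutParams.from_dict(params["layout_params"])
            if "layout_params" in params
            else state.layout_params
        )
        return replace(state, layout_engine=engine, layout_params=lp)
    if op == "export":
        return state  # provenance only; exports do not change view state
    raise SessionError(f"unknown operation {op!r}; expected one of {VALID_OPS}")


def record(state: SessionState, dataset: Dataset, op: str, params: dict | None = None) -> SessionState:
    """Apply ``op`` and append it to the history.  Pure: returns a new state.

    On any error the input state is returned unchanged to the caller by
    virtue of immutability — nothing is mutated before validation.
    """
    params = dict(params or {})
    try:
        json.dumps(params)
    except TypeError as exc:
        raise SessionError(f"operation parameters are not JSON-serializable: {exc}")
    new = _apply(state, dataset, op, params)
    entry = HistoryEntry(len(state.history), op, params)
    return replace(new, history=state.history + [entry])


def replay(dataset: Dataset, history: list[HistoryEntry | dict]) -> SessionState:
    """Reconstruct the state that produced ``history`` from scratch."""
    state = initial_state(dataset, dataset_id="")
    for i, entry in enumerate(history):
        if isinstance(entry, dict):
            entry = HistoryEntry(entry["index"], entry["op"], entry.get("params", {}))
        if entry.index != i:
            raise SessionError(f"history entry {i}: non-contiguous index {entry.index}")
        try:
            state = record(state, dataset, entry.op, entry.params)
        except Exception as exc:
            raise SessionError(f"history entry {i} ({entry.op}): {exc}")
    return state


def _displayed_to_dict(displayed: Subnetwork) -> dict:
    return {
        "proteins": sorted(displayed.proteins),
        "interactions": [list(k) for k in sorted(displayed.edge_keys)],
    }


def serialize(state: SessionState, extra: dict | None = None) -> str:
    """Lossless, byte-stable (sorted keys) JSON for sharing/persistence."""
    doc = {
        "version": SCHEMA_VERSION,
        "dataset_id": state.dataset_id,
        "dataset_hash": state.dataset_hash,
        "displayed": _displayed_to_dict(state.displayed),
        "rules": [r.to_dict() for r in state.rules],
        "layout_engine": state.layout_engine,
        "layout_params": state.layout_params.to_dict(),
        "history": [e.to_dict() for e in state.history],
    }
    if extra:
        doc.update(extra)
    return json.dumps(doc, sort_keys=True, indent=2) + "\n"


def _require(doc: dict, key: str, types, path: str):
    if key not in doc:
        raise SessionError(f"state JSON invalid at {path}.{key}: missing")
    if not isinstance(doc[key], types):
        raise SessionError(
            f"state JSON invalid at {path}.{key}: expected {types}, got {type(doc[key]).__name__}"
        )
    return doc[key]


def deserialize(text: str, dataset: Dataset, check_hash: bool = True) -> SessionState:
    """Parse and validate state JSON against the dataset.

    Raises :class:`SessionError` with a JSON path on schema violations
    and on a dataset content-hash mismatch (the share-link safeguard).
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SessionError(f"state JSON unreadable: {exc}")
    if not isinstance(doc, dict):
        raise SessionError("state JSON invalid at $: expected an object")
    version = _require(doc, "version", str, "$")
    if version != SCHEMA_VERSION:
        raise SessionError(f"state JSON invalid at $.version: expected {SCHEMA_VERSION!r}, got {version!r}")
    dataset_id = _require(doc, "dataset_id", str, "$")
    dataset_hash = _require(doc, "dataset_hash", str, "$")
    if check_hash and dataset_hash != content_hash(dataset):
        raise SessionError(
            "dataset mismatch: the provided dataset does not match the hash in the state file"
        )
    disp = _require(doc, "displayed", dict, "$")
    prots = set(_require(disp, "proteins", list, "$.displayed"))
    for acc in prots:
        if acc not in dataset.proteins:
            raise SessionError(f"state JSON invalid at $.displayed.proteins: unknown accession {acc!r}")
    interactions = []
    for i, pair in enumerate(_require(disp, "interactions", list, "$.displayed")):
        key = tuple(pair)
        rec = dataset.interaction_by_key(key)  # type: ignore[arg-type]
        if rec is None:
            raise SessionError(
                f"state JSON invalid at $.displayed.interactions[{i}]: unknown interaction {key}"
            )
        interactions.append(rec)
    rules = []
    for i, rd in enumerate(_require(doc, "rules", list, "$")):
        try:
            rules.append(Rule.from_dict(rd))
        except Exception as exc:
            raise SessionError(f"state JSON invalid at $.rules[{i}]: {exc}")
    engine = _require(doc, "layout_engine", str, "$")
    if engine not in LAYOUT_ENGINES:
        raise SessionError(f"state JSON invalid at $.layout_engine: unknown engine {engine!r}")
    try:
        lp = LayoutParams.from_dict(_require(doc, "layout_params", dict, "$"))
    except Exception as exc:
        raise SessionError(f"state JSON invalid at $.layout_params: {exc}")
    history = []
    for i, ed in enumerate(_require(doc, "history", list, "$")):
        if not isinstance(ed, dict) or "op" not in ed or "index" not in ed:
            raise SessionError(f"state JSON invalid at $.history[{i}]: expected {{index, op, params}}")
        history.append(HistoryEntry(ed["index"], ed["op"], ed.get("params", {})))
    return SessionState(
        dataset_id=dataset_id,
        dataset_hash=dataset_hash,
        displayed=Subnetwork(prots, sorted(interactions, key=lambda r: r.key)),
        rules=rules,
        layout_engine=engine,
        layout_params=lp,
        history=history,
    )


def embed_snippet(state_url: str, width: int = 600, height: int = 400) -> str:
    """HTML iframe snippet embedding a shared view in a web page."""
    if not state_url:
        raise SessionError("embed snippet requires a non-empty URL")
    url = html.escape(state_url, quote=True)
    return (
        f'<iframe src="{url}" width="{int(width)}" height="{int(height)}" '
        f'frameborder="0" title="pinetviz network view"></iframe>'
    )
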