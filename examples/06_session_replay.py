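"""Provenance history, replay, sharing.

Every action is recorded with its parameters; replaying the history
against the same dataset rebuilds the exact view, and the serialized
JSON is the share payload (with a dataset content hash so collaborators
detect mismatched data).
"""

from pinetviz import (
    Action,
    Rule,
    deserialize,
    embed_snippet,
    initial_state,
    record,
    replay,
    serialize,
    toy6,
)

dataset = toy6()
state = record(initial_state(dataset, "toy"), dataset, "load", {"dataset_id": "toy"})
state = record(state, dataset, "search", {"query": ["P3"], "mode": "recursive"})
state = record(state, dataset, "add_rule", {"rule": Rule(
    "protein", None, Action("color_by_category", {"feature": "organism"})).to_dict()})
state = record(state, dataset, "set_layout", {"engine": "circle"})

for entry in state.history:
    print(f"step {entry.index}: {entry.op} {entry.params}")

rebuilt = replay(dataset, state.history)
print(f"replay reproduces the state exactly: {rebuilt.equivalent(state)}")

payload = serialize(state)
print(f"share payload: {len(payload)} bytes of schema 'pinv-state-v1' JSON")
print(f"round trip lossless: {deserialize(payload, dataset).equivalent(state)}")
print(embed_snippet("https://example.org/shared-state.json", 600, 400))
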