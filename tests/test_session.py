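import json

import pytest

from pinetviz import (
    Action,
    FilterCondition,
    Rule,
    SessionError,
    deserialize,
    embed_snippet,
    initial_state,
    record,
    replay,
    search,
    serialize,
)
from pinetviz._rng import PortableRandom


def session_with(toy, *ops):
    state = record(initial_state(toy, "toy"), toy, "load", {"dataset_id": "toy"})
    for op, params in ops:
        state = record(state, toy, op, params)
    return state


class TestRecord:
    def test_history_grows(self, toy):
        state = session_with(toy, ("search", {"query": ["P1"], "mode": "normal"}))
        assert [e.op for e in state.history] == ["load", "search"]
        assert [e.index for e in state.history] == [0, 1]

    def test_search_op_updates_displayed(self, toy):
        state = session_with(toy, ("search", {"query": ["P1"], "mode": "normal"}))
        assert state.displayed == search(toy, ["P1"], "normal")

    def test_invalid_op_leaves_state_unchanged(self, toy):
        state = session_with(toy)
        with pytest.raises(SessionError):
            record(state, toy, "frobnicate", {})
        assert len(state.history) == 1

    def test_record_is_pure(self, toy):
        state = session_with(toy)
        record(state, toy, "search", {"query": ["P1"], "mode": "normal"})
        assert len(state.history) == 1 and not state.displayed.proteins

    def test_unserializable_params_rejected(self, toy):
        state = session_with(toy)
        with pytest.raises(SessionError):
            record(state, toy, "search", {"query": object(), "mode": "normal"})


class TestReplay:
    def test_empty_history(self, toy):
        state = replay(toy, [])
        assert not state.displayed.proteins and state.rules == []

    def test_replay_reproduces_state(self, toy):
        state = session_with(
            toy,
            ("search", {"query": ["P3"], "mode": "recursive"}),
            ("add_rule", {"rule": Rule("protein", None,
                                       Action("set_color", {"color": "#ff0000"})).to_dict()}),
            ("set_layout", {"engine": "circle"}),
        )
        assert replay(toy, state.history).equivalent(state)

    def test_prefix_replay_gives_intermediate_state(self, toy):
        state = session_with(
            toy,
            ("search", {"query": ["P1"], "mode": "normal"}),
            ("search", {"query": ["P5"], "mode": "normal"}),
        )
        mid = replay(toy, state.history[:2])
        assert mid.displayed == search(toy, ["P1"], "normal")

    def test_bad_entry_reports_index(self, toy):
        state = session_with(toy, ("search", {"query": ["P1"], "mode": "normal"}))
        entries = [e.to_dict() for e in state.history]
        entries[1]["params"] = {"query": ["P1"], "mode": "sideways"}
        with pytest.raises(SessionError, match="entry 1"):
            replay(toy, entries)

    def test_non_contiguous_indices_rejected(self, toy):
        with pytest.raises(SessionError, match="non-contiguous"):
            replay(toy, [{"index": 3, "op": "load", "params": {}}])

    def test_randomized_histories_replay_identically(self, toy):
        rng = PortableRandom(2024)
        accs = sorted(toy.proteins)
        for _ in range(15):
            state = session_with(toy)
            for _ in range(10):
                roll = rng.randint(4)
                if roll == 0:
                    q = [accs[rng.randint(len(accs))]]
                    mode = ("normal", "explicit", "recursive")[rng.randint(3)]
                    state = record(state, toy, "search", {"query": q, "mode": mode})
                elif roll == 1:
                    rule = Rule("protein", None, Action("set_size", {"size": 1.0 + rng.randint(9)}))
                    state = record(state, toy, "add_rule", {"rule": rule.to_dict()})
                elif roll == 2 and state.rules:
                    state = record(state, toy, "remove_rule", {"index": rng.randint(len(state.rules))})
                else:
                    engine = ("force", "circle")[rng.randint(2)]
                    state = record(state, toy, "set_layout", {"engine": engine})
            assert replay(toy, state.history).equivalent(state)


class TestSerialization:
    def test_round_trip_lossless(self, toy):
        state = session_with(
            toy,
            ("search", {"query": ["P3"], "mode": "recursive"}),
            ("add_rule", {"rule": Rule("protein", None,
                                       Action("show_label", {"feature": "description"})).to_dict()}),
        )
        restored = deserialize(serialize(state), toy)
        assert restored.equivalent(state)
        assert [e.to_dict() for e in restored.history] == [e.to_dict() for e in state.history]

    def test_byte_stable(self, toy):
        state = session_with(toy, ("search", {"query": ["P1"], "mode": "normal"}))
        assert serialize(state) == serialize(state)

    def test_missing_version_rejected(self, toy):
        doc = json.loads(serialize(session_with(toy)))
        del doc["version"]
        with pytest.raises(SessionError, match=r"\$\.version"):
            deserialize(json.dumps(doc), toy)

    def test_wrong_version_rejected(self, toy):
        doc = json.loads(serialize(session_with(toy)))
        doc["version"] = "pinv-state-v999"
        with pytest.raises(SessionError, match="version"):
            deserialize(json.dumps(doc), toy)

    def test_dataset_hash_mismatch_detected(self, toy, random_dataset):
        text = serialize(session_with(toy))
        with pytest.raises(SessionError, match="mismatch"):
            deserialize(text, random_dataset(1))

    def test_unknown_displayed_accession_located(self, toy):
        doc = json.loads(serialize(session_with(toy)))
        doc["displayed"]["proteins"] = ["ZZ"]
        with pytest.raises(SessionError, match=r"displayed\.proteins"):
            deserialize(json.dumps(doc), toy)


class TestEmbedSnippet:
    def test_iframe_dimensions(self):
        snippet = embed_snippet("https://x/y", 600, 400)
        assert snippet.startswith("<iframe ")
        assert 'width="600"' in snippet and 'height="400"' in snippet
        assert 'src="https://x/y"' in snippet

    def test_quotes_escaped(self):
        snippet = embed_snippet('https://x/y?q="a"')
        assert '"a"' not in snippet and "&quot;a&quot;" in snippet

    def test_empty_url_rejected(self):
        with pytest.raises(SessionError):
            embed_snippet("")
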