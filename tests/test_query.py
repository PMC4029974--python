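import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pinetviz import (
    FilterCondition,
    QueryError,
    Subnetwork,
    apply_prefilters,
    autocomplete,
    full_subnetwork,
    get_protein_card,
    parse_condition,
    search,
)
from _oracles import explicit_oracle, normal_oracle, recursive_oracle


class TestPrefilters:
    def test_empty_filter_is_identity(self, toy):
        summary = apply_prefilters(toy, [])
        assert summary.total == 5 and summary.counts == []
        assert summary.result.edge_keys == {r.key for r in toy.interactions}

    def test_organism_equals_either_endpoint(self, toy):
        summary = apply_prefilters(toy, [FilterCondition("protein", "organism", "equals", "B")])
        assert summary.result.edge_keys == {("P3", "P4"), ("P4", "P5")}
        assert summary.counts == [2]

    def test_conjunction_with_cumulative_counts(self, toy):
        conds = [
            FilterCondition("protein", "organism", "equals", "B"),
            FilterCondition("interaction", "score", "ge", 0.6),
        ]
        summary = apply_prefilters(toy, conds)
        assert summary.counts == [2, 1]
        assert summary.result.edge_keys == {("P3", "P4")}

    def test_both_endpoints_switch(self, toy):
        summary = apply_prefilters(
            toy, [FilterCondition("protein", "organism", "equals", "B")], protein_match="all"
        )
        assert summary.result.edge_keys == {("P4", "P5")}

    def test_description_contains_is_case_insensitive(self, toy):
        summary = apply_prefilters(
            toy, [FilterCondition("protein", "description", "contains", "sensor")]
        )
        assert summary.counts == [4]

    def test_evidence_present(self, toy):
        summary = apply_prefilters(toy, [FilterCondition("interaction", "string", "present")])
        assert summary.counts == [1]
        assert summary.result.edge_keys == {("P3", "P4")}

    def test_unknown_field_lists_available(self, toy):
        with pytest.raises(QueryError, match="organism"):
            apply_prefilters(toy, [FilterCondition("protein", "nope", "equals", "x")])

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_non_increasing_on_random_data(self, random_dataset, seed):
        ds = random_dataset(seed)
        conds = [
            FilterCondition("protein", "organism", "equals", "ORG1"),
            FilterCondition("interaction", "score", "ge", 0.3),
            FilterCondition("interaction", "score", "le", 0.9),
        ]
        summary = apply_prefilters(ds, conds)
        counts = [summary.total] + summary.counts
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSearchModes:
    def test_normal_neighborhood(self, toy):
        got = search(toy, ["P1"], "normal")
        assert got.edge_keys == {("P1", "P2"), ("P1", "P3")}
        assert got.proteins == {"P1", "P2", "P3"}

    def test_explicit_without_connecting_edge(self, toy):
        got = search(toy, ["P1", "P4"], "explicit")
        assert got.edge_keys == set()
        assert got.proteins == {"P1", "P4"}

    def test_explicit_connects_to_displayed(self, toy):
        displayed = search(toy, ["P1"], "normal")
        got = search(toy, ["P4"], "explicit", displayed)
        assert ("P3", "P4") in got.edge_keys

    def test_recursive_induced_closure(self, toy):
        got = search(toy, ["P3"], "recursive")
        assert got.proteins == {"P1", "P2", "P3", "P4"}
        assert got.edge_keys == {("P1", "P2"), ("P1", "P3"), ("P2", "P3"), ("P3", "P4")}

    def test_empty_query_returns_displayed_with_warning(self, toy):
        displayed = search(toy, ["P1"], "normal")
        warnings: list[str] = []
        got = search(toy, [], "normal", displayed, warnings)
        assert got == displayed and len(warnings) == 1

    def test_unknown_accessions_warn_not_fail(self, toy):
        warnings: list[str] = []
        got = search(toy, ["P1", "ZZ"], "normal", warnings=warnings)
        assert "P1" in got.proteins
        assert any("ZZ" in w for w in warnings)

    def test_result_is_closed(self, toy):
        got = search(toy, ["P3"], "recursive")
        for rec in got.interactions:
            assert set(rec.key) <= got.proteins

    @pytest.mark.parametrize("mode,oracle", [
        ("normal", normal_oracle),
        ("recursive", recursive_oracle),
    ])
    @pytest.mark.parametrize("seed", range(8))
    def test_modes_match_bruteforce_oracle(self, random_dataset, mode, oracle, seed):
        ds = random_dataset(seed, n=25)
        query = sorted(ds.proteins)[seed % 5 :: 6]
        got = search(ds, query, mode)
        proteins, edges = oracle(ds, query)
        assert got.proteins == proteins and got.edge_keys == edges

    @pytest.mark.parametrize("seed", range(8))
    def test_explicit_matches_oracle(self, random_dataset, seed):
        ds = random_dataset(seed, n=25)
        query = sorted(ds.proteins)[::4]
        got = search(ds, query, "explicit")
        proteins, edges = explicit_oracle(ds, query)
        assert got.proteins == proteins and got.edge_keys == edges

    @pytest.mark.parametrize("seed", range(6))
    def test_mode_nesting(self, random_dataset, seed):
        ds = random_dataset(seed, n=25)
        query = sorted(ds.proteins)[::5]
        exp = search(ds, query, "explicit").edge_keys
        nor = search(ds, query, "normal").edge_keys
        rec = search(ds, query, "recursive").edge_keys
        assert exp <= nor <= rec

    @pytest.mark.parametrize("mode", ["normal", "explicit", "recursive"])
    def test_idempotence(self, toy, mode):
        once = search(toy, ["P3"], mode)
        twice = search(toy, ["P3"], mode, once)
        assert twice == once

    def test_recursive_equals_normal_then_explicit_per_protein(self, random_dataset):
        # the operational definition: normal first, then an explicit
        # query for every recovered protein
        for seed in range(4):
            ds = random_dataset(seed, n=20)
            query = sorted(ds.proteins)[::4]
            composed = search(ds, query, "normal")
            for acc in sorted(composed.proteins):
                composed = search(ds, [acc], "explicit", composed)
            assert composed == search(ds, query, "recursive")


class TestAutocomplete:
    def test_prefix_matches_all(self, toy):
        got = autocomplete(toy, "P", 10)
        assert [acc for acc, _ in got] == ["P1", "P2", "P3", "P4", "P5", "P6"]
        assert got[0] == ("P1", "A")

    def test_exact_prefix(self, toy):
        assert autocomplete(toy, "P1", 10) == [("P1", "A")]

    def test_case_insensitive(self, toy):
        assert autocomplete(toy, "p1", 10) == [("P1", "A")]

    def test_empty_prefix_truncates(self, toy):
        assert [a for a, _ in autocomplete(toy, "", 3)] == ["P1", "P2", "P3"]

    def test_limit_must_be_positive(self, toy):
        with pytest.raises(QueryError):
            autocomplete(toy, "P", 0)


class TestProteinCard:
    def test_card_order_organism_first(self, toy):
        assert get_protein_card(toy, "P1") == {"organism": "A", "description": "kinase alpha"}

    def test_card_includes_expression(self, toy_expr):
        card = get_protein_card(toy_expr, "P1")
        assert card["heat"] == 2.5 and card["cold"] == 0.5
        assert list(card)[0] == "organism"

    def test_stub_protein_card(self):
        from pinetviz import build_dataset, InteractionRecord, ProteinRecord

        ds = build_dataset([InteractionRecord("P1", "P2", 0.5)], [ProteinRecord("P1", "A")])
        assert get_protein_card(ds, "P2") == {"organism": "unspecified"}

    def test_unknown_accession_errors(self, toy):
        with pytest.raises(QueryError):
            get_protein_card(toy, "ZZ")


class TestConditionGrammar:
    @pytest.mark.parametrize("text,expected", [
        ("protein.organism contains tuberculosis",
         FilterCondition("protein", "organism", "contains", "tuberculosis")),
        ("interaction.score ge 0.6", FilterCondition("interaction", "score", "ge", 0.6)),
        ("interaction.string present", FilterCondition("interaction", "string", "present")),
        ("protein.description contains Sensor histidine",
         FilterCondition("protein", "description", "contains", "Sensor histidine")),
    ])
    def test_parse_condition(self, text, expected):
        assert parse_condition(text) == expected

    @pytest.mark.parametrize("bad", [
        "organism contains x", "protein.score ge abc", "protein.organism", "p.f gt"
    ])
    def test_bad_grammar_raises(self, bad):
        with pytest.raises(QueryError):
            parse_condition(bad)


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_subnetwork_closure_property(seed):
    """Any search result on any generated dataset is closed."""
    from pinetviz import GeneratorSpec, generate_dataset

    ds = generate_dataset(GeneratorSpec(n_proteins=15, seed=seed))
    query = sorted(ds.proteins)[: (seed % 4) + 1]
    for mode in ("normal", "explicit", "recursive"):
        got = search(ds, query, mode)
        for rec in got.interactions:
            assert set(rec.key) <= got.proteins
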