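import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pinetviz import (
    Action,
    FilterCondition,
    Rule,
    RuleError,
    apply_rules,
    compute_metrics,
    contextual_rule_for,
    evaluate_condition,
    full_subnetwork,
    quantitative_color,
)
from pinetviz.rules import DEFAULT_EDGE_STYLE, DEFAULT_NODE_STYLE, PALETTE12, UNANNOTATED_COLOR


def rule(target, cond, kind, **params):
    return Rule(target, cond, Action(kind, params))


class TestEvaluateCondition:
    def test_degree_condition(self, toy, toy_full):
        metrics = compute_metrics(toy_full)
        cond = FilterCondition("protein", "degree", "gt", 2)
        assert evaluate_condition(cond, toy.proteins["P3"], toy_full, toy, metrics)
        assert not evaluate_condition(cond, toy.proteins["P1"], toy_full, toy, metrics)

    def test_with_protein_endpoint(self, toy, toy_full):
        cond = FilterCondition("interaction", "accession", "equals", "P1")
        edge = toy.interactions[0]  # P1-P2
        assert evaluate_condition(cond, edge, toy_full, toy)

    def test_organism_mismatch(self, toy, toy_full):
        cond = FilterCondition("protein", "organism", "equals", "B")
        assert not evaluate_condition(cond, toy.proteins["P1"], toy_full, toy)

    def test_expression_condition(self, toy_expr):
        sub = full_subnetwork(toy_expr)
        cond = FilterCondition("protein", "heat", "gt", 2.0)
        assert evaluate_condition(cond, toy_expr.proteins["P1"], sub, toy_expr)
        assert not evaluate_condition(cond, toy_expr.proteins["P2"], sub, toy_expr)


class TestApplyRules:
    def test_no_rules_is_all_defaults(self, toy, toy_full):
        style = apply_rules(toy_full, [], toy)
        assert all(v == DEFAULT_NODE_STYLE for v in style.node_style.values())
        assert all(v == DEFAULT_EDGE_STYLE for v in style.edge_style.values())
        assert style.legend == []

    def test_label_rule_selects_high_degree_nodes(self, toy, toy_full):
        # "display the gene name at the side of proteins with more than 2 interactions"
        r = rule("protein", FilterCondition("protein", "degree", "gt", 2),
                 "show_label", feature="gene")
        style = apply_rules(toy_full, [r], toy)
        labelled = {acc for acc, s in style.node_style.items() if s["label"] is not None}
        assert labelled == {"P3"}

    def test_later_rule_overrides_category_color(self, toy, toy_full):
        rules = [
            rule("protein", None, "color_by_category", feature="organism"),
            rule("protein", FilterCondition("protein", "accession", "equals", "P1"),
                 "set_color", color="#ff0000"),
        ]
        style = apply_rules(toy_full, rules, toy)
        assert style.node_style["P1"]["color"] == "#ff0000"
        assert style.node_style["P2"]["color"] == PALETTE12[0]  # organism "A" seen first
        assert style.node_style["P4"]["color"] == PALETTE12[1]
        assert len(style.legend) == 2

    def test_legend_lists_categories_first_seen_order(self, toy, toy_full):
        style = apply_rules(
            toy_full, [rule("protein", None, "color_by_category", feature="organism")], toy
        )
        assert style.legend == [("A", PALETTE12[0]), ("B", PALETTE12[1])]

    def test_missing_category_value_gets_unannotated_gray(self, toy, toy_full):
        style = apply_rules(
            toy_full, [rule("protein", None, "color_by_category", feature="gene")], toy
        )
        assert all(s["color"] == UNANNOTATED_COLOR for s in style.node_style.values())
        assert style.legend == [("unannotated", UNANNOTATED_COLOR)]

    def test_completeness(self, toy, toy_full):
        style = apply_rules(toy_full, [], toy)
        assert set(style.node_style) == toy_full.proteins
        assert set(style.edge_style) == toy_full.edge_keys

    def test_edge_rule_with_protein(self, toy, toy_full):
        r = rule("interaction", FilterCondition("interaction", "accession", "equals", "P1"),
                 "set_color", color="#00ff00")
        style = apply_rules(toy_full, [r], toy)
        green = {k for k, s in style.edge_style.items() if s["color"] == "#00ff00"}
        assert green == {("P1", "P2"), ("P1", "P3")}

    def test_hide_rule(self, toy, toy_full):
        r = rule("protein", FilterCondition("protein", "organism", "equals", "B"), "hide")
        style = apply_rules(toy_full, [r], toy)
        assert not style.node_style["P4"]["visible"]
        assert style.node_style["P1"]["visible"]

    def test_expression_gradient(self, toy_expr):
        sub = full_subnetwork(toy_expr)
        r = rule("protein", None, "color_by_value", feature="heat",
                 vmin=0.0, vmax=4.0, color_low="#000000", color_high="#ffffff")
        style = apply_rules(sub, [r], toy_expr)
        assert style.node_style["P6"]["color"] == "#000000"  # heat 0.0
        assert style.node_style["P3"]["color"] == "#ffffff"  # heat 4.0

    def test_size_by_betweenness(self, toy, toy_full):
        r = rule("protein", None, "size_by_value", feature="betweenness",
                 vmin=0.0, vmax=4.0, size_min=4.0, size_max=12.0)
        style = apply_rules(toy_full, [r], toy)
        assert style.node_style["P3"]["size"] == pytest.approx(12.0)
        assert style.node_style["P6"]["size"] == pytest.approx(4.0)

    def test_determinism(self, toy, toy_full):
        rules = [
            rule("protein", None, "color_by_category", feature="description"),
            rule("protein", FilterCondition("protein", "degree", "gt", 2),
                 "show_label", feature="description"),
        ]
        a = apply_rules(toy_full, rules, toy)
        b = apply_rules(toy_full, rules, toy)
        assert a.node_style == b.node_style and a.legend == b.legend

    def test_numeric_op_on_text_field_fails_at_compile(self, toy, toy_full):
        r = rule("protein", FilterCondition("protein", "description", "gt", 2), "hide")
        with pytest.raises(RuleError):
            apply_rules(toy_full, [r], toy)


class TestQuantitativeColor:
    def test_boundaries(self):
        assert quantitative_color(0.0, 0.0, 1.0, "#112233", "#aabbcc") == "#112233"
        assert quantitative_color(1.0, 0.0, 1.0, "#112233", "#aabbcc") == "#aabbcc"

    def test_midpoint_rounds_half_down(self):
        assert quantitative_color(0.5, 0.0, 1.0, "#000000", "#ffffff") == "#7f7f7f"

    def test_clamped_outside_range(self):
        assert quantitative_color(-5.0, 0.0, 1.0, "#000000", "#ffffff") == "#000000"
        assert quantitative_color(9.0, 0.0, 1.0, "#000000", "#ffffff") == "#ffffff"

    def test_invalid_range(self):
        with pytest.raises(RuleError):
            quantitative_color(0.5, 1.0, 1.0, "#000000", "#ffffff")


class TestContextualRule:
    def test_targets_only_that_protein(self, toy, toy_full):
        r = contextual_rule_for(toy_full, "P1", Action("set_color", {"color": "#00ff00"}))
        style = apply_rules(toy_full, [r], toy)
        green = {acc for acc, s in style.node_style.items() if s["color"] == "#00ff00"}
        assert green == {"P1"}

    def test_idempotent(self, toy, toy_full):
        r = contextual_rule_for(toy_full, "P1", Action("set_color", {"color": "#00ff00"}))
        once = apply_rules(toy_full, [r], toy)
        twice = apply_rules(toy_full, [r, r], toy)
        assert once.node_style == twice.node_style

    def test_undisplayed_accession_rejected(self, toy_full):
        with pytest.raises(RuleError):
            contextual_rule_for(toy_full, "P9", Action("hide", {}))


_colors = st.sampled_from(["#ff0000", "#00ff00", "#0000ff", "#123456"])


@given(first=_colors, second=_colors, acc=st.sampled_from(["P1", "P3", "P5"]))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_override_order_last_writer_wins(first, second, acc):
    """Two rules writing the same attribute: the later one's value sticks."""
    from pinetviz import toy6

    toy = toy6()
    sub = full_subnetwork(toy)
    cond = FilterCondition("protein", "accession", "equals", acc)
    rules = [rule("protein", cond, "set_color", color=first),
             rule("protein", cond, "set_color", color=second)]
    style = apply_rules(sub, rules, toy)
    assert style.node_style[acc]["color"] == second


def test_rule_serialization_round_trip(toy):
    r = rule("protein", FilterCondition("protein", "degree", "gt", 2),
             "show_label", feature="description")
    assert Rule.from_dict(r.to_dict()) == r
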