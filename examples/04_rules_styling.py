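"""Declarative styling rules: target + condition + action.

Rules are applied in order over documented defaults; later rules
override earlier ones.  This reproduces a typical session: color by
organism, label hub proteins (more than 2 interactions), and shade by
expression under heat stress.
"""

from pinetviz import (
    Action,
    FilterCondition,
    Rule,
    apply_rules,
    full_subnetwork,
    toy6,
)

dataset = toy6(with_expression=True)
sub = full_subnetwork(dataset)

rules = [
    Rule("protein", None, Action("color_by_category", {"feature": "organism"})),
    Rule("protein", FilterCondition("protein", "degree", "gt", 2),
         Action("show_label", {"feature": "description"})),
    Rule("protein", None, Action("color_by_value", {
        "feature": "heat", "vmin": 0.0, "vmax": 4.0,
        "color_low": "#ffffff", "color_high": "#d62728"})),
    Rule("protein", FilterCondition("protein", "accession", "equals", "P1"),
         Action("set_color", {"color": "#0000ff"})),
]
style = apply_rules(sub, rules, dataset)
for acc in sorted(style.node_style):
    s = style.node_style[acc]
    print(f"{acc}: color={s['color']} size={s['size']} label={s['label']!r}")
print(f"legend: {style.legend}")
print("The heat gradient overrode the organism palette (later rule wins),")
print("and the final per-protein paint overrode both for P1.")
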