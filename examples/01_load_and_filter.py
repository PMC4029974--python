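"""Load the built-in toy dataset and shrink it with prefilters.

Prefilters are AND-combined conditions applied to the whole dataset
before anything is displayed; the running interaction count after each
condition shows how the network shrinks.
"""

from pinetviz import FilterCondition, apply_prefilters, toy6

dataset = toy6()
print(f"dataset: {len(dataset.proteins)} proteins, {len(dataset.interactions)} interactions")

conditions = [
    FilterCondition("protein", "description", "contains", "sensor"),
    FilterCondition("interaction", "score", "ge", 0.6),
]
summary = apply_prefilters(dataset, conditions)
print(f"before filtering: {summary.total} interactions")
for cond, count in summary.steps:
    print(f"  after {cond.scope}.{cond.field} {cond.operator} {cond.value!r}: {count}")
print(f"kept proteins: {sorted(summary.result.proteins)}")
# The counts can only shrink: each condition is ANDed onto the previous ones.
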