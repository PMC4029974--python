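"""The three search modes: normal, explicit, recursive.

normal returns the query's whole neighborhood; explicit only edges among
the query (and anything already displayed); recursive the induced
subgraph on the query plus its neighbors, so every interaction between
displayed proteins is shown.
"""

from pinetviz import search, toy6

dataset = toy6()

for mode in ("normal", "explicit", "recursive"):
    result = search(dataset, ["P3"], mode)
    print(f"{mode:>9}: proteins={sorted(result.proteins)} "
          f"interactions={sorted(result.edge_keys)}")

# Searches are additive: merging a second query never removes content.
displayed = search(dataset, ["P1"], "normal")
merged = search(dataset, ["P4"], "explicit", displayed)
print(f"P1 neighborhood then explicit P4: {sorted(merged.edge_keys)}")
print("(the P3-P4 bridge appears because P3 was already displayed)")
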