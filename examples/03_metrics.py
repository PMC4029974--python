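"""Degree, betweenness centrality and connected components.

Betweenness counts the unordered protein pairs whose shortest paths run
through a node — the classic marker of bridging proteins in a PPI
network (here P3, which connects the organism-A triangle to organism B).
"""

from pinetviz import compute_metrics, full_subnetwork, toy6, write_table_csv

dataset = toy6()
table = compute_metrics(full_subnetwork(dataset))
print(write_table_csv(table.rows(), ["accession", "degree", "betweenness", "component_id"]))
print("P3 bridges the two halves: highest degree and betweenness;")
print("P6 is isolated, so it forms its own component (id 1).")
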