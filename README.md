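# pinetviz

A scriptable protein-protein interaction (PPI) network visualizer.
`pinetviz` re-implements, as an importable Python library plus a thin
command line, the computational core of interactive web PPI viewers:
loading simple tab-separated interaction/feature/expression files,
reducing the network with prefilters and query modes, styling it with
declarative rules, laying it out with organism-aware force simulation,
exporting SVG/PNG/CSV, and recording every step in a replayable,
shareable session.

It is aimed at computational biologists who want reproducible,
scriptable network figures — for example a *Mycobacterium tuberculosis*
drug target shown with its host-pathogen interactions in *Homo sapiens*
— without a browser in the loop.

## The data model and the algorithms

A dataset is two TSV files (plus an optional third):

* **interactions** — `accession_a  accession_b  score  [evidence ...]`,
  an undirected edge with an aggregate confidence score and optional
  per-source evidence scores (e.g. STRING, IntAct);
* **features** — `accession  organism  [annotations ...]`; the organism
  is the only required annotation;
* **expression** — `accession  value ...`, numeric per-condition values.

On top of this the package provides:

* **Prefilters** — an AND-chain of conditions over the whole dataset
  with cumulative interaction counts after each condition.
* **Search modes** — for a query set *Q* against the displayed set *D*:
  *normal* returns *Q* and every interaction touching *Q*; *explicit*
  only interactions within *Q* (or between *Q* and *D*); *recursive*
  the induced subgraph on *Q* ∪ N(*Q*), i.e. all interactions between
  displayed proteins.
* **Metrics** — degree, Brandes shortest-path betweenness centrality
  C_B(v) = Σ_{s≠v≠t} σ_st(v)/σ_st (unordered pairs; optional
  (n−1)(n−2)/2 normalization), connected components.
* **Rules** — ordered `target + condition + action` records
  (paint, label, resize, hide; categorical palettes with a legend;
  linear two-color gradients over expression or scores).
* **Layouts** — Fruchterman–Reingold-style force simulation with one
  gravity well per organism (repulsion k²/d, springs d²/k,
  k = √(area/n), linear gravity), and a deterministic circle layout
  with contiguous organism arcs.
* **Sessions** — a provenance log of parameterized actions that replays
  deterministically and serializes to versioned JSON
  (`pinv-state-v1`) with a dataset content hash.

## Worked example

```python
from pinetviz import (toy6, full_subnetwork, search, compute_metrics,
                      force_layout, LayoutParams)

ds = toy6()                      # 6 proteins (organisms A and B), 5 interactions
hit = search(ds, ["P3"], "recursive")
print(sorted(hit.proteins))      # ['P1', 'P2', 'P3', 'P4']

table = compute_metrics(full_subnetwork(ds))
print(table["P3"])               # {'degree': 3, 'betweenness': 4.0, 'component_id': 0}

res = force_layout(full_subnetwork(ds), ds, LayoutParams(seed=42))
print(res.converged, res.iterations_run)   # True 105
```

The recursive query on the bridging protein P3 recovers the organism-A
triangle plus the bridge into organism B; P3's betweenness of 4.0 counts
the four protein pairs whose shortest paths run through it; and the
seeded force layout converges deterministically, placing each protein
nearest its own organism's gravity center. The scripts in `examples/`
walk through every capability (filtering, search modes, metrics, rules,
layouts/export, session replay, synthetic data) and print the numbers
they compute.

The same pipeline from a shell:

```sh
pinetviz --state s.json load --interactions inter.tsv --features feat.tsv
pinetviz --state s.json search --ids P3 --mode recursive
pinetviz --state s.json filter --where "protein.organism contains tuberculosis"
pinetviz --state s.json layout --engine force --seed 42
pinetviz --state s.json export --svg net.svg --csv net.csv
```

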