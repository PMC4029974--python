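# Methods

This note documents the models, conventions and numerical choices
behind `pinetviz`, in the spirit of a methods appendix: what each
component computes, which knobs matter, and what the synthetic data do
and do not demonstrate.

## File formats and repair policy

Datasets are UTF-8 tab-separated files; `#` lines and blank lines are
ignored. The interactions file is `a  b  score  [evidence...]`; a first
line whose third field is non-numeric is treated as a header naming the
evidence columns. The features file is `accession  organism
[annotations...]`; because its third column is free text, the numeric
header heuristic cannot apply, so a header is recognized when the first
cell is one of `accession`, `id`, `protein`, `protein_id` or `acc`
(case-insensitive). Expression files always carry a header row naming
the conditions.

Parsing is *total*: every line yields a record, a warning, or an error
naming the line (and column where relevant). Loading repairs rather
than rejects: duplicate unordered pairs keep the highest-scoring record
(preserving the strongest evidence), duplicate accessions resolve
last-wins, endpoints missing from the features file get a stub protein
with organism `"unspecified"`, and self-interactions are kept but drawn
only in the table/CSV views. Every repair appends a warning to
`Dataset.warnings`. Interaction endpoints are stored in lexicographic
order, so an unordered pair has exactly one canonical key. Scores must
be finite but are deliberately not range-checked: aggregate confidence
conventions differ between sources and nothing downstream assumes
[0, 1].

## Query semantics

Prefilter conditions are AND-combined in order over the *interactions*
of the dataset. A protein-scope condition passes an edge when at least
one endpoint satisfies it (default `protein_match="any"`); this keeps
cross-species edges visible when filtering by one organism, which is
the behavior a host-pathogen analysis needs. A `"all"` switch requires
both endpoints. `contains` is case-insensitive substring matching
(protein descriptions vary in case between sources); evidence
`present` means the file cell was non-empty, not merely non-zero.

The three search modes are additive set operations (they never remove
displayed content). For query Q, displayed D, edge set E:

* normal: D ∪ { e ∈ E : e ∩ Q ≠ ∅ } ∪ Q
* explicit: D ∪ { e : e ⊆ Q } ∪ { e : |e ∩ Q| = 1, e \ Q ⊆ D } ∪ Q
* recursive: D ∪ induced(E, Q ∪ N(Q)) ∪ Q

Recursive is definitionally a normal query followed by one explicit
query per recovered protein; that identity is tested directly. Unknown
accessions are reported through a warnings channel instead of failing
the search, matching interactive use where a typo should not destroy a
session.

## Metrics

Betweenness is Brandes' algorithm on the unweighted graph — interaction
scores never affect shortest paths, since confidence is not a distance.
Unnormalized values count unordered pairs (both-direction accumulation
halved), so a path midpoint scores 1 and a k-leaf star center scores
k(k−1)/2; normalization divides by (n−1)(n−2)/2. Disconnected pairs
contribute nothing; self-loops are excluded from degree and adjacency.
Both normalized and raw variants are exposed because figure-making
conventions differ. Component ids are 0..k−1 ordered by decreasing
size, ties by smallest accession, so layout seeding and reports are
stable.

## Rules engine

Defaults are applied first (node `#888888`, radius 5.0, label hidden,
visible; edge `#999999`, width 1.0), then rules in list order; the last
writer of an attribute wins, including the interplay between a
categorical coloring and later per-element paints — list order is a
deliberate convention. Categorical colors come from a fixed 12-class
qualitative palette (ColorBrewer Set3 hues, hard-coded in
`rules.PALETTE12`); values are assigned palette slots in first-seen
order over proteins sorted by accession, so legends are deterministic.
Past 12 categories the palette cycles with a warning. Missing category
values get a reserved gray listed last in the legend as
`unannotated`. Quantitative color maps clamp to [vmin, vmax] and
interpolate each RGB channel linearly, rounding *half down* to an
integer (`ceil(x − 0.5)`), which makes the black-to-white midpoint
`#7f7f7f` bit-stable. `show_label` uses the named annotation and falls
back to the accession when a protein lacks it, so a labelling rule is
still informative on sparsely annotated data. Rules are plain
serializable records; type errors (numeric operator on a text field)
are raised when the rule list is compiled, not per element.

## Layouts

The force layout is Fruchterman–Reingold with gravity wells. With
canvas area A and n nodes, k = √(A/n); each iteration applies repulsion
c_r·k²/d between all node pairs, spring attraction c_a·d²/k along
edges, and a linear pull g·(center − position) toward the node's
organism gravity center. Gravity points: one organism sits at the
canvas center; for m ≥ 2 they sit evenly on a circle of radius
min(w, h)/4 starting at angle 0 (east) and proceeding counter-clockwise
(screen coordinates are y-down, SVG convention). Repulsion is applied
between *all* pairs, linked or not — with springs dominating on edges
this is the standard formulation and visually equivalent to
repelling only unlinked nodes.

Per-node displacement is capped by a temperature that starts at
0.1·min(w, h) and shrinks geometrically by `cooling_factor` (default
0.95) each iteration; the run stops when the maximum displacement falls
below `displacement_tolerance` (default 0.5 canvas units). Because the
cap is geometric, convergence within the default 1000 iterations is
guaranteed (~105 iterations on a 1000×1000 canvas). Defaults
c_r = 0.05, c_a = 1.0, g = 0.5 were chosen so that organism clusters
equilibrate well inside the canvas and every node ends nearest its own
organism's center when no cross-organism edges exist; the cluster
radius scales as k·√(c_r·(m−1)/g). Coincident points are protected by a
minimum distance of 1e-4. Initial positions are jittered uniformly
(±min(w, h)/20) around each node's gravity center using the package's
portable 32-bit linear congruential generator
(state ← 1664525·state + 1013904223 mod 2³²), stated here so layouts
are reproducible bit-for-bit from a seed in any language. A
single-node subnetwork is placed directly at its gravity center (the
exact force balance). Final positions are clamped to the canvas.

The circle layout is fully deterministic: all nodes on a circle of
radius 0.4·min(w, h); organisms occupy contiguous arcs in lexicographic
order, separated by one empty slot each when there are two or more
organisms; within an arc nodes are sorted by accession. With n nodes
and m organisms the angular step is 2π/(n + gaps), gaps = m when m ≥ 2
else 0.

## Rendering

SVG output is byte-stable: elements are emitted in canonical order
(edges by key, nodes by accession), coordinates are formatted to two
decimals, and there are no timestamps or generated ids. Hidden nodes
are dropped together with their incident edges; element counts
therefore equal the visible style entries. An option maps organisms to
circle/square/diamond glyphs in lexicographic order. PNG export
re-draws the emitted element vocabulary (rect, line, circle, polygon,
text) through Pillow at an integer scale; it asserts only decodability
and dimensions, and a missing Pillow produces a clear error advising
SVG export.

## Sessions

History entries store operations and their *parameters*, never results;
replay against the same dataset is the authority for reconstructing the
view, which keeps share payloads small and makes provenance auditable.
"Jump to an intermediate state" is prefix replay. The serialized state
(`pinv-state-v1`, sorted-keys JSON, byte-stable) carries the dataset id
plus a SHA-256 content hash over a canonical serialization; opening a
state against different data fails loudly instead of silently drawing
the wrong network. Schema validation is hand-rolled over this small,
closed schema and reports JSON paths. The share *service* is out of
scope; the JSON itself is the payload, and `embed_snippet` emits the
iframe fragment for embedding a hosted state.

## Synthetic data

The generator produces organism blocks sized by largest-remainder
apportionment, independent Bernoulli edges (default within-organism
probability 0.08, cross-organism 0.02 — sparse networks with rarer
host-pathogen links, the regime the query and layout machinery
targets), scores uniform on (0, 1], evidence cells present with
probability 0.5, annotations drawn from a small vocabulary, and
uniform expression values; everything flows from one LCG seed. It makes
no attempt at biological realism — no heavy-tailed degree
distributions, no interologs, no correlated evidence — so passing tests
demonstrate the correctness of the set/graph/geometry computations, not
fidelity to real interactome structure. The fixed 6-protein toy network
(two organisms, a triangle bridged to a path, one isolated protein, one
evidence value) is the worked example for every documented behavior and
ships as checked-in TSVs that the `toy6()` loader parses directly.

Test and acceptance problem sizes (datasets ≤ 50 nodes for query
oracles, ≤ 30 for path-enumeration betweenness, ≤ 200 for layout
convergence, 20 layout seeds, 50 replayed 20-operation histories) were
chosen so exhaustive oracles remain exact and the whole suite runs in
seconds while still exercising non-trivial graphs.

## Known limitations

* Interactive behaviors (drag, hover, context menus) and any server
  plumbing (upload modes, indexing, hosted share links) are out of
  scope; their data lookups (protein cards, contextual rule creation)
  are provided as pure operations.
* The force layout is O(n²) per iteration; it is comfortable to a few
  thousand nodes but not intended for whole-interactome rendering, for
  which prefiltering to a subnetwork is the supported route.
* Evidence columns are positional beyond the header; reordering columns
  between files changes their identity.
* PSI-MITAB import is not implemented; converting columns 1, 2 and 15
  to the native TSV is a few lines of user code.
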