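"""Organism-gravity force layout, circle layout, and SVG/CSV export.

The force layout creates one gravity point per organism in the current
selection, so species separate visually; the circle layout places all
proteins on one ring with one empty slot between organism arcs.
"""

import math
from pathlib import Path

from pinetviz import (
    LayoutParams,
    apply_rules,
    circle_layout,
    force_layout,
    full_subnetwork,
    render_svg,
    render_table,
    toy6,
    write_table_csv,
)

dataset = toy6()
sub = full_subnetwork(dataset)
params = LayoutParams(seed=42)

result = force_layout(sub, dataset, params)
print(f"force layout converged={result.converged} after {result.iterations_run} iterations")
for acc, (x, y) in sorted(result.positions.items()):
    org = dataset.proteins[acc].organism
    centers = result.gravity_centers
    nearest = min(centers, key=lambda o: math.dist((x, y), centers[o]))
    print(f"  {acc} (organism {org}) at ({x:6.1f}, {y:6.1f}), nearest gravity center: {nearest}")

ring = circle_layout(sub, dataset, params)
radii = {round(math.dist(p, (500, 500)), 6) for p in ring.positions.values()}
print(f"circle layout: all {len(ring.positions)} nodes at radius {radii}")

style = apply_rules(sub, [], dataset)
svg = render_svg(sub, result, style)
out = Path("scratch_toy6.svg")
out.write_text(svg)
print(f"wrote {out} ({len(svg)} bytes; identical bytes on every run with this seed)")

columns, rows = render_table(sub, dataset, sort_by="score", descending=True)
print(write_table_csv(rows[:2], columns))
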