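"""Deterministic layouts: organism-gravity force simulation and circle.

The force layout follows the Fruchterman-Reingold scheme — repulsion
``k^2/d`` between all node pairs, spring attraction ``d^2/k`` along
interactions, with ``k = sqrt(area/n)`` — plus a linear gravity pull
``g * (center - position)`` toward one gravity point per organism in
the displayed selection.  With two or more organisms the gravity points
sit evenly on a circle of radius ``min(width, height)/4`` around the
canvas center (angle 0 at east, proceeding counter-clockwise), which
separates the species visually.

Per-iteration displacement is capped by a geometrically cooling
temperature (initially ``0.1*min(width, height)``, multiplied by
``cooling_factor`` each step), so the simulation always converges: once
the temperature drops below ``displacement_tolerance`` no node can move
farther than the tolerance.  Initial positions are jittered around each
node's organism gravity center using the portable LCG documented in
:mod:`pinetviz._rng`; all arithmetic is plain float64, so a fixed seed
reproduces positions bit-for-bit.

Coordinates use the SVG convention: origin top-left, y grows downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._rng import PortableRandom
from .errors import LayoutError
from .io import Dataset
from .metrics import organisms_of
from .query import Subnetwork

__all__ = ["LayoutParams", "LayoutResult", "gravity_centers", "force_layout", "circle_layout"]

_MIN_DIST = 1e-4


@dataclass(frozen=True)
class LayoutParams:
    """Canvas geometry and force-simulation constants."""

    width: float = 1000.0
    height: float = 1000.0
    repulsion_strength: float = 0.05
    attraction_strength: float = 1.0
    gravity_strength: float = 0.5
    max_iterations: int = 1000
    displacement_tolerance: float = 0.5
    cooling_factor: float = 0.95
    seed: int = 42

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise LayoutError("canvas dimensions must be positive")
        if self.max_iterations < 1:
            raise LayoutError("max_iterations must be >= 1")
        if self.displacement_tolerance <= 0:
            raise LayoutError("displacement_tolerance must be positive")
        if not 0.0 < self.cooling_factor < 1.0:
            raise LayoutError("cooling_factor must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "repulsion_strength": self.repulsion_strength,
            "attraction_strength": self.attraction_strength,
            "gravity_strength": self.gravity_strength,
            "max_iterations": self.max_iterations,
            "displacement_tolerance": self.displacement_tolerance,
            "cooling_factor": self.cooling_factor,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LayoutParams":
        return cls(**d)


@dataclass
class LayoutResult:
    """Positions plus convergence diagnostics."""

    positions: dict[str, tuple[float, float]]
    iterations_run: int
    converged: bool
    gravity_centers: dict[str, tuple[float, float]] = field(default_factory=dict)
    displacement_trace: list[float] = field(default_factory=list)


def gravity_centers(
    organisms: list[str], params: LayoutParams
) -> dict[str, tuple[float, float]]:
    """One gravity point per organism.

    A single organism sits at the canvas center; two or more are spread
    evenly on a circle of radius ``min(width, height)/4``, starting at
    angle 0 (east) and proceeding counter-clockwise in list order.
    """
    cx, cy = params.width / 2.0, params.height / 2.0
    if not organisms:
        return {}
    if len(organisms) == 1:
        return {organisms[0]: (cx, cy)}
    radius = min(params.width, params.height) / 4.0
    centers = {}
    for i, org in enumerate(organisms):
        theta = 2.0 * math.pi * i / len(organisms)
        # y is flipped (SVG y-down) so positive angles turn counter-clockwise on screen
        centers[org] = (cx + radius * math.cos(theta), cy - radius * math.sin(theta))
    return centers


def force_layout(
    subnetwork: Subnetwork, dataset: Dataset, params: LayoutParams | None = None
) -> LayoutResult:
    """Iterative force-directed layout with per-organism gravity wells."""
    params = params or LayoutParams()
    if not subnetwork.proteins:
        raise LayoutError("cannot lay out an empty subnetwork")
    nodes = sorted(subnetwork.proteins)
    orgs = organisms_of(subnetwork, dataset)
    centers = gravity_centers(orgs, params)
    center_of = {acc: centers[dataset.proteins[acc].organism] for acc in nodes}

    if len(nodes) == 1:
        # gravity is the only force: equilibrium is the gravity center itself
        acc = nodes[0]
        return LayoutResult({acc: center_of[acc]}, 0, True, centers)

    rng = PortableRandom(params.seed)
    jitter = min(params.width, params.height) / 20.0
    pos = np.empty((len(nodes), 2), dtype=np.float64)
    for i, acc in enumerate(nodes):
        cx, cy = center_of[acc]
        pos[i, 0] = cx + rng.uniform(-jitter, jitter)
        pos[i, 1] = cy + rng.uniform(-jitter, jitter)

    anchors = np.array([center_of[acc] for acc in nodes], dtype=np.float64)
    index = {acc: i for i, acc in enumerate(nodes)}
    edge_pairs = np.array(
        [
            (index[rec.endpoint_a], index[rec.endpoint_b])
            for rec in subnetwork.sorted_interactions()
            if not rec.is_self_loop
        ],
        dtype=np.intp,
    ).reshape(-1, 2)

    n = len(nodes)
    k = math.sqrt(params.width * params.height / n)
    temperature = 0.1 * min(params.width, params.height)
    iterations = 0
    converged = False
    trace: list[float] = []

    for iterations in range(1, params.max_iterations + 1):
        diff = pos[:, None, :] - pos[None, :, :]            # (n, n, 2)
        dist = np.sqrt((diff * diff).sum(axis=2))
        np.fill_diagonal(dist, 1.0)
        dist = np.maximum(dist, _MIN_DIST)
        # repulsion k^2/d between every pair (capped implicitly by the
        # temperature limit on displacement)
        rep = params.repulsion_strength * (k * k) / (dist * dist)
        np.fill_diagonal(rep, 0.0)
        disp = (diff * rep[:, :, None]).sum(axis=1)
        # spring attraction d^2/k along interactions
        if len(edge_pairs):
            a, b = edge_pairs[:, 0], edge_pairs[:, 1]
            evec = pos[a] - pos[b]
            edist = np.maximum(np.sqrt((evec * evec).sum(axis=1)), _MIN_DIST)
            pull = params.attraction_strength * edist / k   # (d^2/k)/d per unit vector
            np.subtract.at(disp, a, evec * pull[:, None])
            np.add.at(disp, b, evec * pull[:, None])
        # linear gravity toward the organism center
        disp += params.gravity_strength * (anchors - pos)
        # limit displacement by the cooling temperature
        norm = np.sqrt((disp * disp).sum(axis=1))
        scale = np.minimum(norm, temperature) / np.maximum(norm, 1e-12)
        step = disp * scale[:, None]
        pos += step
        pos[:, 0] = np.clip(pos[:, 0], 0.0, params.width)
        pos[:, 1] = np.clip(pos[:, 1], 0.0, params.height)
        max_disp = float(np.sqrt((step * step).sum(axis=1)).max())
        trace.append(max_disp)
        if max_disp < params.displacement_tolerance:
            converged = True
            break
        temperature *= params.cooling_factor

    positions = {acc: (float(pos[i, 0]), float(pos[i, 1])) for i, acc in enumerate(nodes)}
    return LayoutResult(positions, iterations, converged, centers, trace)


def circle_layout(
    subnetwork: Subnetwork, dataset: Dataset, params: LayoutParams | None = None
) -> LayoutResult:
    """All nodes on one circle, organisms in contiguous lexicographic arcs.

    Radius is ``0.4 * min(width, height)``.  With two or more organisms
    each arc is followed by one empty gap slot, visually separating the
    species; within an arc nodes are ordered by accession.  Fully
    deterministic — no randomness is involved.
    """
    params = params or LayoutParams()
    if not subnetwork.proteins:
        raise LayoutError("cannot lay out an empty subnetwork")
    orgs = organisms_of(subnetwork, dataset)
    by_org = {
        org: sorted(
            acc for acc in subnetwork.proteins if dataset.proteins[acc].organism == org
        )
        for org in orgs
    }
    n = len(subnetwork.proteins)
    gaps = len(orgs) if len(orgs) >= 2 else 0
    slots = n + gaps
    cx, cy = params.width / 2.0, params.height / 2.0
    radius = 0.4 * min(params.width, params.height)
    positions: dict[str, tuple[float, float]] = {}
    slot = 0
    for org in orgs:
        for acc in by_org[org]:
            theta = 2.0 * math.pi * slot / slots
            positions[acc] = (cx + radius * math.cos(theta), cy - radius * math.sin(theta))
            slot += 1
        if gaps:
            slot += 1  # empty slot between organism arcs
    return LayoutResult(positions, 0, True, {})
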