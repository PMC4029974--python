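"""Graph statistics consumed by styling rules and reports.

Betweenness centrality is computed with Brandes' dependency-accumulation
algorithm on the unweighted graph (interaction scores never affect
shortest paths).  Unnormalized values count unordered pairs of distinct
proteins whose shortest paths pass through the node — so the middle of
a 3-node path scores 1, and a star center with k leaves scores k(k-1)/2.
Normalization divides by (n-1)(n-2)/2.  Self-interactions are ignored
throughout; disconnected pairs contribute nothing.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .errors import QueryError
from .io import Dataset
from .query import Subnetwork

__all__ = [
    "degree",
    "betweenness",
    "connected_components",
    "organisms_of",
    "MetricTable",
    "compute_metrics",
]


def _adjacency(subnetwork: Subnetwork) -> dict[str, list[str]]:
    adj: dict[str, list[str]] = {acc: [] for acc in subnetwork.proteins}
    for rec in subnetwork.sorted_interactions():
        if rec.is_self_loop:
            continue
        adj[rec.endpoint_a].append(rec.endpoint_b)
        adj[rec.endpoint_b].append(rec.endpoint_a)
    return adj


def degree(subnetwork: Subnetwork, accession: str) -> int:
    """Number of incident non-loop interactions."""
    if accession not in subnetwork.proteins:
        raise QueryError(f"unknown accession {accession!r}")
    return sum(
        1
        for rec in subnetwork.interactions
        if not rec.is_self_loop and rec.touches(accession)
    )


def betweenness(subnetwork: Subnetwork, normalized: bool = False) -> dict[str, float]:
    """Shortest-path betweenness of every displayed protein (Brandes)."""
    adj = _adjacency(subnetwork)
    nodes = sorted(adj)
    cb = {v: 0.0 for v in nodes}
    for s in nodes:
        # single-source shortest-path counts
        stack: list[str] = []
        preds: dict[str, list[str]] = {v: [] for v in nodes}
        sigma = {v: 0.0 for v in nodes}
        dist = {v: -1 for v in nodes}
        sigma[s] = 1.0
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        # dependency accumulation
        delta = {v: 0.0 for v in nodes}
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += (sigma[v] / sigma[w]) * (1.0 + delta[w])
            if w != s:
                cb[w] += delta[w]
    # each unordered pair was counted from both endpoints
    for v in cb:
        cb[v] /= 2.0
    if normalized:
        n = len(nodes)
        denom = (n - 1) * (n - 2) / 2.0
        if denom > 0:
            for v in cb:
                cb[v] /= denom
    return cb


def connected_components(subnetwork: Subnetwork) -> dict[str, int]:
    """Component ids, 0..k-1 by decreasing size, ties by smallest accession."""
    adj = _adjacency(subnetwork)
    seen: set[str] = set()
    comps: list[list[str]] = []
    for start in sorted(adj):
        if start in seen:
            continue
        queue = deque([start])
        seen.add(start)
        members = []
        while queue:
            v = queue.popleft()
            members.append(v)
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    queue.append(w)
        comps.append(sorted(members))
    comps.sort(key=lambda m: (-len(m), m[0]))
    return {acc: i for i, members in enumerate(comps) for acc in members}


def organisms_of(subnetwork: Subnetwork, dataset: Dataset) -> list[str]:
    """Distinct organisms of the displayed proteins, sorted for stable
    gravity-point assignment."""
    orgs = set()
    for acc in subnetwork.proteins:
        if acc not in dataset.proteins:
            raise QueryError(f"displayed accession {acc!r} not in dataset")
        orgs.add(dataset.proteins[acc].organism)
    return sorted(orgs)


@dataclass
class MetricTable:
    """Per-protein degree, betweenness and component id for one subnetwork."""

    values: dict[str, dict[str, float]]
    normalized: bool = False

    def __getitem__(self, accession: str) -> dict[str, float]:
        return self.values[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self.values

    def rows(self) -> list[dict]:
        return [
            {"accession": acc, **self.values[acc]} for acc in sorted(self.values)
        ]


def compute_metrics(subnetwork: Subnetwork, normalized: bool = False) -> MetricTable:
    """Degree, betweenness and component id for every displayed protein."""
    bt = betweenness(subnetwork, normalized=normalized)
    comp = connected_components(subnetwork)
    deg: dict[str, int] = {acc: 0 for acc in subnetwork.proteins}
    for rec in subnetwork.interactions:
        if rec.is_self_loop:
            continue
        deg[rec.endpoint_a] += 1
        deg[rec.endpoint_b] += 1
    return MetricTable(
        {
            acc: {
                "degree": deg[acc],
                "betweenness": bt[acc],
                "component_id": comp[acc],
            }
            for acc in subnetwork.proteins
        },
        normalized=normalized,
    )
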