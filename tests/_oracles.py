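"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (set comprehensions, explicit
path enumeration) and shares no code with the package implementation.
"""

from collections import deque
from itertools import combinations


def edge_set(dataset):
    return {rec.key for rec in dataset.interactions}


def normal_oracle(dataset, query):
    q = set(query) & set(dataset.proteins)
    edges = {k for k in edge_set(dataset) if k[0] in q or k[1] in q}
    proteins = q | {acc for k in edges for acc in k}
    return proteins, edges


def explicit_oracle(dataset, query, displayed_proteins=frozenset()):
    q = set(query) & set(dataset.proteins)
    edges = set()
    for a, b in edge_set(dataset):
        if a in q and b in q:
            edges.add((a, b))
        elif (a in q and b in displayed_proteins) or (b in q and a in displayed_proteins):
            edges.add((a, b))
    proteins = q | {acc for k in edges for acc in k}
    return proteins, edges


def recursive_oracle(dataset, query):
    q = set(query) & set(dataset.proteins)
    closure = set(q)
    for a, b in edge_set(dataset):
        if a == b:
            continue
        if a in q:
            closure.add(b)
        if b in q:
            closure.add(a)
    edges = {k for k in edge_set(dataset) if k[0] in closure and k[1] in closure}
    proteins = q | {acc for k in edges for acc in k}
    return proteins, edges


def betweenness_by_path_enumeration(nodes, edges):
    """Unnormalized betweenness by enumerating every shortest path.

    For each unordered pair (s, t), all shortest s-t paths are listed by
    backtracking through BFS distance layers; each interior node of a
    path gets credit 1/(number of shortest s-t paths).
    """
    adj = {v: set() for v in nodes}
    for a, b in edges:
        if a == b:
            continue
        adj[a].add(b)
        adj[b].add(a)

    def bfs_dist(source):
        dist = {source: 0}
        queue = deque([source])
        while queue:
            v = queue.popleft()
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
        return dist

    score = {v: 0.0 for v in nodes}
    for s, t in combinations(sorted(nodes), 2):
        dist = bfs_dist(s)
        if t not in dist:
            continue
        paths = []

        def extend(path):
            v = path[-1]
            if v == s:
                paths.append(path)
                return
            for w in adj[v]:
                if dist.get(w) == dist[v] - 1:
                    extend(path + [w])

        extend([t])
        for path in paths:
            for interior in path[1:-1]:
                score[interior] += 1.0 / len(paths)
    return score
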