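"""Degree, betweenness and closeness centrality on typed networks.

Betweenness uses Brandes' dependency-accumulation algorithm over BFS
shortest-path DAGs; the raw value is in unordered source-sink pair units
(endpoints excluded), the convention used by Cytoscape's NetworkAnalyzer
before normalisation. Closeness is the within-component form r/D, where r
is the number of nodes reachable from v and D the sum of their distances —
1.0 for a node adjacent to everything it can reach, 0 for an isolate. Both
definitions are well behaved on disconnected graphs.

Exhaustive reference implementations (`brute_force_*`) are provided for
cross-checking on small graphs; they enumerate shortest paths explicitly
and share no code with the production routines.
"""

from __future__ import annotations

from collections import deque
from typing import Optional

import pandas as pd

from .model import TypedNetwork

__all__ = [
    "degree_centrality",
    "betweenness_centrality",
    "closeness_centrality",
    "centrality_table",
    "class_mean",
    "brute_force_betweenness",
    "brute_force_closeness",
]


def degree_centrality(net: TypedNetwork) -> dict[str, int]:
    """Raw degree: count of incident edges per node."""
    return {n: net.degree(n) for n in net.nodes()}


def betweenness_centrality(net: TypedNetwork, normalized: bool = False) -> dict[str, float]:
    """Brandes betweenness for all nodes.

    Raw value: sum over unordered pairs (s, t), s != v != t, of
    sigma_st(v) / sigma_st, with pairs restricted to sigma_st > 0.
    Normalised value divides by (n-1)(n-2)/2 with n the node count.
    """
    nodes = net.nodes()
    bc = {v: 0.0 for v in nodes}
    for s in nodes:
        # single-source shortest paths (BFS) with path counts
        sigma = {v: 0.0 for v in nodes}
        dist = {v: -1 for v in nodes}
        pred: dict[str, list[str]] = {v: [] for v in nodes}
        sigma[s] = 1.0
        dist[s] = 0
        order: list[str] = []
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in net.neighbors(v):
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        # dependency accumulation
        delta = {v: 0.0 for v in nodes}
        for w in reversed(order):
            for v in pred[w]:
                delta[v] += (sigma[v] / sigma[w]) * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair was accumulated from both endpoints
    for v in bc:
        bc[v] /= 2.0
    if normalized:
        n = len(nodes)
        scale = (n - 1) * (n - 2) / 2.0
        if scale > 0:
            for v in bc:
                bc[v] /= scale
        else:
            bc = {v: 0.0 for v in bc}
    return bc


def closeness_centrality(net: TypedNetwork) -> dict[str, float]:
    """Within-component closeness r/D; isolated nodes get 0."""
    out: dict[str, float] = {}
    for s in net.nodes():
        dist = {s: 0}
        queue = deque([s])
        total = 0
        while queue:
            v = queue.popleft()
            for w in net.neighbors(v):
                if w not in dist:
                    dist[w] = dist[v] + 1
                    total += dist[w]
                    queue.append(w)
        reachable = len(dist) - 1
        out[s] = reachable / total if total > 0 else 0.0
    return out


def centrality_table(net: TypedNetwork) -> pd.DataFrame:
    """All three centralities per node, indexed by node id.

    Columns: node_class, degree, betweenness (raw), betweenness_norm,
    closeness.
    """
    deg = degree_centrality(net)
    bet = betweenness_centrality(net, normalized=False)
    bet_n = betweenness_centrality(net, normalized=True)
    clo = closeness_centrality(net)
    nodes = net.nodes()
    return pd.DataFrame(
        {
            "node_class": [net.node_class(n) for n in nodes],
            "degree": [deg[n] for n in nodes],
            "betweenness": [bet[n] for n in nodes],
            "betweenness_norm": [bet_n[n] for n in nodes],
            "closeness": [clo[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def class_mean(table: pd.DataFrame, metric: str, node_class: str) -> float:
    """Arithmetic mean of one metric over nodes of one class only."""
    sub = table.loc[table["node_class"] == node_class, metric]
    if sub.empty:
        raise ValueError(f"no nodes of class {node_class!r} in table")
    return float(sub.mean())


# ---------------------------------------------------------------------------
# Exhaustive oracles (small graphs only)
# ---------------------------------------------------------------------------


def _all_shortest_paths(net: TypedNetwork, s: str, t: str) -> list[list[str]]:
    """Every shortest s-t path, by BFS predecessor DAG expansion."""
    dist = {s: 0}
    pred: dict[str, list[str]] = {s: []}
    queue = deque([s])
    while queue:
        v = queue.popleft()
        for w in net.neighbors(v):
            if w not in dist:
                dist[w] = dist[v] + 1
                pred[w] = [v]
                queue.append(w)
            elif dist[w] == dist[v] + 1:
                pred[w].append(v)
    if t not in dist:
        return []
    paths: list[list[str]] = []

    def expand(node: str, suffix: list[str]) -> None:
        if node == s:
            paths.append([s] + suffix)
            return
        for p in pred[node]:
            expand(p, [node] + suffix)

    expand(t, [])
    return paths


def brute_force_betweenness(net: TypedNetwork) -> dict[str, float]:
    """Raw betweenness by explicit enumeration of all shortest paths."""
    nodes = net.nodes()
    bc = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            paths = _all_shortest_paths(net, s, t)
            if not paths:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                bc[v] += through / len(paths)
    return bc


def brute_force_closeness(net: TypedNetwork) -> dict[str, float]:
    """Closeness r/D via Floyd-Warshall all-pairs distances."""
    nodes = net.nodes()
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    inf = float("inf")
    d = [[0.0 if i == j else inf for j in range(n)] for i in range(n)]
    for u, v in net.edges():
        d[idx[u]][idx[v]] = 1.0
        d[idx[v]][idx[u]] = 1.0
    for k in range(n):
        for i in range(n):
            dik = d[i][k]
            if dik == inf:
                continue
            for j in range(n):
                alt = dik + d[k][j]
                if alt < d[i][j]:
                    d[i][j] = alt
    out = {}
    for v in nodes:
        row = d[idx[v]]
        finite = [x for j, x in enumerate(row) if j != idx[v] and x < inf]
        total = sum(finite)
        out[v] = len(finite) / total if total > 0 else 0.0
    return out
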