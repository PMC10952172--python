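"""Structural description of association networks.

Covers four statistics:

* **density** — realized fraction of possible edges, 2E / (n(n-1));
* **coefficient of variation of edge weights** — SD/mean over dyads, the
  statistic compared against the permutation null to detect non-random
  structure;
* **weighted betweenness centrality** — number of weighted shortest paths
  passing through a node, with fractional credit for ties;
* **walktrap communities** — agglomerative clustering by short random-walk
  distances (Pons & Latapy), cut at the maximum-modularity dendrogram level,
  with weighted Newman modularity.

Betweenness is delegated to networkx; the walktrap agglomeration and the
modularity score are implemented here and cross-checked against an
independent graph library in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .association import AssociationNetwork


class DegenerateInputError(ValueError):
    pass


class UndefinedStatisticError(ValueError):
    pass


@dataclass
class CommunityPartition:
    assignment: dict[str, int]
    n_modules: int
    modularity: float

    def modules(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for node, mod in self.assignment.items():
            out.setdefault(mod, set()).add(node)
        return [out[k] for k in sorted(out)]


@dataclass
class MetricsReport:
    density: float
    cv_edge_weights: float
    betweenness: dict[str, float]
    partition: CommunityPartition
    options: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "density": self.density,
            "cv_edge_weights": self.cv_edge_weights,
            "betweenness": self.betweenness,
            "modularity": self.partition.modularity,
            "n_modules": self.partition.n_modules,
            "module_assignment": self.partition.assignment,
            "options": self.options,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    def betweenness_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            sorted(self.betweenness.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["node", "betweenness"],
        )
        df.to_csv(path, index=False)


def density(net: AssociationNetwork) -> float:
    """2E / (n(n-1)) with E the number of dyads with weight > 0."""
    n = net.n_nodes
    if n < 2:
        raise DegenerateInputError("density needs at least 2 nodes")
    e = int((net.upper_triangle() > 0).sum())
    return 2 * e / (n * (n - 1))


def cv_edge_weights(net: AssociationNetwork, include_zero_dyads: bool = True) -> float:
    """Sample SD / mean of dyad weights.

    By default the statistic runs over all unordered dyads, zeros included:
    the permutation null redistributes weight across dyads, so absent edges
    are informative. ``include_zero_dyads=False`` restricts to realized edges.
    """
    w = net.upper_triangle()
    if not include_zero_dyads:
        w = w[w > 0]
    if w.size < 2:
        raise UndefinedStatisticError("CV needs at least 2 dyads")
    m = w.mean()
    if m == 0:
        raise UndefinedStatisticError("CV undefined: mean edge weight is 0")
    return float(w.std(ddof=1) / m)


def cv_from_weights(w: np.ndarray) -> float:
    """CV of a raw dyad-weight vector (used on permuted matrices)."""
    if w.size < 2:
        return float("nan")
    m = w.mean()
    return float(w.std(ddof=1) / m) if m > 0 else float("nan")


def betweenness(net: AssociationNetwork, weight_mode: str = "cost") -> dict[str, float]:
    """Freeman betweenness over weighted shortest paths, unnormalized.

    ``weight_mode="cost"`` passes association weights directly as path
    lengths, reproducing the convention of the graph libraries commonly used
    on association matrices; ``"similarity_reciprocal"`` uses 1/weight so
    that strong associations give short paths. Disconnected pairs contribute
    nothing.
    """
    if weight_mode not in ("cost", "similarity_reciprocal"):
        raise ValueError(f"unknown weight_mode: {weight_mode!r}")
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    i, j = np.triu_indices(net.n_nodes, k=1)
    for a, b in zip(i, j):
        w = net.weights[a, b]
        if w > 0:
            dist = w if weight_mode == "cost" else 1.0 / w
            g.add_edge(net.nodes[a], net.nodes[b], distance=dist)
    scores = nx.betweenness_centrality(g, weight="distance", normalized=False)
    return {node: float(scores[node]) for node in net.nodes}


def modularity(net: AssociationNetwork, partition: dict[str, int]) -> float:
    """Weighted Newman modularity Q of a node->module assignment.

    Q = sum_c [ w_in(c)/m - (s(c)/(2m))^2 ] with m the total edge weight,
    w_in(c) the weight inside module c and s(c) the summed node strength.
    """
    if set(partition) != set(net.nodes):
        raise ValueError("partition must assign every node exactly once")
    w = net.weights
    m = w.sum() / 2.0
    if m == 0:
        return 0.0
    labels = np.array([partition[n] for n in net.nodes])
    strength = w.sum(axis=1)
    q = 0.0
    for mod in np.unique(labels):
        mask = labels == mod
        w_in = w[np.ix_(mask, mask)].sum() / 2.0
        s = strength[mask].sum()
        q += w_in / m - (s / (2 * m)) ** 2
    return float(q)


def _walktrap_merges(w: np.ndarray, steps: int) -> list[tuple[int, int]]:
    """Pons-Latapy agglomeration on the weighted adjacency ``w``.

    Returns the merge sequence as (community_rep_a, community_rep_b) pairs of
    node indices; isolated nodes never merge. Ties in the merge criterion
    break on the smallest (min, max) index pair.
    """
    n = w.shape[0]
    d = w.sum(axis=1)
    active = {i: [i] for i in range(n) if d[i] > 0}
    if len(active) < 2:
        return []
    # lazy walk: every node carries a self-loop equal to its strength, so
    # P_ii = 1/2; this is the convention of the reference implementation
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(d[:, None] > 0, w / np.where(d[:, None] > 0, 2 * d[:, None], 1), 0.0)
    p[np.diag_indices(n)] += np.where(d > 0, 0.5, 0.0)
    pt = np.linalg.matrix_power(p, steps)
    inv_d = np.where(d > 0, 1.0 / np.where(d > 0, d, 1), 0.0)

    prob = {i: pt[i].copy() for i in active}  # community walk profiles
    adj = {i: {j for j in np.flatnonzero(w[i] > 0) if j != i} for i in active}
    merges: list[tuple[int, int]] = []

    def delta_sigma(a: int, b: int) -> float:
        diff = prob[a] - prob[b]
        r2 = float((diff * diff * inv_d).sum())
        na, nb = len(active[a]), len(active[b])
        return na * nb / (na + nb) / n * r2

    while True:
        best = None
        for a in active:
            for b in adj[a]:
                if b <= a:
                    continue
                ds = delta_sigma(a, b)
                key = (ds, a, b)
                if best is None or key < best:
                    best = key
        if best is None:
            break
        _, a, b = best
        merges.append((a, b))
        na, nb = len(active[a]), len(active[b])
        prob[a] = (na * prob[a] + nb * prob[b]) / (na + nb)
        active[a] = active[a] + active[b]
        adj[a] = (adj[a] | adj[b]) - {a, b}
        for c in adj[b]:
            adj[c].discard(b)
            if c != a:
                adj[c].add(a)
        del active[b], prob[b], adj[b]
    return merges


def walktrap(net: AssociationNetwork, steps: int = 4) -> CommunityPartition:
    """Random-walk community detection, cut at maximum modularity.

    Communities are built by agglomerating nodes whose ``steps``-step random
    walk distributions are similar (walks weighted by edge weight), then the
    dendrogram level with the highest weighted modularity is returned.
    Disconnected components agglomerate independently; isolated nodes stay
    singleton modules.
    """
    n = net.n_nodes
    merges = _walktrap_merges(net.weights, steps)

    # replay the dendrogram, scoring modularity at every level
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def current_partition() -> dict[str, int]:
        roots = {}
        assignment = {}
        for i, node in enumerate(net.nodes):
            r = find(i)
            assignment[node] = roots.setdefault(r, len(roots))
        return assignment

    best_assignment = current_partition()
    best_q = modularity(net, best_assignment)
    for a, b in merges:
        parent[find(b)] = find(a)
        assignment = current_partition()
        q = modularity(net, assignment)
        if q > best_q + 1e-12:
            best_q, best_assignment = q, assignment
    return CommunityPartition(
        assignment=best_assignment,
        n_modules=len(set(best_assignment.values())),
        modularity=best_q,
    )


def metrics_report(
    net: AssociationNetwork,
    weight_mode: str = "cost",
    include_zero_dyads: bool = True,
    walktrap_steps: int = 4,
) -> MetricsReport:
    """Full structural report for one network."""
    return MetricsReport(
        density=density(net),
        cv_edge_weights=cv_edge_weights(net, include_zero_dyads=include_zero_dyads),
        betweenness=betweenness(net, weight_mode=weight_mode),
        partition=walktrap(net, steps=walktrap_steps),
        options={
            "weight_mode": weight_mode,
            "cv_include_zero_dyads": include_zero_dyads,
            "walktrap_steps": walktrap_steps,
        },
    )
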