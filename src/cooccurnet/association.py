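"""Simple Ratio Index (SRI) association networks.

For a pair of items A and B, over the samples (rows) of an occurrence
matrix, let x be the number of samples containing both, and y_a / y_b the
numbers containing only A / only B.  The edge weight is

    SRI(A, B) = x / (x + y_a + y_b)

i.e. the proportion of samples containing either item in which both occur.
The classical SRI also carries a y_ab term (both observed in the same
sampling period but apart); here a sample is a single response list, so two
items in the same sample always co-occur and y_ab is structurally zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .occurrence import OccurrenceMatrix

logger = logging.getLogger(__name__)


@dataclass
class AssociationNetwork:
    """Symmetric item-by-item matrix of SRI edge weights in [0, 1]."""

    nodes: list[str]
    weights: np.ndarray  # (n, n) float, symmetric, zero diagonal
    node_counts: np.ndarray  # occurrences (samples) per node
    kind: str = "identity_by_identity"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.node_counts = np.asarray(self.node_counts, dtype=np.int64)
        n = len(self.nodes)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix does not match node list")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal must be zero")
        if self.weights.min() < 0 or self.weights.max() > 1:
            raise ValueError("weights must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def weight(self, a: str, b: str) -> float:
        return float(self.weights[self.nodes.index(a), self.nodes.index(b)])

    def upper_triangle(self) -> np.ndarray:
        """Vector of all unordered dyad weights (zeros included)."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.weights[iu]

    def edge_list(self) -> pd.DataFrame:
        """Unordered pairs with weight > 0, once each."""
        i, j = np.triu_indices(self.n_nodes, k=1)
        w = self.weights[i, j]
        keep = w > 0
        return pd.DataFrame(
            {
                "node_a": [self.nodes[a] for a in i[keep]],
                "node_b": [self.nodes[b] for b in j[keep]],
                "weight": w[keep],
            }
        )

    def to_edge_csv(self, path: str | Path) -> None:
        self.edge_list().to_csv(path, index=False)

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        g = self.to_networkx()
        nx.write_graphml(g, path)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(kind=self.kind)
        for name, count in zip(self.nodes, self.node_counts.tolist()):
            g.add_node(name, occurrences=int(count))
        for row in self.edge_list().itertuples():
            g.add_edge(row.node_a, row.node_b, weight=float(row.weight))
        return g

    def restrict(self, nodes: Iterable[str]) -> "AssociationNetwork":
        """Sub-network on the given nodes, in the given order."""
        nodes = list(nodes)
        ix = [self.nodes.index(n) for n in nodes]
        return AssociationNetwork(
            nodes=nodes,
            weights=self.weights[np.ix_(ix, ix)],
            node_counts=self.node_counts[ix],
            kind=self.kind,
            provenance=dict(self.provenance),
        )


def sri_counts(occ: OccurrenceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise co-occurrence counts x and per-item totals n.

    y_a = n_a - x and y_b = n_b - x, so the SRI denominator is n_a + n_b - x.
    """
    m = occ.cells.astype(np.int64)
    x = m.T @ m
    return x, occ.col_totals


def sri(occ: OccurrenceMatrix, a: str, b: str) -> float:
    """SRI weight between two items of an occurrence matrix."""
    if a == b:
        raise ValueError("a and b must differ")
    try:
        ja, jb = occ.cols.index(a), occ.cols.index(b)
    except ValueError as err:
        raise KeyError(f"unknown node in {occ.kind}: {err}") from None
    ca, cb = occ.cells[:, ja].astype(np.int64), occ.cells[:, jb].astype(np.int64)
    x = int(ca @ cb)
    denom = int(ca.sum() + cb.sum() - x)
    return x / denom if denom else 0.0


def sri_matrix(x: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Full symmetric SRI weight matrix from co-occurrence counts and totals.

    Pairs with a zero denominator (neither item in any sample) get weight 0.
    """
    denom = totals[:, None] + totals[None, :] - x
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, x / np.where(denom > 0, denom, 1), 0.0)
    np.fill_diagonal(w, 0.0)
    return w


def build_network(occ: OccurrenceMatrix, provenance: dict | None = None) -> AssociationNetwork:
    """SRI association network over all unordered pairs of items."""
    x, totals = sri_counts(occ)
    w = sri_matrix(x, totals)
    iu = np.triu_indices(len(totals), k=1)
    denom = (totals[:, None] + totals[None, :] - x)[iu]
    n_zero_denom = int((denom == 0).sum())
    if n_zero_denom:
        logger.warning(
            "%s: %d node pairs had zero SRI denominator; weight set to 0",
            occ.kind,
            n_zero_denom,
        )
    return AssociationNetwork(
        nodes=list(occ.cols),
        weights=w,
        node_counts=totals,
        kind=occ.kind,
        provenance=dict(provenance or {}),
    )
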