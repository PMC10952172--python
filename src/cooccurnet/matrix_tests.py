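"""Mantel correlation between two association networks.

Both matrices are restricted to their shared node set in a common order,
their off-diagonal upper triangles are vectorized, and r is the Pearson
correlation of the paired dyad weights. Significance comes from a two-tailed
permutation test that relabels the nodes of one matrix (simultaneous
row/column permutation), which respects the dependence structure of dyadic
data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .association import AssociationNetwork
from .nullmodels import p_value


class DegenerateInputError(ValueError):
    pass


@dataclass
class MantelResult:
    r: float
    n_shared_nodes: int
    p: float
    n_permutations: int
    seed: int | None
    shared_nodes: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "r": self.r,
            "n_shared_nodes": self.n_shared_nodes,
            "p": self.p,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    def shared_nodes_csv(self, path: str | Path) -> None:
        pd.DataFrame({"node": self.shared_nodes}).to_csv(path, index=False)


def _upper(m: np.ndarray) -> np.ndarray:
    return m[np.triu_indices(m.shape[0], k=1)]


def mantel(
    net1: AssociationNetwork,
    net2: AssociationNetwork,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> MantelResult:
    """Mantel test between two networks on their shared nodes.

    r = 1 means the dyad weights agree perfectly, r = 0 no linear relation,
    r = -1 perfect reversal. ``p`` uses the plus-one convention over
    ``n_permutations`` random node relabelings of the second matrix.
    """
    shared = sorted(set(net1.nodes) & set(net2.nodes))
    if len(shared) < 3:
        raise DegenerateInputError(
            f"need at least 3 shared nodes, found {len(shared)}"
        )
    m1 = net1.restrict(shared).weights
    m2 = net2.restrict(shared).weights
    v1 = _upper(m1)
    v2 = _upper(m2)
    if v1.std() == 0 or v2.std() == 0:
        raise DegenerateInputError("constant dyad weights: correlation undefined")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])

    rng = np.random.default_rng(seed)
    n_nodes = len(shared)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n_nodes)
        v2p = _upper(m2[np.ix_(perm, perm)])
        if v2p.std() == 0:
            continue
        r_null = float(np.corrcoef(v1, v2p)[0, 1])
        if abs(r_null) >= abs(r_obs) - 1e-15:
            count += 1
    return MantelResult(
        r=r_obs,
        n_shared_nodes=n_nodes,
        p=p_value(count, n_permutations, "plus_one"),
        n_permutations=n_permutations,
        seed=seed,
        shared_nodes=shared,
    )
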