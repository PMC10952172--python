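import numpy as np
import pytest

from cooccurnet.association import AssociationNetwork
from cooccurnet.occurrence import OccurrenceMatrix
from cooccurnet.survey_io import dataset_from_rows


@pytest.fixture
def toy_dataset():
    """Three participants, three identities, a couple of behaviours."""
    return dataset_from_rows(
        [
            ("P1", "A", "b1"),
            ("P1", "A", "b2"),
            ("P1", "B", ""),
            ("P2", "A", "b1"),
            ("P3", "B", ""),
            ("P3", "C", "b3"),
        ]
    )


@pytest.fixture
def small_occ():
    """Deterministic 5x3 occurrence matrix."""
    cells = np.array(
        [
            [1, 1, 0],
            [1, 0, 1],
            [0, 1, 1],
            [1, 1, 1],
            [1, 0, 0],
        ],
        dtype=np.uint8,
    )
    return OccurrenceMatrix(
        kind="identity_by_identity",
        rows=[f"p{i}" for i in range(5)],
        cols=["A", "B", "C"],
        cells=cells,
    )


def random_occurrence(seed: int, n_rows: int = 20, n_cols: int = 10, p: float = 0.3):
    """Random binary occurrence matrix with no empty rows or columns."""
    rng = np.random.default_rng(seed)
    while True:
        cells = (rng.random((n_rows, n_cols)) < p).astype(np.uint8)
        if cells.sum(axis=0).min() > 0 and cells.sum(axis=1).min() > 0:
            return OccurrenceMatrix(
                kind="identity_by_identity",
                rows=[f"p{i}" for i in range(n_rows)],
                cols=[f"item{j}" for j in range(n_cols)],
                cells=cells,
            )


def network_from_weights(w: np.ndarray) -> AssociationNetwork:
    n = w.shape[0]
    return AssociationNetwork(
        nodes=[f"n{i}" for i in range(n)],
        weights=w,
        node_counts=np.ones(n, dtype=int),
    )


def random_network(seed: int, n: int = 12, p_edge: float = 0.4) -> AssociationNetwork:
    rng = np.random.default_rng(seed)
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mask = rng.random(len(iu[0])) < p_edge
    w[iu] = np.where(mask, rng.random(len(iu[0])), 0.0)
    w += w.T
    return network_from_weights(w)
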