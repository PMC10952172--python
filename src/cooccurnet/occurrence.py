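"""Binary samples-by-items occurrence matrices ("gambit of the group").

Three constructions are supported, one per network kind:

``identity_by_identity``
    One row (sample) per participant, one column per identity; a cell is 1
    iff the participant reported the identity.
``behaviour_by_identity``
    One row per (participant, identity) entry that lists at least one
    retained behaviour, one column per behaviour.
``identity_by_behaviour``
    One row per distinct behaviour label (aggregated over the population),
    one column per identity; a cell is 1 iff any participant linked that
    behaviour to that identity.

Associations are then computed column-against-column: two items are
associated to the extent they share rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .survey_io import SurveyDataset

KINDS = ("identity_by_identity", "behaviour_by_identity", "identity_by_behaviour")


class DegenerateInputError(ValueError):
    """An occurrence matrix came out with no rows or no columns."""


@dataclass
class OccurrenceMatrix:
    kind: str
    rows: list[str]
    cols: list[str]
    cells: np.ndarray  # (n_rows, n_cols) uint8, binary

    def __post_init__(self) -> None:
        self.cells = np.ascontiguousarray(self.cells, dtype=np.uint8)
        if self.cells.shape != (len(self.rows), len(self.cols)):
            raise ValueError("cell block does not match row/col labels")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("cells must be binary")

    @property
    def row_totals(self) -> np.ndarray:
        return self.cells.sum(axis=1, dtype=np.int64)

    @property
    def col_totals(self) -> np.ndarray:
        return self.cells.sum(axis=0, dtype=np.int64)

    def col_total_map(self) -> dict[str, int]:
        return dict(zip(self.cols, self.col_totals.tolist()))

    def restrict(self, retained: Iterable[str]) -> "OccurrenceMatrix":
        """Keep only retained columns, then drop rows that become all-zero."""
        retained = set(retained)
        keep_c = [j for j, c in enumerate(self.cols) if c in retained]
        cells = self.cells[:, keep_c]
        keep_r = np.flatnonzero(cells.sum(axis=1) > 0)
        out = OccurrenceMatrix(
            kind=self.kind,
            rows=[self.rows[i] for i in keep_r],
            cols=[self.cols[j] for j in keep_c],
            cells=cells[keep_r],
        )
        if out.cells.size == 0:
            raise DegenerateInputError(
                f"{self.kind}: no rows or columns remain after restriction"
            )
        return out

    def to_dense_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.cells, index=self.rows, columns=self.cols).to_csv(path)

    def to_triplet_csv(self, path: str | Path) -> None:
        r, c = np.nonzero(self.cells)
        pd.DataFrame(
            {"row": [self.rows[i] for i in r], "col": [self.cols[j] for j in c], "value": 1}
        ).to_csv(path, index=False)


def build_occurrence(
    dataset: SurveyDataset, kind: str, retained: Iterable[str] | None = None
) -> OccurrenceMatrix:
    """Derive the binary occurrence matrix for one network kind.

    ``retained`` restricts the columns (network nodes); rows that contain no
    retained item are dropped, since they cannot inform any association and
    would freeze checkerboard swaps. ``retained=None`` keeps the full
    vocabulary.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown kind: {kind!r}; expected one of {KINDS}")

    if kind == "identity_by_identity":
        cols = dataset.identity_vocabulary
        rows = [p.participant_id for p in dataset.participants]
        col_ix = {c: j for j, c in enumerate(cols)}
        cells = np.zeros((len(rows), len(cols)), dtype=np.uint8)
        for i, p in enumerate(dataset.participants):
            for ident in p.identities:
                cells[i, col_ix[ident]] = 1
    elif kind == "behaviour_by_identity":
        cols = dataset.behaviour_vocabulary
        col_ix = {c: j for j, c in enumerate(cols)}
        rows = []
        blocks = []
        for p in dataset.participants:
            for ident in p.identities:
                behs = p.behaviours_by_identity.get(ident, [])
                if not behs:
                    continue
                row = np.zeros(len(cols), dtype=np.uint8)
                for b in behs:
                    row[col_ix[b]] = 1
                rows.append(f"{p.participant_id}·{ident}")
                blocks.append(row)
        cells = np.array(blocks, dtype=np.uint8).reshape(len(rows), len(cols))
    else:  # identity_by_behaviour
        cols = dataset.identity_vocabulary
        rows = dataset.behaviour_vocabulary
        col_ix = {c: j for j, c in enumerate(cols)}
        row_ix = {r: i for i, r in enumerate(rows)}
        cells = np.zeros((len(rows), len(cols)), dtype=np.uint8)
        for p in dataset.participants:
            for ident, behs in p.behaviours_by_identity.items():
                for b in behs:
                    cells[row_ix[b], col_ix[ident]] = 1

    occ = OccurrenceMatrix(kind=kind, rows=rows, cols=cols, cells=cells)
    if occ.cells.size == 0:
        raise DegenerateInputError(f"{kind}: empty occurrence matrix")
    if retained is not None:
        occ = occ.restrict(retained)
    return occ
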