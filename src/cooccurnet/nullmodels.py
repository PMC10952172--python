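"""Datastream (Bejder) permutations for association networks.

The null model holds constant (1) the number of samples, (2) the number of
items per sample, and (3) the number of samples containing each item, while
varying which items each sample contains. It is realized as a Markov chain
of margin-preserving 2x2 "checkerboard" swaps on the binary occurrence
matrix: a submatrix

    [[1, 0],      [[0, 1],
     [0, 1]]  ->   [1, 0]]

A chain step draws a uniformly random (row pair, column pair) proposal and
applies the swap iff the proposal forms a checkerboard, staying put
otherwise. Counting rejected proposals as self-loops makes the transition
kernel symmetric, so the stationary distribution is exactly uniform over
matrices with the observed margins (skipping failures instead would bias
the chain toward high-degree matrices). ``swaps_per_permutation`` counts
proposal steps between recorded samples.

Significance uses the serial method of Besag & Clifford: the observed
matrix is placed at a uniformly random position within the recorded chain
by first advancing a random number of steps from it, which by reversibility
makes the rank of the observed statistic among the null values exactly
uniform under the null at *any* chain length. The classic forward scheme
(burn-in, then sample onward) is available as ``scheme="forward"`` for
reproduction of the traditional procedure.

Two tests are provided: a global test comparing the observed CV of dyad
weights with its null distribution, and per-dyad tests classifying node
pairs as *preferred* (observed weight in the upper tail) or *avoided*
(lower tail) at a two-tailed level.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .association import sri_matrix
from .metrics import cv_from_weights
from .occurrence import OccurrenceMatrix

#: proposals tried before a matrix is declared frozen (no swappable submatrix)
MAX_PROPOSALS = 10_000
_BATCH = 128


class FrozenMatrixWarning(UserWarning):
    pass


@dataclass
class PermutationConfig:
    n_permutations: int = 10_000
    #: proposal steps between recorded samples (rejections count)
    swaps_per_permutation: int = 500
    #: forward-scheme burn-in (proposal steps); ignored by the anchored scheme
    burn_in_swaps: int = 1_000
    seed: int | None = None
    alpha: float = 0.95
    p_convention: str = "plus_one"  # or "raw"
    scheme: str = "anchored"  # or "forward"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.p_convention not in ("plus_one", "raw"):
            raise ValueError(f"unknown p_convention: {self.p_convention!r}")
        if self.scheme not in ("anchored", "forward"):
            raise ValueError(f"unknown scheme: {self.scheme!r}")

    @property
    def tail(self) -> float:
        """Per-tail significance level, (1 - alpha) / 2."""
        return (1.0 - self.alpha) / 2.0


@dataclass
class PermutationReport:
    observed_cv: float
    null_cv: np.ndarray
    global_p: float
    frozen: bool = False
    dyads: pd.DataFrame | None = None
    config: PermutationConfig | None = None

    @property
    def n_preferred(self) -> int:
        return 0 if self.dyads is None else int((self.dyads["class"] == "preferred").sum())

    @property
    def n_avoided(self) -> int:
        return 0 if self.dyads is None else int((self.dyads["class"] == "avoided").sum())

    def global_summary(self) -> dict:
        return {
            "observed_cv": self.observed_cv,
            "null_cv_mean": float(np.mean(self.null_cv)),
            "null_cv_sd": float(np.std(self.null_cv, ddof=1)) if len(self.null_cv) > 1 else 0.0,
            "global_p": self.global_p,
            "n_permutations": int(len(self.null_cv)),
            "frozen": self.frozen,
            "n_preferred": self.n_preferred,
            "n_avoided": self.n_avoided,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.global_summary(), indent=2, sort_keys=True))

    def null_cv_csv(self, path: str | Path) -> None:
        pd.DataFrame({"null_cv": self.null_cv}).to_csv(path, index=False)

    def dyads_csv(self, path: str | Path) -> None:
        if self.dyads is None:
            raise ValueError("report carries no dyad table")
        self.dyads.to_csv(path, index=False)


def p_value(count_geq: int, n: int, convention: str = "plus_one") -> float:
    """Permutation p from the number of null values beyond the observed one.

    ``plus_one`` is (k+1)/(n+1), counting the observed value as a member of
    its own null (Ruxton & Neuhäuser convention); ``raw`` is k/n.
    """
    if not (0 <= count_geq <= n):
        raise ValueError("count_geq must lie in [0, n]")
    if convention == "plus_one":
        return (count_geq + 1) / (n + 1)
    if convention == "raw":
        return count_geq / n
    raise ValueError(f"unknown convention: {convention!r}")


def _swap_once(cells: np.ndarray, rng: np.random.Generator, max_proposals: int = MAX_PROPOSALS) -> bool:
    """Apply one uniformly chosen checkerboard swap in place.

    Returns False (matrix unchanged) if no swappable submatrix is found
    within ``max_proposals`` uniform proposals.
    """
    n_rows, n_cols = cells.shape
    tried = 0
    while tried < max_proposals:
        k = min(_BATCH, max_proposals - tried)
        r = rng.integers(0, n_rows, size=(2, k))
        c = rng.integers(0, n_cols, size=(2, k))
        ok = (
            (r[0] != r[1])
            & (c[0] != c[1])
            & (cells[r[0], c[0]] == 1)
            & (cells[r[0], c[1]] == 0)
            & (cells[r[1], c[0]] == 0)
            & (cells[r[1], c[1]] == 1)
        )
        hits = np.flatnonzero(ok)
        if hits.size:
            i = hits[0]
            r1, r2, c1, c2 = r[0, i], r[1, i], c[0, i], c[1, i]
            cells[r1, c1] = 0
            cells[r1, c2] = 1
            cells[r2, c1] = 1
            cells[r2, c2] = 0
            return True
        tried += k
    return False


def checkerboard_swap(
    occ: OccurrenceMatrix, rng: np.random.Generator, max_proposals: int = MAX_PROPOSALS
) -> OccurrenceMatrix:
    """Return a copy of ``occ`` with one margin-preserving swap applied.

    If the matrix admits no swap within the proposal budget it is returned
    unchanged with a :class:`FrozenMatrixWarning`.
    """
    if occ.cells.shape[0] < 2 or occ.cells.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to swap")
    cells = occ.cells.copy()
    if not _swap_once(cells, rng, max_proposals):
        warnings.warn("no swappable 2x2 submatrix found; matrix frozen", FrozenMatrixWarning)
    return OccurrenceMatrix(kind=occ.kind, rows=list(occ.rows), cols=list(occ.cols), cells=cells)


try:  # compiled proposal loop; falls back to pure python without numba
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _advance_py(cells, r1, r2, c1, c2):
    n_applied = 0
    for i in range(r1.shape[0]):
        a, b, c, d = r1[i], r2[i], c1[i], c2[i]
        if (
            a != b
            and c != d
            and cells[a, c] == 1
            and cells[a, d] == 0
            and cells[b, c] == 0
            and cells[b, d] == 1
        ):
            cells[a, c] = 0
            cells[a, d] = 1
            cells[b, c] = 1
            cells[b, d] = 0
            n_applied += 1
    return n_applied


if _HAVE_NUMBA:
    _advance = _njit(cache=True)(_advance_py)
else:  # pragma: no cover
    _advance = _advance_py

_CHUNK = 1 << 18


def _advance_chain(cells: np.ndarray, n_proposals: int, rng: np.random.Generator) -> int:
    """Run ``n_proposals`` uniform checkerboard proposals in place.

    Invalid proposals leave the matrix unchanged but still consume a step
    (self-loop), keeping the stationary distribution uniform. Returns the
    number of swaps actually applied.
    """
    n_rows, n_cols = cells.shape
    applied = 0
    done = 0
    while done < n_proposals:
        k = min(_CHUNK, n_proposals - done)
        r = rng.integers(0, n_rows, size=(2, k))
        c = rng.integers(0, n_cols, size=(2, k))
        applied += _advance(cells, r[0], r[1], c[0], c[1])
        done += k
    return applied


def _run_chain(
    occ: OccurrenceMatrix,
    config: PermutationConfig,
    statistic: Callable[[np.ndarray], float] | None,
    collect_dyads: bool,
) -> PermutationReport:
    """Shared chain driver for the global and dyadic tests."""
    rng = np.random.default_rng(config.seed)
    cells = occ.cells.copy()
    totals = occ.col_totals
    row_tot = occ.row_totals
    n_items = cells.shape[1]
    iu = np.triu_indices(n_items, k=1)
    ftotals = totals.astype(np.float64)

    def dyad_weights(c: np.ndarray) -> np.ndarray:
        f = c.astype(np.float64)
        x = f.T @ f
        return sri_matrix(x, ftotals)[iu]

    obs_w = dyad_weights(cells)
    if statistic is None:
        stat = cv_from_weights
        observed = stat(obs_w)
    else:
        stat = None
        observed = statistic(occ.cells)

    n = config.n_permutations
    s = config.swaps_per_permutation
    applied = 0
    null_stat = np.empty(n)
    count_geq = np.zeros_like(obs_w, dtype=np.int64)
    count_leq = np.zeros_like(obs_w, dtype=np.int64)
    pos = 0

    def record_run(run_cells: np.ndarray, length: int) -> None:
        nonlocal applied, pos, count_geq, count_leq
        for _ in range(length):
            applied += _advance_chain(run_cells, s, rng)
            # margins are conserved by construction; verify each sampled state
            assert (run_cells.sum(axis=0) == totals).all()
            assert (run_cells.sum(axis=1) == row_tot).all()
            if stat is not None or collect_dyads:
                w = dyad_weights(run_cells)
            null_stat[pos] = stat(w) if stat is not None else statistic(run_cells)
            if collect_dyads:
                count_geq += w >= obs_w
                count_leq += w <= obs_w
            pos += 1

    if config.scheme == "anchored":
        # Besag-Clifford serial test: two independent runs out of the
        # observed matrix (the "backward" run equals a forward run because
        # the proposal kernel is symmetric). Their union is a stationary
        # path with the observed state at a uniformly random position, so
        # its rank among the null values is exactly uniform under the null.
        n_back = int(rng.integers(0, n + 1))
        record_run(cells, n_back)
        record_run(occ.cells.copy(), n - n_back)
    else:
        _advance_chain(cells, config.burn_in_swaps, rng)
        record_run(cells, n)

    frozen = applied == 0
    if frozen:
        warnings.warn(
            "no checkerboard swap was ever applied; the null is frozen and "
            "p-values carry no information",
            FrozenMatrixWarning,
        )
    k_geq = int((null_stat >= observed).sum())
    report = PermutationReport(
        observed_cv=float(observed),
        null_cv=null_stat,
        global_p=p_value(k_geq, n, config.p_convention),
        frozen=frozen,
        config=config,
    )
    if collect_dyads:
        p_upper = np.array([p_value(int(k), n, config.p_convention) for k in count_geq])
        p_lower = np.array([p_value(int(k), n, config.p_convention) for k in count_leq])
        cls = np.where(
            p_upper <= config.tail, "preferred", np.where(p_lower <= config.tail, "avoided", "neutral")
        )
        report.dyads = pd.DataFrame(
            {
                "node_a": [occ.cols[a] for a in iu[0]],
                "node_b": [occ.cols[b] for b in iu[1]],
                "observed_weight": obs_w,
                "p_upper": p_upper,
                "p_lower": p_lower,
                "class": cls,
            }
        )
    return report


def null_chain(
    occ: OccurrenceMatrix,
    config: PermutationConfig,
    statistic: Callable[[np.ndarray], float] | None = None,
) -> PermutationReport:
    """Global non-randomness test.

    ``statistic`` maps a binary occurrence matrix to a scalar; the default
    is the CV of all SRI dyad weights. ``global_p`` is the probability that
    a null value is at least as large as the observed one.
    """
    return _run_chain(occ, config, statistic, collect_dyads=False)


def dyad_tests(occ: OccurrenceMatrix, config: PermutationConfig) -> PermutationReport:
    """Global test plus per-dyad preferred/avoided classification.

    For every unordered pair of retained nodes (observed-zero pairs
    included), ``p_upper`` = P(null weight >= observed) and ``p_lower`` =
    P(null weight <= observed); ties count toward both tails. A dyad is
    *preferred* when ``p_upper`` <= (1-alpha)/2 and *avoided* when
    ``p_lower`` <= (1-alpha)/2.
    """
    return _run_chain(occ, config, statistic=None, collect_dyads=True)
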