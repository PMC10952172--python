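import itertools

import numpy as np
import pytest

from cooccurnet.nullmodels import (
    FrozenMatrixWarning,
    PermutationConfig,
    checkerboard_swap,
    dyad_tests,
    null_chain,
    p_value,
    _advance_chain,
)
from cooccurnet.occurrence import OccurrenceMatrix

from .conftest import random_occurrence


def occ_from_cells(cells):
    cells = np.asarray(cells, dtype=np.uint8)
    return OccurrenceMatrix(
        kind="identity_by_identity",
        rows=[f"r{i}" for i in range(cells.shape[0])],
        cols=[f"c{j}" for j in range(cells.shape[1])],
        cells=cells,
    )


class TestPValue:
    @pytest.mark.parametrize(
        "count, n, convention, expected",
        [
            (0, 9999, "plus_one", 0.0001),
            (9999, 9999, "plus_one", 1.0),
            (50, 1000, "raw", 0.05),
        ],
    )
    def test_conventions(self, count, n, convention, expected):
        assert p_value(count, n, convention) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            p_value(11, 10, "plus_one")

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            p_value(1, 10, "mid")


class TestCheckerboardSwap:
    def test_defining_move(self):
        occ = occ_from_cells([[1, 0], [0, 1]])
        swapped = checkerboard_swap(occ, np.random.default_rng(0))
        np.testing.assert_array_equal(swapped.cells, [[0, 1], [1, 0]])

    def test_margins_conserved(self):
        occ = random_occurrence(0)
        swapped = checkerboard_swap(occ, np.random.default_rng(1))
        assert (swapped.row_totals == occ.row_totals).all()
        assert (swapped.col_totals == occ.col_totals).all()
        assert (swapped.cells != occ.cells).sum() == 4  # exactly one swap

    def test_permutation_matrix_stays_permutation(self):
        occ = occ_from_cells(np.eye(5, dtype=np.uint8))
        rng = np.random.default_rng(2)
        for _ in range(20):
            occ = checkerboard_swap(occ, rng)
            assert (occ.row_totals == 1).all() and (occ.col_totals == 1).all()

    def test_frozen_matrix_warns_and_returns_input(self):
        occ = occ_from_cells([[1, 1], [1, 1]])  # no checkerboard exists
        with pytest.warns(FrozenMatrixWarning):
            out = checkerboard_swap(occ, np.random.default_rng(0), max_proposals=200)
        np.testing.assert_array_equal(out.cells, occ.cells)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            checkerboard_swap(occ_from_cells([[1]]), np.random.default_rng(0))


class TestChain:
    def test_long_chain_conserves_margins(self):
        occ = random_occurrence(1)
        cells = occ.cells.copy()
        _advance_chain(cells, 10_000, np.random.default_rng(0))
        assert (cells.sum(axis=0) == occ.col_totals).all()
        assert (cells.sum(axis=1) == occ.row_totals).all()

    def test_occupancy_approaches_uniform_over_margin_class(self):
        """On a small matrix the chain visits every matrix with the observed
        margins equally often (compared against exhaustive enumeration)."""
        start = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0]], dtype=np.uint8)
        row_t, col_t = start.sum(axis=1), start.sum(axis=0)
        universe = [
            m
            for bits in itertools.product([0, 1], repeat=9)
            for m in [np.array(bits, dtype=np.uint8).reshape(3, 3)]
            if (m.sum(axis=1) == row_t).all() and (m.sum(axis=0) == col_t).all()
        ]
        assert len(universe) > 1
        counts = dict.fromkeys(bytes(m) for m in universe)
        for k in counts:
            counts[k] = 0
        cells = start.copy()
        rng = np.random.default_rng(0)
        n_samples = 20_000
        for _ in range(n_samples):
            _advance_chain(cells, 5, rng)
            counts[bytes(cells)] += 1
        freqs = np.array(list(counts.values())) / n_samples
        expected = 1 / len(universe)
        assert np.abs(freqs - expected).max() < 0.25 * expected

    def test_total_cooccurrence_conserved_but_distribution_varies(self):
        """Margins fix the total co-occurrence count (sum_r C(k_r, 2)), so
        the statistic sum(x) is constant along the chain, while its
        concentration sum(x^2) varies."""
        occ = occ_from_cells(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1], [1, 0, 1, 0]]
        )

        def pair_counts(cells):
            f = cells.astype(float)
            x = f.T @ f
            return x[np.triu_indices(x.shape[0], k=1)]

        cfg = PermutationConfig(n_permutations=200, swaps_per_permutation=20, seed=0)
        total = null_chain(occ, cfg, statistic=lambda c: float(pair_counts(c).sum()))
        assert set(total.null_cv.tolist()) == {float(pair_counts(occ.cells).sum())}
        spread = null_chain(occ, cfg, statistic=lambda c: float((pair_counts(c) ** 2).sum()))
        assert len(set(spread.null_cv.tolist())) > 1

    def test_global_p_at_least_one_over_n_plus_one(self):
        occ = random_occurrence(2)
        rep = null_chain(occ, PermutationConfig(n_permutations=99, seed=0))
        assert rep.global_p >= 1 / 100

    def test_seeded_reports_are_reproducible(self):
        occ = random_occurrence(3)
        cfg = PermutationConfig(n_permutations=50, seed=11)
        r1 = dyad_tests(occ, cfg)
        r2 = dyad_tests(occ, cfg)
        assert r1.global_p == r2.global_p
        np.testing.assert_array_equal(r1.null_cv, r2.null_cv)
        assert r1.dyads.equals(r2.dyads)
        r3 = dyad_tests(occ, PermutationConfig(n_permutations=50, seed=12))
        assert not np.array_equal(r1.null_cv, r3.null_cv)

    def test_frozen_chain_flagged(self):
        occ = occ_from_cells([[1, 1], [1, 1], [1, 1]])
        with pytest.warns(FrozenMatrixWarning):
            rep = null_chain(occ, PermutationConfig(n_permutations=10, seed=0))
        assert rep.frozen


class TestDyadClassification:
    def test_classes_consistent_with_thresholds(self):
        occ = random_occurrence(5, n_rows=40, n_cols=8)
        cfg = PermutationConfig(n_permutations=200, seed=0)
        rep = dyad_tests(occ, cfg)
        d = rep.dyads
        tail = cfg.tail
        assert ((d["class"] == "preferred") == (d.p_upper <= tail)).all()
        assert (
            (d["class"] == "avoided") == ((d.p_lower <= tail) & (d.p_upper > tail))
        ).all()
        # never both: a dyad in the upper tail cannot also sit in the lower tail
        assert not ((d.p_upper <= tail) & (d.p_lower <= tail)).any()

    def test_planted_inseparable_pair_is_preferred(self):
        """Two labels co-occurring in all 20 of their samples, among 12
        independent background labels, are flagged preferred."""
        rng = np.random.default_rng(0)
        background = (rng.random((60, 12)) < 0.3).astype(np.uint8)
        pair = np.zeros((60, 2), dtype=np.uint8)
        pair[:20] = 1
        occ = occ_from_cells(np.hstack([pair, background]))
        rep = dyad_tests(
            occ, PermutationConfig(n_permutations=500, swaps_per_permutation=2000, seed=1)
        )
        d = rep.dyads
        row = d[(d.node_a == "c0") & (d.node_b == "c1")].iloc[0]
        assert row["class"] == "preferred"

    def test_planted_exclusive_pair_is_avoided(self):
        """Two frequent labels that never share a sample are flagged avoided."""
        rng = np.random.default_rng(0)
        background = (rng.random((80, 12)) < 0.3).astype(np.uint8)
        a = np.zeros(80, dtype=np.uint8)
        b = np.zeros(80, dtype=np.uint8)
        a[:40] = 1
        b[40:] = 1
        occ = occ_from_cells(np.column_stack([a, b, background]))
        rep = dyad_tests(
            occ, PermutationConfig(n_permutations=500, swaps_per_permutation=2000, seed=2)
        )
        d = rep.dyads
        row = d[(d.node_a == "c0") & (d.node_b == "c1")].iloc[0]
        assert row["class"] == "avoided"
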