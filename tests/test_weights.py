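"""Stump fitting and edge-weight computation, with independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from switchtfi import (
    CellStatePartition,
    ExpressionMatrix,
    compute_weight,
    fit_stump,
    partition_cells,
    select_cells,
    weight_all_edges,
)
from switchtfi.data import BaselineGRN
from switchtfi.weights import (
    DegenerateStumpError,
    RegressionStump,
    SingleStateSubsetError,
    weight_from_counts,
)


def brute_force_stump_mse(x, y):
    """Oracle: minimum two-leaf MSE over midpoints of consecutive distinct
    sorted predictor values plus the degenerate one-leaf predictor."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    uniq = np.unique(x)
    candidates = list((uniq[:-1] + uniq[1:]) / 2) + [uniq[-1]]
    best = np.inf
    for b in candidates:
        left = x <= b
        sse = 0.0
        for side in (left, ~left):
            if side.any():
                sse += np.sum((y[side] - y[side].mean()) ** 2)
        best = min(best, sse / x.size)
    # degenerate single-leaf predictor (everything in one mean)
    best = min(best, np.var(y))
    return best


class TestFitStump:
    def test_perfectly_separable(self):
        stump = fit_stump(np.array([1.0, 1, 2, 2]), np.array([0.0, 0, 10, 10]))
        assert 1 <= stump.boundary < 2
        assert stump.left_mean == 0 and stump.right_mean == 10
        assert stump.mse == 0

    def test_constant_target_gives_zero_mse(self):
        stump = fit_stump(np.array([1.0, 2, 3, 4]), np.array([5.0, 5, 5, 5]))
        assert stump.mse == 0
        for mean in (stump.left_mean, stump.right_mean):
            if not np.isnan(mean):
                assert mean == 5

    def test_constant_tf_is_degenerate(self):
        with pytest.raises(DegenerateStumpError):
            fit_stump(np.array([2.0, 2, 2]), np.array([1.0, 2, 3]))

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 11)
        x = rng.choice([0.0, 0.5, 1.0, 2.0, 3.0], size=n)
        if np.all(x == x[0]):
            x[0] += 1.0
        y = rng.normal(size=n)
        stump = fit_stump(x, y)
        assert stump.mse == pytest.approx(brute_force_stump_mse(x, y), abs=1e-12)
        assert min(x) <= stump.boundary <= max(x)

    def test_matches_sklearn_tree(self):
        """Cross-check against an established CART implementation."""
        from sklearn.tree import DecisionTreeRegressor

        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=25)
            y = rng.normal(size=25)
            stump = fit_stump(x, y)
            tree = DecisionTreeRegressor(max_depth=1).fit(x[:, None], y)
            pred = tree.predict(x[:, None])
            assert stump.mse == pytest.approx(np.mean((y - pred) ** 2), abs=1e-10)

    def test_mse_tie_broken_to_smallest_boundary(self):
        # symmetric configuration: both split positions give identical MSE
        stump = fit_stump(np.array([0.0, 1.0, 2.0]), np.array([1.0, 0.0, 1.0]))
        assert stump.boundary == 0.5


class TestPartitionCells:
    @pytest.mark.parametrize("boundary,expected_left", [
        (0.5, []),           # below min: everything right
        (3.0, [0, 1, 2]),    # at max: everything left (<= is inclusive)
        (1.5, [0]),
    ])
    def test_boundary_semantics(self, boundary, expected_left):
        stump = RegressionStump(boundary, 0.0, 0.0, 0.0)
        tf = np.array([1.0, 2.0, 3.0])
        left, right = partition_cells(stump, tf, np.arange(3))
        assert list(left) == expected_left
        assert sorted(list(left) + list(right)) == [0, 1, 2]


class TestComputeWeight:
    def test_perfect_alignment_gives_one(self, balanced_partition):
        assert compute_weight({"c1", "c2"}, {"c3", "c4"}, balanced_partition) == 1.0

    def test_swapped_alignment_gives_one(self, balanced_partition):
        assert compute_weight({"c3", "c4"}, {"c1", "c2"}, balanced_partition) == 1.0

    def test_all_one_side_balanced_gives_quarter(self, balanced_partition):
        assert compute_weight({"c1", "c2", "c3", "c4"}, set(), balanced_partition) == 0.25
        assert compute_weight(set(), {"c1", "c2", "c3", "c4"}, balanced_partition) == 0.25

    def test_crossing_partition_hand_value(self, balanced_partition):
        # P={c1,c2}, O={c3,c4}, L={c1,c3}, R={c2,c4}: all four JI terms are 1/3
        w = compute_weight({"c1", "c3"}, {"c2", "c4"}, balanced_partition)
        assert w == pytest.approx(1 / 3)

    def test_single_state_subset_rejected(self, balanced_partition):
        with pytest.raises(SingleStateSubsetError):
            compute_weight({"c1"}, {"c2"}, balanced_partition)

    def test_relabeling_invariance(self, balanced_partition):
        renamed = CellStatePartition({
            "x1": "progenitor", "x2": "progenitor",
            "x3": "offspring", "x4": "offspring"})
        w1 = compute_weight({"c1", "c3"}, {"c2", "c4"}, balanced_partition)
        w2 = compute_weight({"x1", "x3"}, {"x2", "x4"}, renamed)
        assert w1 == w2

    @given(st.integers(2, 8), st.integers(0, 255), st.integers(0, 255))
    @settings(max_examples=300, deadline=None)
    def test_weight_range_property(self, n, p_bits, l_bits):
        """Any {P,O} x {L,R} pair of bipartitions yields w in [0.25, 1]."""
        p_mask = [(p_bits >> i) & 1 for i in range(n)]
        l_mask = [(l_bits >> i) & 1 for i in range(n)]
        if sum(p_mask) in (0, n):
            return  # both states must be nonempty
        pl = sum(p and l for p, l in zip(p_mask, l_mask))
        pr = sum(p_mask) - pl
        ol = sum(l_mask) - pl
        orr = n - sum(p_mask) - ol
        w = weight_from_counts(pl, pr, ol, orr)
        assert 0.25 - 1e-12 <= w <= 1 + 1e-12

    def test_symmetry_under_side_swap(self):
        for pl, pr, ol, orr in itertools.product(range(3), repeat=4):
            if pl + pr == 0 or ol + orr == 0:
                continue
            assert weight_from_counts(pl, pr, ol, orr) == \
                weight_from_counts(pr, pl, orr, ol)


class TestSelectCells:
    def test_all_cells_coexpressing(self, small_matrix):
        subset = select_cells(("tfA", "g1"), small_matrix, 0.20)
        assert list(subset) == [0, 1, 2, 3]

    def test_below_threshold_skipped(self):
        values = np.zeros((20, 2))
        values[:3] = 1.0  # co-expression in 3/20 = 0.15 < 0.20
        m = ExpressionMatrix(values, [f"c{i}" for i in range(20)], ["a", "b"])
        assert select_cells(("a", "b"), m, 0.20) is None

    def test_zero_threshold_disables_filter(self):
        values = np.zeros((20, 2))
        values[0] = 1.0
        m = ExpressionMatrix(values, [f"c{i}" for i in range(20)], ["a", "b"])
        assert list(select_cells(("a", "b"), m, 0.0)) == [0]


class TestWeightAllEdges:
    def test_exclusion_bookkeeping(self):
        # 10 cells: 3 informative genes + 2 genes expressed in 1/10 cells (<20%)
        rng = np.random.default_rng(0)
        n = 10
        values = np.column_stack([
            rng.uniform(1, 2, n),   # tfA, always on
            rng.uniform(1, 2, n),   # g1, always on
            rng.uniform(1, 2, n),   # g2, always on
            np.eye(n)[0],           # rare1: one cell only
            np.eye(n)[1],           # rare2: one cell only
        ])
        m = ExpressionMatrix(values, [f"c{i}" for i in range(n)],
                             ["tfA", "g1", "g2", "rare1", "rare2"])
        part = CellStatePartition({f"c{i}": ("progenitor" if i < 5 else "offspring")
                                   for i in range(n)})
        grn = BaselineGRN([("tfA", "g1"), ("tfA", "g2"),
                           ("tfA", "rare1"), ("rare2", "g1"), ("ghost", "g1")])
        stats, report = weight_all_edges(grn, m, part)
        assert set(stats) == {("tfA", "g1"), ("tfA", "g2")}
        reasons = dict(report)
        assert reasons[("tfA", "rare1")] == "low_coexpression"
        assert reasons[("rare2", "g1")] == "low_coexpression"
        assert reasons[("ghost", "g1")] == "missing_gene"
        assert len(stats) + len(report) == len(grn)

    def test_state_separating_edges_get_weight_one(self, small_matrix,
                                                   balanced_partition, small_grn):
        stats, report = weight_all_edges(small_grn, small_matrix, balanced_partition)
        assert not report
        assert all(st.weight == 1.0 for st in stats.values())

    def test_driver_edges_outweigh_null_edges(self, separable_run):
        stats, _ = weight_all_edges(
            separable_run["grn"], separable_run["matrix"], separable_run["partition"])
        truth = separable_run["truth"]
        driver = [s.weight for e, s in stats.items() if e in truth.driver_edges]
        null = [s.weight for e, s in stats.items() if e not in truth.driver_edges]
        assert np.mean(driver) > np.mean(null)
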