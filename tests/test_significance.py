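"""Label permutation, max-T adjusted P-values, and pruning."""

import itertools

import numpy as np
import pytest

from switchtfi import (
    BaselineGRN,
    CellStatePartition,
    adjusted_pvalues,
    permutation_weights,
    permute_labels,
    prune,
)
from switchtfi.data import EdgeStatistics
from switchtfi.significance import PermutationEnsemble
from switchtfi.weights import weight_from_counts


def make_partition(cells, prog):
    return CellStatePartition(
        {c: ("progenitor" if c in prog else "offspring") for c in cells})


def make_stats(edge, left, right, partition):
    from switchtfi.weights import compute_weight

    return EdgeStatistics(
        edge=edge, n_cells_used=len(left) + len(right),
        coexpression_fraction=1.0, boundary=0.0,
        left_cells=frozenset(left), right_cells=frozenset(right),
        weight=compute_weight(set(left), set(right), partition))


class TestPermuteLabels:
    def test_class_sizes_preserved_and_deterministic(self):
        cells = [f"c{i}" for i in range(10)]
        part = make_partition(cells, set(cells[:3]))
        m1 = permute_labels(part, cells, q=20, seed=5)
        m2 = permute_labels(part, cells, q=20, seed=5)
        np.testing.assert_array_equal(m1, m2)
        assert (m1.sum(axis=1) == 3).all()

    def test_different_seed_differs(self):
        cells = [f"c{i}" for i in range(10)]
        part = make_partition(cells, set(cells[:5]))
        assert not np.array_equal(permute_labels(part, cells, 20, 1),
                                  permute_labels(part, cells, 20, 2))

    def test_exchangeability(self):
        """Each cell is progenitor in about |P|/|C| of the permutations."""
        cells = [f"c{i}" for i in range(8)]
        part = make_partition(cells, set(cells[:4]))
        masks = permute_labels(part, cells, q=1000, seed=0)
        freq = masks.mean(axis=0)
        se = np.sqrt(0.25 / 1000)
        assert np.all(np.abs(freq - 0.5) < 4 * se + 1e-9)


class TestPermutationWeights:
    def test_identity_permutation_reproduces_observed_weight(self):
        cells = [f"c{i}" for i in range(6)]
        part = make_partition(cells, set(cells[:3]))
        st = make_stats(("A", "B"), cells[:2], cells[2:], part)
        identity = part.progenitor_mask(cells)[None, :]
        ens = permutation_weights({("A", "B"): st}, identity, cells)
        assert ens.weights[0, 0] == pytest.approx(st.weight, abs=1e-12)

    def test_label_swap_symmetry(self):
        """Swapping P and O leaves the weight unchanged (max over matchings)."""
        cells = [f"c{i}" for i in range(6)]
        part = make_partition(cells, set(cells[:2]))
        st = make_stats(("A", "B"), cells[:3], cells[3:], part)
        mask = part.progenitor_mask(cells)
        ens = permutation_weights(
            {("A", "B"): st}, np.vstack([mask, ~mask]), cells)
        assert ens.weights[0, 0] == pytest.approx(ens.weights[1, 0], abs=1e-12)

    def test_exhaustive_balanced_relabelings_match_brute_force(self):
        """|C|=4, one edge: all 6 balanced relabelings agree with direct
        evaluation of the permuted-weight formula."""
        cells = ["c0", "c1", "c2", "c3"]
        part = make_partition(cells, {"c0", "c1"})
        left, right = ["c0", "c2"], ["c1", "c3"]
        st = make_stats(("A", "B"), left, right, part)
        masks = np.array(
            [[i in combo for i in range(4)]
             for combo in itertools.combinations(range(4), 2)])
        ens = permutation_weights({("A", "B"): st}, masks, cells)
        for row, combo in zip(ens.weights[:, 0],
                              itertools.combinations(range(4), 2)):
            prog = {cells[i] for i in combo}
            pl = len(prog & set(left))
            expected = weight_from_counts(pl, 2 - pl, 2 - pl, pl)
            assert row == pytest.approx(expected, abs=1e-12)

    def test_empty_class_policies(self):
        """A permutation putting every cell of the edge subset in one state
        is omitted from the maximum by default, or counted as 1 under the
        conservative policy."""
        cells = [f"c{i}" for i in range(6)]
        part = make_partition(cells, {"c0", "c3", "c4"})
        # edge uses only the first 3 cells (observed: c0 progenitor, c1/c2 not)
        st = make_stats(("A", "B"), cells[:2], [cells[2]], part)
        masks = np.array([
            [True, True, True, False, False, False],   # subset all-progenitor
            [True, False, True, False, True, False],
        ])
        ens = permutation_weights({("A", "B"): st}, masks, cells)
        assert np.isnan(ens.weights[0, 0]) and not np.isnan(ens.weights[1, 0])
        cons = permutation_weights({("A", "B"): st}, masks, cells,
                                   empty_class_policy="conservative")
        assert cons.weights[0, 0] == 1.0


class TestAdjustedPvalues:
    def _ensemble(self, max_weights):
        q = len(max_weights)
        return PermutationEnsemble(
            edges=[("A", "B")], weights=np.full((q, 1), np.nan),
            max_weights=np.asarray(max_weights, float), q=q)

    def test_direct_count(self):
        ens = self._ensemble([0.6, 0.8, 0.5, 0.9])
        assert adjusted_pvalues({("A", "B"): 0.7}, ens)[("A", "B")] == 0.5

    def test_extremes(self):
        ens = self._ensemble([0.5, 0.5, 0.5])
        assert adjusted_pvalues({("A", "B"): 0.99}, ens)[("A", "B")] == 0.0
        assert adjusted_pvalues({("A", "B"): 0.3}, ens)[("A", "B")] == 1.0

    def test_monotone_in_weight(self):
        rng = np.random.default_rng(0)
        ens = self._ensemble(rng.uniform(0.25, 1.0, size=200))
        ws = np.sort(rng.uniform(0.25, 1.0, size=50))
        ps = [adjusted_pvalues({("A", "B"): w}, ens)[("A", "B")] for w in ws]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))


class TestPrune:
    def _inputs(self, pvals):
        cells = ["c0", "c1", "c2", "c3"]
        part = make_partition(cells, {"c0", "c1"})
        grn = BaselineGRN([("A", f"B{i}") for i in range(len(pvals))])
        stats = {e: make_stats(e, cells[:2], cells[2:], part) for e in grn.edges}
        return grn, stats, dict(zip(grn.edges, pvals))

    def test_threshold_is_inclusive(self):
        grn, stats, pvals = self._inputs([0.01, 0.05, 0.06])
        tgrn = prune(grn, stats, pvals, alpha=0.05)
        assert len(tgrn) == 2
        assert all(st.p_adjusted <= 0.05 for st in tgrn.edges)

    def test_alpha_one_keeps_all_weighted_edges(self):
        grn, stats, pvals = self._inputs([0.2, 0.9, 1.0])
        assert len(prune(grn, stats, pvals, alpha=1.0)) == 3

    def test_empty_result_warns(self):
        grn, stats, pvals = self._inputs([0.5, 0.6])
        with pytest.warns(UserWarning, match="empty"):
            tgrn = prune(grn, stats, pvals, alpha=0.05)
        assert len(tgrn) == 0

    def test_node_set_induced_by_retained_edges(self):
        grn, stats, pvals = self._inputs([0.01, 0.5])
        tgrn = prune(grn, stats, pvals, alpha=0.05)
        assert tgrn.nodes == {"A", "B0"}


def test_seed_determinism_end_to_end(separable_run):
    """Identical inputs and seed give bit-identical adjusted P-values."""
    from switchtfi import fit_transition_grn

    run = separable_run
    tgrn2, _ = fit_transition_grn(
        run["matrix"], run["grn"], run["partition"],
        n_permutations=500, seed=7, ranking="both")
    p1 = {st.edge: st.p_adjusted for st in run["tgrn"].edges}
    p2 = {st.edge: st.p_adjusted for st in tgrn2.edges}
    assert p1 == p2
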