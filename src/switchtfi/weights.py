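"""Edge relevance weights from regression-stump cell partitions.

For each GRN edge (TF i, target j), a depth-1 regression tree (stump) of
target expression on TF expression is fit over the cells where both genes
are expressed. The stump's decision boundary b splits those cells into
L = {c : x_{c,i} <= b} and R = {c : x_{c,i} > b}. If the edge matters for
the progenitor -> offspring transition, this expression-driven split
lines up with the state annotation split {P, O}; the weight

    w = max( JI(P, L) + JI(O, R),  JI(P, R) + JI(O, L) ) / 2

(JI = Jaccard index) measures that alignment after matching the two
partitions' blocks optimally, and is guaranteed to lie in [0.25, 1] for
any nonempty P, O. Weights near 1 flag state-switching regulation;
weights near 0.25 flag state-independent edges.

Edges are excluded (with a reason recorded) when the TF-target pair is
co-expressed in too few cells, when the TF is constant over the subset
(no informative split exists), or when the subset contains only one cell
state (the Jaccard terms would be undefined).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import BaselineGRN, CellStatePartition, EdgeStatistics, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionStump",
    "DegenerateStumpError",
    "SingleStateSubsetError",
    "select_cells",
    "fit_stump",
    "partition_cells",
    "jaccard",
    "compute_weight",
    "weight_from_counts",
    "weight_all_edges",
]


class DegenerateStumpError(ValueError):
    """The TF expression vector is constant: only the trivial split exists."""


class SingleStateSubsetError(ValueError):
    """The edge's cell subset contains only progenitors or only offspring."""


@dataclass
class RegressionStump:
    """A fitted depth-1 regression tree.

    ``boundary`` lies within the observed TF expression range; the leaf
    predictions are the target means over the two sides, and ``mse`` is
    the mean squared error of the resulting two-leaf predictor. An empty
    side has prediction ``nan``.
    """

    boundary: float
    left_mean: float
    right_mean: float
    mse: float


def select_cells(
    edge: tuple[str, str],
    matrix: ExpressionMatrix,
    min_coexpression_fraction: float = 0.20,
) -> np.ndarray | None:
    """Indices of cells with strictly positive expression of both genes.

    Returns ``None`` ("skipped") when the co-expressing subset covers less
    than ``min_coexpression_fraction`` of *all* cells in the dataset.
    Sparse co-expression makes the fitted weight unstable, so such edges
    are excluded from weighting and testing; 0.20 is the recommended
    default.
    """
    tf, target = edge
    mask = (matrix.gene_column(tf) > 0) & (matrix.gene_column(target) > 0)
    if mask.sum() < min_coexpression_fraction * matrix.n_cells:
        return None
    return np.flatnonzero(mask)


def fit_stump(tf_expr: np.ndarray, target_expr: np.ndarray) -> RegressionStump:
    """Fit the MSE-optimal regression stump of target on TF expression.

    Candidate boundaries are the midpoints between consecutive distinct
    sorted TF values — these realize every achievable bipartition — plus
    the degenerate all-left split at the maximum TF value. Ties in MSE are
    broken toward the smallest boundary, which makes the fit deterministic
    on discrete imputed values.
    """
    x = np.asarray(tf_expr, dtype=float)
    y = np.asarray(target_expr, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("tf_expr and target_expr must be 1-D vectors of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 cells to fit a stump")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    if xs[0] == xs[-1]:
        raise DegenerateStumpError("TF expression constant over the cell subset")

    csum = np.cumsum(ys)
    total, total_sq = csum[-1], float(np.sum(ys * ys))
    n_left = np.arange(1, n)
    left_sum = csum[:-1]
    # SSE of the two-means predictor for each split position (vectorized)
    sse_split = total_sq - left_sum**2 / n_left - (total - left_sum) ** 2 / (n - n_left)
    valid = xs[:-1] != xs[1:]
    boundaries = (xs[:-1] + xs[1:]) / 2.0
    cand_sse = np.append(sse_split[valid], total_sq - total**2 / n)
    cand_b = np.append(boundaries[valid], xs[-1])  # degenerate: everything left

    # boundaries ascend, so argmin's first-hit rule is the smallest-boundary tie-break
    best = int(np.argmin(cand_sse))
    b = float(cand_b[best])
    left = xs <= b
    left_mean = float(ys[left].mean()) if left.any() else float("nan")
    right_mean = float(ys[~left].mean()) if (~left).any() else float("nan")
    mse = max(float(cand_sse[best]) / n, 0.0)  # clip fp negatives
    return RegressionStump(boundary=b, left_mean=left_mean, right_mean=right_mean, mse=mse)


def partition_cells(
    stump: RegressionStump, tf_expr: np.ndarray, cells: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split ``cells`` by the stump boundary (TF <= boundary goes left)."""
    tf_expr = np.asarray(tf_expr, dtype=float)
    cells = np.asarray(cells)
    left = tf_expr <= stump.boundary
    return cells[left], cells[~left]


def jaccard(a: set, b: set) -> float:
    """Jaccard index |A∩B| / |A∪B|; two empty sets have index 1."""
    union = len(a | b)
    return 1.0 if union == 0 else len(a & b) / union


def weight_from_counts(p_left: int, p_right: int, o_left: int, o_right: int) -> float:
    """Edge weight from the 2x2 contingency of state vs stump side.

    Evaluates both block matchings of the two bipartitions and keeps the
    better one; the count form is shared with the permutation stage so
    observed and permuted weights are computed with identical arithmetic.
    """
    n_p, n_o = p_left + p_right, o_left + o_right
    n_l, n_r = p_left + o_left, p_right + o_right
    if n_p == 0 or n_o == 0:
        raise SingleStateSubsetError("both cell states must be present")

    def ji(inter: int, size_a: int, size_b: int) -> float:
        union = size_a + size_b - inter
        return 1.0 if union == 0 else inter / union

    direct = ji(p_left, n_p, n_l) + ji(o_right, n_o, n_r)
    crossed = ji(p_right, n_p, n_r) + ji(o_left, n_o, n_l)
    return max(direct, crossed) / 2.0


def compute_weight(
    left_cells: set[str] | frozenset[str],
    right_cells: set[str] | frozenset[str],
    partition: CellStatePartition,
) -> float:
    """Edge weight for an explicit left/right cell split.

    The progenitor and offspring sets are restricted to the cells in
    ``left_cells | right_cells`` before the Jaccard terms are formed; both
    restrictions must be nonempty (:class:`SingleStateSubsetError`
    otherwise). The result lies in [0.25, 1].
    """
    if set(left_cells) & set(right_cells):
        raise ValueError("left and right cell sets must be disjoint")
    cells = set(left_cells) | set(right_cells)
    p = partition.progenitors & cells
    o = partition.offspring & cells
    return weight_from_counts(
        len(p & set(left_cells)), len(p & set(right_cells)),
        len(o & set(left_cells)), len(o & set(right_cells)),
    )


def weight_all_edges(
    grn: BaselineGRN,
    matrix: ExpressionMatrix,
    partition: CellStatePartition,
    *,
    min_coexpression_fraction: float = 0.20,
) -> tuple[dict[tuple[str, str], EdgeStatistics], list[tuple[tuple[str, str], str]]]:
    """Fit a stump and weight for every GRN edge.

    Edges with an endpoint absent from the matrix are dropped first (with
    a warning). Every remaining edge either receives an
    :class:`~switchtfi.data.EdgeStatistics` record or appears in the
    exclusion report with one of the reasons ``low_coexpression``,
    ``degenerate_tf`` or ``single_state_subset``.
    """
    grn, dropped = grn.restrict_to_genes(matrix.gene_ids)
    report: list[tuple[tuple[str, str], str]] = [(e, "missing_gene") for e in dropped]
    cell_ids = np.asarray(matrix.cell_ids)
    stats: dict[tuple[str, str], EdgeStatistics] = {}

    for edge in grn.edges:
        subset = select_cells(edge, matrix, min_coexpression_fraction)
        if subset is None:
            report.append((edge, "low_coexpression"))
            continue
        tf_expr = matrix.gene_column(edge[0])[subset]
        target_expr = matrix.gene_column(edge[1])[subset]
        try:
            stump = fit_stump(tf_expr, target_expr)
        except DegenerateStumpError:
            report.append((edge, "degenerate_tf"))
            continue
        left_idx, right_idx = partition_cells(stump, tf_expr, subset)
        left_names = frozenset(cell_ids[left_idx])
        right_names = frozenset(cell_ids[right_idx])
        try:
            w = compute_weight(left_names, right_names, partition)
        except SingleStateSubsetError:
            report.append((edge, "single_state_subset"))
            continue
        stats[edge] = EdgeStatistics(
            edge=edge,
            n_cells_used=int(subset.size),
            coexpression_fraction=subset.size / matrix.n_cells,
            boundary=stump.boundary,
            left_cells=left_names,
            right_cells=right_names,
            weight=w,
        )

    if report:
        logger.info("excluded %d / %d edges from weighting", len(report),
                    len(report) + len(stats))
    return stats, report
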