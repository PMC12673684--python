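"""Westfall-Young max-statistic permutation testing and GRN pruning.

The edge weight is treated as the test statistic of the null hypothesis
"this edge carries no explanatory power for the state transition". The
null distribution of the weights is unknown and the weights of edges
sharing TFs or targets are dependent, so adjusted P-values are computed
with the Westfall-Young max-T scheme: progenitor/offspring labels are
permuted q times; in each permutation k every edge's weight is
re-evaluated against its *fixed* observed split {L_e, R_e} (stumps are
not refit), the per-permutation maximum w_max^(k) over all tested edges
is recorded, and

    P_e = (1/q) * #{ k : w_max^(k) >= w_e }.

Rejecting the edges with P_e <= alpha controls the family-wise error
rate at level alpha over the tested family while respecting the
dependence between edges; one shared global permutation per replicate is
applied across all edges, which is what makes the max-T construction
valid.

Permutations under which an edge's cell subset contains only one state
leave that edge's permuted weight undefined; by default the edge simply
contributes nothing to that permutation's maximum (``omit``), with a
``conservative`` policy available that counts the undefined weight as 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data import BaselineGRN, CellStatePartition, EdgeStatistics, TransitionGRN

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationEnsemble",
    "permute_labels",
    "permutation_weights",
    "adjusted_pvalues",
    "prune",
]


@dataclass
class PermutationEnsemble:
    """Permutation weights for all tested edges.

    ``weights`` has shape ``(q, n_edges)`` with ``nan`` marking
    permutations where an edge's restricted class was empty;
    ``max_weights`` is the per-permutation maximum over the defined
    entries.
    """

    edges: list[tuple[str, str]]
    weights: np.ndarray
    max_weights: np.ndarray
    q: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.weights.shape != (self.q, len(self.edges)):
            raise ValueError("ensemble weight array has wrong shape")
        defined = self.weights[~np.isnan(self.weights)]
        if defined.size and (defined.min() < 0.25 - 1e-12 or defined.max() > 1 + 1e-12):
            raise ValueError("permutation weights outside [0.25, 1]")


def permute_labels(
    partition: CellStatePartition,
    cell_ids: list[str],
    q: int,
    seed: int,
) -> np.ndarray:
    """Draw q uniform label permutations of the full cell set.

    Returns a boolean array of shape ``(q, n_cells)`` whose rows mark the
    permuted progenitor cells in the order of ``cell_ids``; every row has
    exactly the observed progenitor count, so the global class sizes
    |P| and |O| are preserved. Deterministic given ``seed``.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    base = partition.progenitor_mask(cell_ids)
    rng = np.random.default_rng(seed)
    masks = np.empty((q, base.size), dtype=bool)
    for k in range(q):
        masks[k] = base[rng.permutation(base.size)]
    return masks


def _ji_counts(inter: np.ndarray, size_a: np.ndarray, size_b) -> np.ndarray:
    union = size_a + size_b - inter
    return np.where(union > 0, inter / np.maximum(union, 1), 1.0)


def permutation_weights(
    edge_stats: dict[tuple[str, str], EdgeStatistics],
    perm_masks: np.ndarray,
    cell_ids: list[str],
    *,
    empty_class_policy: str = "omit",
    seed: int | None = None,
) -> PermutationEnsemble:
    """Evaluate every edge's weight under every label permutation.

    The observed splits {L_e, R_e} are held fixed; each global
    permutation is restricted to the edge's cell subset before the
    Jaccard terms are formed, mirroring how the observed weight was
    computed.
    """
    if empty_class_policy not in ("omit", "conservative"):
        raise ValueError(f"unknown empty_class_policy '{empty_class_policy}'")
    edges = list(edge_stats)
    q = perm_masks.shape[0]
    cell_index = {c: i for i, c in enumerate(cell_ids)}
    weights = np.full((q, len(edges)), np.nan)

    for e_col, edge in enumerate(edges):
        st = edge_stats[edge]
        left_idx = np.fromiter((cell_index[c] for c in st.left_cells),
                               dtype=int, count=len(st.left_cells))
        right_idx = np.fromiter((cell_index[c] for c in st.right_cells),
                                dtype=int, count=len(st.right_cells))
        n_l, n_r = left_idx.size, right_idx.size
        m = n_l + n_r
        p_left = perm_masks[:, left_idx].sum(axis=1) if n_l else np.zeros(q)
        p_right = perm_masks[:, right_idx].sum(axis=1) if n_r else np.zeros(q)
        n_p = p_left + p_right
        n_o = m - n_p
        o_left, o_right = n_l - p_left, n_r - p_right
        direct = _ji_counts(p_left, n_p, n_l) + _ji_counts(o_right, n_o, n_r)
        crossed = _ji_counts(p_right, n_p, n_r) + _ji_counts(o_left, n_o, n_l)
        w = np.maximum(direct, crossed) / 2.0
        defined = (n_p > 0) & (n_o > 0)
        if not defined.any():
            raise ValueError(
                f"edge {edge}: no permutation leaves both states represented "
                "in its cell subset (pathological subset)")
        weights[defined, e_col] = w[defined]
        if empty_class_policy == "conservative":
            weights[~defined, e_col] = 1.0

    all_undefined = np.all(np.isnan(weights), axis=1)
    if all_undefined.any():
        warnings.warn(f"{int(all_undefined.sum())} permutation(s) with no defined "
                      "edge weight; they contribute no maximum")
    with np.errstate(all="ignore"):
        max_w = np.where(all_undefined, -np.inf,
                         np.nanmax(np.where(np.isnan(weights), -np.inf, weights), axis=1))
    return PermutationEnsemble(edges=edges, weights=weights, max_weights=max_w,
                               q=q, seed=seed)


def adjusted_pvalues(
    weights: dict[tuple[str, str], float],
    ensemble: PermutationEnsemble,
) -> dict[tuple[str, str], float]:
    """Single-step max-T adjusted P-values.

    ``P_e`` is the fraction of permutations whose maximum weight reaches
    the observed ``w_e``; larger weights never receive larger P-values.
    A P-value of exactly 0 (observed weight above every permutation
    maximum) is stored as such — flooring is left to the scoring step.
    """
    missing = set(weights) - set(ensemble.edges)
    if missing:
        raise ValueError(f"ensemble does not cover edges {sorted(missing)[:5]}")
    return {
        e: float(np.mean(ensemble.max_weights >= weights[e])) for e in weights
    }


def prune(
    grn: BaselineGRN,
    edge_stats: dict[tuple[str, str], EdgeStatistics],
    pvalues: dict[tuple[str, str], float],
    alpha: float = 0.05,
) -> TransitionGRN:
    """Retain the edges with adjusted P-value <= alpha (inclusive).

    Edge order follows the baseline GRN. An empty result is valid (the
    transition carries no significant edge at this alpha) and triggers a
    warning rather than an error.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    retained: list[EdgeStatistics] = []
    for edge in grn.edges:
        if edge not in edge_stats or edge not in pvalues:
            continue
        st = edge_stats[edge]
        st.p_adjusted = pvalues[edge]
        if st.p_adjusted <= alpha:
            retained.append(st)
    if not retained:
        warnings.warn(f"no edge passed the FWER threshold alpha={alpha}; "
                      "transition GRN is empty")
    return TransitionGRN(edges=retained, alpha=alpha)
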