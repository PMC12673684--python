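"""Driver-TF ranking in the transition GRN.

Two centralities are offered. PageRank is computed on the *edge-reversed*,
unweighted transition GRN, so regulatory importance flows from targets
back to the TFs that control them; the resulting vector is a probability
distribution over all nodes, which is then restricted to TFs. The
alternative is the weighted outdegree: each retained edge gets a score

    s_e = -log10(max(P_e, 1/q)) * w_e

combining its weight and adjusted P-value (floored at the permutation
resolution 1/q so a P of exactly 0 stays finite), and a TF's value is the
sum of its outgoing edge scores. Both rankings list only TFs with at
least one outgoing edge in the transition GRN, descending, with
lexicographic tie-breaks.
"""

from __future__ import annotations

import math
import warnings

import networkx as nx

from .data import TransitionGRN

__all__ = ["edge_score", "pagerank_ranking", "outdegree_ranking", "rank_tfs"]


def edge_score(weight: float, p_adjusted: float, q: int) -> float:
    """Score of a single retained edge: ``-log10(max(P, 1/q)) * w``."""
    if q <= 0:
        raise ValueError("q (number of permutations) must be positive")
    if not 0 <= p_adjusted <= 1:
        raise ValueError(f"p_adjusted {p_adjusted} outside [0, 1]")
    if not 0.25 - 1e-12 <= weight <= 1 + 1e-12:
        raise ValueError(f"weight {weight} outside [0.25, 1]")
    return -math.log10(max(p_adjusted, 1.0 / q)) * weight


def _sorted_entries(values: dict[str, float]) -> list[tuple[str, float]]:
    return sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))


def pagerank_ranking(grn: TransitionGRN, damping: float = 0.85) -> list[tuple[str, float]]:
    """Unweighted PageRank on the edge-reversed transition GRN.

    The PageRank vector is normalized over *all* nodes of the transition
    GRN before being restricted to TFs, so reported values are a
    sub-distribution. Dangling-node mass is redistributed uniformly
    (networkx default). Empty GRN yields an empty ranking with a warning.
    """
    if not grn.edges:
        warnings.warn("transition GRN is empty; PageRank ranking is empty")
        return []
    reversed_graph = nx.DiGraph()
    reversed_graph.add_nodes_from(grn.nodes)
    reversed_graph.add_edges_from((tg, tf) for tf, tg in grn.edge_list())
    pr = nx.pagerank(reversed_graph, alpha=damping)
    return _sorted_entries({tf: pr[tf] for tf in grn.tfs})


def outdegree_ranking(grn: TransitionGRN, q: int = 1000) -> list[tuple[str, float]]:
    """Score-weighted outdegree ranking.

    Fills in each edge's ``score`` (via :func:`edge_score`) if not already
    set, then sums scores over each TF's outgoing edges.
    """
    if not grn.edges:
        warnings.warn("transition GRN is empty; outdegree ranking is empty")
        return []
    totals: dict[str, float] = {}
    for st in grn.edges:
        if st.score is None:
            st.score = edge_score(st.weight, st.p_adjusted, q)
        totals[st.edge[0]] = totals.get(st.edge[0], 0.0) + st.score
    return _sorted_entries(totals)


def rank_tfs(
    grn: TransitionGRN,
    mode: str = "pagerank",
    *,
    damping: float = 0.85,
    q: int = 1000,
) -> TransitionGRN:
    """Attach the requested ranking(s) to the transition GRN in place.

    ``mode`` is ``"pagerank"``, ``"outdegree"`` or ``"both"``. Edge scores
    are always computed so the written edge table is complete.
    """
    for st in grn.edges:
        st.score = edge_score(st.weight, st.p_adjusted, q)
    if mode in ("pagerank", "both"):
        grn.rankings["pagerank"] = pagerank_ranking(grn, damping=damping)
    if mode in ("outdegree", "both"):
        grn.rankings["outdegree"] = outdegree_ranking(grn, q=q)
    if mode not in ("pagerank", "outdegree", "both"):
        raise ValueError(f"unknown ranking mode '{mode}'")
    return grn
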