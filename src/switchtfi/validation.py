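"""Network-level validation statistics.

A biologically meaningful transition GRN should not be an arbitrary
scatter of edges: its edges are expected to cluster around a few driver
TFs, making the subnetwork unusually well connected. Connectivity is
summarized by the score

    CS = sum_r (|C_r| / |V|)^2

over the weakly connected components C_r — equal to 1 for a connected
graph and 1/m for m equally sized fragments — and compared against random
edge-induced subnetworks of the baseline GRN of the same edge count via a
pseudocount-corrected empirical P-value. The average pairwise Jaccard
index over set collections serves robustness analyses (stability of node
sets, edge sets, or top-k TF lists across repeated runs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .data import BaselineGRN, TransitionGRN

__all__ = [
    "ConnectivityResult",
    "connectivity_score",
    "sample_random_subnetwork",
    "connectivity_test",
    "pairwise_jaccard_similarity",
]


@dataclass
class ConnectivityResult:
    """Observed connectivity score, its null distribution and P-value."""

    score_observed: float
    null_scores: list[float]
    p_empirical: float

    def __post_init__(self) -> None:
        q = len(self.null_scores)
        if not (1.0 / (q + 1) - 1e-12 <= self.p_empirical <= 1 + 1e-12):
            raise ValueError("empirical P outside [1/(q+1), 1]")


def connectivity_score(edges: Iterable[tuple[str, str]]) -> float:
    """Sum of squared component-size fractions (weak connectivity).

    Directed edges are treated as undirected for component finding, per
    the weakly-connected convention. The node set is the union of edge
    endpoints; the score lies in (0, 1], reaching 1 exactly when the
    graph is connected.
    """
    g = nx.DiGraph()
    g.add_edges_from(edges)
    if g.number_of_nodes() == 0:
        raise ValueError("connectivity score undefined for an empty graph")
    n = g.number_of_nodes()
    return float(sum((len(c) / n) ** 2 for c in nx.weakly_connected_components(g)))


def sample_random_subnetwork(
    grn: BaselineGRN, n_edges: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Edge-induced subgraph on ``n_edges`` edges drawn uniformly without replacement."""
    if n_edges > len(grn):
        raise ValueError(f"cannot sample {n_edges} edges from a GRN with {len(grn)}")
    if n_edges < 1:
        raise ValueError("n_edges must be >= 1")
    idx = rng.choice(len(grn), size=n_edges, replace=False)
    return [grn.edges[i] for i in idx]


def connectivity_test(
    grn: BaselineGRN,
    tgrn: TransitionGRN,
    q: int = 1000,
    seed: int = 0,
) -> ConnectivityResult:
    """Empirical connectivity P-value of the transition GRN.

    q random edge-induced subnetworks of the baseline GRN with
    ``|E^T|`` edges each form the null;

        P = (1 + #{ CS^(k) >= CS^T }) / (q + 1)

    with the +1 pseudocount, so P is never 0.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    if not tgrn.edges:
        raise ValueError("connectivity test undefined for an empty transition GRN")
    observed = connectivity_score(tgrn.edge_list())
    rng = np.random.default_rng(seed)
    null = [
        connectivity_score(sample_random_subnetwork(grn, len(tgrn), rng))
        for _ in range(q)
    ]
    p = (1 + sum(cs >= observed for cs in null)) / (q + 1)
    return ConnectivityResult(score_observed=observed, null_scores=null, p_empirical=p)


def pairwise_jaccard_similarity(sets: Sequence[set]) -> float:
    """Average Jaccard index over all unordered pairs of sets.

    Used to quantify robustness of repeated runs: identical collections
    score 1, pairwise disjoint nonempty collections score 0. A pair of
    empty sets has Jaccard index 1 (flagged with a warning).
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    sets = [set(s) for s in sets]
    if any(not a and not b for i, a in enumerate(sets) for b in sets[i + 1:]):
        warnings.warn("pair of empty sets encountered; their Jaccard index is 1")
    total, n_pairs = 0.0, 0
    for i, a in enumerate(sets):
        for b in sets[i + 1:]:
            union = len(a | b)
            total += 1.0 if union == 0 else len(a & b) / union
            n_pairs += 1
    return total / n_pairs
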