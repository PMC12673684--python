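"""Minimal static regulon plot (best-effort extra, not a tested surface).

Draws a TF with its transition-GRN targets arranged on a circle, edge
shade proportional to the edge score s_e.
"""

from __future__ import annotations

import numpy as np

from .data import TransitionGRN

__all__ = ["plot_regulon"]


def plot_regulon(grn: TransitionGRN, tf: str, ax=None):
    """Plot one TF's scored edges to its transition-GRN targets."""
    import matplotlib.pyplot as plt

    edges = [st for st in grn.edges if st.edge[0] == tf]
    if not edges:
        raise ValueError(f"TF '{tf}' has no outgoing edges in the transition GRN")
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    scores = np.array([st.score if st.score is not None else 0.0 for st in edges])
    smax = scores.max() if scores.max() > 0 else 1.0
    angles = np.linspace(0, 2 * np.pi, len(edges), endpoint=False)
    for st, score, ang in zip(edges, scores, angles):
        x, y = np.cos(ang), np.sin(ang)
        shade = 0.85 * (1 - score / smax)
        ax.plot([0, x], [0, y], color=(shade, shade, shade), lw=1 + 2 * score / smax)
        ax.annotate(st.edge[1], (x, y), ha="center", va="center", fontsize=8,
                    bbox=dict(boxstyle="round", fc="white", ec="gray"))
    ax.annotate(tf, (0, 0), ha="center", va="center", fontsize=10,
                bbox=dict(boxstyle="round", fc="lightsteelblue", ec="black"))
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
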