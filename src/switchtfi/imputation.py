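"""Diffusion-based dropout imputation on a cell-similarity graph.

Single-cell counts are sparse: lowly sequenced transcripts drop out, so a
TF and its target are often not observed together even when co-expressed.
Before edge weights are fit, expression is smoothed over a
similarity-weighted k-nearest-neighbor graph of the cells: an adaptive
Gaussian-like kernel is built on (optionally PCA-reduced) expression
space, symmetrized, row-normalized into a Markov matrix ``M``, and the
matrix ``M^t X`` replaces ``X``.

The diffusion depth defaults to ``t = 1``, the most conservative choice:
each imputed value is a convex combination of the gene's expression over
the cell's immediate neighborhood, and a zero survives imputation exactly
when the gene is unexpressed across that whole neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .data import ExpressionMatrix

__all__ = ["DiffusionOperator", "build_diffusion_operator", "impute"]


@dataclass
class DiffusionOperator:
    """Row-stochastic cell-by-cell Markov matrix with its kernel settings.

    ``markov[c, c']`` is positive only when ``c'`` lies in the symmetrized
    k-nearest-neighbor set of ``c``; every row sums to 1.
    """

    markov: sp.csr_matrix
    t: int
    k: int
    ka: int
    decay: float

    def __post_init__(self) -> None:
        sums = np.asarray(self.markov.sum(axis=1)).ravel()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("diffusion operator rows must sum to 1")
        if self.markov.nnz and self.markov.data.min() < 0:
            raise ValueError("diffusion operator entries must be nonnegative")
        if self.t < 0:
            raise ValueError("diffusion depth t must be >= 0")


def build_diffusion_operator(
    matrix: ExpressionMatrix,
    *,
    k: int | None = None,
    ka: int = 4,
    decay: float = 2.0,
    n_pca: int | None = 20,
    t: int = 1,
    seed: int = 0,
) -> DiffusionOperator:
    """Build the row-stochastic diffusion operator for a cell population.

    Pipeline: optional PCA to ``n_pca`` dimensions (skipped when the gene
    count is below 50), Euclidean kNN graph, adaptive kernel
    ``exp(-(d / sigma_c)^decay)`` with ``sigma_c`` the distance from cell
    ``c`` to its ``ka``-th neighbor, symmetrization ``(A + A^T)/2``, and
    row normalization. When ``k`` is ``None`` the default 15 is used,
    reduced automatically to ``|cells| // 2`` on tiny inputs; an explicit
    ``k`` must satisfy ``k < |cells|`` and is used as given (``ka`` is
    capped at ``k`` either way). Duplicate cells at zero distance receive
    kernel value 1.

    ``seed`` fixes the PCA initialization; the kNN/kernel path is
    deterministic.
    """
    n = matrix.n_cells
    if n < 2:
        raise ValueError("need at least 2 cells to build a diffusion operator")
    if k is None:
        k_eff = min(15, max(1, n // 2))
    else:
        if k >= n:
            raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
        k_eff = k
    ka_eff = min(ka, k_eff)

    data = matrix.values
    if n_pca is not None and matrix.n_genes >= 50:
        n_comp = min(n_pca, n - 1, matrix.n_genes)
        data = PCA(n_components=n_comp, random_state=seed).fit_transform(data)

    # k_eff + 1 neighbors so the query point's own zero-distance hit is included
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(data)
    dist, idx = nn.kneighbors(data)

    sigma = dist[:, ka_eff].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(sigma[:, None] > 0, dist / sigma[:, None], np.inf)
    kernel = np.exp(-(scaled ** decay))
    kernel[dist == 0] = 1.0  # self and exact duplicates

    rows = np.repeat(np.arange(n), k_eff + 1)
    affinity = sp.csr_matrix((kernel.ravel(), (rows, idx.ravel())), shape=(n, n))
    affinity = (affinity + affinity.T) / 2.0

    inv_rowsum = 1.0 / np.asarray(affinity.sum(axis=1)).ravel()
    markov = sp.diags(inv_rowsum) @ affinity
    return DiffusionOperator(markov.tocsr(), t=t, k=k_eff, ka=ka_eff, decay=decay)


def impute(matrix: ExpressionMatrix, op: DiffusionOperator) -> ExpressionMatrix:
    """Apply ``t`` steps of diffusion: returns ``M^t X`` as a new matrix.

    With ``t = 0`` the input is returned unchanged (as a copy). Imputed
    values are convex combinations of observed values, hence stay within
    the observed per-gene range, and exact zeros persist wherever a gene
    is zero across the full support of a cell's Markov row.
    """
    if op.markov.shape[0] != matrix.n_cells:
        raise ValueError(
            f"operator built for {op.markov.shape[0]} cells, matrix has {matrix.n_cells}")
    values = matrix.values.copy()
    for _ in range(op.t):
        values = op.markov @ values
    return ExpressionMatrix(values, list(matrix.cell_ids), list(matrix.gene_ids))
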