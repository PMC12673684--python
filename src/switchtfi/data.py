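"""Core domain types and file I/O.

The pipeline operates on three inputs: a cells-by-genes expression matrix,
a directed baseline gene regulatory network (GRN) given as a TF -> target
edge list, and a per-cell annotation assigning each cell to one of two
consecutive differentiation states ("progenitor" and "offspring").

Supported on-disk formats:

* expression matrix: dense CSV/TSV (header row = gene names, first column =
  cell names) or MatrixMarket coordinate (``.mtx``) with newline-delimited
  sidecar files for gene and cell names;
* GRN: TSV edge list with named ``tf`` and ``target`` columns, extra columns
  preserved as metadata;
* labels: TSV with ``cell`` and ``state`` columns.

All tabular output is TSV with fixed column order and 6 significant digits,
so runs diff deterministically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "BaselineGRN",
    "CellStatePartition",
    "EdgeStatistics",
    "TransitionGRN",
    "InputValidationError",
    "read_expression_matrix",
    "read_grn",
    "read_labels",
    "write_transition_grn",
    "read_transition_edge_table",
]

#: format string used for every floating-point value written to disk
_FLOAT_FMT = "%.6g"


class InputValidationError(ValueError):
    """Raised when an input file violates the data contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A cells-by-genes matrix of nonnegative expression values.

    Values may be raw counts or continuous imputed values; the pipeline
    does not distinguish, it only requires nonnegativity.

    Parameters
    ----------
    values
        Array of shape ``(n_cells, n_genes)``, all entries >= 0.
    cell_ids, gene_ids
        Unique, ordered names matching the array dimensions.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise InputValidationError("expression values must be a 2-D array")
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids) or n_genes != len(self.gene_ids):
            raise InputValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cell names / {len(self.gene_ids)} gene names"
            )
        for kind, names in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            if len(set(names)) != len(names):
                dupes = sorted({n for n in names if names.count(n) > 1})
                raise InputValidationError(f"duplicate {kind} names: {dupes[:5]}")
        if np.any(self.values < 0):
            c, g = np.argwhere(self.values < 0)[0]
            raise InputValidationError(
                f"negative expression value {self.values[c, g]} at "
                f"cell '{self.cell_ids[c]}', gene '{self.gene_ids[g]}'"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_column(self, gene: str) -> np.ndarray:
        """Expression vector of one gene over all cells."""
        try:
            return self.values[:, self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"gene '{gene}' not in matrix") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_index

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


@dataclass
class BaselineGRN:
    """Directed TF -> target edge list with optional pass-through metadata.

    ``metadata`` (one row per edge, aligned with ``edges``) carries any
    extra columns of the source file, e.g. inference weights from a
    SCENIC-style tool; they are never used in computation.
    """

    edges: list[tuple[str, str]]
    metadata: pd.DataFrame | None = None
    self_loops: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(set(self.edges)) != len(self.edges):
            raise InputValidationError("BaselineGRN edges must be unique")
        self.self_loops = {e for e in self.edges if e[0] == e[1]}
        if self.self_loops:
            logger.warning("GRN contains %d self-loop(s): %s",
                           len(self.self_loops), sorted(self.self_loops)[:5])

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def tfs(self) -> set[str]:
        """Nodes with at least one outgoing edge (structural TF definition)."""
        return {tf for tf, _ in self.edges}

    @property
    def nodes(self) -> set[str]:
        return {g for e in self.edges for g in e}

    def restrict_to_genes(
        self, genes: Iterable[str]
    ) -> tuple["BaselineGRN", list[tuple[str, str]]]:
        """Drop edges with an endpoint absent from ``genes``.

        Returns the restricted GRN and the list of dropped edges, so
        ``len(kept) + len(dropped) == len(self)`` always holds.
        """
        genes = set(genes)
        kept_idx = [i for i, (tf, tg) in enumerate(self.edges)
                    if tf in genes and tg in genes]
        dropped = [e for i, e in enumerate(self.edges) if i not in set(kept_idx)]
        if dropped:
            logger.warning(
                "dropped %d GRN edge(s) with endpoints absent from the "
                "expression matrix (first few: %s)", len(dropped), dropped[:5])
        meta = self.metadata.iloc[kept_idx].reset_index(drop=True) \
            if self.metadata is not None else None
        return BaselineGRN([self.edges[i] for i in kept_idx], meta), dropped


@dataclass
class CellStatePartition:
    """Bipartition of the cell set into progenitor and offspring cells.

    Both classes must be nonempty: the weight's range guarantee rests on
    the Jaccard terms being defined for P and O.
    """

    labels: dict[str, str]
    progenitor_token: str = "progenitor"
    offspring_token: str = "offspring"

    def __post_init__(self) -> None:
        tokens = {self.progenitor_token, self.offspring_token}
        bad = {s for s in self.labels.values() if s not in tokens}
        if bad:
            raise InputValidationError(f"unknown state token(s): {sorted(bad)}")
        if not self.progenitors:
            raise InputValidationError("progenitor class empty")
        if not self.offspring:
            raise InputValidationError("offspring class empty")

    @property
    def progenitors(self) -> set[str]:
        return {c for c, s in self.labels.items() if s == self.progenitor_token}

    @property
    def offspring(self) -> set[str]:
        return {c for c, s in self.labels.items() if s == self.offspring_token}

    def progenitor_mask(self, cell_ids: Sequence[str]) -> np.ndarray:
        """Boolean vector over ``cell_ids``: True where cell is progenitor."""
        missing = [c for c in cell_ids if c not in self.labels]
        if missing:
            raise InputValidationError(
                f"{len(missing)} cell(s) without state label, e.g. '{missing[0]}'")
        return np.array(
            [self.labels[c] == self.progenitor_token for c in cell_ids], dtype=bool)


@dataclass
class EdgeStatistics:
    """Per-edge record produced by weight fitting and significance testing.

    ``left_cells`` / ``right_cells`` partition the co-expressing cell subset
    by the fitted stump boundary (TF expression <= boundary goes left).
    ``p_adjusted`` and ``score`` stay ``None`` until the corresponding
    pipeline stages run.
    """

    edge: tuple[str, str]
    n_cells_used: int
    coexpression_fraction: float
    boundary: float
    left_cells: frozenset[str]
    right_cells: frozenset[str]
    weight: float
    p_adjusted: float | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.left_cells & self.right_cells:
            raise ValueError("left and right cell sets must be disjoint")
        if len(self.left_cells) + len(self.right_cells) != self.n_cells_used:
            raise ValueError("left/right sets must cover the cells used")
        if not (0.25 - 1e-12 <= self.weight <= 1 + 1e-12):
            raise ValueError(f"weight {self.weight} outside [0.25, 1]")


@dataclass
class TransitionGRN:
    """Edge-induced subnetwork of the baseline GRN after FWER pruning.

    Retains exactly the edges with adjusted P-value <= ``alpha``; the node
    set is the union of retained-edge endpoints. ``rankings`` maps a
    centrality mode ('pagerank' / 'outdegree') to a descending list of
    ``(tf, value)`` pairs.
    """

    edges: list[EdgeStatistics]
    alpha: float
    rankings: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for st in self.edges:
            if st.p_adjusted is None or st.p_adjusted > self.alpha + 1e-12:
                raise ValueError(
                    f"edge {st.edge} with P={st.p_adjusted} violates alpha={self.alpha}")

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def nodes(self) -> set[str]:
        return {g for st in self.edges for g in st.edge}

    @property
    def tfs(self) -> set[str]:
        return {st.edge[0] for st in self.edges}

    def edge_list(self) -> list[tuple[str, str]]:
        return [st.edge for st in self.edges]

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for st in self.edges:
            g.add_edge(*st.edge, weight=st.weight,
                       p_adjusted=st.p_adjusted,
                       score=st.score if st.score is not None else float("nan"))
        return g


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_name_file(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_expression_matrix(
    path: str | Path,
    format: str = "dense_csv",
    *,
    orientation: str = "cells_by_genes",
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    sep: str | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    Parameters
    ----------
    format
        ``"dense_csv"`` (header = column names, first column = row names;
        separator inferred from the extension unless ``sep`` is given) or
        ``"mtx_triplet"`` (MatrixMarket coordinate file, with the row and
        column names in newline-delimited sidecars ``cells_path`` /
        ``genes_path``).
    orientation
        ``"cells_by_genes"`` (default) or ``"genes_by_cells"``; the matrix
        is transposed to cells-as-rows on read.
    """
    path = Path(path)
    if not path.exists():
        raise InputValidationError(f"expression matrix file not found: {path}")
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise InputValidationError(f"unknown orientation '{orientation}'")

    if format == "dense_csv":
        if sep is None:
            sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        rows, cols = list(df.index.astype(str)), list(df.columns.astype(str))
    elif format == "mtx_triplet":
        if genes_path is None or cells_path is None:
            raise InputValidationError(
                "mtx_triplet format requires genes_path and cells_path sidecars")
        values = np.asarray(mmread(path).todense(), dtype=float)
        if orientation == "cells_by_genes":
            rows, cols = _read_name_file(Path(cells_path)), _read_name_file(Path(genes_path))
        else:
            rows, cols = _read_name_file(Path(genes_path)), _read_name_file(Path(cells_path))
    else:
        raise InputValidationError(f"unknown matrix format '{format}'")

    if orientation == "genes_by_cells":
        values, rows, cols = values.T, cols, rows
    return ExpressionMatrix(values, rows, cols)


def read_grn(path: str | Path, *, sep: str = "\t") -> BaselineGRN:
    """Read a TF -> target edge list (TSV with ``tf`` and ``target`` columns).

    Duplicate (tf, target) rows are dropped, keeping the first occurrence;
    extra columns ride along as metadata.
    """
    path = Path(path)
    if not path.exists():
        raise InputValidationError(f"GRN file not found: {path}")
    df = pd.read_csv(path, sep=sep)
    missing = {"tf", "target"} - set(df.columns)
    if missing:
        raise InputValidationError(
            f"GRN file lacks required column(s) {sorted(missing)}; found {list(df.columns)}")
    if df.empty:
        raise InputValidationError(f"GRN file {path} contains no edges")
    df["tf"] = df["tf"].astype(str)
    df["target"] = df["target"].astype(str)
    dup_mask = df.duplicated(subset=["tf", "target"], keep="first")
    if dup_mask.any():
        logger.warning("GRN file contains %d duplicate edge row(s); keeping first occurrence",
                       int(dup_mask.sum()))
    df = df.loc[~dup_mask].reset_index(drop=True)
    edges = list(zip(df["tf"], df["target"]))
    extra = df.drop(columns=["tf", "target"])
    return BaselineGRN(edges, metadata=extra if extra.shape[1] else None)


def read_labels(
    path: str | Path,
    matrix: ExpressionMatrix | None = None,
    *,
    progenitor_token: str = "progenitor",
    offspring_token: str = "offspring",
    sep: str = "\t",
) -> CellStatePartition:
    """Read per-cell state labels (TSV with ``cell`` and ``state`` columns).

    If ``matrix`` is given, every matrix cell must be labeled.
    """
    path = Path(path)
    if not path.exists():
        raise InputValidationError(f"labels file not found: {path}")
    df = pd.read_csv(path, sep=sep)
    missing = {"cell", "state"} - set(df.columns)
    if missing:
        raise InputValidationError(f"labels file lacks required column(s) {sorted(missing)}")
    labels = {str(c): str(s) for c, s in zip(df["cell"], df["state"])}
    if matrix is not None:
        unlabeled = [c for c in matrix.cell_ids if c not in labels]
        if unlabeled:
            raise InputValidationError(
                f"{len(unlabeled)} matrix cell(s) missing from labels file, "
                f"e.g. '{unlabeled[0]}'")
        labels = {c: labels[c] for c in matrix.cell_ids}
    try:
        return CellStatePartition(labels, progenitor_token, offspring_token)
    except InputValidationError as err:
        raise InputValidationError(f"invalid labeling in {path}: {err}") from None


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

EDGE_TABLE_COLUMNS = ["tf", "target", "n_cells_used", "coexpression_fraction",
                      "boundary", "weight", "p_adjusted", "score"]


def _edge_table(edges: Iterable[EdgeStatistics]) -> pd.DataFrame:
    rows = [
        {
            "tf": st.edge[0],
            "target": st.edge[1],
            "n_cells_used": st.n_cells_used,
            "coexpression_fraction": st.coexpression_fraction,
            "boundary": st.boundary,
            "weight": st.weight,
            "p_adjusted": st.p_adjusted,
            "score": st.score,
        }
        for st in edges
    ]
    return pd.DataFrame(rows, columns=EDGE_TABLE_COLUMNS)


def write_transition_grn(grn: TransitionGRN, out_dir: str | Path) -> dict[str, Path]:
    """Write the transition GRN to ``out_dir``.

    Produces ``edges.tsv`` (one row per retained edge), one
    ``ranked_tfs_<mode>.tsv`` per ranking mode, and
    ``transition_grn.graphml`` with weight / p_adjusted / score as edge
    attributes. Returns the paths written, keyed by artifact name.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise InputValidationError(f"cannot create output directory {out_dir}: {err}")
    if not out_dir.is_dir():
        raise InputValidationError(f"not a directory: {out_dir}")

    written: dict[str, Path] = {}
    edge_path = out_dir / "edges.tsv"
    _edge_table(grn.edges).to_csv(edge_path, sep="\t", index=False,
                                  float_format=_FLOAT_FMT)
    written["edges"] = edge_path

    for mode, entries in grn.rankings.items():
        df = pd.DataFrame(entries, columns=["tf", "centrality"])
        df.insert(2, "rank", np.arange(1, len(df) + 1))
        p = out_dir / f"ranked_tfs_{mode}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
        written[f"ranking_{mode}"] = p

    gml_path = out_dir / "transition_grn.graphml"
    nx.write_graphml(grn.to_digraph(), gml_path)
    written["graphml"] = gml_path

    if not grn.edges:
        warnings.warn("transition GRN is empty; edge table has header only")
    return written


def read_transition_edge_table(path: str | Path, alpha: float = 1.0) -> TransitionGRN:
    """Re-read an ``edges.tsv`` written by :func:`write_transition_grn`.

    Cell membership sets are not stored in the table, so the reconstructed
    records carry empty left/right sets; weights, P-values and scores
    round-trip at the printed precision.
    """
    df = pd.read_csv(path, sep="\t")
    stats = [
        EdgeStatistics(
            edge=(str(r.tf), str(r.target)),
            n_cells_used=0,
            coexpression_fraction=float(r.coexpression_fraction),
            boundary=float(r.boundary),
            left_cells=frozenset(),
            right_cells=frozenset(),
            weight=float(r.weight),
            p_adjusted=float(r.p_adjusted),
            score=None if pd.isna(r.score) else float(r.score),
        )
        for r in df.itertuples()
    ]
    return TransitionGRN(stats, alpha=alpha)
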