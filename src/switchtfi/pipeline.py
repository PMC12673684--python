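"""End-to-end orchestration: imputation -> weighting -> testing -> ranking.

:func:`fit_transition_grn` is the in-memory entry point used by the test
suite and scripts; :func:`run_fit` / :func:`run_validate` wrap it with
file I/O, logging and output writing for the command-line workflow.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .data import (
    BaselineGRN,
    CellStatePartition,
    ExpressionMatrix,
    TransitionGRN,
    read_expression_matrix,
    read_grn,
    read_labels,
    write_transition_grn,
)
from .imputation import build_diffusion_operator, impute
from .ranking import rank_tfs
from .significance import adjusted_pvalues, permutation_weights, permute_labels, prune
from .validation import ConnectivityResult, connectivity_test
from .weights import weight_all_edges

logger = logging.getLogger(__name__)

__all__ = ["fit_transition_grn", "run_fit", "run_validate"]


def fit_transition_grn(
    matrix: ExpressionMatrix,
    grn: BaselineGRN,
    partition: CellStatePartition,
    *,
    impute_enabled: bool = True,
    t: int = 1,
    k: int | None = None,
    ka: int = 4,
    decay: float = 2.0,
    n_pca: int | None = 20,
    min_coexpression_fraction: float = 0.20,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    empty_class_policy: str = "omit",
    ranking: str = "both",
    damping: float = 0.85,
) -> tuple[TransitionGRN, list[tuple[tuple[str, str], str]]]:
    """Run the full inference on in-memory inputs.

    Returns the pruned, ranked transition GRN and the edge-exclusion
    report. ``seed`` drives both the PCA initialization of the imputation
    stage and the label permutations.
    """
    if impute_enabled:
        op = build_diffusion_operator(
            matrix, k=k, ka=ka, decay=decay, n_pca=n_pca, t=t, seed=seed)
        matrix = impute(matrix, op)
    stats, report = weight_all_edges(
        grn, matrix, partition,
        min_coexpression_fraction=min_coexpression_fraction)
    if not stats:
        logger.warning("no edge survived the exclusion filters; transition GRN empty")
        return TransitionGRN(edges=[], alpha=alpha), report
    masks = permute_labels(partition, matrix.cell_ids, n_permutations, seed)
    ensemble = permutation_weights(
        stats, masks, matrix.cell_ids,
        empty_class_policy=empty_class_policy, seed=seed)
    pvalues = adjusted_pvalues({e: s.weight for e, s in stats.items()}, ensemble)
    tgrn = prune(grn, stats, pvalues, alpha)
    rank_tfs(tgrn, ranking, damping=damping, q=n_permutations)
    return tgrn, report


def _load_inputs(config: RunConfig):
    matrix = read_expression_matrix(
        config.counts, config.matrix_format,
        orientation=config.orientation,
        genes_path=config.genes_path, cells_path=config.cells_path)
    grn = read_grn(config.grn)
    partition = read_labels(
        config.labels, matrix,
        progenitor_token=config.progenitor_token,
        offspring_token=config.offspring_token)
    return matrix, grn, partition


def run_fit(config: RunConfig) -> tuple[TransitionGRN, list[tuple[tuple[str, str], str]]]:
    """File-based fit: read inputs, run the pipeline, write all outputs.

    The output directory receives the edge table, one ranking table per
    mode, the GraphML export, the edge-exclusion report, the resolved
    configuration and a run log with per-stage wall times and edge
    counts.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"switchtfi {__version__}"]

    def stage(name: str):
        t0 = time.perf_counter()

        def done(msg: str) -> None:
            log_lines.append(f"{name}: {msg} ({time.perf_counter() - t0:.2f}s)")

        return done

    done = stage("load")
    matrix, grn, partition = _load_inputs(config)
    done(f"{matrix.n_cells} cells x {matrix.n_genes} genes, {len(grn)} GRN edges")

    done = stage("fit")
    tgrn, report = fit_transition_grn(
        matrix, grn, partition,
        impute_enabled=config.impute.enabled, t=config.impute.t,
        k=config.impute.k, ka=config.impute.ka, decay=config.impute.decay,
        n_pca=config.impute.n_pca,
        min_coexpression_fraction=config.weight.min_coexpression_fraction,
        n_permutations=config.test.n_permutations, alpha=config.test.alpha,
        seed=config.test.seed, empty_class_policy=config.test.empty_class_policy,
        ranking=config.rank.mode, damping=config.rank.damping)
    done(f"{len(grn) - len(report)} edges weighted, {len(report)} excluded, "
         f"{len(tgrn)} retained at alpha={config.test.alpha} "
         f"(seed={config.test.seed}, q={config.test.n_permutations})")

    done = stage("write")
    write_transition_grn(tgrn, out_dir)
    pd.DataFrame(
        [(tf, tg, reason) for (tf, tg), reason in report],
        columns=["tf", "target", "reason"],
    ).to_csv(out_dir / "excluded_edges.tsv", sep="\t", index=False)
    config.to_yaml(out_dir / "resolved_config.yaml")
    done(f"outputs in {out_dir}")

    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return tgrn, report


def run_validate(config: RunConfig, tgrn: TransitionGRN) -> ConnectivityResult:
    """Connectivity test of a fitted transition GRN against the baseline.

    Writes ``null_scores.tsv`` and ``connectivity.json`` into the run's
    output directory.
    """
    if not tgrn.edges:
        raise ValueError("cannot validate an empty transition GRN")
    grn = read_grn(config.grn)
    result = connectivity_test(
        grn, tgrn, q=config.validate.n_samples, seed=config.validate.seed)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"null_connectivity_score": result.null_scores}).to_csv(
        out_dir / "null_scores.tsv", sep="\t", index=False, float_format="%.6g")
    (out_dir / "connectivity.json").write_text(json.dumps(
        {"connectivity_score": result.score_observed,
         "p_empirical": result.p_empirical,
         "n_samples": config.validate.n_samples,
         "seed": config.validate.seed}, indent=2) + "\n")
    return result
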