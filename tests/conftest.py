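"""Shared fixtures: tiny hand-built inputs and one mid-sized synthetic run."""

import numpy as np
import pytest

from switchtfi import (
    BaselineGRN,
    CellStatePartition,
    ExpressionMatrix,
    SyntheticConfig,
    fit_transition_grn,
    generate,
)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4 cells x 3 genes, all positive."""
    values = np.array([
        [1.0, 0.5, 2.0],
        [2.0, 1.0, 1.8],
        [5.0, 4.0, 0.5],
        [6.0, 5.0, 0.2],
    ])
    return ExpressionMatrix(values, ["c1", "c2", "c3", "c4"], ["tfA", "g1", "g2"])


@pytest.fixture
def balanced_partition() -> CellStatePartition:
    return CellStatePartition({
        "c1": "progenitor", "c2": "progenitor",
        "c3": "offspring", "c4": "offspring",
    })


@pytest.fixture
def small_grn() -> BaselineGRN:
    return BaselineGRN([("tfA", "g1"), ("tfA", "g2")])


@pytest.fixture(scope="session")
def separable_run():
    """One separable synthetic dataset fitted end to end (session-cached)."""
    cfg = SyntheticConfig(n_cells=200, effect_size=3.0, dropout_rate=0.0, seed=7)
    matrix, grn, partition, truth = generate(cfg)
    tgrn, report = fit_transition_grn(
        matrix, grn, partition, n_permutations=500, seed=7, ranking="both")
    return {"matrix": matrix, "grn": grn, "partition": partition,
            "truth": truth, "tgrn": tgrn, "report": report}
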