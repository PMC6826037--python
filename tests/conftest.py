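"""Shared synthetic datasets.

All fixtures are generated programmatically with fixed seeds; the heavier
ones are session-scoped so the clustering, marker and annotation tests share
one generation pass.
"""
import numpy as np
import pytest

import mucocensus as mc


@pytest.fixture(scope="session")
def lineage6():
    """Six-type airway tree (basal root)."""
    return mc.airway_lineage(cycling_root=False)


@pytest.fixture(scope="session")
def program6(lineage6):
    return mc.ExpressionProgram.build(lineage6, n_genes=1000, seed=7)


@pytest.fixture(scope="session")
def standard_ds(lineage6, program6):
    """600 cells, 6 planted types, 15 markers/type, fold 8, no hybrids."""
    matrix, truth = mc.generate_counts(
        lineage6, program6, n_cells=600, hybrid_fraction=0.0, seed=11
    )
    return matrix, truth, mc.normalize(matrix)


@pytest.fixture(scope="session")
def hybrid_airway_ds(lineage6, program6):
    """1000 cells with an 8.9% hybrid share on the goblet->MCC transition."""
    matrix, truth = mc.generate_counts(
        lineage6, program6, n_cells=1000, hybrid_fraction=0.089, seed=42
    )
    return matrix, truth, mc.normalize(matrix)


@pytest.fixture(scope="session")
def gc_mcc_ds():
    """Goblet+MCC population, 1000 cells, exactly 89 planted hybrids."""
    lineage = mc.gc_mcc_lineage()
    program = mc.ExpressionProgram.build(lineage, n_genes=1000, seed=7)
    matrix, truth = mc.generate_counts(
        lineage, program, n_cells=1000, hybrid_fraction=0.089,
        exact_hybrid_count=True, seed=42,
    )
    return matrix, truth, mc.normalize(matrix)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def tiny_matrix():
    """4 genes x 5 cells, one mito gene, deterministic raw counts."""
    values = np.array(
        [
            [0, 1, 2, 0, 4],
            [5, 0, 0, 1, 1],
            [0, 0, 3, 3, 0],
            [1, 1, 1, 1, 1],
        ]
    )
    return mc.CountMatrix(
        values,
        gene_ids=np.array(["G1", "G2", "G3", "MT-G4"], dtype=object),
        barcodes=np.array([f"c{i}" for i in range(5)], dtype=object),
    )
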