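import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from tme.datatypes import NormalizedMatrix, RepertoireTable, SparseCounts


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_counts(matrix, conditions=None, mito=None, samples=None) -> SparseCounts:
    """Build a SparseCounts from a dense array with generated names."""
    matrix = np.asarray(matrix)
    n_genes, n_cells = matrix.shape
    genes = pd.Index([f"g{i}" for i in range(n_genes)])
    cells = pd.Index([f"c{j}" for j in range(n_cells)])
    if conditions is None:
        conditions = ["CTRL"] * n_cells
    if mito is None:
        mito = np.zeros(n_genes, bool)
    return SparseCounts(
        matrix=sp.csr_matrix(matrix),
        genes=genes,
        cells=cells,
        cell_conditions=pd.Series(conditions, index=cells),
        mito=np.asarray(mito, bool),
        cell_samples=None if samples is None else pd.Series(samples, index=cells),
    )


def make_norm(matrix, conditions=None, samples=None) -> NormalizedMatrix:
    matrix = np.asarray(matrix, float)
    n_genes, n_cells = matrix.shape
    genes = pd.Index([f"g{i}" for i in range(n_genes)])
    cells = pd.Index([f"c{j}" for j in range(n_cells)])
    return NormalizedMatrix(
        matrix=sp.csr_matrix(matrix),
        genes=genes,
        cells=cells,
        scale_factor=1e4,
        cell_conditions=None if conditions is None else pd.Series(conditions, index=cells),
        cell_samples=None if samples is None else pd.Series(samples, index=cells),
    )


def make_repertoire(counts, sample_id="s", mouse_id="m", timepoint="T0") -> RepertoireTable:
    counts = np.asarray(counts, float)
    templates = np.array([f"CASS{i:03d}F" for i in range(len(counts))], object)
    return RepertoireTable(sample_id, mouse_id, timepoint, templates, counts)
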