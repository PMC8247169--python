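"""Shared fixtures: synthetic datasets generated once per session."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from cbstates.core_io import CountMatrix, lognormalize
from cbstates.synthdata import SimConfig, generate_reference_cells, generate_spots


@pytest.fixture(scope="session")
def ref_default():
    """Default developmental reference: 1,000 cells, 4 states, effect 1.0."""
    cfg = SimConfig(seed=7)
    cm, truth = generate_reference_cells(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def ref_norm(ref_default):
    _, cm, _ = ref_default
    return lognormalize(cm)


@pytest.fixture(scope="session")
def spot_data():
    """Layered spots over a 1,200-cell reference."""
    cfg = SimConfig(n_cells=1200, seed=5)
    cm, truth = generate_reference_cells(cfg)
    spots, truth = generate_spots(cfg, cm, truth)
    return cfg, cm, spots, truth


def tiny_counts(values, cell_prefix="c", gene_prefix="g", gene_names=None):
    """Small dense CountMatrix helper for constructed fixtures."""
    values = np.asarray(values)
    n, g = values.shape
    cells = np.array([f"{cell_prefix}{i}" for i in range(n)], dtype=object)
    genes = (
        np.asarray(gene_names, dtype=object)
        if gene_names is not None
        else np.array([f"{gene_prefix}{j}" for j in range(g)], dtype=object)
    )
    return CountMatrix(sp.csr_matrix(values), cells, genes)
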