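"""Shared fixtures: small hand-built tables and session-scoped simulations."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ontotree import core, synthdata as sd
from ontotree.datatypes import CellTable


def make_table(counts, timepoints=None, **cell_cols) -> CellTable:
    """Build a CellTable from a dense count array with minimal metadata."""
    counts = np.asarray(counts)
    n, g = counts.shape
    if timepoints is None:
        timepoints = np.full(n, 10.0)
    cell_meta = pd.DataFrame(
        {"timepoint": timepoints, **cell_cols},
        index=[f"c{i}" for i in range(n)],
    )
    gene_meta = pd.DataFrame(index=[f"g{j}" for j in range(g)])
    return CellTable(sp.csr_matrix(counts), cell_meta, gene_meta)


@pytest.fixture(scope="session")
def two_type_sim():
    """Small two-type series with bridges and spiked doublets."""
    spec, tps = sd.two_type_lineage(seed=1)
    cfg = sd.SimConfig(
        timepoints=tps, cells_per_timepoint=400, doublet_rate=0.06, seed=1
    )
    table, truth = sd.simulate_atlas(spec, cfg)
    return spec, cfg, table, truth


@pytest.fixture(scope="session")
def tree_sim():
    """The 10-type branching lineage at reduced size for unit tests."""
    spec, tps = sd.default_lineage(seed=0)
    cfg = sd.SimConfig(timepoints=tps, cells_per_timepoint=1200, seed=1)
    table, truth = sd.simulate_atlas(spec, cfg)
    return spec, cfg, table, truth


@pytest.fixture(scope="session")
def tree_candidates(tree_sim):
    from ontotree import graph_builder as gb

    _, _, table, _ = tree_sim
    return gb.build_subsystem_candidates(table, k=15)


@pytest.fixture(scope="session")
def two_type_embedding(two_type_sim):
    _, _, table, _ = two_type_sim
    return core.embed_table(table)
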