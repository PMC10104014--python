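"""Plain-text persistence: MatrixMarket counts + TSV metadata + JSON configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .datatypes import CellTable

__all__ = [
    "write_cell_table",
    "read_cell_table",
    "write_truth",
    "read_truth",
    "write_json",
]

COUNTS = "counts.mtx"
CELLS = "cells.tsv"
GENES = "genes.tsv"
TRUTH = "truth.tsv"


def write_cell_table(table: CellTable, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(out / COUNTS, table.counts.astype(np.int64))
    table.cell_meta.to_csv(out / CELLS, sep="\t", index_label="cell_id")
    table.gene_meta.to_csv(out / GENES, sep="\t", index_label="gene_id")
    return out


def read_cell_table(in_dir) -> CellTable:
    src = Path(in_dir)
    counts = sp.csr_matrix(sio.mmread(src / COUNTS))
    cells = pd.read_csv(src / CELLS, sep="\t", index_col="cell_id")
    genes = pd.read_csv(src / GENES, sep="\t", index_col="gene_id")
    return CellTable(counts, cells, genes)


def write_truth(truth, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.cells.to_csv(out / TRUTH, sep="\t", index_label="cell_id")
    truth.drivers.to_csv(out / "truth_drivers.tsv", sep="\t", index=False)
    return out


def read_truth(in_dir) -> pd.DataFrame:
    return pd.read_csv(Path(in_dir) / TRUTH, sep="\t", index_col="cell_id")


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, frozenset):
            return sorted(o)
        return str(o)

    path.write_text(json.dumps(obj, indent=2, default=default))
    return path
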