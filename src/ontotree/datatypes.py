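"""Shared containers for the pipeline.

The in-memory unit is :class:`CellTable`: a sparse cell-by-gene UMI count
matrix plus per-cell and per-gene metadata frames, convertible to/from
:class:`anndata.AnnData` for interop with the wider single-cell ecosystem.
Derived objects (:class:`Embedding`, :class:`NeighborGraph`,
:class:`MNNPairSet`) carry the provenance needed to make downstream
statistics reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CellTable",
    "Embedding",
    "NeighborGraph",
    "MNNPairSet",
    "GrowthModel",
]

REQUIRED_CELL_COLUMNS = ("timepoint",)


@dataclass
class CellTable:
    """Sparse cell x gene UMI counts with aligned metadata.

    ``cell_meta`` must contain a ``timepoint`` column (embryonic day); common
    optional columns are ``embryo_id``, ``somite_count``, ``type_label``,
    ``ribo_pct``, ``mito_pct`` and ``unmatched_rate``. ``umi_total`` and
    ``gene_count`` are (re)computed from the matrix on construction so that
    they can never drift out of sync with the counts.
    """

    counts: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape[0] != len(self.cell_meta):
            raise ValueError(
                f"counts has {self.counts.shape[0]} rows but cell_meta has "
                f"{len(self.cell_meta)} entries"
            )
        if self.counts.shape[1] != len(self.gene_meta):
            raise ValueError(
                f"counts has {self.counts.shape[1]} columns but gene_meta has "
                f"{len(self.gene_meta)} entries"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        for col in REQUIRED_CELL_COLUMNS:
            if col not in self.cell_meta.columns:
                raise ValueError(f"cell_meta missing required column {col!r}")
        tp = np.asarray(self.cell_meta["timepoint"], dtype=float)
        if tp.size and not np.all(np.isfinite(tp)):
            raise ValueError("timepoint must be finite")
        self.cell_meta = self.cell_meta.copy()
        self.cell_meta["umi_total"] = np.asarray(
            self.counts.sum(axis=1)
        ).ravel()
        self.cell_meta["gene_count"] = np.asarray(
            (self.counts > 0).sum(axis=1)
        ).ravel()

    # -- basic protocol ---------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> np.ndarray:
        return np.asarray(self.cell_meta.index)

    @property
    def gene_ids(self) -> np.ndarray:
        return np.asarray(self.gene_meta.index)

    def subset_cells(self, mask_or_idx) -> "CellTable":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CellTable(
            self.counts[idx],
            self.cell_meta.iloc[idx],
            self.gene_meta,
        )

    def subset_genes(self, mask_or_idx) -> "CellTable":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CellTable(
            self.counts[:, idx],
            self.cell_meta,
            self.gene_meta.iloc[idx],
        )

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        """Positions of ``gene_ids`` in the gene axis; errors name misses."""
        lookup = pd.Index(self.gene_meta.index)
        pos = lookup.get_indexer(list(gene_ids))
        if (pos < 0).any():
            missing = [g for g, p in zip(gene_ids, pos) if p < 0]
            raise KeyError(f"genes not present in table: {missing}")
        return pos

    # -- interop ----------------------------------------------------------
    def to_anndata(self):
        import anndata as ad

        return ad.AnnData(
            X=self.counts.copy(),
            obs=self.cell_meta.copy(),
            var=self.gene_meta.copy(),
        )

    @classmethod
    def from_anndata(cls, adata) -> "CellTable":
        return cls(
            sp.csr_matrix(adata.X),
            adata.obs.copy(),
            adata.var.copy(),
        )


@dataclass
class Embedding:
    """Cells x d coordinates with the provenance needed to reproduce them."""

    coords: np.ndarray
    hvg_list: np.ndarray
    gene_means: np.ndarray
    gene_sds: np.ndarray
    variance_fractions: np.ndarray
    components: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] < 1:
            raise ValueError("coords must be 2-D with d >= 1")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        vf = np.asarray(self.variance_fractions, dtype=float)
        if vf.size > 1 and np.any(np.diff(vf) > 1e-12):
            raise ValueError("variance fractions must be non-increasing")
        self.variance_fractions = vf

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass
class NeighborGraph:
    """Exact Euclidean k-nearest neighbours (self excluded)."""

    indices: np.ndarray  # (n, k) int
    distances: np.ndarray  # (n, k) float, ascending per row
    k: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.indices.shape != self.distances.shape:
            raise ValueError("indices/distances shape mismatch")
        if self.indices.shape[1] != self.k:
            raise ValueError("second dimension must equal k")
        if np.any(np.diff(self.distances, axis=1) < -1e-12):
            raise ValueError("distances must be sorted ascending per row")

    @property
    def n(self) -> int:
        return self.indices.shape[0]

    def adjacency(self) -> sp.csr_matrix:
        """Directed boolean kNN adjacency (row -> its neighbours)."""
        n, k = self.indices.shape
        rows = np.repeat(np.arange(n), k)
        return sp.csr_matrix(
            (np.ones(n * k, dtype=bool), (rows, self.indices.ravel())),
            shape=(n, n),
        )


@dataclass
class MNNPairSet:
    """Unordered mutual-nearest-neighbour cell pairs.

    ``mode`` is ``"global"`` (mutuality judged over all cells) or
    ``"cross-group"`` (kNN searched from group A into group B only, and vice
    versa). Pairs are stored with ``pairs[:, 0] < pairs[:, 1]`` and sorted
    lexicographically so that equal pair sets compare equal.
    """

    pairs: np.ndarray  # (m, 2) int, i < j
    k: int
    mode: str = "global"

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        if pairs.size and np.any(pairs[:, 0] == pairs[:, 1]):
            raise ValueError("self-pairs are not allowed")
        pairs = np.sort(pairs, axis=1)
        if pairs.size:
            order = np.lexsort((pairs[:, 1], pairs[:, 0]))
            pairs = np.unique(pairs[order], axis=0)
        self.pairs = pairs
        if self.mode not in ("global", "cross-group"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def __len__(self) -> int:
        return self.pairs.shape[0]

    def as_set(self) -> set[tuple[int, int]]:
        return {tuple(p) for p in self.pairs}

    def partner_lists(self, n: int) -> list[np.ndarray]:
        """Per-cell array of MNN partners (cells 0..n-1)."""
        adj: list[list[int]] = [[] for _ in range(n)]
        for i, j in self.pairs:
            adj[i].append(j)
            adj[j].append(i)
        return [np.asarray(a, dtype=int) for a in adj]


@dataclass
class GrowthModel:
    """Cubic model of whole-embryo growth: log2(N) = a3 d^3 + a2 d^2 + a1 d + a0."""

    a3: float
    a2: float
    a1: float
    a0: float
    adj_r2: float | None = None
    day_range: tuple[float, float] | None = None

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.a3, self.a2, self.a1, self.a0], dtype=float)

    def log2_cells(self, day) -> np.ndarray | float:
        return np.polyval(self.coefficients, day)
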