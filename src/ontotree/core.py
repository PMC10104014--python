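"""Matrix and graph primitives shared by every pipeline stage.

The conventions here are deliberately rigid so downstream statistics are
bit-reproducible:

* normalization is ``ln(1 + count * scale_target / umi_total)``;
* highly variable genes are ranked with a deterministic tie-break on gene id;
* PCA fixes component signs (largest-magnitude loading positive);
* kNN search is exact Euclidean with ties broken by ascending cell index.
"""

from __future__ import annotations

import random
import warnings
from typing import Sequence

import igraph
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .datatypes import CellTable, Embedding, MNNPairSet, NeighborGraph

__all__ = [
    "normalize_log",
    "select_hvg",
    "scale_genes",
    "pca",
    "embed_table",
    "knn",
    "mnn_pairs",
    "cluster_graph",
    "neighbor_smooth",
]


def normalize_log(table: CellTable, scale_target: float = 1e4) -> sp.csr_matrix:
    """Depth-normalize UMI counts and log-transform.

    Each entry becomes ``ln(1 + count * scale_target / umi_total)``; the
    sparsity pattern is preserved. Cells with zero total are rejected by name.
    """
    totals = np.asarray(table.counts.sum(axis=1), dtype=float).ravel()
    if np.any(totals <= 0):
        bad = table.cell_ids[np.flatnonzero(totals <= 0)]
        raise ValueError(f"cells with zero total UMI count: {list(bad[:10])}")
    out = table.counts.astype(float).tocsr(copy=True)
    row_len = np.diff(out.indptr)
    out.data *= np.repeat(scale_target / totals, row_len)
    np.log1p(out.data, out=out.data)
    return out


def _column_moments(matrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mean and population variance of a (sparse) matrix."""
    n = matrix.shape[0]
    if sp.issparse(matrix):
        mean = np.asarray(matrix.mean(axis=0)).ravel()
        sq = np.asarray(matrix.multiply(matrix).mean(axis=0)).ravel()
    else:
        m = np.asarray(matrix, dtype=float)
        mean = m.mean(axis=0)
        sq = (m**2).mean(axis=0)
    var = np.maximum(sq - mean**2, 0.0)
    return mean, var


def select_hvg(
    norm_matrix,
    n: int,
    flavor: str = "variance",
    gene_ids: Sequence | None = None,
) -> np.ndarray:
    """Top ``n`` highly variable genes of a log-normalized matrix.

    ``flavor="variance"`` ranks genes by the variance of the log-normalized
    values; ``flavor="dispersion"`` ranks by variance/mean of the de-logged
    (linear-scale) values. Constant genes are never selected, and ties are
    broken by ascending gene id for determinism. Returns column positions.
    """
    n_genes = norm_matrix.shape[1]
    if gene_ids is None:
        gene_ids = np.arange(n_genes)
    gene_ids = np.asarray(gene_ids)
    _, var = _column_moments(norm_matrix)
    eligible = var > 0
    if flavor == "variance":
        criterion = var
    elif flavor == "dispersion":
        if sp.issparse(norm_matrix):
            lin = norm_matrix.copy()
            lin.data = np.expm1(lin.data)
        else:
            lin = np.expm1(np.asarray(norm_matrix, dtype=float))
        lmean, lvar = _column_moments(lin)
        with np.errstate(divide="ignore", invalid="ignore"):
            criterion = np.where(lmean > 0, lvar / lmean, 0.0)
        eligible &= lvar > 0
    else:
        raise ValueError(f"unknown flavor {flavor!r}")
    n_avail = int(eligible.sum())
    if n > n_avail:
        raise ValueError(
            f"requested {n} highly variable genes but only {n_avail} genes "
            "have nonzero variance"
        )
    idx = np.flatnonzero(eligible)
    # stable ordering: descending criterion, ties by ascending gene id
    order = np.lexsort((gene_ids[idx], -criterion[idx]))
    return idx[order][:n]


def scale_genes(
    norm_matrix, gene_idx=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center to zero mean / unit variance per gene; returns (X, means, sds).

    Output is dense. Genes with zero variance scale to all-zero columns.
    """
    if gene_idx is not None:
        norm_matrix = norm_matrix[:, np.asarray(gene_idx)]
    X = np.asarray(
        norm_matrix.todense() if sp.issparse(norm_matrix) else norm_matrix,
        dtype=np.float64,
    )
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    safe = np.where(sds > 0, sds, 1.0)
    X = (X - means) / safe
    X[:, sds == 0] = 0.0
    return X, means, sds


def pca(
    scaled_matrix: np.ndarray,
    d: int,
    hvg_list=None,
    gene_means=None,
    gene_sds=None,
) -> Embedding:
    """Project a centered/scaled matrix on its top ``d`` principal axes.

    The sign of each component is fixed by making its largest-magnitude
    loading positive. If ``d`` exceeds the matrix rank the dimensionality is
    reduced with a warning.
    """
    X = np.asarray(scaled_matrix, dtype=float)
    max_d = min(X.shape)
    if d > max_d:
        warnings.warn(
            f"requested d={d} exceeds min(cells, genes)={max_d}; reducing"
        )
        d = max_d
    model = PCA(n_components=d, svd_solver="full" if max(X.shape) < 2000 else
                "randomized", random_state=0)
    coords = model.fit_transform(X)
    rank_mask = model.explained_variance_ > 1e-12
    if not rank_mask.all():
        warnings.warn(
            f"requested d={d} exceeds matrix rank {int(rank_mask.sum())}; "
            "reducing"
        )
        coords = coords[:, rank_mask]
        model.components_ = model.components_[rank_mask]
        model.explained_variance_ratio_ = model.explained_variance_ratio_[
            rank_mask
        ]
    comps = model.components_
    flip = np.sign(comps[np.arange(comps.shape[0]),
                         np.abs(comps).argmax(axis=1)])
    flip[flip == 0] = 1.0
    comps = comps * flip[:, None]
    coords = coords * flip[None, :]
    return Embedding(
        coords=coords,
        hvg_list=np.asarray(hvg_list) if hvg_list is not None else np.arange(
            X.shape[1]),
        gene_means=np.asarray(gene_means) if gene_means is not None else
        np.zeros(X.shape[1]),
        gene_sds=np.asarray(gene_sds) if gene_sds is not None else
        np.ones(X.shape[1]),
        variance_fractions=model.explained_variance_ratio_.copy(),
        components=comps,
    )


def embed_table(
    table: CellTable,
    n_hvg: int = 2500,
    d: int = 30,
    scale_target: float = 1e4,
    flavor: str = "variance",
) -> Embedding:
    """Standard recipe: normalize -> HVG -> scale -> PCA.

    ``n_hvg`` is capped at the number of non-constant genes so the same recipe
    applies to compact synthetic gene spaces.
    """
    norm = normalize_log(table, scale_target)
    _, var = _column_moments(norm)
    n_avail = int((var > 0).sum())
    hvg = select_hvg(norm, min(n_hvg, n_avail), flavor=flavor,
                     gene_ids=table.gene_ids)
    X, means, sds = scale_genes(norm, hvg)
    return pca(X, d, hvg_list=table.gene_ids[hvg], gene_means=means,
               gene_sds=sds)


def _chunked_sq_dists(Q: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances via the Gram trick (caller chunks Q)."""
    sq = (
        (Q**2).sum(axis=1)[:, None]
        + (X**2).sum(axis=1)[None, :]
        - 2.0 * (Q @ X.T)
    )
    np.maximum(sq, 0.0, out=sq)
    return sq


def _knn_search(
    Q: np.ndarray,
    X: np.ndarray,
    k: int,
    exclude_self_offset: int | None = None,
    chunk: int = 1024,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact kNN of query rows Q within reference rows X.

    Ties are broken by ascending reference index. If ``exclude_self_offset``
    is given, query row i is assumed to be reference row i+offset and is
    excluded from its own neighbour list.
    """
    nq, nx = Q.shape[0], X.shape[0]
    idx_out = np.empty((nq, k), dtype=np.int64)
    d_out = np.empty((nq, k), dtype=float)
    for start in range(0, nq, chunk):
        stop = min(start + chunk, nq)
        sq = _chunked_sq_dists(Q[start:stop], X)
        if exclude_self_offset is not None:
            rows = np.arange(start, stop)
            sq[np.arange(stop - start), rows + exclude_self_offset] = np.inf
        if nx <= 4096:
            # full lexsort: exact tie-break even among equal distances
            part = np.broadcast_to(np.arange(nx), sq.shape)
            pd_ = sq
        else:
            # partition with padding so boundary ties keep their lowest-index
            # representative before the final lexsort
            m = min(k + 9, nx)
            part = np.argpartition(sq, m - 1, axis=1)[:, :m]
            pd_ = np.take_along_axis(sq, part, axis=1)
        # lexsort per row: primary distance, secondary reference index
        order = np.lexsort((part, pd_), axis=1)[:, :k]
        idx_out[start:stop] = np.take_along_axis(part, order, axis=1)
        d_out[start:stop] = np.sqrt(np.take_along_axis(pd_, order, axis=1))
    return idx_out, d_out


def _coords_of(embedding) -> np.ndarray:
    if isinstance(embedding, Embedding):
        return embedding.coords
    return np.asarray(embedding, dtype=float)


def knn(embedding, k: int) -> NeighborGraph:
    """Exact Euclidean k-nearest neighbours, self excluded.

    Ties at equal distance are broken by ascending cell index.
    """
    X = _coords_of(embedding)
    n = X.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells {n}")
    idx, dist = _knn_search(X, X, k, exclude_self_offset=0)
    return NeighborGraph(indices=idx, distances=dist, k=k)


def mnn_pairs(
    embedding,
    k: int,
    mode: str = "global",
    group_a=None,
    group_b=None,
) -> MNNPairSet:
    """Mutual-nearest-neighbour cell pairs.

    In ``global`` mode a pair is kept iff each cell lies in the other's kNN
    computed over *all* cells. In ``cross-group`` mode the kNN of each A-cell
    is searched among B-cells only (and vice versa), which is the form used
    for dataset bridging and progenitor mapping.
    """
    X = _coords_of(embedding)
    if mode == "global":
        graph = knn(X, k)
        adj = graph.adjacency()
        mutual = adj.multiply(adj.T).tocoo()
        keep = mutual.row < mutual.col
        pairs = np.column_stack([mutual.row[keep], mutual.col[keep]])
        return MNNPairSet(pairs=pairs, k=k, mode="global")
    if mode != "cross-group":
        raise ValueError(f"unknown mode {mode!r}")
    if group_a is None or group_b is None:
        raise ValueError("cross-group mode requires group_a and group_b")
    ga = np.asarray(group_a)
    gb = np.asarray(group_b)
    if ga.dtype == bool:
        ga = np.flatnonzero(ga)
    if gb.dtype == bool:
        gb = np.flatnonzero(gb)
    if ga.size == 0 or gb.size == 0:
        raise ValueError("cross-group mode requires non-empty groups")
    if np.intersect1d(ga, gb).size:
        raise ValueError("groups must be disjoint in cross-group mode")
    ka = min(k, gb.size)
    kb = min(k, ga.size)
    a_nb, _ = _knn_search(X[ga], X[gb], ka)
    b_nb, _ = _knn_search(X[gb], X[ga], kb)
    a_sets = sp.csr_matrix(
        (np.ones(ga.size * ka, bool),
         (np.repeat(np.arange(ga.size), ka), a_nb.ravel())),
        shape=(ga.size, gb.size),
    )
    b_sets = sp.csr_matrix(
        (np.ones(gb.size * kb, bool),
         (np.repeat(np.arange(gb.size), kb), b_nb.ravel())),
        shape=(gb.size, ga.size),
    )
    mutual = a_sets.multiply(b_sets.T).tocoo()
    pairs = np.column_stack([ga[mutual.row], gb[mutual.col]])
    return MNNPairSet(pairs=pairs, k=k, mode="cross-group")


def _neighbor_igraph(graph: NeighborGraph) -> igraph.Graph:
    adj = graph.adjacency()
    sym = (adj + adj.T).tocoo()
    keep = sym.row < sym.col
    edges = list(zip(sym.row[keep].tolist(), sym.col[keep].tolist()))
    return igraph.Graph(n=graph.n, edges=edges)


def cluster_graph(
    neighbor_graph: NeighborGraph,
    resolution: float = 1.0,
    method: str = "leiden",
    seed: int = 0,
) -> np.ndarray:
    """Community detection on the symmetrized kNN graph.

    ``leiden`` uses the RB-configuration quality function (leidenalg);
    ``louvain`` is igraph's multilevel algorithm with the global RNG seeded
    for determinism. Labels are dense integers starting at 0, renumbered by
    first occurrence.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    g = _neighbor_igraph(neighbor_graph)
    if method == "leiden":
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
        labels = np.asarray(part.membership)
    elif method == "louvain":
        igraph.set_random_number_generator(random.Random(seed))
        part = g.community_multilevel(resolution=resolution)
        igraph.set_random_number_generator(random)
        labels = np.asarray(part.membership)
    else:
        raise ValueError(f"unknown method {method!r}")
    _, dense = np.unique(labels, return_inverse=True)
    first_seen = {}
    out = np.empty_like(dense)
    next_id = 0
    for i, lab in enumerate(dense):
        if lab not in first_seen:
            first_seen[lab] = next_id
            next_id += 1
        out[i] = first_seen[lab]
    return out


def neighbor_smooth(values, coords, k: int | None = None) -> np.ndarray:
    """kNN-average smoothing followed by min-max scaling to [0, 1].

    ``k`` defaults to ``round(ln n)`` (the natural-log rule used for spatial
    voxel probability maps). The point itself counts among its own k nearest
    neighbours. A constant input maps to all zeros by convention.
    """
    v = np.asarray(values, dtype=float).ravel()
    X = np.asarray(coords, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if v.shape[0] != n:
        raise ValueError("values and coords disagree in length")
    if k is None:
        k = max(1, int(round(np.log(n))))
    k = min(k, n)
    nb, _ = _knn_search(X, X, k)  # self included (distance 0)
    smoothed = v[nb].mean(axis=1)
    lo, hi = smoothed.min(), smoothed.max()
    if hi - lo <= 0:
        return np.zeros(n)
    return (smoothed - lo) / (hi - lo)
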