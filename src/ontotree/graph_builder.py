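"""Cell-type graph construction from mutual-nearest-neighbour statistics.

Within a subsystem, cells are embedded (HVG -> scale -> PCA 30) and global
MNN pairs are computed; for every pair of cell-type nodes the inter-node
pair count is normalized to a score ``100 * n_pairs / min(|A|, |B|)`` and
node pairs scoring above 1 become candidate edges. Edges are categorized
(developmental progression / spatial continuity / dataset equivalence) and
oriented — by curation where provided, otherwise from earlier to later
median timepoint of the MNN-participating cells. Dataset bridging co-embeds
two tables after a naive per-dataset centering and links reciprocal-best
node pairs; progenitor mapping sends the earliest cells of each derivative
type into a progenitor pool by cross-group MNN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import embed_table, mnn_pairs, normalize_log, pca, scale_genes, select_hvg, _column_moments
from .datatypes import CellTable, Embedding, MNNPairSet

__all__ = [
    "CellTypeEdge",
    "CandidateEdges",
    "build_subsystem_candidates",
    "categorize_and_orient",
    "edges_to_graph",
    "edge_time_profile",
    "bridge_datasets",
    "map_progenitors",
    "ProgenitorMap",
]

CATEGORIES = (
    "developmental_progression",
    "spatial_continuity",
    "dataset_equivalence",
)


@dataclass
class CellTypeEdge:
    node_a: str
    node_b: str
    n_mnn_pairs: int
    normalized_score: float
    category: str = "developmental_progression"
    orientation: str = "a_to_b"  # a_to_b | b_to_a | bidirectional
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.orientation not in ("a_to_b", "b_to_a", "bidirectional"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.normalized_score < 0:
            raise ValueError("normalized_score must be >= 0")


@dataclass
class CandidateEdges:
    """Scored candidate edges plus the evidence behind them."""

    table: pd.DataFrame  # node_a, node_b, n_pairs, score, score_min_k, ...
    pairs: MNNPairSet
    embedding: Embedding
    edge_cells: dict  # (node_a, node_b) -> array of participating cell idx
    k: int

    def candidates(self, threshold: float = 1.0) -> pd.DataFrame:
        return self.table[self.table["score"] > threshold].reset_index(
            drop=True
        )


def _score_pairs(
    pairs: MNNPairSet,
    labels: np.ndarray,
    times: np.ndarray,
    sizes: dict,
    k: int,
) -> tuple[pd.DataFrame, dict]:
    p = pairs.pairs
    la = labels[p[:, 0]]
    lb = labels[p[:, 1]]
    inter = la != lb
    rows, edge_cells = [], {}
    if inter.any():
        key_a = np.where(la < lb, la, lb)[inter]
        key_b = np.where(la < lb, lb, la)[inter]
        sub = p[inter]
        df = pd.DataFrame({"a": key_a, "b": key_b})
        for (a, b), grp in df.groupby(["a", "b"], sort=True):
            idx = sub[grp.index.to_numpy()]
            cells = np.unique(idx)
            n_pairs = len(grp)
            denom = min(sizes[a], sizes[b])
            a_cells = cells[labels[cells] == a]
            b_cells = cells[labels[cells] == b]
            rows.append(
                {
                    "node_a": a,
                    "node_b": b,
                    "n_pairs": n_pairs,
                    "score": 100.0 * n_pairs / denom,
                    "score_min_k": n_pairs / (denom * k),
                    "n_cells_a": sizes[a],
                    "n_cells_b": sizes[b],
                    "median_time_a": float(np.median(times[a_cells]))
                    if a_cells.size else np.nan,
                    "median_time_b": float(np.median(times[b_cells]))
                    if b_cells.size else np.nan,
                    "node_median_time_a": float(
                        np.median(times[labels == a])
                    ),
                    "node_median_time_b": float(
                        np.median(times[labels == b])
                    ),
                }
            )
            edge_cells[(a, b)] = cells
    table = pd.DataFrame(
        rows,
        columns=[
            "node_a", "node_b", "n_pairs", "score", "score_min_k",
            "n_cells_a", "n_cells_b", "median_time_a", "median_time_b",
            "node_median_time_a", "node_median_time_b",
        ],
    )
    if len(table):
        table = table.sort_values("score", ascending=False).reset_index(
            drop=True
        )
    return table, edge_cells


def build_subsystem_candidates(
    table: CellTable,
    k: int,
    label_col: str = "type_label",
    n_hvg: int = 2500,
    d: int = 30,
    partition: tuple | None = None,
) -> CandidateEdges:
    """Embed a subsystem and score every intra-subsystem node pair by MNNs.

    ``k`` follows the subsystem convention (10 for pre-gastrulation and
    gastrulation, 15 for organogenesis & fetal development). ``partition``
    optionally splits the node labels in two stages ``(core, derivatives)``:
    stage one scores edges among core nodes only, stage two scores only
    core-derivative edges in a joint embedding (the treatment used for the
    most complex subsystem).
    """
    labels = np.asarray(table.cell_meta[label_col], dtype=object)
    sizes = pd.Series(labels).value_counts().to_dict()
    small = [t for t, n in sizes.items() if n < 2]
    if small:
        warnings.warn(f"excluding nodes with < 2 cells: {sorted(small)}")
        keep = ~np.isin(labels, small)
        table = table.subset_cells(keep)
        labels = labels[keep]
        sizes = {t: n for t, n in sizes.items() if n >= 2}

    if partition is not None:
        core, deriv = (set(partition[0]), set(partition[1]))
        if core & deriv:
            raise ValueError("partition sets must be disjoint")
        stage1 = build_subsystem_candidates(
            table.subset_cells(np.isin(labels, sorted(core))),
            k, label_col, n_hvg, d,
        )
        stage2 = build_subsystem_candidates(table, k, label_col, n_hvg, d)
        cross = stage2.table[
            stage2.table.apply(
                lambda r: (r.node_a in core) != (r.node_b in core), axis=1
            )
        ]
        merged = pd.concat([stage1.table, cross], ignore_index=True)
        merged = merged.sort_values("score", ascending=False).reset_index(
            drop=True
        )
        edge_cells = dict(stage1.edge_cells)
        for key in cross[["node_a", "node_b"]].itertuples(index=False):
            edge_cells[tuple(key)] = stage2.edge_cells[tuple(key)]
        return CandidateEdges(merged, stage2.pairs, stage2.embedding,
                              edge_cells, k)

    emb = embed_table(table, n_hvg=n_hvg, d=d)
    pairs = mnn_pairs(emb, k, mode="global")
    times = np.asarray(table.cell_meta["timepoint"], dtype=float)
    tab, edge_cells = _score_pairs(pairs, labels, times, sizes, k)
    return CandidateEdges(tab, pairs, emb, edge_cells, k)


def categorize_and_orient(
    candidates: pd.DataFrame,
    curation: pd.DataFrame | None = None,
    manual_edges: list[CellTypeEdge] | None = None,
    default_category: str = "developmental_progression",
) -> list[CellTypeEdge]:
    """Turn scored candidates into categorized, oriented edges.

    Defaults: category ``developmental_progression``; orientation from the
    node whose MNN-participating cells have the earlier median timepoint,
    falling back to the node-wide median timepoint when the participating
    cells tie (inter-node MNN cells are temporally coincident by nature, so
    ties are common). A curation table (columns node_a, node_b, category,
    orientation; empty strings leave a field at its default) always wins.
    Spatial-continuity edges are forced bidirectional; manual edges may be
    appended.
    """
    known = set(candidates["node_a"]) | set(candidates["node_b"])
    cur = {}
    if curation is not None:
        for row in curation.itertuples(index=False):
            a, b = row.node_a, row.node_b
            if a not in known or b not in known:
                raise ValueError(f"curation references unknown nodes: {(a, b)}")
            cur[tuple(sorted((a, b)))] = row
    edges = []
    for row in candidates.itertuples(index=False):
        a, b = row.node_a, row.node_b
        category = default_category
        ta, tb = row.median_time_a, row.median_time_b
        if np.isnan(ta) or np.isnan(tb) or ta == tb:
            ta = getattr(row, "node_median_time_a", np.nan)
            tb = getattr(row, "node_median_time_b", np.nan)
        if np.isnan(ta) or np.isnan(tb) or ta == tb:
            orientation = "bidirectional"
        elif ta < tb:
            orientation = "a_to_b"
        else:
            orientation = "b_to_a"
        entry = cur.get(tuple(sorted((a, b))))
        if entry is not None:
            if getattr(entry, "category", ""):
                category = entry.category
            if getattr(entry, "orientation", ""):
                orientation = entry.orientation
                if {entry.node_a, entry.node_b} == {a, b} and entry.node_a != a:
                    flip = {"a_to_b": "b_to_a", "b_to_a": "a_to_b"}
                    orientation = flip.get(orientation, orientation)
        if category == "spatial_continuity":
            orientation = "bidirectional"
        edges.append(
            CellTypeEdge(
                node_a=a,
                node_b=b,
                n_mnn_pairs=int(row.n_pairs),
                normalized_score=float(row.score),
                category=category,
                orientation=orientation,
                provenance={
                    "median_time_a": row.median_time_a,
                    "median_time_b": row.median_time_b,
                },
            )
        )
    if manual_edges:
        edges.extend(manual_edges)
    return edges


def edges_to_graph(
    edges: list[CellTypeEdge],
    node_meta: pd.DataFrame | None = None,
    root: str | None = None,
) -> nx.DiGraph:
    """Materialize edges as a rooted directed graph (bidirectional edges are
    stored in both directions)."""
    g = nx.DiGraph()
    for e in edges:
        pairs = []
        if e.orientation in ("a_to_b", "bidirectional"):
            pairs.append((e.node_a, e.node_b))
        if e.orientation in ("b_to_a", "bidirectional"):
            pairs.append((e.node_b, e.node_a))
        for u, v in pairs:
            g.add_edge(
                u, v,
                n_mnn_pairs=e.n_mnn_pairs,
                normalized_score=e.normalized_score,
                category=e.category,
                orientation=e.orientation,
            )
    if node_meta is not None:
        for node, row in node_meta.iterrows():
            if node in g:
                g.nodes[node].update(row.to_dict())
    if root is not None:
        g.graph["root"] = root
        missing = set(g.nodes) - set(nx.descendants(g, root)) - {root}
        if missing:
            warnings.warn(f"nodes unreachable from root: {sorted(missing)}")
    return g


def edge_time_profile(
    participating_cells,
    cell_times,
    bins,
) -> pd.DataFrame:
    """Percent of a bin's cells that participate in one edge's MNN pairs.

    ``bins`` is a sequence of discrete time values; for each bin the profile
    is 100 x (edge cells from that bin) / (total cells from that bin). Empty
    bins report 0 with a flag.
    """
    cells = np.asarray(participating_cells, dtype=int)
    times = np.asarray(cell_times, dtype=float)
    member = np.zeros(times.size, dtype=bool)
    member[cells] = True
    rows = []
    for b in bins:
        in_bin = times == b
        n = int(in_bin.sum())
        if n == 0:
            rows.append({"bin": b, "pct": 0.0, "n_cells": 0, "empty": True})
        else:
            rows.append(
                {
                    "bin": b,
                    "pct": 100.0 * member[in_bin].sum() / n,
                    "n_cells": n,
                    "empty": False,
                }
            )
    return pd.DataFrame(rows)


def bridge_datasets(
    table_x: CellTable,
    table_y: CellTable,
    shared_timepoints,
    k: int,
    label_col: str = "type_label",
    n_hvg: int = 2500,
    d: int = 30,
    score_threshold: float = 1.0,
    max_offset_ratio: float = 0.5,
    manual_table: pd.DataFrame | None = None,
) -> list[CellTypeEdge]:
    """Link equivalent cell-type nodes across two datasets.

    Both tables are restricted to the shared timepoints and intersected gene
    space, co-embedded after a naive batch adjustment (per-dataset centering
    of the scaled matrix), and cross-dataset node pairs are scored as in
    subsystem candidate building. Reciprocal-best pairs above the score
    threshold become dataset-equivalence edges, oriented forward in time.

    Per-dataset centering removes a global batch offset but, when the two
    datasets hold different type compositions, it can slide distinct types
    onto each other. Candidates are therefore also checked in the
    *uncorrected* space: a pair whose centroid separation before correction
    exceeds ``max_offset_ratio`` times the typical between-type centroid
    distance is rejected — the naive adjustment is only trusted for offsets
    small relative to type separation.
    """
    shared = set(float(t) for t in shared_timepoints)

    def restrict(t: CellTable) -> CellTable:
        mask = np.isin(np.asarray(t.cell_meta["timepoint"], dtype=float),
                       sorted(shared))
        return t.subset_cells(mask)

    tx, ty = restrict(table_x), restrict(table_y)
    genes = np.intersect1d(tx.gene_ids, ty.gene_ids)
    if genes.size == 0:
        raise ValueError("gene spaces do not intersect")
    tx = tx.subset_genes(tx.gene_index(genes))
    ty = ty.subset_genes(ty.gene_index(genes))

    import scipy.sparse as sp

    counts = sp.vstack([tx.counts, ty.counts]).tocsr()
    meta = pd.concat([tx.cell_meta, ty.cell_meta])
    meta = meta.assign(
        _dataset=np.r_[np.zeros(tx.n_cells, int), np.ones(ty.n_cells, int)]
    )
    merged = CellTable(counts, meta, tx.gene_meta)
    norm = normalize_log(merged)
    _, var = _column_moments(norm)
    hvg = select_hvg(norm, min(n_hvg, int((var > 0).sum())),
                     gene_ids=merged.gene_ids)
    X, means, sds = scale_genes(norm, hvg)
    ds = np.asarray(meta["_dataset"])
    labels_plain = np.asarray(meta[label_col], dtype=object)
    # uncorrected per-node centroids for the offset-magnitude guard
    centroids: dict[tuple[int, str], np.ndarray] = {}
    for dval in (0, 1):
        for lab in pd.unique(labels_plain[ds == dval]):
            centroids[(dval, lab)] = X[
                (ds == dval) & (labels_plain == lab)
            ].mean(axis=0)
    within = [
        np.linalg.norm(centroids[(dv, a)] - centroids[(dv, b)])
        for dv in (0, 1)
        for i, a in enumerate(sorted({l for d, l in centroids if d == dv}))
        for b in sorted({l for d, l in centroids if d == dv})[i + 1:]
    ]
    type_scale = float(np.median(within)) if within else None
    for dval in (0, 1):
        X[ds == dval] -= X[ds == dval].mean(axis=0)
    emb = pca(X, d, hvg_list=merged.gene_ids[hvg], gene_means=means,
              gene_sds=sds)
    # global MNN on the co-embedding; only pairs that cross datasets count.
    # (Forcing neighbours across datasets with a cross-group search would
    # fabricate matches even for disjoint type sets.)
    pairs_all = mnn_pairs(emb, k, mode="global")
    cross = ds[pairs_all.pairs[:, 0]] != ds[pairs_all.pairs[:, 1]]
    pairs = MNNPairSet(pairs=pairs_all.pairs[cross], k=k, mode="global")
    labels = np.array(
        [f"X::{v}" for v in tx.cell_meta[label_col]]
        + [f"Y::{v}" for v in ty.cell_meta[label_col]],
        dtype=object,
    )
    sizes = pd.Series(labels).value_counts().to_dict()
    times = np.asarray(meta["timepoint"], dtype=float)
    tab, _ = _score_pairs(pairs, labels, times, sizes, k)
    tab = tab[tab["score"] > score_threshold]
    # reciprocal best match across datasets
    best: dict[str, tuple[str, float]] = {}
    for row in tab.itertuples(index=False):
        for u, v in ((row.node_a, row.node_b), (row.node_b, row.node_a)):
            if u not in best or row.score > best[u][1]:
                best[u] = (v, row.score)
    edges = []
    for row in tab.itertuples(index=False):
        a, b = row.node_a, row.node_b
        if best.get(a, (None,))[0] != b or best.get(b, (None,))[0] != a:
            continue
        if type_scale is not None and type_scale > 0:
            la = a.split("::", 1)[1]
            lb = b.split("::", 1)[1]
            da = 0 if a.startswith("X::") else 1
            db = 0 if b.startswith("X::") else 1
            sep = np.linalg.norm(centroids[(da, la)] - centroids[(db, lb)])
            if sep > max_offset_ratio * type_scale:
                continue
        forward = (
            row.median_time_a <= row.median_time_b
            if np.isfinite(row.median_time_a)
            and np.isfinite(row.median_time_b)
            else True
        )
        edges.append(
            CellTypeEdge(
                node_a=a if forward else b,
                node_b=b if forward else a,
                n_mnn_pairs=int(row.n_pairs),
                normalized_score=float(row.score),
                category="dataset_equivalence",
                orientation="a_to_b",
                provenance={"k": k},
            )
        )
    if manual_table is not None:
        for row in manual_table.itertuples(index=False):
            edges.append(
                CellTypeEdge(
                    node_a=row.node_a,
                    node_b=row.node_b,
                    n_mnn_pairs=0,
                    normalized_score=0.0,
                    category="dataset_equivalence",
                    orientation="a_to_b",
                    provenance={"manual": True},
                )
            )
    return edges


@dataclass
class ProgenitorMap:
    distributions: dict  # derivative -> pd.Series over territories
    unmapped: list
    excluded: list
    n_pairs: dict
    iterations: int


def map_progenitors(
    table: CellTable,
    derivative_types,
    progenitor_pool_types,
    k: int = 10,
    n_early: int = 500,
    min_pairs: int = 50,
    label_col: str = "type_label",
    n_hvg: int = 2500,
    d: int = 30,
    max_iterations: int = 5,
) -> ProgenitorMap:
    """Map each derivative cell type onto progenitor territories by MNN.

    For each derivative with at least ``n_early`` cells, the ``n_early``
    earliest cells (by timepoint, ties by index) are matched to the pool by
    cross-group MNN (k = 10); the pair counts per territory, normalized to
    1, form its progenitor distribution. Derivatives with fewer than
    ``min_pairs`` pairs are retried iteratively against the pool plus the
    early cells of already-mapped derivatives; any still unmatched are
    reported unmapped.
    """
    labels = np.asarray(table.cell_meta[label_col], dtype=object)
    times = np.asarray(table.cell_meta["timepoint"], dtype=float)
    deriv = [str(x) for x in derivative_types]
    pool = [str(x) for x in progenitor_pool_types]
    emb = embed_table(table, n_hvg=n_hvg, d=d)

    excluded = [
        t for t in deriv if int((labels == t).sum()) < n_early
    ]
    if excluded:
        warnings.warn(
            f"derivatives with < {n_early} cells excluded: {excluded}"
        )
    active = [t for t in deriv if t not in excluded]
    early_cells = {}
    for t in active:
        idx = np.flatnonzero(labels == t)
        order = np.lexsort((idx, times[idx]))
        early_cells[t] = idx[order][:n_early]
    pool_idx = np.flatnonzero(np.isin(labels, pool))

    distributions: dict[str, pd.Series] = {}
    n_pairs_out: dict[str, int] = {}
    pending = list(active)
    iteration = 0
    while pending and iteration < max_iterations:
        iteration += 1
        target_idx = pool_idx
        if distributions:
            mapped_early = np.concatenate(
                [early_cells[t] for t in distributions]
            )
            target_idx = np.union1d(pool_idx, mapped_early)
        still = []
        for t in pending:
            query = np.setdiff1d(early_cells[t], target_idx)
            if query.size == 0:
                still.append(t)
                continue
            pairs = mnn_pairs(
                emb, k, mode="cross-group", group_a=query,
                group_b=target_idx,
            )
            n_pairs_out[t] = len(pairs)
            if len(pairs) < min_pairs:
                still.append(t)
                continue
            partner = np.where(
                np.isin(pairs.pairs[:, 0], query),
                pairs.pairs[:, 1], pairs.pairs[:, 0],
            )
            dist = (
                pd.Series(labels[partner]).value_counts(normalize=True)
                .sort_index()
            )
            distributions[t] = dist
        if still == pending:
            break
        pending = still
    return ProgenitorMap(
        distributions=distributions,
        unmapped=pending,
        excluded=excluded,
        n_pairs={t: n_pairs_out.get(t, 0) for t in active},
        iterations=iteration,
    )
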