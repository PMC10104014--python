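"""Three-step doublet removal, per-cell QC filters, and embryo sexing.

Step 1 scores each cell with a simulated-doublet kNN classifier: artificial
doublets (sums of random observed pairs, thinned to an observed library
size) are co-embedded with the observed cells, and the fraction q of
simulated doublets among a cell's neighbours is converted to a posterior
doublet probability given the expected doublet rate (see
:func:`_score_from_q`). Step 2 clusters and subclusters the data and flags
subclusters whose step-1 doublet fraction exceeds 15%. Step 3 targets
doublets hiding in rare clusters: it reclusters on highly dispersed genes,
picks top marker panels per cluster, and flags subclusters that
underexpress their own cluster's markers while overexpressing another
cluster's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import (
    cluster_graph,
    knn,
    normalize_log,
    pca,
    scale_genes,
    select_hvg,
    _column_moments,
)
from .datatypes import CellTable

__all__ = [
    "DoubletScoreParams",
    "QCConfig",
    "DoubletReport",
    "score_doublets",
    "flag_doublet_subclusters",
    "flag_marker_deviant_subclusters",
    "apply_cell_filters",
    "assign_sex",
    "run_doublet_pipeline",
]


@dataclass
class DoubletScoreParams:
    """Parameters of the simulated-doublet scoring step."""

    sim_doublet_ratio: float = 2.0
    n_neighbors: int = 30
    n_pcs: int = 30
    expected_doublet_rate: float = 0.06
    min_count: int = 3
    min_cells: int = 3
    hvg_quantile: float = 0.85
    scale_target: float = 1e4


@dataclass
class QCConfig:
    """Per-cell filter thresholds (defaults follow the published recipe)."""

    min_umi: int = 200
    min_genes: int = 100
    max_unmatched_rate: float = 0.4
    score_threshold_step1: float = 0.2
    subcluster_doublet_frac: float = 0.15
    final_score_threshold: float = 0.15
    max_ribo_pct: float = 5.0
    max_mito_pct: float = 10.0


@dataclass
class DoubletReport:
    doublet_score: pd.Series
    score_flag: pd.Series
    subcluster_flag: pd.Series
    marker_flag: pd.Series
    subcluster_fractions: pd.DataFrame
    removal_ledger: dict = field(default_factory=dict)

    @property
    def removed(self) -> pd.Series:
        return self.score_flag | self.subcluster_flag | self.marker_flag


def _score_from_q(q, r: float, rho: float = 0.06):
    """Doublet score from the simulated-neighbour fraction q.

    The local simulated:observed density ratio, corrected for the r-fold
    excess of simulated doublets, is converted to a posterior doublet
    probability with prior ``rho`` (the expected doublet rate):
    ``score = (q rho / r) / (q rho / r + (1 - q)(1 - rho))``. A neighbourhood
    in which simulated doublets are merely proportionally represented
    (q = r/(r+1)) therefore scores rho, not 1/2, which is what makes the
    0.2/0.15 thresholds meaningful for singlets.
    """
    q = np.asarray(q, dtype=float)
    num = q * rho / r
    return num / (num + (1.0 - q) * (1.0 - rho))


def score_doublets(
    table: CellTable,
    params: DoubletScoreParams | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell doublet score in [0, 1] from simulated-doublet kNN voting."""
    params = params or DoubletScoreParams()
    n = table.n_cells
    if n < 100:
        raise ValueError("need at least 100 cells to score doublets")
    if n <= params.n_neighbors:
        raise ValueError("fewer cells than n_neighbors")
    rng = np.random.default_rng(seed)
    counts = table.counts
    gene_tot = np.asarray(counts.sum(axis=0)).ravel()
    gene_cells = np.asarray((counts > 0).sum(axis=0)).ravel()
    gmask = (gene_tot >= params.min_count) & (gene_cells >= params.min_cells)
    counts = counts[:, np.flatnonzero(gmask)].tocsr()

    n_sim = int(round(params.sim_doublet_ratio * n))
    ia = rng.integers(0, n, size=n_sim)
    ib = rng.integers(0, n, size=n_sim)
    sim_counts = (counts[ia] + counts[ib]).tocsr()
    # thin each simulated doublet to one observed library size: a raw sum is
    # an average of two cells after depth normalization and has ~1/sqrt(2)
    # their sampling noise, which would concentrate homotypic doublets at
    # cluster cores and inflate singlet scores
    lib = np.asarray(counts.sum(axis=1), dtype=float).ravel()
    target = lib[np.where(rng.random(n_sim) < 0.5, ia, ib)]
    tot = np.asarray(sim_counts.sum(axis=1), dtype=float).ravel()
    keep_p = np.minimum(1.0, target / np.maximum(tot, 1.0))
    sim_counts.data = rng.binomial(
        sim_counts.data.astype(np.int64),
        np.repeat(keep_p, np.diff(sim_counts.indptr)),
    )
    sim_counts.eliminate_zeros()

    def lognorm(m):
        tot = np.asarray(m.sum(axis=1), dtype=float).ravel()
        tot[tot == 0] = 1.0
        out = m.astype(float).tocsr(copy=True)
        out.data *= np.repeat(params.scale_target / tot, np.diff(out.indptr))
        np.log1p(out.data, out=out.data)
        return out

    obs_norm = lognorm(counts)
    sim_norm = lognorm(sim_counts)
    _, var = _column_moments(obs_norm)
    pos = var[var > 0]
    cutoff = np.quantile(pos, params.hvg_quantile) if pos.size else 0.0
    hvg = np.flatnonzero(var >= max(cutoff, 1e-12))
    Xo = np.asarray(obs_norm[:, hvg].todense())
    mean = Xo.mean(axis=0)
    sd = Xo.std(axis=0)
    sd[sd == 0] = 1.0
    Xo = (Xo - mean) / sd
    Xs = (np.asarray(sim_norm[:, hvg].todense()) - mean) / sd

    emb = pca(Xo, min(params.n_pcs, min(Xo.shape)))
    coords_obs = emb.coords
    # PCA is fit on observed cells only; the simulated doublets are projected
    # onto its axes (Xo is exactly zero-centered after scaling, so no further
    # centering is needed)
    coords_sim = Xs @ emb.components.T
    coords = np.vstack([coords_obs, coords_sim])
    k_adj = int(round(params.n_neighbors * (1 + params.sim_doublet_ratio)))
    graph = knn(coords, min(k_adj, coords.shape[0] - 1))
    is_sim = np.r_[np.zeros(n, bool), np.ones(n_sim, bool)]
    # smoothed neighbour fraction, as in kNN classifiers with add-one counts
    n_sim_nb = is_sim[graph.indices[:n]].sum(axis=1)
    q = (n_sim_nb + 1.0) / (graph.k + 2.0)
    return _score_from_q(q, params.sim_doublet_ratio,
                         params.expected_doublet_rate)


def _cluster_recipe(
    table: CellTable,
    resolution: float,
    seed: int,
    n_hvg: int = 3000,
    d: int = 30,
    n_neighbors: int = 50,
    method: str = "louvain",
    drop_sex_genes: bool = True,
) -> np.ndarray:
    """Cluster cells with the shared recipe: HVG -> scale -> PCA -> kNN ->
    community detection (sex-chromosome genes removed when annotated)."""
    sub = table
    if drop_sex_genes and "chromosome" in table.gene_meta.columns:
        keep = ~table.gene_meta["chromosome"].isin(["chrX", "chrY", "X", "Y"])
        sub = table.subset_genes(np.asarray(keep))
    norm = normalize_log(sub)
    _, var = _column_moments(norm)
    n_avail = int((var > 0).sum())
    hvg = select_hvg(norm, min(n_hvg, n_avail), gene_ids=sub.gene_ids)
    X, _, _ = scale_genes(norm, hvg)
    emb = pca(X, min(d, min(X.shape)))
    graph = knn(emb, min(n_neighbors, emb.n_cells - 1))
    return cluster_graph(graph, resolution=resolution, method=method,
                         seed=seed)


def _flag_by_fraction(
    subcluster_labels: np.ndarray,
    doublet_flags: np.ndarray,
    frac: float,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag all cells of subclusters whose doublet fraction exceeds frac."""
    flags = np.zeros(len(subcluster_labels), dtype=bool)
    rows = []
    for lab in pd.unique(subcluster_labels):
        mask = subcluster_labels == lab
        f = float(doublet_flags[mask].mean())
        rows.append({"subcluster": lab, "n": int(mask.sum()),
                     "doublet_fraction": f, "flagged": f > frac})
        if f > frac:
            flags[mask] = True
    return flags, pd.DataFrame(rows)


def flag_doublet_subclusters(
    table: CellTable,
    scores: np.ndarray,
    score_threshold: float = 0.2,
    res_main: float = 1.0,
    res_sub: float = 3.0,
    frac: float = 0.15,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag cells in subclusters enriched (> frac) for step-1 doublets."""
    step1 = np.asarray(scores) > score_threshold
    main = _cluster_recipe(table, res_main, seed)
    flags = np.zeros(table.n_cells, dtype=bool)
    frames = []
    for c in np.unique(main):
        idx = np.flatnonzero(main == c)
        if idx.size < 10:
            sub_labels = np.zeros(idx.size, dtype=int)
        else:
            sub_labels = _cluster_recipe(
                table.subset_cells(idx), res_sub, seed
            )
        fl, tab = _flag_by_fraction(sub_labels, step1[idx], frac)
        flags[idx] = fl
        tab.insert(0, "cluster", c)
        frames.append(tab)
    return flags, pd.concat(frames, ignore_index=True)


def _auroc_markers(
    norm: sp.csr_matrix,
    labels: np.ndarray,
    gene_ids: np.ndarray,
    top_n: int = 10,
    min_frac_expressing: float = 0.1,
) -> dict:
    """Top marker genes per cluster ranked by one-vs-rest AUROC."""
    from scipy.stats import rankdata

    X = np.asarray(norm.todense())
    n = X.shape[0]
    markers = {}
    for c in np.unique(labels):
        mask = labels == c
        n1 = int(mask.sum())
        n0 = n - n1
        if n1 == 0 or n0 == 0:
            continue
        frac_expr = (X[mask] > 0).mean(axis=0)
        ranks = rankdata(X, axis=0)
        auroc = (ranks[mask].sum(axis=0) - n1 * (n1 + 1) / 2) / (n1 * n0)
        eligible = frac_expr >= min_frac_expressing
        order = np.lexsort((gene_ids, -auroc))
        order = [i for i in order if eligible[i]][:top_n]
        markers[c] = list(gene_ids[order])
    return markers


def flag_marker_deviant_subclusters(
    table: CellTable,
    res_main: float = 1.0,
    res_sub: float = 3.0,
    n_hvg: int = 5000,
    n_pcs_main: int = 50,
    n_pcs_sub: int = 10,
    top_n_markers: int = 10,
    min_frac_expressing: float = 0.1,
    downsample: int = 2500,
    theta_low: float = 0.25,
    theta_high: float = 0.75,
    min_cluster_size: int = 30,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Flag subclusters that express another cluster's markers.

    The procedure: restrict to protein-coding/lincRNA/pseudogene biotypes
    (when annotated), drop genes in < 10 cells and cells with < 100 genes,
    cluster on PCA(50) of the top highly dispersed genes, pick top-10 marker
    panels per cluster (AUROC-ranked, fraction-expressing filter), then
    subcluster each cluster on PCA(10) of the combined marker panel. A
    subcluster is flagged when its mean own-cluster marker score falls below
    the cluster's ``theta_low`` quantile while its mean best other-cluster
    score exceeds the ``theta_high`` quantile.
    """
    rng = np.random.default_rng(seed)
    gene_keep = np.ones(table.n_genes, dtype=bool)
    if "biotype" in table.gene_meta.columns:
        gene_keep &= np.asarray(
            table.gene_meta["biotype"].isin(
                ["protein_coding", "lincRNA", "pseudogene"]
            )
        )
    gene_keep &= np.asarray((table.counts > 0).sum(axis=0)).ravel() >= 10
    sub = table.subset_genes(gene_keep)
    cell_keep = np.asarray((sub.counts > 0).sum(axis=1)).ravel() >= 100
    kept_idx = np.flatnonzero(cell_keep)
    sub = sub.subset_cells(kept_idx)

    norm = normalize_log(sub)
    _, var = _column_moments(norm)
    n_avail = int((var > 0).sum())
    hvg = select_hvg(norm, min(n_hvg, n_avail), flavor="dispersion",
                     gene_ids=sub.gene_ids)
    X, _, _ = scale_genes(norm, hvg)
    emb = pca(X, min(n_pcs_main, min(X.shape)))
    graph = knn(emb, min(50, emb.n_cells - 1))
    clusters = cluster_graph(graph, resolution=res_main, method="louvain",
                             seed=seed)

    # marker panels from downsampled clusters
    ds_idx = []
    for c in np.unique(clusters):
        idx = np.flatnonzero(clusters == c)
        if idx.size > downsample:
            idx = np.sort(rng.choice(idx, size=downsample, replace=False))
        ds_idx.append(idx)
    ds_idx = np.concatenate(ds_idx)
    markers = _auroc_markers(
        norm[ds_idx], clusters[ds_idx], sub.gene_ids,
        top_n=top_n_markers, min_frac_expressing=min_frac_expressing,
    )
    panel_genes = sorted({g for panel in markers.values() for g in panel})
    if not panel_genes:
        return np.zeros(table.n_cells, dtype=bool), {"markers": markers}
    panel_idx = sub.gene_index(panel_genes)
    Xp = np.asarray(norm[:, panel_idx].todense())
    mu, sdv = Xp.mean(axis=0), Xp.std(axis=0)
    sdv[sdv == 0] = 1.0
    Z = (Xp - mu) / sdv
    col_of = {g: i for i, g in enumerate(panel_genes)}
    panel_scores = {
        c: Z[:, [col_of[g] for g in panel]].mean(axis=1)
        for c, panel in markers.items() if panel
    }

    flags_sub = np.zeros(sub.n_cells, dtype=bool)
    detail = {"markers": markers, "subclusters": []}
    for c in np.unique(clusters):
        idx = np.flatnonzero(clusters == c)
        if idx.size < min_cluster_size or c not in panel_scores:
            warnings.warn(f"cluster {c} too small for marker evaluation; "
                          "skipped")
            continue
        own = panel_scores[c][idx]
        others = [panel_scores[o][idx] for o in panel_scores if o != c]
        if not others:
            continue
        other = np.max(np.vstack(others), axis=0)
        lo = np.quantile(own, theta_low)
        hi = np.quantile(other, theta_high)
        Xc, _, _ = scale_genes(norm[idx][:, panel_idx])
        emb_c = pca(Xc, min(n_pcs_sub, min(Xc.shape)))
        g_c = knn(emb_c, min(50, emb_c.n_cells - 1))
        sub_labels = cluster_graph(g_c, resolution=res_sub, method="louvain",
                                   seed=seed)
        for s in np.unique(sub_labels):
            smask = sub_labels == s
            mo, mx = float(own[smask].mean()), float(other[smask].mean())
            flagged = (mo < lo) and (mx > hi)
            detail["subclusters"].append(
                {"cluster": int(c), "subcluster": int(s),
                 "n": int(smask.sum()), "mean_own": mo, "mean_other": mx,
                 "flagged": flagged}
            )
            if flagged:
                flags_sub[idx[smask]] = True
    flags = np.zeros(table.n_cells, dtype=bool)
    flags[kept_idx] = flags_sub
    return flags, detail


def apply_cell_filters(
    table: CellTable,
    scores: np.ndarray | None,
    cfg: QCConfig | None = None,
) -> tuple[CellTable, dict]:
    """Remove cells violating any QC threshold; ledger counts per rule."""
    cfg = cfg or QCConfig()
    meta = table.cell_meta
    n = table.n_cells
    rules: dict[str, np.ndarray] = {}
    rules["min_umi"] = np.asarray(meta["umi_total"]) < cfg.min_umi
    rules["min_genes"] = np.asarray(meta["gene_count"]) < cfg.min_genes
    if "unmatched_rate" in meta.columns:
        rules["unmatched_rate"] = (
            np.asarray(meta["unmatched_rate"], dtype=float)
            >= cfg.max_unmatched_rate
        )
    if scores is not None:
        rules["doublet_score"] = (
            np.asarray(scores) > cfg.final_score_threshold
        )
    if "ribo_pct" in meta.columns:
        rules["ribo_pct"] = (
            np.asarray(meta["ribo_pct"], dtype=float) > cfg.max_ribo_pct
        )
    if "mito_pct" in meta.columns:
        rules["mito_pct"] = (
            np.asarray(meta["mito_pct"], dtype=float) > cfg.max_mito_pct
        )
    removed = np.zeros(n, dtype=bool)
    ledger = {}
    for name, mask in rules.items():
        ledger[name] = int(mask.sum())
        removed |= mask
    ledger["total_removed"] = int(removed.sum())
    ledger["total_kept"] = int(n - removed.sum())
    return table.subset_cells(~removed), ledger


def assign_sex(
    table: CellTable,
    xist_gene: str,
    chry_genes,
    embryo_col: str = "embryo_id",
) -> pd.Series:
    """Per-embryo sex from Xist vs chrY read totals (tie -> ambiguous)."""
    chry_genes = list(chry_genes)
    if not chry_genes:
        raise ValueError("chrY gene list must be non-empty")
    xist_idx = table.gene_index([xist_gene])
    chry_idx = table.gene_index(chry_genes)
    xist = np.asarray(table.counts[:, xist_idx].sum(axis=1)).ravel()
    chry = np.asarray(table.counts[:, chry_idx].sum(axis=1)).ravel()
    df = pd.DataFrame(
        {
            "embryo": np.asarray(table.cell_meta[embryo_col]),
            "xist": xist,
            "chry": chry,
        }
    )
    totals = df.groupby("embryo").sum()
    sex = pd.Series("ambiguous", index=totals.index, name="sex", dtype=object)
    sex[totals["xist"] > totals["chry"]] = "female"
    sex[totals["chry"] > totals["xist"]] = "male"
    return sex


def run_doublet_pipeline(
    table: CellTable,
    cfg: QCConfig | None = None,
    score_params: DoubletScoreParams | None = None,
    seed: int = 0,
) -> tuple[CellTable, DoubletReport]:
    """All three doublet steps plus the QC filters; returns the cleaned table.

    The removed set is the union of the three doublet flags and every cell
    filter violation.
    """
    cfg = cfg or QCConfig()
    scores = score_doublets(table, score_params, seed=seed)
    score_flag = scores > cfg.score_threshold_step1
    sub_flag, sub_tab = flag_doublet_subclusters(
        table, scores, score_threshold=cfg.score_threshold_step1,
        frac=cfg.subcluster_doublet_frac, seed=seed,
    )
    marker_flag, _ = flag_marker_deviant_subclusters(table, seed=seed)
    doublet_removed = score_flag | sub_flag | marker_flag
    filtered, ledger = apply_cell_filters(
        table.subset_cells(~doublet_removed),
        scores[~doublet_removed],
        cfg,
    )
    ledger["score_flag"] = int(score_flag.sum())
    ledger["subcluster_flag"] = int(sub_flag.sum())
    ledger["marker_flag"] = int(marker_flag.sum())
    idx = table.cell_ids
    report = DoubletReport(
        doublet_score=pd.Series(scores, index=idx),
        score_flag=pd.Series(score_flag, index=idx),
        subcluster_flag=pd.Series(sub_flag, index=idx),
        marker_flag=pd.Series(marker_flag, index=idx),
        subcluster_fractions=sub_tab,
        removal_ledger=ledger,
    )
    return filtered, report
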