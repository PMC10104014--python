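"""Core primitives against closed forms and brute-force oracles."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from ontotree import core
from ontotree.datatypes import MNNPairSet

from conftest import make_table


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_normalize_log_closed_form():
    table = make_table([[2, 0]])
    out = core.normalize_log(table, scale_target=100)
    assert np.isclose(out[0, 0], np.log(101))
    assert out[0, 1] == 0


def test_normalize_log_scale_invariance_and_zero_pattern():
    rng = np.random.default_rng(0)
    counts = rng.poisson(2.0, size=(10, 8))
    counts[3] = counts[2] * 3  # proportional rows
    counts[:, 5] = 0
    table = make_table(counts)
    # guard against zero-total rows in the fixture
    assert (counts.sum(axis=1) > 0).all()
    out = core.normalize_log(table)
    assert np.allclose(out[2].toarray(), out[3].toarray())
    assert (out.toarray() == 0).all(axis=0)[5]
    assert np.array_equal(out.toarray() != 0, counts != 0)


def test_normalize_log_matches_loop_oracle():
    rng = np.random.default_rng(1)
    counts = rng.poisson(1.5, size=(50, 20))
    counts[:, 0] += 1  # ensure nonzero totals
    table = make_table(counts)
    target = 1e4
    out = core.normalize_log(table, target).toarray()
    expected = np.zeros_like(out)
    for i in range(50):
        tot = counts[i].sum()
        for j in range(20):
            expected[i, j] = np.log1p(counts[i, j] * target / tot)
    assert np.allclose(out, expected)


def test_normalize_log_rejects_zero_total_by_name():
    counts = np.ones((3, 2))
    counts[1] = 0
    table = make_table(counts)
    with pytest.raises(ValueError, match="c1"):
        core.normalize_log(table)


def test_normalize_log_cross_checks_scanpy():
    """Independent route: scanpy's normalize_total + log1p."""
    import anndata as ad
    import scanpy as sc

    rng = np.random.default_rng(2)
    counts = rng.poisson(2.0, size=(30, 15)) + (rng.random((30, 15)) < 0.1)
    counts[:, 0] += 1
    table = make_table(counts.astype(int))
    ours = core.normalize_log(table, scale_target=1e4).toarray()
    adata = ad.AnnData(sp.csr_matrix(counts.astype(float)))
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    assert np.allclose(ours, adata.X.toarray())


# ---------------------------------------------------------------------------
# HVG selection
# ---------------------------------------------------------------------------

def test_select_hvg_excludes_constant_and_ranks_planted():
    rng = np.random.default_rng(3)
    X = rng.normal(0, 0.05, size=(200, 100))
    X[:, 10] = 1.0  # constant gene
    planted = [3, 17, 42, 55, 60, 61, 77, 80, 91, 99]
    for j in planted:
        X[:, j] = rng.normal(0, 3.0, size=200)
    idx = core.select_hvg(X, 10)
    assert set(idx) == set(planted)
    # independent variance oracle for the full ordering
    var = np.array([X[:, j].var() for j in range(100)])
    assert 10 not in core.select_hvg(X, 99)
    full = core.select_hvg(X, 99)
    assert np.all(np.diff(var[full]) <= 1e-12)


def test_select_hvg_all_nonconstant_and_overflow():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(50, 12))
    assert len(core.select_hvg(X, 12)) == 12
    with pytest.raises(ValueError):
        core.select_hvg(X, 13)


def test_select_hvg_tie_break_by_gene_id():
    X = np.zeros((4, 3))
    X[:, 0] = [0, 1, 0, 1]
    X[:, 1] = [1, 0, 1, 0]
    X[:, 2] = [0, 0, 1, 1]  # all three have equal variance
    idx = core.select_hvg(X, 2, gene_ids=np.array(["gb", "ga", "gc"]))
    assert list(idx) == [1, 0]  # ga, gb


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_line_gives_unit_pc1():
    t = np.linspace(-1, 1, 40)
    X = np.column_stack([t, 2 * t, -t])
    emb = core.pca(X - X.mean(axis=0), 2)
    assert np.isclose(emb.variance_fractions[0], 1.0)


def test_pca_rotation_invariant_variance_fractions():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(100, 6)) @ np.diag([3, 2, 1.5, 1, 0.5, 0.2])
    X -= X.mean(axis=0)
    q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
    e1 = core.pca(X, 4)
    e2 = core.pca(X @ q, 4)
    assert np.allclose(e1.variance_fractions, e2.variance_fractions)


def test_pca_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(200, 30))
    X -= X.mean(axis=0)
    emb = core.pca(X, 5)
    cov = X.T @ X / 200
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    v = v[:, order[:5]]
    oracle = X @ v
    for j in range(5):
        dot = np.abs(np.dot(emb.coords[:, j], oracle[:, j]))
        assert np.isclose(
            dot, np.linalg.norm(emb.coords[:, j]) * np.linalg.norm(
                oracle[:, j]), rtol=1e-8
        )


def test_pca_full_rank_reconstruction():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(20, 8))
    X -= X.mean(axis=0)
    emb = core.pca(X, 8)
    recon = emb.coords @ emb.components
    assert np.allclose(recon, X, atol=1e-8)


def test_pca_rank_deficient_warns_and_reduces():
    X = np.zeros((10, 4))
    X[:, 0] = np.arange(10) - 4.5
    X[:, 1] = 2 * X[:, 0]
    with pytest.warns(UserWarning, match="rank"):
        emb = core.pca(X, 4)
    assert emb.d < 4


# ---------------------------------------------------------------------------
# kNN / MNN
# ---------------------------------------------------------------------------

def test_knn_tie_break_collinear():
    coords = np.array([[0.0], [1.0], [2.0]])
    graph = core.knn(coords, 1)
    assert graph.indices[1, 0] == 0  # equidistant: lower index wins


def test_knn_duplicates_mutual_zero_distance():
    rng = np.random.default_rng(8)
    coords = rng.normal(size=(20, 3))
    coords[7] = coords[3]
    graph = core.knn(coords, 1)
    assert graph.indices[3, 0] == 7
    assert graph.indices[7, 0] == 3
    assert graph.distances[3, 0] == 0


def brute_force_knn(coords, k):
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    out = []
    for i in range(len(coords)):
        order = sorted(range(len(coords)), key=lambda j: (d[i, j], j))
        out.append(order[:k])
    return np.array(out)


def brute_force_mnn(coords, k):
    nb = brute_force_knn(coords, k)
    sets = [set(row) for row in nb]
    return {
        (i, j)
        for i in range(len(coords))
        for j in sets[i]
        if i < j and i in sets[j]
    }


@pytest.mark.parametrize("seed", [0, 1])
def test_knn_and_mnn_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    coords = rng.normal(size=(300, 5))
    k = 10
    graph = core.knn(coords, k)
    assert np.array_equal(graph.indices, brute_force_knn(coords, k))
    pairs = core.mnn_pairs(coords, k)
    assert pairs.as_set() == brute_force_mnn(coords, k)


def test_mnn_two_cells_single_pair():
    coords = np.array([[0.0, 0.0], [1.0, 1.0]])
    pairs = core.mnn_pairs(coords, 1)
    assert pairs.as_set() == {(0, 1)}


def test_mnn_subset_of_knn_and_symmetric(two_type_embedding):
    coords = two_type_embedding.coords[:400]
    k = 8
    graph = core.knn(coords, k)
    pairs = core.mnn_pairs(coords, k)
    adj = {(i, int(j)) for i in range(400) for j in graph.indices[i]}
    for i, j in pairs.as_set():
        assert (i, j) in adj and (j, i) in adj


def test_mnn_cross_group_matches_brute_force():
    rng = np.random.default_rng(9)
    coords = rng.normal(size=(120, 4))
    ga, gb = np.arange(50), np.arange(50, 120)
    k = 6
    pairs = core.mnn_pairs(coords, k, mode="cross-group", group_a=ga,
                           group_b=gb)
    d = cdist(coords[ga], coords[gb])
    a_nb = [set(sorted(range(70), key=lambda j: (d[i, j], j))[:k])
            for i in range(50)]
    b_nb = [set(sorted(range(50), key=lambda i: (d[i, j], i))[:k])
            for j in range(70)]
    oracle = {
        (i, 50 + j) for i in range(50) for j in a_nb[i] if i in b_nb[j]
    }
    assert pairs.as_set() == oracle


def test_mnn_cross_group_rejects_overlap():
    coords = np.random.default_rng(0).normal(size=(10, 2))
    with pytest.raises(ValueError, match="disjoint"):
        core.mnn_pairs(coords, 2, mode="cross-group",
                       group_a=[0, 1, 2], group_b=[2, 3])


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("method", ["leiden", "louvain"])
def test_cluster_graph_two_blobs(method):
    rng = np.random.default_rng(10)
    coords = np.vstack([
        rng.normal(0, 0.3, size=(100, 4)),
        rng.normal(8, 0.3, size=(100, 4)),
    ])
    graph = core.knn(coords, 50)  # the pipeline's neighbourhood size
    labels = core.cluster_graph(graph, 1.0, method=method, seed=0)
    assert len(np.unique(labels)) == 2
    assert len(np.unique(labels[:100])) == 1
    assert len(np.unique(labels[100:])) == 1


def test_cluster_graph_deterministic_and_validates():
    rng = np.random.default_rng(11)
    coords = rng.normal(size=(80, 3))
    graph = core.knn(coords, 5)
    l1 = core.cluster_graph(graph, 1.0, seed=42)
    l2 = core.cluster_graph(graph, 1.0, seed=42)
    assert np.array_equal(l1, l2)
    with pytest.raises(ValueError):
        core.cluster_graph(graph, 0.0)


# ---------------------------------------------------------------------------
# neighbour smoothing
# ---------------------------------------------------------------------------

def test_neighbor_smooth_constant_is_zero():
    rng = np.random.default_rng(12)
    coords = rng.normal(size=(50, 2))
    out = core.neighbor_smooth(np.full(50, 3.3), coords)
    assert np.array_equal(out, np.zeros(50))


def test_neighbor_smooth_default_k_follows_ln_rule():
    # the ln rule: 9,000 points -> k = round(ln 9000) = 9
    assert int(round(np.log(9000))) == 9
    rng = np.random.default_rng(13)
    coords = rng.normal(size=(100, 2))
    v = rng.normal(size=100)
    out_default = core.neighbor_smooth(v, coords)
    out_explicit = core.neighbor_smooth(v, coords, k=round(np.log(100)))
    assert np.allclose(out_default, out_explicit)


def test_neighbor_smooth_matches_loop_oracle():
    rng = np.random.default_rng(14)
    coords = rng.normal(size=(100, 3))
    v = rng.normal(size=100)
    k = 5
    d = cdist(coords, coords)
    sm = np.empty(100)
    for i in range(100):
        order = sorted(range(100), key=lambda j: (d[i, j], j))
        sm[i] = v[order[:k]].mean()
    oracle = (sm - sm.min()) / (sm.max() - sm.min())
    assert np.allclose(core.neighbor_smooth(v, coords, k=k), oracle)


def test_embed_table_caps_hvg_and_is_finite(two_type_sim):
    _, _, table, _ = two_type_sim
    emb = core.embed_table(table, n_hvg=10**6, d=10)
    assert emb.d == 10
    assert np.isfinite(emb.coords).all()
    assert np.all(np.diff(emb.variance_fractions) <= 1e-12)


def test_mnn_pairset_validates():
    with pytest.raises(ValueError, match="self-pairs"):
        MNNPairSet(pairs=np.array([[3, 3]]), k=5)
    ps = MNNPairSet(pairs=np.array([[5, 2], [2, 5], [1, 4]]), k=5)
    assert len(ps) == 2  # deduplicated, unordered
    assert ps.pairs[0].tolist() == [1, 4]
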