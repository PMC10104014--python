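"""Cell-type graph inference against the simulated lineage truth."""

import numpy as np
import pandas as pd
import pytest

from ontotree import graph_builder as gb, synthdata as sd


def true_edge_keys(spec):
    return {tuple(sorted(e)) for e in spec.true_edges()}


# ---------------------------------------------------------------------------
# candidate scoring
# ---------------------------------------------------------------------------

def test_chain_scores_exceed_skip_edge(tree_sim, tree_candidates):
    """Adjacent types in a chain outscore the grandparent pair."""
    df = tree_candidates.table.set_index(["node_a", "node_b"])

    def score(a, b):
        key = tuple(sorted((a, b)))
        return df.loc[key, "score"] if key in df.index else 0.0

    # t0 -> t1 -> t3 is a chain in the default lineage
    assert score("t0", "t1") > score("t0", "t3")
    assert score("t1", "t3") > score("t0", "t3")


def test_candidate_threshold_is_score_over_one(tree_candidates):
    cand = tree_candidates.candidates(1.0)
    assert (cand["score"] > 1.0).all()
    assert len(cand) < len(tree_candidates.table)


def test_true_edges_outrank_non_adjacent(tree_sim, tree_candidates):
    spec, _, _, _ = tree_sim
    df = tree_candidates.table
    truth = true_edge_keys(spec)
    is_true = np.array(
        [tuple(sorted((a, b))) in truth
         for a, b in zip(df["node_a"], df["node_b"])]
    )
    present = {tuple(sorted((a, b)))
               for a, b in zip(df["node_a"], df["node_b"])}
    # every true edge appears among candidates
    assert truth <= present
    assert df[is_true]["score"].min() > df[~is_true]["score"].max()


def test_score_symmetric_and_bounded(tree_candidates):
    df = tree_candidates.table
    assert (df["node_a"] < df["node_b"]).all()  # canonical unordered keys
    assert (df["score"] >= 0).all()
    k = tree_candidates.k
    assert (df["score"] <= 100 * k).all()
    # alternative normalizations emitted for sensitivity analysis
    assert {"n_pairs", "score_min_k"} <= set(df.columns)


def test_small_nodes_excluded_with_warning(two_type_sim):
    _, _, table, _ = two_type_sim
    meta = table.cell_meta.copy()
    meta.loc[meta.index[0], "type_label"] = "singleton_type"
    from ontotree.datatypes import CellTable

    t2 = CellTable(table.counts, meta, table.gene_meta)
    with pytest.warns(UserWarning, match="singleton_type"):
        cand = gb.build_subsystem_candidates(
            t2.subset_cells(np.arange(1200)), k=10
        )
    labels = set(cand.table["node_a"]) | set(cand.table["node_b"])
    assert "singleton_type" not in labels


# ---------------------------------------------------------------------------
# categorize / orient
# ---------------------------------------------------------------------------

def test_synthetic_tree_orientations_recovered(tree_sim, tree_candidates):
    spec, _, _, _ = tree_sim
    edges = gb.categorize_and_orient(tree_candidates.candidates(1.0))
    truth = dict()
    for p, c in spec.true_edges():
        truth[tuple(sorted((p, c)))] = (p, c)
    checked = 0
    for e in edges:
        key = tuple(sorted((e.node_a, e.node_b)))
        if key not in truth:
            continue
        checked += 1
        oriented = (
            (e.node_a, e.node_b) if e.orientation == "a_to_b"
            else (e.node_b, e.node_a) if e.orientation == "b_to_a"
            else None
        )
        assert oriented == truth[key]
        assert e.category == "developmental_progression"
    assert checked >= 6


def test_curation_overrides_and_validates(tree_candidates):
    cand = tree_candidates.candidates(1.0)
    a, b = cand.iloc[0][["node_a", "node_b"]]
    curation = pd.DataFrame(
        [{"node_a": a, "node_b": b, "category": "spatial_continuity",
          "orientation": ""}]
    )
    edges = gb.categorize_and_orient(cand, curation=curation)
    edge = next(e for e in edges if {e.node_a, e.node_b} == {a, b})
    assert edge.category == "spatial_continuity"
    assert edge.orientation == "bidirectional"  # forced for spatial edges
    bad = pd.DataFrame(
        [{"node_a": "nope", "node_b": b, "category": "", "orientation": ""}]
    )
    with pytest.raises(ValueError, match="unknown nodes"):
        gb.categorize_and_orient(cand, curation=bad)


def test_manual_edges_injected(tree_candidates):
    manual = gb.CellTypeEdge(
        node_a="zygote", node_b="t0", n_mnn_pairs=0, normalized_score=0.0,
        orientation="a_to_b",
    )
    edges = gb.categorize_and_orient(tree_candidates.candidates(1.0),
                                     manual_edges=[manual])
    assert any(e.node_a == "zygote" for e in edges)
    g = gb.edges_to_graph(edges, root="zygote")
    assert g.has_edge("zygote", "t0")


# ---------------------------------------------------------------------------
# edge time profiles
# ---------------------------------------------------------------------------

def test_edge_time_profile_no_pairs_all_zero():
    times = np.array([9.0, 9.0, 10.0, 10.0])
    prof = gb.edge_time_profile([], times, [9.0, 10.0])
    assert (prof["pct"] == 0).all()


def test_edge_time_profile_bounds_and_empty_bin_flag(tree_sim,
                                                     tree_candidates):
    _, cfg, table, _ = tree_sim
    times = np.asarray(table.cell_meta["timepoint"], dtype=float)
    cells = tree_candidates.edge_cells[("t0", "t1")]
    prof = gb.edge_time_profile(cells, times, list(cfg.timepoints) + [99.0])
    assert ((prof["pct"] >= 0) & (prof["pct"] <= 100)).all()
    assert prof.iloc[-1]["empty"] and prof.iloc[-1]["pct"] == 0


def test_edge_time_profile_peaks_at_transition(tree_sim, tree_candidates):
    spec, cfg, table, _ = tree_sim
    times = np.asarray(table.cell_meta["timepoint"], dtype=float)
    birth = {t.type_id: t.birth_time for t in spec.types}
    for key in [("t0", "t1"), ("t0", "t2")]:
        prof = gb.edge_time_profile(
            tree_candidates.edge_cells[key], times, cfg.timepoints
        )
        peak_bin = prof.loc[prof["pct"].idxmax(), "bin"]
        assert peak_bin == birth[key[1]]


# ---------------------------------------------------------------------------
# dataset bridging
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def split_datasets():
    """One simulation split in two, with a dataset-specific mean offset
    (a multiplicative depth-like batch effect on a third of the genes)."""
    spec, tps = sd.default_lineage(seed=0)
    cfg = sd.SimConfig(timepoints=tps, cells_per_timepoint=900, seed=4)
    table, _ = sd.simulate_atlas(spec, cfg)
    ds = np.array(
        [int(e.split("_")[-1]) for e in table.cell_meta["embryo_id"]]
    )
    tx = table.subset_cells(ds == 0)
    ty = table.subset_cells(ds == 1)
    rng = np.random.default_rng(0)
    boosted = rng.choice(ty.n_genes, size=ty.n_genes // 3, replace=False)
    counts = ty.counts.tolil()
    counts[:, boosted] = (counts[:, boosted].toarray() * 1.5).round()
    from ontotree.datatypes import CellTable

    ty = CellTable(counts.tocsr(), ty.cell_meta, ty.gene_meta)
    return tx, ty, tps


def test_bridge_datasets_self_matching(split_datasets):
    tx, ty, tps = split_datasets
    edges = gb.bridge_datasets(tx, ty, tps, k=15)
    assert len(edges) > 0
    for e in edges:
        assert e.category == "dataset_equivalence"
        assert e.orientation == "a_to_b"  # forward in time
        assert e.node_a.split("::")[1] == e.node_b.split("::")[1]


def test_bridge_datasets_disjoint_types_no_edges(split_datasets):
    tx, ty, tps = split_datasets
    half_a = tx.subset_cells(
        np.isin(tx.cell_meta["type_label"], ["t0", "t1", "t3"])
    )
    half_b = ty.subset_cells(
        np.isin(ty.cell_meta["type_label"], ["t2", "t6"])
    )
    edges = gb.bridge_datasets(half_a, half_b, tps, k=15)
    assert edges == []


def test_bridge_datasets_empty_gene_intersection(split_datasets):
    tx, ty, tps = split_datasets
    ga = tx.subset_genes(np.arange(0, 100))
    gbb = ty.subset_genes(np.arange(100, 200))
    with pytest.raises(ValueError, match="intersect"):
        gb.bridge_datasets(ga, gbb, tps, k=10)


# ---------------------------------------------------------------------------
# progenitor mapping
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def progenitor_sim():
    spec, tps = sd.progenitor_benchmark_lineage(seed=1)
    cfg = sd.SimConfig(timepoints=tps, cells_per_timepoint=2500, seed=1)
    table, truth = sd.simulate_atlas(spec, cfg)
    return spec, table, truth


def test_map_progenitors_mass_on_true_territory(progenitor_sim):
    _, table, _ = progenitor_sim
    pm = gb.map_progenitors(table, ["D1", "D2"], ["P1", "P2"])
    assert pm.distributions["D1"]["P1"] >= 0.9
    assert pm.distributions["D2"]["P2"] >= 0.9
    for dist in pm.distributions.values():
        assert np.isclose(dist.sum(), 1.0)


def test_map_progenitors_excludes_small_and_unmaps_sparse(progenitor_sim):
    _, table, _ = progenitor_sim
    with pytest.warns(UserWarning, match="excluded"):
        pm = gb.map_progenitors(
            table, ["D1", "D2"], ["P1", "P2"], n_early=10**6
        )
    assert set(pm.excluded) == {"D1", "D2"}
    # an impossible pair threshold leaves every derivative unmapped
    pm2 = gb.map_progenitors(table, ["D1"], ["P1", "P2"],
                             min_pairs=10**6)
    assert pm2.unmapped == ["D1"]
    assert pm2.distributions == {}


def test_graph_output_reproducible(tree_sim):
    _, _, table, _ = tree_sim
    sub = table.subset_cells(np.arange(4000))
    c1 = gb.build_subsystem_candidates(sub, k=15)
    c2 = gb.build_subsystem_candidates(sub, k=15)
    pd.testing.assert_frame_equal(c1.table, c2.table)
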