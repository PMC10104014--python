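"""Four-phase stratification of cell-type transitions and driver nomination.

A directed edge A->B is modeled as a 1->2->3->4 progression:

* group 2 — A-cells participating in inter-node MNN pairs with B;
* group 3 — B-cells participating in those pairs;
* group 1 — within-A MNN partners of group 2 (minus group 2);
* group 4 — within-B MNN partners of group 3 (minus group 3).

Small groups are grown to a minimum size by iteratively adding within-type
MNN partners, which concentrates statistical power on cells proximate to the
transition. Differential expression is then tested on the early (1 vs 2),
inter-node (2 vs 3) and late (3 vs 4) contrasts with a Wilcoxon rank-sum
test on log-normalized values, Benjamini-Hochberg correction, a 10%
detection filter and a |ln fold-change| > 0.25 significance rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import normalize_log
from .datatypes import CellTable, MNNPairSet

__all__ = ["PhaseAssignment", "stratify_phases", "de_test",
           "nominate_edge_genes"]

PHASES = ("early", "internode", "late")


@dataclass
class PhaseAssignment:
    edge: tuple[str, str]
    group1: np.ndarray
    group2: np.ndarray
    group3: np.ndarray
    group4: np.ndarray
    expansion_iterations: dict = field(default_factory=dict)
    exhausted: dict = field(default_factory=dict)

    def groups(self) -> dict[int, np.ndarray]:
        return {1: self.group1, 2: self.group2, 3: self.group3,
                4: self.group4}


def _expand(
    seed_set: set[int],
    partners: list[np.ndarray],
    allowed: np.ndarray,
    exclude: set[int],
    min_group: int,
    rng: np.random.Generator | None = None,
) -> tuple[set[int], int, bool]:
    """Grow ``seed_set`` by within-type MNN partners until >= min_group.

    ``allowed`` is a boolean per-cell mask of the owning cell type; cells in
    ``exclude`` (the sibling group on the same side) are never added. The
    mutual-kNN graph can stall below the target (its transition-region
    component may be small); in that case the group is topped up with a
    seeded uniform sample of the node's unused cells and flagged as
    exhausted. Random fill (rather than any embedding-guided choice) keeps
    the contrast unbiased: selecting cells by position in expression space
    would itself induce differential expression.
    """
    group = set(int(c) for c in seed_set)
    iters = 0
    while len(group) < min_group:
        frontier = set()
        for c in group:
            for p in partners[c]:
                if allowed[p] and p not in group and p not in exclude:
                    frontier.add(int(p))
        if not frontier:
            break
        group |= frontier
        iters += 1
    exhausted = len(group) < min_group
    if exhausted and rng is not None:
        # top up from the type's other MNN-participating cells (seeded
        # uniform sample). Restricting the pool to cells that engage in
        # within-type mutual pairs keeps its selection profile comparable to
        # the MNN-derived groups; admitting arbitrary cells would make the
        # filled group systematically different from its contrast partner
        # even on label-exchangeable data.
        pool = np.array(
            [
                c for c in np.flatnonzero(allowed)
                if c not in group and c not in exclude
                and len(partners[c]) > 0
            ],
            dtype=int,
        )
        need = min(min_group - len(group), pool.size)
        if need > 0:
            pick = rng.choice(pool.size, size=need, replace=False)
            group |= set(int(c) for c in pool[np.sort(pick)])
    return group, iters, exhausted


def stratify_phases(
    edge: tuple[str, str],
    pairs: MNNPairSet,
    table: CellTable,
    min_group: int = 200,
    label_col: str = "type_label",
    seed: int = 0,
) -> PhaseAssignment:
    """Assign cells of an A->B edge to the four transition groups.

    ``seed`` drives the uniform fallback sampling used when MNN expansion
    stalls below ``min_group``.
    """
    a, b = edge
    rng = np.random.default_rng(seed)
    labels = np.asarray(table.cell_meta[label_col], dtype=object)
    in_a = labels == a
    in_b = labels == b
    p = pairs.pairs
    la, lb = labels[p[:, 0]], labels[p[:, 1]]
    inter = ((la == a) & (lb == b)) | ((la == b) & (lb == a))
    if not inter.any():
        raise ValueError(f"edge {edge} has no inter-node MNN pairs")
    inter_cells = np.unique(p[inter])
    g2 = set(int(c) for c in inter_cells if in_a[c])
    g3 = set(int(c) for c in inter_cells if in_b[c])
    partners = pairs.partner_lists(table.n_cells)

    def intra_partners(seed: set[int], allowed: np.ndarray) -> set[int]:
        out = set()
        for c in seed:
            for q in partners[c]:
                if allowed[q]:
                    out.add(int(q))
        return out - seed

    g1 = intra_partners(g2, in_a)
    g4 = intra_partners(g3, in_b)

    iters, exhausted = {}, {}
    g2, iters[2], exhausted[2] = _expand(g2, partners, in_a, set(), min_group,
                                         rng)
    g3, iters[3], exhausted[3] = _expand(g3, partners, in_b, set(), min_group,
                                         rng)
    g1 -= g2
    g4 -= g3
    g1, iters[1], exhausted[1] = _expand(g1, partners, in_a, g2, min_group,
                                         rng)
    g4, iters[4], exhausted[4] = _expand(g4, partners, in_b, g3, min_group,
                                         rng)
    for gi, name in ((1, "group1"), (2, "group2"), (3, "group3"),
                     (4, "group4")):
        if exhausted[gi]:
            warnings.warn(
                f"edge {edge}: {name} MNN expansion stalled before "
                f"{min_group} cells"
            )
    return PhaseAssignment(
        edge=edge,
        group1=np.array(sorted(g1), dtype=int),
        group2=np.array(sorted(g2), dtype=int),
        group3=np.array(sorted(g3), dtype=int),
        group4=np.array(sorted(g4), dtype=int),
        expansion_iterations=iters,
        exhausted=exhausted,
    )


def de_test(
    group_x,
    group_y,
    table: CellTable,
    norm_matrix=None,
    min_detection_frac: float = 0.1,
    lfc_threshold: float = 0.25,
    alpha: float = 0.05,
    scale_target: float = 1e4,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum differential expression between two groups.

    Genes detected in < ``min_detection_frac`` of cells in *both* groups are
    dropped before testing. The log fold-change is computed on the average
    de-logged normalized expression with a pseudocount of 1 (natural-log
    scale): ln((mean_x + 1) / (mean_y + 1)). Significance requires
    |lnFC| > ``lfc_threshold`` and BH-adjusted p < ``alpha``.
    """
    gx = np.asarray(group_x, dtype=int)
    gy = np.asarray(group_y, dtype=int)
    if gx.size == 0 or gy.size == 0:
        raise ValueError("both groups must be non-empty")
    if norm_matrix is None:
        norm_matrix = normalize_log(table, scale_target)
    X = np.asarray(norm_matrix[gx].todense())
    Y = np.asarray(norm_matrix[gy].todense())
    pct_x = (X > 0).mean(axis=0)
    pct_y = (Y > 0).mean(axis=0)
    tested = np.flatnonzero((pct_x >= min_detection_frac)
                            | (pct_y >= min_detection_frac))
    if tested.size == 0:
        return pd.DataFrame(
            columns=["gene", "ln_fc", "p", "p_adj", "pct_x", "pct_y",
                     "direction", "significant"]
        )
    Xs, Ys = X[:, tested], Y[:, tested]
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(Xs, Ys, axis=0, alternative="two-sided",
                                 method="asymptotic")
    p = np.asarray(res.pvalue, dtype=float)
    p = np.nan_to_num(p, nan=1.0)
    mean_x = np.expm1(Xs).mean(axis=0)
    mean_y = np.expm1(Ys).mean(axis=0)
    ln_fc = np.log(mean_x + 1.0) - np.log(mean_y + 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene": table.gene_ids[tested],
            "ln_fc": ln_fc,
            "p": p,
            "p_adj": p_adj,
            "pct_x": pct_x[tested],
            "pct_y": pct_y[tested],
            "direction": np.sign(ln_fc).astype(int),
            "significant": (np.abs(ln_fc) > lfc_threshold) & (p_adj < alpha),
        }
    )
    return out


def nominate_edge_genes(
    edge: tuple[str, str],
    phases: PhaseAssignment,
    table: CellTable,
    tf_list=None,
    norm_matrix=None,
    **de_kwargs,
) -> pd.DataFrame:
    """Phase-resolved DEG/DETF nomination for one edge.

    Runs the three contrasts (1 vs 2, 2 vs 3, 3 vs 4), keeps significant
    genes, ranks within each phase by adjusted p then |lnFC|, marks TFs and
    flags genes nominated exclusively in the early or late phase.
    """
    if tf_list is None:
        if "is_tf" in table.gene_meta.columns:
            tf_set = set(table.gene_ids[np.asarray(table.gene_meta["is_tf"],
                                                   dtype=bool)])
        else:
            warnings.warn("no TF list supplied; DEG output only")
            tf_set = set()
    else:
        tf_set = set(tf_list)
    if norm_matrix is None:
        norm_matrix = normalize_log(table)
    contrasts = {
        "early": (phases.group1, phases.group2),
        "internode": (phases.group2, phases.group3),
        "late": (phases.group3, phases.group4),
    }
    frames = []
    for phase, (gx, gy) in contrasts.items():
        de = de_test(gx, gy, table, norm_matrix=norm_matrix, **de_kwargs)
        de = de[de["significant"]].copy()
        de["phase"] = phase
        frames.append(de)
    nom = pd.concat(frames, ignore_index=True)
    if nom.empty:
        nom = nom.reindex(columns=list(nom.columns) + ["is_tf",
                                                       "exclusive_phase",
                                                       "rank"])
        return nom
    nom["is_tf"] = nom["gene"].isin(tf_set)
    phase_count = nom.groupby("gene")["phase"].transform("nunique")
    nom["exclusive_phase"] = (phase_count == 1) & nom["phase"].isin(
        ["early", "late"]
    )
    nom = nom.sort_values(
        ["phase", "p_adj", "ln_fc"],
        ascending=[True, True, False],
        key=lambda s: s.abs() if s.name == "ln_fc" else s,
    ).reset_index(drop=True)
    nom["rank"] = nom.groupby("phase").cumcount() + 1
    return nom
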