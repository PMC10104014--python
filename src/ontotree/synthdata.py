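"""Seeded synthetic embryo-series data with known ground truth.

The generator emulates the statistical structure the pipeline assumes rather
than embryo biology: cell types are gene programs arranged on a known lineage
tree, each type expressed within a birth window on a developmental time axis;
library sizes are lognormal (median calibrated to ~2,700 UMIs per nucleus);
counts are negative-binomial; transitions are populated by "bridge" cells
whose log-mean program linearly interpolates parent and child; doublets are
sums of two same-timepoint cells thinned to a single library size; designated
"abrupt" types swap in a disjoint program at the final timepoint only.

Every draw flows from a single :class:`numpy.random.Generator` seeded by
``SimConfig.seed``, so identical spec+config give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import CellTable, GrowthModel

__all__ = [
    "TypeSpec",
    "DriverSpec",
    "LineageSpec",
    "SimConfig",
    "TruthLabels",
    "simulate_atlas",
    "simulate_growth_series",
    "default_lineage",
    "two_type_lineage",
    "birth_series_lineage",
]


@dataclass
class TypeSpec:
    """One cell type: its place in the tree, lifetime, and gene program."""

    type_id: str
    parent_id: str | None
    birth_time: float
    death_time: float | None
    program_genes: dict[int, float]
    drift_genes: dict[int, float] = field(default_factory=dict)

    def alive_at(self, t: float) -> bool:
        if t < self.birth_time:
            return False
        return self.death_time is None or t <= self.death_time


@dataclass
class DriverSpec:
    """A planted transition driver gene on one parent->child edge.

    ``phase`` semantics (matching the four-phase transition model):

    * ``early`` — upregulated in parent-side bridge cells (mixing u < 0.5);
    * ``internode`` — upregulated in child-side bridge cells and settled
      child cells;
    * ``late`` — upregulated in settled child cells only.
    """

    gene: int
    parent: str
    child: str
    phase: str
    ln_fc: float

    def __post_init__(self) -> None:
        if self.phase not in ("early", "internode", "late"):
            raise ValueError(f"unknown driver phase {self.phase!r}")


@dataclass
class LineageSpec:
    types: list[TypeSpec]
    n_genes: int
    tf_genes: list[int] = field(default_factory=list)
    bridge_fraction: float = 0.1
    abrupt_types: frozenset = frozenset()
    drivers: list[DriverSpec] = field(default_factory=list)
    baseline_log_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        roots = [t for t in self.types if t.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"exactly one root required, found {len(roots)}")
        by_id = {t.type_id: t for t in self.types}
        if len(by_id) != len(self.types):
            raise ValueError("type ids must be unique")
        for t in self.types:
            if t.parent_id is not None:
                if t.parent_id not in by_id:
                    raise ValueError(f"unknown parent {t.parent_id!r}")
                if t.birth_time < by_id[t.parent_id].birth_time:
                    raise ValueError(
                        f"{t.type_id} born before its parent {t.parent_id}"
                    )
            for g, eff in t.program_genes.items():
                if g >= self.n_genes:
                    raise ValueError(
                        f"program gene {g} exceeds n_genes={self.n_genes}"
                    )
                if eff <= 0:
                    raise ValueError("program effect sizes must be > 0")
        if any(g >= self.n_genes for g in self.tf_genes):
            raise ValueError("tf_genes must be a subset of all genes")
        program_genes = {g for t in self.types for g in t.program_genes}
        for d in self.drivers:
            if d.gene in program_genes:
                raise ValueError(
                    f"driver gene {d.gene} collides with a type program; "
                    "planted effects would be confounded with program "
                    "interpolation"
                )
            if (d.parent, d.child) not in {
                (t.parent_id, t.type_id) for t in self.types
            }:
                raise ValueError(
                    f"driver edge {(d.parent, d.child)} is not a lineage edge"
                )
        unknown = set(self.abrupt_types) - set(by_id)
        if unknown:
            raise ValueError(f"abrupt_types not in lineage: {sorted(unknown)}")
        if self.baseline_log_weights is not None:
            blw = np.asarray(self.baseline_log_weights, dtype=float)
            if blw.shape != (self.n_genes,):
                raise ValueError("baseline_log_weights must have length n_genes")
            self.baseline_log_weights = blw
        self.abrupt_types = frozenset(self.abrupt_types)

    @property
    def root(self) -> TypeSpec:
        return next(t for t in self.types if t.parent_id is None)

    def type_map(self) -> dict[str, TypeSpec]:
        return {t.type_id: t for t in self.types}

    def true_edges(self) -> list[tuple[str, str]]:
        return [
            (t.parent_id, t.type_id) for t in self.types
            if t.parent_id is not None
        ]


@dataclass
class SimConfig:
    timepoints: list[float]
    cells_per_timepoint: int = 2000
    doublet_rate: float = 0.0
    library_size_log_mean: float = float(np.log(2700.0))
    library_size_log_sd: float = 0.35
    nb_dispersion: float = 1.5
    seed: int = 0
    n_embryos_per_timepoint: int = 2
    sex_genes: bool = False
    doublet_mode: str = "random"  # random | heterotypic

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size == 0 or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be non-empty, strictly increasing")
        if not (0 <= self.doublet_rate < 0.5):
            raise ValueError("doublet_rate must be in [0, 0.5)")
        if self.cells_per_timepoint < 1:
            raise ValueError("cells_per_timepoint must be >= 1")
        if self.doublet_mode not in ("random", "heterotypic"):
            raise ValueError(f"unknown doublet_mode {self.doublet_mode!r}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        self.timepoints = [float(t) for t in tp]


@dataclass
class TruthLabels:
    """Ground truth for every simulated cell plus the planted driver table."""

    cells: pd.DataFrame  # true_type, true_is_doublet, source_a/b, true_phase,
    #                      bridge_u, bridge_edge
    drivers: pd.DataFrame  # gene_id, parent, child, phase, ln_fc


def _type_log_weights(spec: LineageSpec) -> dict[str, np.ndarray]:
    base = (
        spec.baseline_log_weights
        if spec.baseline_log_weights is not None
        else np.zeros(spec.n_genes)
    )
    out = {}
    for t in spec.types:
        w = base.copy()
        for g, eff in t.program_genes.items():
            w[g] = base[g] + np.log(eff)
        out[t.type_id] = w
    return out


def _alt_programs(spec: LineageSpec, rng: np.random.Generator) -> dict[str, dict[int, float]]:
    """Disjoint replacement programs for abrupt types (deterministic)."""
    used = set()
    for t in spec.types:
        used |= set(t.program_genes)
    used |= {d.gene for d in spec.drivers}
    free = np.array(sorted(set(range(spec.n_genes)) - used), dtype=int)
    alt = {}
    for tid in sorted(spec.abrupt_types):
        prog = spec.type_map()[tid].program_genes
        if free.size < len(prog):
            raise ValueError("not enough unused genes for abrupt programs")
        pick = rng.choice(free.size, size=len(prog), replace=False)
        genes = free[np.sort(pick)]
        free = np.delete(free, np.sort(pick))
        alt[tid] = dict(zip(genes.tolist(), prog.values()))
    return alt


def simulate_atlas(
    spec: LineageSpec, cfg: SimConfig
) -> tuple[CellTable, TruthLabels]:
    """Simulate a cell-by-gene UMI table for an embryo time series."""
    root_birth = spec.root.birth_time
    if min(cfg.timepoints) < root_birth:
        raise ValueError(
            f"timepoint {min(cfg.timepoints)} precedes root birth {root_birth}"
        )
    rng = np.random.default_rng(cfg.seed)
    type_logw = _type_log_weights(spec)
    alt = _alt_programs(spec, rng) if spec.abrupt_types else {}
    tmap = spec.type_map()
    base = (
        spec.baseline_log_weights
        if spec.baseline_log_weights is not None
        else np.zeros(spec.n_genes)
    )
    final_tp = cfg.timepoints[-1]
    # Expected share of each type's cells that fall on its birth timepoint,
    # given uniform allocation among alive types: the per-cell bridge
    # probability at birth is scaled so that ~bridge_fraction of the type's
    # cells overall are bridges.
    n_alive_at = {
        x: sum(ts.alive_at(x) for ts in spec.types) for x in cfg.timepoints
    }
    bridge_prob = {}
    for ts in spec.types:
        shares = [
            1.0 / n_alive_at[x] for x in cfg.timepoints if ts.alive_at(x)
        ]
        if shares and ts.alive_at(ts.birth_time):
            birth_share = 1.0 / n_alive_at[ts.birth_time]
            bridge_prob[ts.type_id] = min(
                1.0, spec.bridge_fraction * sum(shares) / birth_share
            )
        else:
            bridge_prob[ts.type_id] = 0.0
    child_births = {}  # birth times of children, keyed by parent id
    for t in spec.types:
        if t.parent_id is not None:
            child_births.setdefault(t.parent_id, []).append(t.birth_time)

    blocks, meta_rows, truth_rows = [], [], []
    for t in cfg.timepoints:
        alive = sorted(
            (ts.type_id for ts in spec.types if ts.alive_at(t))
        )
        if not alive:
            raise ValueError(f"no types alive at timepoint {t}")
        n = cfg.cells_per_timepoint
        n_doub = int(round(cfg.doublet_rate * n))
        n_sing = n - n_doub

        assign = rng.integers(0, len(alive), size=n_sing)
        labels = np.array(alive, dtype=object)[assign]
        logW = np.empty((n_sing, spec.n_genes))
        bridge_u = np.full(n_sing, np.nan)
        bridge_edge = np.array([None] * n_sing, dtype=object)
        obs_label = labels.copy()
        for i in range(n_sing):
            tid = labels[i]
            ts = tmap[tid]
            if tid in alt and t == final_tp:
                w = base.copy()
                for g, eff in alt[tid].items():
                    w[g] = base[g] + np.log(eff)
            else:
                w = type_logw[tid].copy()
            if ts.drift_genes:
                for g, rate in ts.drift_genes.items():
                    w[g] = w[g] + rate * (t - ts.birth_time)
            is_bridge = False
            if ts.parent_id is not None and t == ts.birth_time:
                if rng.random() < bridge_prob[tid]:
                    is_bridge = True
                    u = rng.random()
                    w = (1 - u) * type_logw[ts.parent_id] + u * type_logw[tid]
                    bridge_u[i] = u
                    bridge_edge[i] = (ts.parent_id, tid)
                    obs_label[i] = ts.parent_id if u < 0.5 else tid
                    for drv in spec.drivers:
                        if (drv.parent, drv.child) != (ts.parent_id, tid):
                            continue
                        if drv.phase == "early" and u < 0.5:
                            w = w.copy()
                            w[drv.gene] += drv.ln_fc
                        elif drv.phase == "internode" and u >= 0.5:
                            w = w.copy()
                            w[drv.gene] += drv.ln_fc
            if not is_bridge:
                for drv in spec.drivers:
                    if drv.child == tid and drv.phase in ("internode", "late"):
                        w = w.copy()
                        w[drv.gene] += drv.ln_fc
            logW[i] = w

        W = np.exp(logW)
        P = W / W.sum(axis=1, keepdims=True)
        lib = rng.lognormal(
            cfg.library_size_log_mean, cfg.library_size_log_sd, size=n_sing
        )
        mu = lib[:, None] * P
        r = cfg.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int32)

        # doublets: sum of two same-timepoint singlets, thinned to one library
        if n_doub:
            ia = rng.integers(0, n_sing, size=n_doub)
            ib = rng.integers(0, n_sing, size=n_doub)
            if cfg.doublet_mode == "heterotypic" and len(set(alive)) > 1:
                clash = labels[ia] == labels[ib]
            else:
                clash = ia == ib
            while clash.any():
                ib[clash] = rng.integers(0, n_sing, size=int(clash.sum()))
                if cfg.doublet_mode == "heterotypic" and len(set(alive)) > 1:
                    clash = labels[ia] == labels[ib]
                else:
                    clash = ia == ib
            summed = counts[ia] + counts[ib]
            lib_d = rng.lognormal(
                cfg.library_size_log_mean, cfg.library_size_log_sd,
                size=n_doub,
            )
            tot = summed.sum(axis=1).astype(float)
            keep_p = np.minimum(1.0, lib_d / np.maximum(tot, 1.0))
            doub_counts = rng.binomial(summed, keep_p[:, None]).astype(np.int32)
        else:
            ia = ib = np.array([], dtype=int)
            doub_counts = np.empty((0, spec.n_genes), dtype=np.int32)

        block = np.vstack([counts, doub_counts])
        blocks.append(sp.csr_matrix(block))

        embryos = [
            f"emb_{t:g}_{i % cfg.n_embryos_per_timepoint}"
            for i in range(n)
        ]
        for i in range(n_sing):
            tid = labels[i]
            if bridge_edge[i] is not None:
                phase = "bridge"
            elif tid in child_births and t in child_births[tid]:
                phase = "progenitor"
            else:
                phase = "settled"
            meta_rows.append((embryos[i], t, obs_label[i]))
            truth_rows.append(
                (tid, False, None, None, phase, bridge_u[i], bridge_edge[i])
            )
        for j in range(n_doub):
            sa, sb = labels[ia[j]], labels[ib[j]]
            meta_rows.append((embryos[n_sing + j], t, sa))
            truth_rows.append(
                (f"{sa}+{sb}", True, sa, sb, "doublet", np.nan, None)
            )

    counts_all = sp.vstack(blocks).tocsr()
    n_cells = counts_all.shape[0]
    cell_ids = [f"cell_{i:06d}" for i in range(n_cells)]
    cell_meta = pd.DataFrame(
        meta_rows, columns=["embryo_id", "timepoint", "type_label"],
        index=cell_ids,
    )
    cell_meta["ribo_pct"] = np.clip(np.abs(rng.normal(2.0, 1.0, n_cells)), 0, 100)
    cell_meta["mito_pct"] = np.clip(np.abs(rng.normal(4.0, 2.0, n_cells)), 0, 100)

    gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]
    is_tf = np.zeros(spec.n_genes, dtype=bool)
    is_tf[np.asarray(spec.tf_genes, dtype=int)] = True
    gene_meta = pd.DataFrame(
        {"is_tf": is_tf, "biotype": "protein_coding"}, index=gene_ids
    )

    if cfg.sex_genes:
        sexes = {}
        for e in pd.unique(cell_meta["embryo_id"]):
            sexes[e] = "female" if len(sexes) % 2 == 0 else "male"
        fem = cell_meta["embryo_id"].map(sexes).to_numpy() == "female"
        xist = np.where(fem, rng.poisson(5.0, n_cells), 0)
        chry = np.where(
            fem[:, None], 0, rng.poisson(3.0, size=(n_cells, 2))
        )
        extra = sp.csr_matrix(
            np.column_stack([xist, chry]).astype(np.int32)
        )
        counts_all = sp.hstack([counts_all, extra]).tocsr()
        gene_meta = pd.concat(
            [
                gene_meta,
                pd.DataFrame(
                    {"is_tf": False, "biotype": "lincRNA"},
                    index=["Xist", "chrY1", "chrY2"],
                ),
            ]
        )
        cell_meta["true_sex"] = cell_meta["embryo_id"].map(sexes)

    table = CellTable(counts_all, cell_meta, gene_meta)
    truth_cells = pd.DataFrame(
        truth_rows,
        columns=[
            "true_type", "true_is_doublet", "source_a", "source_b",
            "true_phase", "bridge_u", "bridge_edge",
        ],
        index=cell_ids,
    )
    drivers = pd.DataFrame(
        [
            (gene_ids[d.gene], d.parent, d.child, d.phase, d.ln_fc)
            for d in spec.drivers
        ],
        columns=["gene_id", "parent", "child", "phase", "ln_fc"],
    )
    return table, TruthLabels(cells=truth_cells, drivers=drivers)


def simulate_growth_series(
    model: GrowthModel,
    days,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell counts along a day series: log2(count) = cubic(day) + N(0, sd)."""
    days = np.asarray(days, dtype=float)
    if days.size == 0:
        raise ValueError("days must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    log2n = model.log2_cells(days) + rng.normal(0.0, noise_sd, size=days.size)
    return pd.DataFrame({"day": days, "cell_count": 2.0**log2n})


# ---------------------------------------------------------------------------
# canonical study-condition builders
# ---------------------------------------------------------------------------

def _programs(
    rng: np.random.Generator,
    n_types: int,
    n_genes: int,
    program_size: int,
    effect: float,
) -> list[dict[int, float]]:
    """Disjoint per-type gene programs with a fixed effect size."""
    perm = rng.permutation(n_genes)
    if n_types * program_size > n_genes:
        raise ValueError("gene space too small for requested programs")
    return [
        {int(g): effect for g in
         np.sort(perm[i * program_size:(i + 1) * program_size])}
        for i in range(n_types)
    ]


def default_lineage(
    n_genes: int = 2000,
    program_size: int = 30,
    effect: float = 8.0,
    bridge_fraction: float = 0.1,
    baseline_log_sd: float = 1.0,
    seed: int = 0,
) -> tuple[LineageSpec, list[float]]:
    """The canonical 10-type branching lineage over 9 half-day timepoints.

    Each type is alive for 3 consecutive timepoints (E8.5-E12.5 at 0.5-day
    steps, births staggered by tree depth), giving the bridge structure the
    graph heuristic assumes.
    """
    rng = np.random.default_rng(seed)
    parents = [None, "t0", "t0", "t1", "t1", "t2", "t2", "t3", "t4", "t5"]
    depth = [0, 1, 1, 2, 2, 2, 2, 3, 3, 3]
    births = [8.5 + d for d in depth]
    progs = _programs(rng, 10, n_genes, program_size, effect)
    types = []
    for i in range(10):
        death = births[i] + 1.0
        types.append(
            TypeSpec(
                type_id=f"t{i}",
                parent_id=parents[i],
                birth_time=births[i],
                death_time=death,
                program_genes=progs[i],
            )
        )
    all_prog = sorted({g for p in progs for g in p})
    tf_genes = [int(g) for g in rng.choice(all_prog, size=30, replace=False)]
    spec = LineageSpec(
        types=types,
        n_genes=n_genes,
        tf_genes=sorted(tf_genes),
        bridge_fraction=bridge_fraction,
        baseline_log_weights=rng.normal(0.0, baseline_log_sd, n_genes),
    )
    timepoints = [8.5 + 0.5 * i for i in range(9)]
    return spec, timepoints


def two_type_lineage(
    n_genes: int = 1000,
    program_size: int = 40,
    effect: float = 10.0,
    bridge_fraction: float = 0.15,
    driver_phases: list[tuple[str, float]] | None = None,
    baseline_log_sd: float = 1.0,
    seed: int = 0,
) -> tuple[LineageSpec, list[float]]:
    """Two separable types (B branching from A mid-series).

    ``driver_phases`` is a list of (phase, ln_fc) tuples; driver genes are
    assigned deterministically from well-expressed genes outside both
    programs and recorded in ``spec.drivers``.
    """
    rng = np.random.default_rng(seed)
    progs = _programs(rng, 2, n_genes, program_size, effect)
    types = [
        TypeSpec("A", None, 9.0, None, progs[0]),
        TypeSpec("B", "A", 10.0, None, progs[1]),
    ]
    used = set(progs[0]) | set(progs[1])
    baseline = rng.normal(0.0, baseline_log_sd, n_genes)
    free = np.array(sorted(set(range(n_genes)) - used), dtype=int)
    # plant drivers on well-expressed genes (top baseline quartile of the
    # free pool): a driver hidden among dropout zeros has intrinsically
    # bounded rank-test power regardless of its fold change
    cut = np.quantile(baseline[free], 0.75)
    eligible = [int(g) for g in free if baseline[g] >= cut]
    drivers = [
        DriverSpec(gene=eligible[i], parent="A", child="B", phase=phase,
                   ln_fc=ln_fc)
        for i, (phase, ln_fc) in enumerate(driver_phases or [])
    ]
    tf = sorted({d.gene for d in drivers} | set(list(progs[0])[:5]))
    spec = LineageSpec(
        types=types,
        n_genes=n_genes,
        tf_genes=[int(g) for g in tf],
        bridge_fraction=bridge_fraction,
        drivers=drivers,
        baseline_log_weights=baseline,
    )
    timepoints = [9.0, 9.5, 10.0, 10.5, 11.0]
    return spec, timepoints


def null_transition_lineage(
    n_genes: int = 1000,
    program_size: int = 40,
    effect: float = 10.0,
    bridge_fraction: float = 0.4,
    baseline_log_sd: float = 1.0,
    seed: int = 0,
) -> tuple[LineageSpec, list[float]]:
    """Driver-free null for the transition DE calibration: the child type
    shares the parent's program exactly, so the A/B labels partition one
    homogeneous expression distribution and any nomination is a false call."""
    rng = np.random.default_rng(seed)
    prog = _programs(rng, 1, n_genes, program_size, effect)[0]
    types = [
        TypeSpec("A", None, 9.0, None, prog),
        TypeSpec("B", "A", 10.0, None, dict(prog)),
    ]
    spec = LineageSpec(
        types=types,
        n_genes=n_genes,
        tf_genes=[],
        bridge_fraction=bridge_fraction,
        baseline_log_weights=rng.normal(0.0, baseline_log_sd, n_genes),
    )
    return spec, [9.0, 9.5, 10.0, 10.5, 11.0]


def doublet_benchmark_lineage(
    n_genes: int = 1000,
    program_size: int = 40,
    effect: float = 10.0,
    baseline_log_sd: float = 1.0,
    seed: int = 0,
) -> tuple[LineageSpec, list[float]]:
    """Two well-separated types coexisting at every timepoint, no bridges —
    the benchmark background for heterotypic doublet spiking."""
    rng = np.random.default_rng(seed)
    progs = _programs(rng, 2, n_genes, program_size, effect)
    types = [
        TypeSpec("A", None, 9.0, None, progs[0]),
        TypeSpec("B", "A", 9.0, None, progs[1]),
    ]
    spec = LineageSpec(
        types=types,
        n_genes=n_genes,
        tf_genes=[],
        bridge_fraction=0.0,
        baseline_log_weights=rng.normal(0.0, baseline_log_sd, n_genes),
    )
    return spec, [9.0, 9.5, 10.0, 10.5, 11.0]


def progenitor_benchmark_lineage(
    n_genes: int = 1500,
    program_size: int = 30,
    effect: float = 8.0,
    bridge_fraction: float = 0.35,
    baseline_log_sd: float = 1.0,
    seed: int = 0,
) -> tuple[LineageSpec, list[float]]:
    """Two progenitor territories, each spawning one derivative type.

    Sized so each derivative has >= 500 cells in its birth bin, most of them
    transition (bridge) cells — the regime the earliest-cells MNN mapping
    assumes (a derivative whose early cells sit on the path from its
    territory of origin).
    """
    rng = np.random.default_rng(seed)
    progs = _programs(rng, 4, n_genes, program_size, effect)
    types = [
        TypeSpec("P1", None, 8.5, None, progs[0]),
        TypeSpec("P2", "P1", 8.5, None, progs[1]),
        TypeSpec("D1", "P1", 9.5, None, progs[2]),
        TypeSpec("D2", "P2", 9.5, None, progs[3]),
    ]
    spec = LineageSpec(
        types=types,
        n_genes=n_genes,
        tf_genes=[],
        bridge_fraction=bridge_fraction,
        baseline_log_weights=rng.normal(0.0, baseline_log_sd, n_genes),
    )
    return spec, [8.5, 9.0, 9.5, 10.0, 10.5]


def birth_series_lineage(
    n_genes: int = 1200,
    program_size: int = 40,
    effect: float = 8.0,
    drift_rate: float = 0.15,
    seed: int = 0,
) -> tuple[LineageSpec, list[float]]:
    """Two coexisting types for the birth analysis: one switches its program
    abruptly at the final timepoint, the other only drifts slowly."""
    rng = np.random.default_rng(seed)
    progs = _programs(rng, 2, n_genes, program_size, effect)
    drift_genes = {g: drift_rate for g in list(progs[1])[:20]}
    types = [
        TypeSpec("abrupt", None, 16.0, None, progs[0]),
        TypeSpec("drift", "abrupt", 16.0, None, progs[1],
                 drift_genes=drift_genes),
    ]
    spec = LineageSpec(
        types=types,
        n_genes=n_genes,
        tf_genes=[],
        bridge_fraction=0.0,
        abrupt_types=frozenset({"abrupt"}),
        baseline_log_weights=rng.normal(0.0, 1.0, n_genes),
    )
    timepoints = [16.0, 16.5, 17.0, 17.5, 18.0, 18.5, 19.0, 19.5]
    return spec, timepoints
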