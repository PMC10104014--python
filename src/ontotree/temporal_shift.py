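"""Abrupt temporal-shift detection and whole-embryo growth modeling.

Two neighbour-based statistics quantify how sharply a cell type's
transcriptional state moves across consecutive timepoints:

* timepoint purity — for each cell, the proportion of its k nearest
  neighbours (in a per-type PCA embedding) that come from a *different*
  timepoint. Averaged per timepoint; a low value at one timepoint flags an
  abrupt shift (the cells of that timepoint neighbour only each other).
* timepoint correlation — Pearson r between each cell's timepoint and the
  mean timepoint of its k nearest neighbours in a global embedding; high r
  means rapid, synchronized change.

Growth modeling fits log2 cell number to a cubic in embryonic day and
derives a doubling time from the fitted proliferation rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import embed_table, knn, _knn_search
from .datatypes import CellTable, GrowthModel

__all__ = [
    "PurityResult",
    "timepoint_purity",
    "timepoint_correlation",
    "fit_growth",
    "predict_cells",
    "doubling_time",
]


@dataclass
class PurityResult:
    eligible: bool
    reason: str | None
    per_timepoint: pd.DataFrame | None  # timepoint, frac_other_timepoint, n
    k: int | None = None
    n_downsampled: int | None = None


def timepoint_purity(
    table: CellTable,
    cell_type: str | None = None,
    min_cells: int = 200,
    min_pre_final_timepoints: int = 5,
    n_hvg: int = 2500,
    d: int = 30,
    seed: int = 0,
) -> PurityResult:
    """Mean proportion of k-NN from a different timepoint, per timepoint.

    Eligibility mirrors the birth analysis: at least ``min_cells`` at the
    final timepoint and at ``min_pre_final_timepoints`` earlier timepoints.
    Timepoints with >= ``min_cells`` are downsampled (seeded) to the median
    selected size; k = round(log2(median size)), floored at 2.
    """
    if cell_type is not None:
        table = table.subset_cells(
            np.asarray(table.cell_meta["type_label"]) == cell_type
        )
    times = np.asarray(table.cell_meta["timepoint"], dtype=float)
    if times.size == 0:
        return PurityResult(False, "no cells", None)
    uniq, counts = np.unique(times, return_counts=True)
    final = uniq[-1]
    if counts[-1] < min_cells:
        return PurityResult(
            False, f"fewer than {min_cells} cells at final timepoint", None
        )
    n_pre = int(((counts[:-1] >= min_cells)).sum())
    if n_pre < min_pre_final_timepoints:
        return PurityResult(
            False,
            f"only {n_pre} pre-final timepoints with >= {min_cells} cells",
            None,
        )
    selected = uniq[counts >= min_cells]
    med = int(np.median(counts[counts >= min_cells]))
    rng = np.random.default_rng(seed)
    keep = []
    for t in selected:
        idx = np.flatnonzero(times == t)
        if idx.size > med:
            idx = np.sort(rng.choice(idx, size=med, replace=False))
        keep.append(idx)
    keep = np.concatenate(keep)
    sub = table.subset_cells(keep)
    sub_times = times[keep]
    k = max(2, int(round(np.log2(med))))
    emb = embed_table(sub, n_hvg=n_hvg, d=d)
    graph = knn(emb, k)
    other = (sub_times[graph.indices] != sub_times[:, None]).mean(axis=1)
    if selected.size == 1:
        other[:] = 0.0  # single timepoint: no foreign neighbours by definition
    per_tp = (
        pd.DataFrame({"timepoint": sub_times, "frac_other_timepoint": other})
        .groupby("timepoint", as_index=False)
        .agg(frac_other_timepoint=("frac_other_timepoint", "mean"))
    )
    per_tp["n"] = [int((sub_times == t).sum()) for t in per_tp["timepoint"]]
    return PurityResult(True, None, per_tp, k=k, n_downsampled=med)


def timepoint_correlation(
    embedding,
    times,
    groups,
    k: int = 10,
) -> pd.Series:
    """Per-group Pearson r of (own timepoint, mean k-NN timepoint).

    Neighbours are searched in the global embedding (all cells); groups with
    fewer than k+1 cells or zero time variance yield NaN.
    """
    coords = embedding.coords if hasattr(embedding, "coords") else np.asarray(
        embedding, dtype=float
    )
    times = np.asarray(times, dtype=float)
    groups = np.asarray(groups)
    if np.unique(times).size < 2:
        raise ValueError("need at least 2 distinct timepoints")
    nb, _ = _knn_search(coords, coords, min(k, coords.shape[0] - 1),
                        exclude_self_offset=0)
    nb_time = times[nb].mean(axis=1)
    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() < k + 1:
            out[g] = np.nan
            continue
        t = times[mask]
        m = nb_time[mask]
        if np.std(t) == 0 or np.std(m) == 0:
            out[g] = np.nan
            continue
        out[g] = float(stats.pearsonr(t, m)[0])
    return pd.Series(out, name="timepoint_correlation")


def fit_growth(days, cell_counts) -> GrowthModel:
    """OLS cubic fit of log2 cell number against embryonic day."""
    days = np.asarray(days, dtype=float)
    counts = np.asarray(cell_counts, dtype=float)
    if days.size != counts.size:
        raise ValueError("days and cell_counts disagree in length")
    if days.size < 5:
        raise ValueError("need at least 5 points for a cubic fit")
    if np.any(counts <= 0):
        raise ValueError("cell counts must be positive")
    y = np.log2(counts)
    coef = np.polyfit(days, y, deg=3)
    pred = np.polyval(coef, days)
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    n, p = days.size, 3
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return GrowthModel(
        a3=float(coef[0]), a2=float(coef[1]), a1=float(coef[2]),
        a0=float(coef[3]), adj_r2=adj_r2,
        day_range=(float(days.min()), float(days.max())),
    )


def predict_cells(model: GrowthModel, day) -> np.ndarray | float:
    """Predicted whole-embryo cell number, 2^cubic(day)."""
    import warnings

    day_arr = np.asarray(day, dtype=float)
    if model.day_range is not None:
        lo, hi = model.day_range
        if np.any(day_arr < lo) or np.any(day_arr > hi):
            warnings.warn(
                f"day outside fitted range [{lo}, {hi}]; extrapolating"
            )
    out = 2.0 ** model.log2_cells(day_arr)
    return float(out) if np.isscalar(day) else out


def doubling_time(model: GrowthModel, day) -> float:
    """Hours for the embryo to double its cell number at ``day``.

    The log2-scaled proliferation rate is the derivative of the growth
    polynomial, p(day) = 3 a3 day^2 + 2 a2 day + a1; doubling time is
    24 x 2 / 2^p(day). Non-positive rates give an undefined (NaN) time.
    """
    d = float(day)
    p = 3 * model.a3 * d**2 + 2 * model.a2 * d + model.a1
    if p <= 0:
        return float("nan")
    return 24.0 * 2.0 / (2.0**p)
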