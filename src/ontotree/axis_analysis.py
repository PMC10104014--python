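"""PC-feature correlation and cross-compartment sign-concordance tests.

A feature (gene or covariate such as somite count) is "significantly
associated" with a principal component when its Pearson correlation lies
outside mean +/- 1 SD of all correlations for that PC *and* its BH-adjusted
p-value is below 0.05. Signed significant gene lists from two compartments
are then compared by overlap and sign concordance with a one-cell chi-square
goodness-of-fit test against a stated null fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pc_feature_correlation",
    "ConcordanceResult",
    "concordance_test",
    "ReplicationResult",
    "replication_check",
]


def _pearson_with_p(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Pearson r of X against y, with two-sided t-test p-values."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = Xc.std(axis=0)
    sy = yc.std()
    denom = sx * sy * n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return r, p


def pc_feature_correlation(
    embedding,
    features,
    pcs,
    feature_ids=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate features with selected PCs and flag significant ones.

    ``features`` is a cells x features matrix (log-normalized, optionally
    scaled, expression — Pearson r is scale-invariant — or covariates);
    ``pcs`` are 0-based PC indices into the embedding. Constant features are
    excluded from testing. Returns one row per (feature, pc) with r, p,
    BH-adjusted p, sign and the mean+/-1SD + FDR significance flag.
    """
    coords = embedding.coords if hasattr(embedding, "coords") else np.asarray(
        embedding, dtype=float
    )
    X = np.asarray(
        features.todense() if sp.issparse(features) else features, dtype=float
    )
    if X.ndim == 1:
        X = X[:, None]
    if feature_ids is None:
        feature_ids = (
            list(features.columns)
            if isinstance(features, pd.DataFrame)
            else [f"f{i}" for i in range(X.shape[1])]
        )
    feature_ids = np.asarray(feature_ids, dtype=object)
    keep = X.std(axis=0) > 0
    X = X[:, keep]
    feature_ids = feature_ids[keep]
    rows = []
    for pc in pcs:
        y = coords[:, pc]
        r, p = _pearson_with_p(X, y)
        p_adj = multipletests(p, method="fdr_bh")[1]
        mean_r, sd_r = r.mean(), r.std()
        outlying = (r < mean_r - sd_r) | (r > mean_r + sd_r)
        sig = outlying & (p_adj < alpha)
        rows.append(
            pd.DataFrame(
                {
                    "feature": feature_ids,
                    "pc": pc,
                    "r": r,
                    "p": p,
                    "p_adj": p_adj,
                    "sign": np.sign(r).astype(int),
                    "significant": sig,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


@dataclass
class ConcordanceResult:
    n_overlap: int
    n_concordant: int
    concordant_fraction: float
    chi2_statistic: float | None
    p: float | None
    null_fraction: float

    def __post_init__(self) -> None:
        if self.n_concordant > self.n_overlap:
            raise ValueError("n_concordant cannot exceed n_overlap")


def _as_sign_map(signed_list) -> dict:
    if isinstance(signed_list, pd.DataFrame):
        return dict(zip(signed_list.iloc[:, 0], np.sign(signed_list.iloc[:, 1])))
    if isinstance(signed_list, pd.Series):
        return {g: np.sign(v) for g, v in signed_list.items()}
    return {g: np.sign(v) for g, v in dict(signed_list).items()}


def concordance_test(
    signed_list_a,
    signed_list_b,
    null_fraction: float = 0.5,
) -> ConcordanceResult:
    """Overlap two signed gene lists and test sign concordance.

    The chi-square is a one-cell goodness-of-fit of the concordant count
    against ``null_fraction x n_overlap``. An empty overlap yields an
    undefined test (statistic and p are None).
    """
    if not (0 < null_fraction < 1):
        raise ValueError("null_fraction must be in (0, 1)")
    a = _as_sign_map(signed_list_a)
    b = _as_sign_map(signed_list_b)
    shared = sorted(set(a) & set(b))
    n = len(shared)
    if n == 0:
        return ConcordanceResult(0, 0, 0.0, None, None, null_fraction)
    conc = sum(1 for g in shared if a[g] == b[g] and a[g] != 0)
    expected = np.array([null_fraction * n, (1 - null_fraction) * n])
    observed = np.array([conc, n - conc])
    chi2, p = stats.chisquare(observed, expected)
    return ConcordanceResult(
        n_overlap=n,
        n_concordant=conc,
        concordant_fraction=conc / n,
        chi2_statistic=float(chi2),
        p=float(p),
        null_fraction=null_fraction,
    )


@dataclass
class ReplicationResult:
    n_tested: int
    n_replicating: int
    fraction: float
    n_missing: int
    null_fraction: float
    chi2_statistic: float | None
    p: float | None


def replication_check(
    discovery_signs,
    replication_table: pd.DataFrame,
    null_fraction: float = 0.25,
) -> ReplicationResult:
    """Fraction of discovery genes whose direction replicates in BOTH contexts.

    ``replication_table`` is indexed by gene with one column per context
    holding the mean-expression difference on the replication data. A gene
    replicates iff the sign of its difference matches the discovery sign in
    every context; with two independent contexts the chance level is 0.25.
    Genes absent from the table are excluded but counted.
    """
    signs = _as_sign_map(discovery_signs)
    contexts = list(replication_table.columns)
    if len(contexts) < 1:
        raise ValueError("replication table needs at least one context column")
    tested, replicating, missing = 0, 0, 0
    for g, s in signs.items():
        if g not in replication_table.index:
            missing += 1
            continue
        tested += 1
        row = replication_table.loc[g]
        if all(np.sign(row[c]) == s and s != 0 for c in contexts):
            replicating += 1
    if tested == 0:
        return ReplicationResult(0, 0, 0.0, missing, null_fraction, None, None)
    expected = np.array(
        [null_fraction * tested, (1 - null_fraction) * tested]
    )
    observed = np.array([replicating, tested - replicating])
    chi2, p = stats.chisquare(observed, expected)
    return ReplicationResult(
        n_tested=tested,
        n_replicating=replicating,
        fraction=replicating / tested,
        n_missing=missing,
        null_fraction=null_fraction,
        chi2_statistic=float(chi2),
        p=float(p),
    )
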