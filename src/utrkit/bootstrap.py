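"""Bootstrap isoform-usage statistics.

Implements the two-sample, cell-resampling bootstrap tests for differential
3'UTR isoform usage: the UTR index (UI, a single flagged isoform's
expression fraction), the weighted UTR index (WUI, positional-rank-weighted
mean of isoform fractions; for two-isoform genes the fraction on the longest
isoform), and the Wasserstein distance (WD, half the L1 distance between
isoform fraction vectors -- the earth-mover distance on the ordered isoform
set). Statistics are computed on pseudobulk (counts summed over the cells of
each resampled group). Columns of the count matrix must be ordered 5'->3'
within each gene.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import sparse

from .models import CellCountMatrix

MODES = ("ui", "wui", "wd")


def positional_weights(n_isoforms: int) -> np.ndarray:
    """Positional-rank weights scaled to the unit interval.

    weight_i = (i-1)/(n-1) for i = 1..n: {0,1} for two isoforms,
    {0, 1/2, 1} for three, {0, 1/3, 2/3, 1} for four.
    """
    if n_isoforms < 2:
        raise ValueError("positional weights require at least two isoforms")
    return np.arange(n_isoforms, dtype=float) / (n_isoforms - 1)


def wui(counts: np.ndarray, weights: Optional[np.ndarray] = None) -> float:
    """Weighted UTR index of one gene's isoform counts (5'->3' order)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return float("nan")
    if weights is None:
        weights = positional_weights(counts.size)
    return float(counts @ weights / total)


def isoform_statistic(
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    mode: str = "wui",
    feature_index: Optional[np.ndarray] = None,
    weights: Optional[np.ndarray] = None,
) -> float:
    """Difference statistic between two isoform count/TPM profiles.

    UI: difference in the flagged isoform's expression fraction.
    WUI: difference in weighted mean of expression fractions.
    WD: half the total absolute difference in expression fractions.
    Returns NaN when either profile has zero total (gene skipped).
    """
    mode = mode.lower()
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must cover the same ordered isoform set")
    ta, tb = a.sum(), b.sum()
    if ta == 0 or tb == 0:
        return float("nan")
    fa, fb = a / ta, b / tb
    if mode == "wd":
        return float(0.5 * np.abs(fa - fb).sum())
    if mode == "ui":
        if feature_index is None:
            raise ValueError("UI mode requires a feature_index flag vector")
        w = np.asarray(feature_index, dtype=float)
    else:
        w = np.asarray(weights, dtype=float) if weights is not None else positional_weights(a.size)
    return float(w @ fa - w @ fb)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaNs propagate)."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(ranked, 1.0)
    q[ok] = qv
    return q


def _gene_structure(ccm: CellCountMatrix):
    genes = pd.unique(ccm.gene_ids)
    gene_index = {g: i for i, g in enumerate(genes)}
    col_gene = np.array([gene_index[g] for g in ccm.gene_ids])
    n_iso = np.bincount(col_gene, minlength=len(genes))
    # positional rank of each column within its gene (columns are 5'->3')
    rank = np.zeros(ccm.n_isoforms, dtype=float)
    seen: dict[int, int] = {}
    for j, gi in enumerate(col_gene):
        rank[j] = seen.get(gi, 0)
        seen[gi] = seen.get(gi, 0) + 1
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(n_iso[col_gene] > 1, rank / np.maximum(n_iso[col_gene] - 1, 1), 0.0)
    G = sparse.csr_matrix(
        (np.ones(ccm.n_isoforms), (np.arange(ccm.n_isoforms), col_gene)),
        shape=(ccm.n_isoforms, len(genes)),
    )
    return genes, col_gene, n_iso, w, G


def _resolve_feature_index(ccm, feature_index) -> np.ndarray:
    if feature_index is None:
        raise ValueError("UI mode requires feature_index")
    if isinstance(feature_index, Mapping):
        flagged = set(feature_index.values()) if not all(
            isinstance(v, (int, np.integer)) for v in feature_index.values()
        ) else {k for k, v in feature_index.items() if v}
        return np.array([iso in flagged for iso in ccm.isoform_ids], dtype=float)
    arr = np.asarray(feature_index, dtype=float)
    if arr.size != ccm.n_isoforms:
        raise ValueError("feature_index must flag each isoform column")
    return arr


def two_sample_bootstrap_test(
    ccm: CellCountMatrix,
    group_a: str,
    group_b: str,
    mode: str = "wui",
    n_boot: int = 1000,
    min_cells_per_gene: int = 50,
    seed: int = 0,
    feature_index=None,
) -> pd.DataFrame:
    """Two-sample bootstrap test per gene between two cell groups.

    Under the null that both groups are samples from one population, cells
    are resampled with replacement from the union of the two groups into
    pseudo-groups of the original sizes (the same bootstrap cell indices are
    shared across genes). The statistic (pseudobulk UI/WUI difference or WD)
    is recomputed per bootstrap; the two-sided p-value is

        p = (1 + #{b valid : |T_b| >= |T_obs|}) / (1 + B_valid)

    where a bootstrap sample is valid for a gene when both pseudo-groups
    contain at least ``min_cells_per_gene`` cells expressing the gene.
    Genes whose *observed* groups fail that minimum are not tested; genes
    with zero valid bootstraps get NaN p. q-values are BH-adjusted across
    tested genes.
    """
    mode = mode.lower()
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    idx_a = ccm.cells_in_group(group_a)
    idx_b = ccm.cells_in_group(group_b)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("both groups must contain cells")
    na, nb = idx_a.size, idx_b.size
    union = np.concatenate([idx_a, idx_b])
    X = ccm.counts[union]
    nU = na + nb
    genes, col_gene, n_iso, w, G = _gene_structure(ccm)
    n_genes = len(genes)
    if X.shape[1] * max(n_boot, 1) <= 50_000_000:
        X = np.asarray(X.todense(), dtype=np.float64)
        dense = True
    else:  # pragma: no cover - large-input fallback
        X = X.tocsr().astype(np.float64)
        dense = False

    if mode == "ui":
        w = _resolve_feature_index(ccm, feature_index)
    Gw = G.multiply(w[:, None]).tocsr()

    # per-cell gene expression indicator for the validity filter
    gene_counts_cells = X @ G if dense else (X @ G).toarray()
    E = (np.asarray(gene_counts_cells) > 0).astype(np.float64)

    def group_stats(counts_rows):
        tot = np.asarray(counts_rows @ G)
        wgt = np.asarray(counts_rows @ Gw)
        return tot, wgt

    obs_a = X[:na].sum(axis=0, keepdims=True) if dense else np.asarray(X[:na].sum(axis=0))
    obs_b = X[na:].sum(axis=0, keepdims=True) if dense else np.asarray(X[na:].sum(axis=0))

    def statistic(counts_a, counts_b):
        ta, wa = group_stats(counts_a)
        tb, wb = group_stats(counts_b)
        with np.errstate(invalid="ignore", divide="ignore"):
            if mode == "wd":
                fa = counts_a / np.maximum(ta[:, col_gene], 1e-300)
                fb = counts_b / np.maximum(tb[:, col_gene], 1e-300)
                stat = 0.5 * np.asarray(np.abs(fa - fb) @ G)
            else:
                stat = wa / ta - wb / tb
        bad = (ta == 0) | (tb == 0)
        stat = np.where(bad, np.nan, stat)
        return stat

    t_obs = statistic(np.asarray(obs_a), np.asarray(obs_b)).ravel()

    expr_a = E[:na].sum(axis=0)
    expr_b = E[na:].sum(axis=0)
    testable = (
        (expr_a >= min_cells_per_gene)
        & (expr_b >= min_cells_per_gene)
        & (n_iso >= 2)
        & ~np.isnan(t_obs)
    )

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, nU, size=(n_boot, nU))
    rows = np.repeat(np.arange(n_boot), na)
    Sa = sparse.csr_matrix(
        (np.ones(n_boot * na), (rows, draws[:, :na].ravel())), shape=(n_boot, nU)
    )
    rows = np.repeat(np.arange(n_boot), nb)
    Sb = sparse.csr_matrix(
        (np.ones(n_boot * nb), (rows, draws[:, na:].ravel())), shape=(n_boot, nU)
    )
    boot_a = np.asarray(Sa @ X)
    boot_b = np.asarray(Sb @ X)
    t_boot = statistic(boot_a, boot_b)  # (n_boot, n_genes)

    nexpr_a = np.asarray(Sa @ E)
    nexpr_b = np.asarray(Sb @ E)
    valid = (nexpr_a >= min_cells_per_gene) & (nexpr_b >= min_cells_per_gene)
    valid &= ~np.isnan(t_boot)

    abs_obs = np.abs(t_obs)[None, :]
    extreme = valid & (np.abs(np.where(valid, t_boot, 0.0)) >= abs_obs)
    n_valid = valid.sum(axis=0)
    n_extreme = extreme.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (1.0 + n_extreme) / (1.0 + n_valid)
    p = np.where(testable & (n_valid > 0), p, np.nan)

    res = pd.DataFrame(
        {
            "gene_id": genes,
            "statistic": mode.upper(),
            "observed": t_obs,
            "p": p,
            "n_bootstraps_retained": np.where(testable, n_valid, 0),
            "tested": testable & (n_valid > 0),
        }
    )
    res["q"] = bh_adjust(res["p"].to_numpy())
    return res


def bootstrap_percentile_ci(
    ccm: CellCountMatrix,
    group: str,
    statistic: str = "wui",
    n_boot: int = 2000,
    levels: tuple[float, float] = (0.025, 0.975),
    seed: int = 0,
) -> pd.DataFrame:
    """Percentile bootstrap confidence intervals per gene for one cell group.

    statistic 'tpm': the mean over cells of per-cell gene TPM (UMIs per
    million per cell). statistic 'wui': the pseudobulk WUI (counts summed
    over the resampled cells first). 2000 resamples by default.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    statistic = statistic.lower()
    idx = ccm.cells_in_group(group)
    if idx.size == 0:
        raise ValueError(f"no cells in group {group!r}")
    X = np.asarray(ccm.counts[idx].todense(), dtype=float)
    genes, col_gene, n_iso, w, G = _gene_structure(ccm)
    Gw = G.multiply(w[:, None]).tocsr()
    n = idx.size
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n, size=(n_boot, n))
    rows = np.repeat(np.arange(n_boot), n)
    S = sparse.csr_matrix((np.ones(n_boot * n), (rows, draws.ravel())), shape=(n_boot, n))
    if statistic == "tpm":
        cell_tot = X.sum(axis=1, keepdims=True)
        gene_cells = np.asarray(X @ G)
        with np.errstate(invalid="ignore", divide="ignore"):
            tpm_cells = np.where(cell_tot > 0, gene_cells / cell_tot * 1e6, 0.0)
        stat = np.asarray(S @ tpm_cells) / n
    elif statistic == "wui":
        tot = np.asarray((S @ X) @ G)
        wgt = np.asarray((S @ X) @ Gw)
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = np.where(tot > 0, wgt / tot, np.nan)
    else:
        raise ValueError("statistic must be 'tpm' or 'wui'")
    lo = np.nanpercentile(stat, levels[0] * 100, axis=0)
    hi = np.nanpercentile(stat, levels[1] * 100, axis=0)
    expressed = np.asarray((X @ G) > 0).sum(axis=0) > 0
    return pd.DataFrame(
        {"gene_id": genes, "lo": np.where(expressed, lo, np.nan),
         "hi": np.where(expressed, hi, np.nan), "expressed": expressed}
    )
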