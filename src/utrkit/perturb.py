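"""Perturbation-screen 3'UTR analysis.

From per-perturbation pseudobulk WUI/TPM matrices and a set of non-targeting
controls this module derives dWUI effect matrices (deviation of each
perturbation's WUI from the cell-count-weighted non-targeting baseline),
z-scales and imputes them, clusters perturbations and response genes
(PCA -> kNN graph -> walktrap communities over several rounds), tests
clusters for differential 3'UTR length and expression (Mann-Whitney),
classifies isoform-specific vs compensatory regulation, quantifies
cross-cluster target overlap, validates clusters against replicate
perturbations, correlates effects with gene features, and fits first-order
decay kinetics to metabolic-labeling conversion rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import igraph as ig
import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .bootstrap import bh_adjust
from .models import HalfLifeFit


@dataclass
class EffectMatrix:
    """Perturbation x gene dWUI effects with baseline metadata."""

    dwui: pd.DataFrame  # perturbations x genes, NaN where missing
    baseline_wui: pd.Series
    cell_counts: pd.Series
    avg_dwui: pd.Series
    avg_dipa: Optional[pd.Series] = None
    zdwui: Optional[pd.DataFrame] = None
    zero_variance_rows: list = field(default_factory=list)


@dataclass
class CompensationRecord:
    gene_id: str
    cluster_id: str
    tpm_su_cluster: float
    tpm_lu_cluster: float
    tpm_su_control: float
    tpm_lu_control: float
    dtpm_su: float
    dtpm_lu: float
    category: Optional[str]  # SU-specific | coordinated | LU-specific | None


def _weighted_mean(values: pd.DataFrame, weights: pd.Series) -> pd.Series:
    w = weights.reindex(values.index).astype(float)
    mask = values.notna()
    wsum = mask.mul(w, axis=0).sum(axis=0)
    return values.mul(w, axis=0).sum(axis=0, skipna=True) / wsum


def compute_effects(
    wui: pd.DataFrame,
    tpm: pd.DataFrame,
    cell_counts: pd.Series,
    non_targeting: Sequence[str],
    ipa: Optional[pd.DataFrame] = None,
    tpm_min: float = 5.0,
    wui_band: tuple[float, float] = (0.1, 0.9),
    min_cells: int = 30,
) -> EffectMatrix:
    """Per-perturbation dWUI effects relative to the non-targeting baseline.

    ``wui`` and ``tpm`` are perturbation x gene pseudobulk matrices. The
    baseline WUI per gene is the mean over non-targeting perturbations
    weighted by their cell counts. Perturbations with fewer than
    ``min_cells`` cells are dropped. The per-perturbation average dWUI (and
    dIPA when an IPA-fraction matrix is supplied) is taken over genes with
    control mean TPM > ``tpm_min`` and baseline value inside ``wui_band``.
    """
    nt = [p for p in non_targeting if p in wui.index]
    if not nt:
        raise ValueError("no non-targeting perturbations present")
    keep = cell_counts.reindex(wui.index).fillna(0) >= min_cells
    baseline = _weighted_mean(wui.loc[nt], cell_counts)
    dwui = wui.loc[keep].sub(baseline, axis=1)

    control_tpm = tpm.loc[nt].mean(axis=0)
    gene_ok = (control_tpm > tpm_min) & baseline.between(*wui_band)
    avg_dwui = dwui.loc[:, gene_ok].mean(axis=1, skipna=True)

    avg_dipa = None
    if ipa is not None:
        ipa_baseline = _weighted_mean(ipa.loc[[p for p in nt if p in ipa.index]],
                                      cell_counts)
        dipa = ipa.loc[ipa.index.intersection(dwui.index)].sub(ipa_baseline, axis=1)
        ipa_ok = (control_tpm.reindex(ipa.columns) > tpm_min) & ipa_baseline.between(*wui_band)
        avg_dipa = dipa.loc[:, ipa_ok].mean(axis=1, skipna=True)

    return EffectMatrix(
        dwui=dwui,
        baseline_wui=baseline,
        cell_counts=cell_counts.reindex(dwui.index),
        avg_dwui=avg_dwui,
        avg_dipa=avg_dipa,
    )


def zscale_impute(
    effects: EffectMatrix,
    control_tpm: Optional[pd.Series] = None,
    detect_frac: Optional[pd.Series] = None,
    max_missing_frac: float = 0.20,
    min_control_tpm: float = 20.0,
) -> pd.DataFrame:
    """z-scaled dWUI matrix with missing effects imputed as exactly zero.

    Gene filters (applied before scaling): at most ``max_missing_frac`` of
    cells non-detecting (``detect_frac`` = detected fraction per gene, when
    available) and control TPM >= ``min_control_tpm``. Each perturbation row
    is divided by its uncentered standard deviation (root mean square) so
    the variance about zero is scaled to 1 without centering -- the center
    is already fixed by the non-targeting baseline. Zero-variance rows are
    left as zeros and flagged on the EffectMatrix.
    """
    dwui = effects.dwui
    cols = dwui.columns
    if control_tpm is not None:
        cols = cols[control_tpm.reindex(cols) >= min_control_tpm]
    if detect_frac is not None:
        cols = cols[(1.0 - detect_frac.reindex(cols)) <= max_missing_frac]
    mat = dwui.loc[:, cols].fillna(0.0)
    rms = np.sqrt((mat**2).mean(axis=1))
    effects.zero_variance_rows = list(mat.index[rms == 0])
    z = mat.div(rms.replace(0.0, np.nan), axis=0).fillna(0.0)
    effects.zdwui = z
    return z


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def knn_walktrap(
    points: np.ndarray,
    n_pcs: int = 30,
    k: int = 5,
    walk_steps: int = 4,
    symmetrize: str = "union",
) -> np.ndarray:
    """Cluster rows of ``points`` by PCA -> kNN graph -> walktrap communities.

    Uses at most min(n_samples, n_features) principal components, an
    unweighted k-nearest-neighbor graph (union symmetrization by default;
    'mutual' keeps only reciprocated edges), and walktrap community
    detection with ``walk_steps``-step random walks cut at the
    modularity-optimal level.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)
    n_pcs_eff = min(n_pcs, n - 1, points.shape[1])
    if n_pcs_eff >= 1 and points.shape[1] > n_pcs_eff:
        points = PCA(n_components=n_pcs_eff, svd_solver="full").fit_transform(points)
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(points)
    _, nbr = nn.kneighbors(points)
    edges = set()
    for i in range(n):
        for j in nbr[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    if symmetrize == "mutual":
        mutual = set()
        nbr_sets = [set(int(j) for j in nbr[i, 1:]) for i in range(n)]
        for a, b in edges:
            if a in nbr_sets[b] and b in nbr_sets[a]:
                mutual.add((a, b))
        # keep every vertex attached to its nearest neighbor
        for i in range(n):
            j = int(nbr[i, 1])
            mutual.add((min(i, j), max(i, j)))
        edges = mutual
    g = ig.Graph(n=n, edges=sorted(edges))
    communities = g.community_walktrap(steps=walk_steps).as_clustering()
    return np.asarray(communities.membership, dtype=int)


DEFAULT_ROUNDS = (
    {"axis": "perturbations", "n_pcs": 30, "k": 5, "drop_patternless": True},
    {"axis": "genes", "n_pcs": 30, "k": 4, "drop_patternless": True},
    {"axis": "both", "n_pcs": 30, "k": 3, "drop_patternless": False},
)


@dataclass
class ClusterRounds:
    rounds: list
    perturbation_labels: pd.Series
    gene_labels: Optional[pd.Series]
    retained_perturbations: list
    retained_genes: list


def cluster_perturbations(
    zdwui: pd.DataFrame,
    rounds: Sequence[Mapping] = DEFAULT_ROUNDS,
    patternless_quantile: float = 0.25,
    symmetrize: str = "union",
) -> ClusterRounds:
    """Multi-round clustering of the z-scaled effect matrix.

    Each round reduces one axis (perturbation rows or gene columns) to
    principal components, clusters it with kNN + walktrap, and -- in rounds
    flagged ``drop_patternless`` -- removes clusters whose dispersion (mean
    |zdWUI| over their members) falls strictly below the
    ``patternless_quantile`` quantile of cluster dispersions, the
    quantitative proxy for visually flat response patterns. The final round
    returns perturbation (and, for axis 'both', gene) cluster labels.
    """
    if zdwui.size == 0:
        raise ValueError("empty effect matrix")
    mat = zdwui.copy()
    history = []
    pert_labels = pd.Series(0, index=mat.index)
    gene_labels: Optional[pd.Series] = None
    for spec in rounds:
        axis = spec.get("axis", "perturbations")
        todo = ["perturbations", "genes"] if axis == "both" else [axis]
        round_record = {"axis": axis}
        for ax in todo:
            points = mat.to_numpy() if ax == "perturbations" else mat.to_numpy().T
            ids = mat.index if ax == "perturbations" else mat.columns
            labels = knn_walktrap(
                points, n_pcs=spec.get("n_pcs", 30), k=spec.get("k", 5),
                symmetrize=symmetrize,
            )
            labels = pd.Series(labels, index=ids)
            if spec.get("drop_patternless", False):
                disp = {}
                for c in sorted(labels.unique()):
                    members = labels.index[labels == c]
                    sub = mat.loc[members] if ax == "perturbations" else mat[members]
                    disp[c] = float(np.abs(sub.to_numpy()).mean())
                cutoff = np.quantile(list(disp.values()), patternless_quantile)
                keep_clusters = [c for c, d in disp.items() if d >= cutoff]
                keep_ids = labels.index[labels.isin(keep_clusters)]
                if ax == "perturbations":
                    mat = mat.loc[keep_ids]
                else:
                    mat = mat[keep_ids]
                labels = labels.loc[keep_ids]
            if ax == "perturbations":
                pert_labels = labels
            else:
                gene_labels = labels
            round_record[ax] = labels
        history.append(round_record)
    return ClusterRounds(
        rounds=history,
        perturbation_labels=pert_labels,
        gene_labels=gene_labels,
        retained_perturbations=list(mat.index),
        retained_genes=list(mat.columns),
    )


# ---------------------------------------------------------------------------
# Cluster-level tests
# ---------------------------------------------------------------------------

def cluster_diff_tests(
    wui: pd.DataFrame,
    tpm: pd.DataFrame,
    cluster_labels: pd.Series,
    non_targeting: Sequence[str],
    tpm_min: float = 5.0,
    q_threshold: float = 0.05,
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """Per-cluster differential 3'UTR length and expression tables.

    For each gene and cluster, a two-sided Mann-Whitney test compares the
    per-perturbation WUI values of the cluster members against the
    non-targeting perturbations (genes pass when the non-targeting or the
    cluster mean TPM exceeds ``tpm_min``); direction is the sign of the mean
    dWUI. DGE is analogous on TPM with the additional |FC| > ``fc_threshold``
    requirement. BH correction is applied per cluster and per test family.
    """
    nt = [p for p in non_targeting if p in wui.index]
    rows = []
    for cluster in sorted(cluster_labels.unique()):
        members = [p for p in cluster_labels.index[cluster_labels == cluster]
                   if p in wui.index]
        if len(members) < 2 or len(nt) < 2:
            continue
        for gene in wui.columns:
            nt_tpm = tpm.loc[nt, gene].mean()
            cl_tpm = tpm.loc[members, gene].mean()
            if not (nt_tpm > tpm_min or cl_tpm > tpm_min):
                continue
            x = wui.loc[members, gene].dropna()
            y = wui.loc[nt, gene].dropna()
            dul_p = _mannwhitney_p(x, y)
            xg = tpm.loc[members, gene].dropna()
            yg = tpm.loc[nt, gene].dropna()
            dge_p = _mannwhitney_p(xg, yg)
            fc = (cl_tpm + 1e-12) / (nt_tpm + 1e-12)
            rows.append({
                "cluster": cluster, "gene_id": gene,
                "dwui": x.mean() - y.mean(),
                "dul_p": dul_p,
                "direction": "lengthening" if x.mean() >= y.mean() else "shortening",
                "fc": fc, "dge_p": dge_p,
            })
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    res["dul_q"] = np.nan
    res["dge_q"] = np.nan
    for cluster in res["cluster"].unique():
        m = res["cluster"] == cluster
        res.loc[m, "dul_q"] = bh_adjust(res.loc[m, "dul_p"].to_numpy())
        res.loc[m, "dge_q"] = bh_adjust(res.loc[m, "dge_p"].to_numpy())
    res["dul_sig"] = res["dul_q"] < q_threshold
    res["dge_sig"] = (res["dge_q"] < q_threshold) & (
        (res["fc"] > fc_threshold) | (res["fc"] < 1.0 / fc_threshold)
    )
    return res


def _mannwhitney_p(x: pd.Series, y: pd.Series) -> float:
    if len(x) < 2 or len(y) < 2:
        return np.nan
    if x.nunique() == 1 and y.nunique() == 1 and x.iloc[0] == y.iloc[0]:
        return 1.0  # all tied
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def compensation_classify(
    gene_id: str,
    cluster_id: str,
    tpm_cluster: float,
    wui_cluster: float,
    tpm_control: float,
    wui_control: float,
    ratio_bounds: tuple[float, float] = (-2.0, -0.5),
) -> CompensationRecord:
    """Classify a two-isoform DUL gene as SU-specific / coordinated / LU-specific.

    Isoform TPMs come from gene TPM and WUI: TPM_SU = TPM * (1 - WUI),
    TPM_LU = TPM * WUI. Regulation is coordinated (compensatory) when the
    isoform TPM changes satisfy lower <= dTPM_LU / dTPM_SU <= upper with the
    inclusive bounds (-2, -0.5): at least half the expression gained by one
    isoform is lost by the other. Otherwise the category is the isoform with
    the larger absolute TPM change; no change in either isoform yields None.
    """
    tpm_su_cl = tpm_cluster * (1.0 - wui_cluster)
    tpm_lu_cl = tpm_cluster * wui_cluster
    tpm_su_ct = tpm_control * (1.0 - wui_control)
    tpm_lu_ct = tpm_control * wui_control
    dsu = tpm_su_cl - tpm_su_ct
    dlu = tpm_lu_cl - tpm_lu_ct
    lo, hi = ratio_bounds
    if dsu == 0 and dlu == 0:
        category = None
    elif dsu == 0:
        category = "LU-specific"
    else:
        ratio = dlu / dsu
        if lo <= ratio <= hi:
            category = "coordinated"
        else:
            category = "SU-specific" if abs(dsu) >= abs(dlu) else "LU-specific"
    return CompensationRecord(
        gene_id=gene_id, cluster_id=cluster_id,
        tpm_su_cluster=tpm_su_cl, tpm_lu_cluster=tpm_lu_cl,
        tpm_su_control=tpm_su_ct, tpm_lu_control=tpm_lu_ct,
        dtpm_su=dsu, dtpm_lu=dlu, category=category,
    )


def cluster_overlap(
    gene_sets: Mapping[tuple[str, str], set],
    universe: set,
) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric enrichment) overlap between cluster
    target-gene sets.

    ``gene_sets`` maps (cluster, direction) with direction in
    {shortening, lengthening} to a gene set. Same-direction pairs are
    synergistic; opposite-direction pairs antagonistic. p = P(X >= overlap)
    for X hypergeometric over the universe.
    """
    n_universe = len(universe)
    keys = sorted(gene_sets)
    rows = []
    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            if ka[0] == kb[0]:
                continue
            a = gene_sets[ka] & universe
            b = gene_sets[kb] & universe
            overlap = len(a & b)
            if not a or not b:
                p = 1.0
            else:
                p = float(stats.hypergeom.sf(overlap - 1, n_universe, len(a), len(b)))
            rows.append({
                "cluster_a": ka[0], "direction_a": ka[1],
                "cluster_b": kb[0], "direction_b": kb[1],
                "type": "synergistic" if ka[1] == kb[1] else "antagonistic",
                "overlap": overlap,
                "p": p,
                "neg_log10_p": -np.log10(max(p, 1e-300)),
            })
    return pd.DataFrame(rows)


def validate_replicates(
    cluster_avg_zdwui: Mapping[str, pd.Series],
    replicate_zdwui: pd.DataFrame,
    replicate_cluster: Mapping[str, str],
    nt_zdwui: pd.DataFrame,
    significant_genes: Optional[Mapping[str, Iterable[str]]] = None,
) -> pd.DataFrame:
    """Replicate validation: correlations of replicate effects with the
    cluster-average profile, against a non-targeting control distribution.

    For each cluster, Pearson correlations are computed between the
    cluster-average profile (restricted to that cluster's significant
    response genes when given) and every replicating perturbation, and
    likewise for every non-targeting control; a one-sided Mann-Whitney tests
    whether replicate correlations exceed the controls. BH across clusters.
    """
    rows = []
    for cluster, avg in cluster_avg_zdwui.items():
        genes = list(avg.index)
        if significant_genes is not None:
            genes = [g for g in genes if g in set(significant_genes.get(cluster, genes))]
        if len(genes) < 2:
            rows.append({"cluster": cluster, "p": np.nan, "n_replicates": 0,
                         "median_replicate_r": np.nan, "median_control_r": np.nan})
            continue
        a = avg[genes].to_numpy()
        reps = [p for p, c in replicate_cluster.items()
                if c == cluster and p in replicate_zdwui.index]
        rep_r = [_pearson(a, replicate_zdwui.loc[p, genes].to_numpy()) for p in reps]
        ctl_r = [_pearson(a, nt_zdwui.loc[p, genes].to_numpy()) for p in nt_zdwui.index]
        rep_r = [r for r in rep_r if not np.isnan(r)]
        ctl_r = [r for r in ctl_r if not np.isnan(r)]
        if len(rep_r) >= 1 and len(ctl_r) >= 1:
            p = float(stats.mannwhitneyu(rep_r, ctl_r, alternative="greater").pvalue)
        else:
            p = np.nan
        rows.append({
            "cluster": cluster, "p": p, "n_replicates": len(rep_r),
            "median_replicate_r": float(np.median(rep_r)) if rep_r else np.nan,
            "median_control_r": float(np.median(ctl_r)) if ctl_r else np.nan,
        })
    res = pd.DataFrame(rows)
    res["q"] = bh_adjust(res["p"].to_numpy())
    return res


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def feature_correlation(
    mean_dwui: pd.DataFrame,
    features: pd.DataFrame,
    control_tpm: Optional[pd.Series] = None,
    tpm_min: float = 5.0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of per-gene mean dWUI with numeric gene features.

    ``mean_dwui`` is clusters x genes; ``features`` is genes x features.
    Genes are filtered to control TPM > ``tpm_min`` when supplied. BH is
    applied within each feature across clusters. Constant features give NaN.
    """
    genes = mean_dwui.columns.intersection(features.index)
    if control_tpm is not None:
        genes = genes[control_tpm.reindex(genes) > tpm_min]
    rows = []
    for feat in features.columns:
        fvals = features.loc[genes, feat].astype(float)
        for cluster in mean_dwui.index:
            d = mean_dwui.loc[cluster, genes].astype(float)
            ok = fvals.notna() & d.notna()
            if ok.sum() < 3 or fvals[ok].std() == 0 or d[ok].std() == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(d[ok], fvals[ok])
            rows.append({"cluster": cluster, "feature": feat,
                         "r": float(r) if r == r else np.nan,
                         "p": float(p) if p == p else np.nan})
    res = pd.DataFrame(rows)
    res["q"] = np.nan
    for feat in res["feature"].unique():
        m = res["feature"] == feat
        res.loc[m, "q"] = bh_adjust(res.loc[m, "p"].to_numpy())
    res["significant"] = res["q"] < q_threshold
    return res


# ---------------------------------------------------------------------------
# Decay kinetics
# ---------------------------------------------------------------------------

def fit_half_life(
    timepoints: Sequence[float],
    rates: np.ndarray,
    weights: Optional[np.ndarray] = None,
    isoform_id: str = "isoform",
) -> HalfLifeFit:
    """First-order kinetics fit of labeling conversion rates.

    ``rates`` may be (replicates, timepoints); the mean conversion rate per
    timepoint is then the read-count-weighted mean over replicates. The
    model c(t) = c_max * (1 - exp(-k t)) is fit by least squares, with the
    plateau c_max a free parameter initialized just above the largest
    observed rate; half-life = ln(2)/k in the timepoint units (minutes for
    the standard 0/120/240/360 design).
    """
    t = np.asarray(timepoints, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if rates.ndim == 2:
        if weights is not None:
            weights = np.asarray(weights, dtype=float)
            c = np.average(rates, axis=0, weights=weights)
        else:
            c = rates.mean(axis=0)
    else:
        c = rates
    if t.size < 3:
        raise ValueError("need at least three timepoints")
    if np.all(c <= 0):
        return HalfLifeFit(isoform_id, 0.0, np.inf, 0.0, 0.0, False,
                           note="zero conversion throughout")
    increasing = bool(np.all(np.diff(c) >= -1e-12))

    def model(tt, c_max, k):
        return c_max * (1.0 - np.exp(-k * tt))

    c_max0 = float(c.max()) * 1.05
    k0 = 1.0 / max(t[t > 0].min(), 1.0)
    try:
        (c_max, k), _ = optimize.curve_fit(
            model, t, c, p0=(c_max0, k0),
            bounds=((1e-12, 1e-9), (np.inf, np.inf)), maxfev=10_000,
        )
    except RuntimeError:
        return HalfLifeFit(isoform_id, np.nan, np.nan, np.nan, np.nan, False,
                           note="fit did not converge")
    half_life = float(np.log(2.0) / k)
    residual = float(np.sqrt(np.mean((model(t, c_max, k) - c) ** 2)))
    note = ""
    reliable = increasing
    if not increasing:
        note = "non-increasing conversion"
    second_tp = np.sort(t[t > 0])[0] if (t > 0).any() else np.inf
    if half_life < second_tp:
        reliable = False
        note = (note + "; " if note else "") + "saturated before second timepoint"
    return HalfLifeFit(isoform_id, float(k), half_life, float(c_max), residual,
                       reliable, note=note)
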