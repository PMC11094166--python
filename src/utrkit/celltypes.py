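"""Gene classification and differential-expression-vs-3'UTR-length analyses.

Genes are classified as single- or multi-UTR from the number of last-exon
isoforms that reach a minimum expression fraction in at least one cell type,
and as IPA genes from intronic-polyadenylation isoform usage. Differential
gene expression (DGE, Welch t-test on log-normalized per-cell counts) is
contrasted with differential 3'UTR length (DUL, bootstrap WUI test) through
a chi-square independence test on the joint significance tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bootstrap import bh_adjust
from .models import CellCountMatrix


@dataclass
class GeneClassification:
    gene_id: str
    utr_class: Optional[str]  # single | multi | None (unclassified)
    n_qualifying_isoforms: int
    is_ipa_gene: bool = False
    switching: Optional[bool] = None
    dominant_isoforms: Optional[dict] = None


def _fractions_per_celltype(pseudobulk: pd.DataFrame, gene_ids: Sequence[str],
                            keep: np.ndarray) -> dict[str, pd.DataFrame]:
    """Per-gene expression fractions per cell type over the kept isoforms."""
    out = {}
    gene_arr = np.asarray(gene_ids, dtype=object)
    for gene in pd.unique(gene_arr[keep]):
        cols = np.flatnonzero((gene_arr == gene) & keep)
        sub = pseudobulk.iloc[:, cols]
        totals = sub.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = sub.div(totals, axis=0)
        out[gene] = frac
    return out


def classify_utr_genes(
    pseudobulk: pd.DataFrame,
    gene_ids: Sequence[str],
    is_ipa: Sequence[bool],
    threshold: float = 0.10,
) -> pd.DataFrame:
    """Single/multi-UTR classification from per-cell-type pseudobulk counts.

    A qualifying isoform is a last-exon (non-IPA) isoform reaching at least
    ``threshold`` of the gene's 3'UTR counts in at least one cell type
    (inclusive). Genes with >= 2 qualifying isoforms are multi-UTR. Genes
    with no counts anywhere are unclassified.
    """
    is_ipa = np.asarray(is_ipa, dtype=bool)
    fracs = _fractions_per_celltype(pseudobulk, gene_ids, ~is_ipa)
    rows = []
    gene_arr = np.asarray(gene_ids, dtype=object)
    for gene in pd.unique(gene_arr):
        frac = fracs.get(gene)
        if frac is None or frac.isna().all().all():
            rows.append({"gene_id": gene, "utr_class": None, "n_qualifying_isoforms": 0})
            continue
        qualifying = int(((frac >= threshold).any(axis=0)).sum())
        rows.append({
            "gene_id": gene,
            "utr_class": "multi" if qualifying >= 2 else "single",
            "n_qualifying_isoforms": qualifying,
        })
    return pd.DataFrame(rows)


def classify_ipa_genes(
    pseudobulk: pd.DataFrame,
    gene_ids: Sequence[str],
    is_ipa: Sequence[bool],
    threshold: float = 0.10,
) -> pd.DataFrame:
    """Flag genes whose IPA isoforms reach ``threshold`` of all gene 3'-end
    reads in at least one cell type (all 3' ends of the unit included)."""
    is_ipa = np.asarray(is_ipa, dtype=bool)
    gene_arr = np.asarray(gene_ids, dtype=object)
    rows = []
    for gene in pd.unique(gene_arr):
        cols = np.flatnonzero(gene_arr == gene)
        sub = pseudobulk.iloc[:, cols]
        totals = sub.sum(axis=1)
        ipa_cols = [c for c in range(len(cols)) if is_ipa[cols[c]]]
        flag = False
        if ipa_cols:
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = sub.iloc[:, ipa_cols].div(totals, axis=0)
            flag = bool((frac >= threshold).any().any())
        rows.append({"gene_id": gene, "is_ipa_gene": flag})
    return pd.DataFrame(rows)


def dominant_switching(
    pseudobulk: pd.DataFrame,
    gene_ids: Sequence[str],
    is_ipa: Sequence[bool],
    cells_per_celltype: Mapping[str, int],
    min_cells: int = 200,
    min_tpm: float = 5.0,
) -> pd.DataFrame:
    """Dominant-isoform switching across cell types for multi-UTR genes.

    Cell types with fewer than ``min_cells`` cells are excluded; a gene is
    evaluated only in cell types where its total non-IPA expression exceeds
    ``min_tpm`` (UMIs per million). The dominant isoform is the highest
    expression fraction (ties resolved toward the more 3' isoform); a gene
    switches when dominants differ across qualifying cell types. Genes with
    fewer than two qualifying cell types get a null switching flag.
    """
    is_ipa = np.asarray(is_ipa, dtype=bool)
    big = [ct for ct in pseudobulk.index if cells_per_celltype.get(ct, 0) >= min_cells]
    pb = pseudobulk.loc[big]
    lib = pb.sum(axis=1)
    gene_arr = np.asarray(gene_ids, dtype=object)
    rows = []
    for gene in pd.unique(gene_arr):
        cols = np.flatnonzero((gene_arr == gene) & ~is_ipa)
        if cols.size < 2:
            rows.append({"gene_id": gene, "switching": None, "dominant": {}})
            continue
        sub = pb.iloc[:, cols]
        with np.errstate(invalid="ignore", divide="ignore"):
            tpm = sub.sum(axis=1) / lib * 1e6
        qualifying = tpm[tpm > min_tpm].index
        if len(qualifying) < 2:
            rows.append({"gene_id": gene, "switching": None, "dominant": {}})
            continue
        dominants = {}
        for ct in qualifying:
            vals = sub.loc[ct].to_numpy()
            # ties toward the more 3' isoform: last argmax
            j = int(np.flatnonzero(vals == vals.max())[-1])
            dominants[ct] = sub.columns[j]
        rows.append({
            "gene_id": gene,
            "switching": bool(len(set(dominants.values())) > 1),
            "dominant": dominants,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Differential gene expression (Welch) and DGE vs DUL independence
# ---------------------------------------------------------------------------

def welch_t(a: np.ndarray, b: np.ndarray):
    """Welch t statistic with Welch-Satterthwaite df and two-sided p.

    Vectorized over the last axis being samples; degenerate zero-variance
    cases resolve to p = 1 for equal means and p = 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ma, mb = a.mean(axis=-1), b.mean(axis=-1)
    va = a.var(axis=-1, ddof=1)
    vb = b.var(axis=-1, ddof=1)
    na, nb = a.shape[-1], b.shape[-1]
    se2 = va / na + vb / nb
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (va**2 / (na**2 * (na - 1)) + vb**2 / (nb**2 * (nb - 1)))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_var = se2 == 0
    if np.ndim(t) == 0:
        if zero_var:
            return 0.0 if ma == mb else np.inf, np.nan, 1.0 if ma == mb else 0.0
        return float(t), float(df), float(p)
    eq = zero_var & (ma == mb)
    ne = zero_var & (ma != mb)
    with np.errstate(invalid="ignore"):
        t = np.where(eq, 0.0, np.where(ne, np.inf * np.sign(ma - mb), t))
    p = np.where(eq, 1.0, np.where(ne, 0.0, p))
    return t, df, p


def size_factors_library(ccm: CellCountMatrix) -> np.ndarray:
    """Per-cell library-size factors normalized to mean 1."""
    lib = np.asarray(ccm.counts.sum(axis=1)).ravel().astype(float)
    mean = lib[lib > 0].mean() if (lib > 0).any() else 1.0
    sf = lib / mean
    sf[sf == 0] = 1.0
    return sf


def dge_welch(
    ccm: CellCountMatrix,
    group_a: str,
    group_b: str,
    size_factors: Optional[np.ndarray] = None,
    fc_threshold: float = 1.5,
    q_threshold: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene Welch t-test on log2 size-factor-normalized counts.

    Counts are summed to the gene level per cell, divided by the cell's size
    factor, and transformed log2(x + pseudocount). The fold change is
    computed from the de-logged group means; a gene is significant when the
    fold change exceeds ``fc_threshold`` in either direction and the BH
    q-value is below ``q_threshold``.
    """
    if size_factors is None:
        size_factors = size_factors_library(ccm)
    genes = pd.unique(ccm.gene_ids)
    gene_index = {g: i for i, g in enumerate(genes)}
    col_gene = np.array([gene_index[g] for g in ccm.gene_ids])
    from scipy import sparse as _sp
    G = _sp.csr_matrix(
        (np.ones(ccm.n_isoforms), (np.arange(ccm.n_isoforms), col_gene)),
        shape=(ccm.n_isoforms, len(genes)),
    )
    gene_counts = np.asarray((ccm.counts @ G).todense(), dtype=float)
    norm = gene_counts / np.asarray(size_factors)[:, None]
    logn = np.log2(norm + pseudocount)
    ia = ccm.cells_in_group(group_a)
    ib = ccm.cells_in_group(group_b)
    if ia.size < 2 or ib.size < 2:
        raise ValueError("need at least two cells per group")
    t, df, p = welch_t(logn[ia].T, logn[ib].T)
    log2fc = logn[ia].mean(axis=0) - logn[ib].mean(axis=0)
    fc = 2.0**log2fc
    q = bh_adjust(p)
    sig = ((fc > fc_threshold) | (fc < 1.0 / fc_threshold)) & (q < q_threshold)
    return pd.DataFrame({
        "gene_id": genes, "t": t, "df": df, "log2FC": log2fc, "FC": fc,
        "dge_p": p, "dge_q": q, "dge_sig": sig,
    })


def categorize_diff(diff: pd.DataFrame) -> pd.Series:
    """Partition genes into none / DGE-only / DUL-only / both."""
    dge = diff["dge_sig"].astype(bool)
    dul = diff["dul_sig"].astype(bool)
    cat = np.select(
        [dge & dul, dge & ~dul, ~dge & dul],
        ["both", "DGE-only", "DUL-only"],
        default="none",
    )
    return pd.Series(cat, index=diff.index, name="category")


def independence_test(table: np.ndarray) -> dict:
    """Chi-square independence test on a 2x2 significance tabulation.

    Reports the Yates-corrected test (the 2x2 default) alongside the
    uncorrected statistic; any zero margin yields NaN with a flag.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return {"chi2": np.nan, "p": np.nan, "chi2_uncorrected": np.nan,
                "p_uncorrected": np.nan, "table": table, "valid": False}
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    chi2_u, p_u, _, _ = stats.chi2_contingency(table, correction=False)
    return {"chi2": chi2, "p": p, "chi2_uncorrected": chi2_u,
            "p_uncorrected": p_u, "table": table, "valid": True}


def dge_dul_independence(diff: pd.DataFrame) -> dict:
    """Independence of DGE and DUL significance across coexpressed genes."""
    dge = diff["dge_sig"].astype(bool)
    dul = diff["dul_sig"].astype(bool)
    table = np.array([
        [(dge & dul).sum(), (dge & ~dul).sum()],
        [(~dge & dul).sum(), (~dge & ~dul).sum()],
    ])
    return independence_test(table)


def minor_isoform_dominance(records: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Fraction of two-UTR genes whose larger fold change hits the
    lower-abundance isoform.

    ``records`` carries, per significant two-UTR gene, the isoform
    abundance fractions in the cell type of lower gene expression
    (frac_iso1, frac_iso2) and the absolute log fold changes (lfc_iso1,
    lfc_iso2). Genes whose two isoforms are exactly equally abundant are
    excluded as ties. Returns (fraction, per-gene table); the fraction is
    NaN when no genes qualify.
    """
    required = {"gene_id", "frac_iso1", "frac_iso2", "lfc_iso1", "lfc_iso2"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    rows = []
    for r in records.itertuples(index=False):
        if r.frac_iso1 == r.frac_iso2:
            continue  # tie in abundance: excluded
        big_lfc_iso = 1 if abs(r.lfc_iso1) >= abs(r.lfc_iso2) else 2
        lower_iso = 1 if r.frac_iso1 < r.frac_iso2 else 2
        rows.append({"gene_id": r.gene_id, "counted": big_lfc_iso == lower_iso})
    detail = pd.DataFrame(rows, columns=["gene_id", "counted"])
    frac = float(detail["counted"].mean()) if len(detail) else float("nan")
    return frac, detail


def isoform_fold_change_records(
    ccm: CellCountMatrix,
    group_a: str,
    group_b: str,
    genes: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Build minor_isoform_dominance inputs from pseudobulk TPM of two groups."""
    pb = ccm.pseudobulk()
    tpm = pb.div(pb.sum(axis=1), axis=0) * 1e6
    gene_arr = np.asarray(ccm.gene_ids, dtype=object)
    rows = []
    for gene in genes:
        cols = np.flatnonzero(gene_arr == gene)
        if cols.size != 2:
            continue
        a = tpm.loc[group_a].iloc[cols].to_numpy()
        b = tpm.loc[group_b].iloc[cols].to_numpy()
        lower_group_vals = a if a.sum() < b.sum() else b
        tot = lower_group_vals.sum()
        f = lower_group_vals / tot if tot > 0 else np.array([0.5, 0.5])
        lfc = np.log2((a + pseudocount) / (b + pseudocount))
        rows.append({
            "gene_id": gene, "frac_iso1": f[0], "frac_iso2": f[1],
            "lfc_iso1": lfc[0], "lfc_iso2": lfc[1],
        })
    return pd.DataFrame(rows, columns=["gene_id", "frac_iso1", "frac_iso2",
                                       "lfc_iso1", "lfc_iso2"])
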