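"""Synthetic fixture generation.

The generators emulate the inputs the toolkit consumes in production:
a toy multi-gene, multi-isoform annotation with genome sequence; 3'-end
reads with gamma-distributed distance from the CS; and cell-level isoform
count matrices with planted weighted-UTR-index (WUI) values and expression
levels, drawn from a Dirichlet-multinomial around the target isoform
fractions.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .models import CellCountMatrix, TranscriptModel


def wui_fractions(wui: float, n_isoforms: int) -> np.ndarray:
    """Isoform fraction vector (5'->3' order) with the requested WUI.

    For two isoforms this is (1-w, w). For more isoforms the mass is
    interpolated between the two positional ranks bracketing the target so
    the positional-rank-weighted mean equals ``wui`` exactly.
    """
    if not 0.0 <= wui <= 1.0:
        raise ValueError("target WUI must lie in [0, 1]")
    if n_isoforms < 2:
        raise ValueError("need at least two isoforms")
    weights = np.arange(n_isoforms) / (n_isoforms - 1)
    frac = np.zeros(n_isoforms)
    hi = int(np.searchsorted(weights, wui))
    if weights[hi] == wui:
        frac[hi] = 1.0
        return frac
    lo = hi - 1
    t = (wui - weights[lo]) / (weights[hi] - weights[lo])
    frac[lo], frac[hi] = 1.0 - t, t
    return frac


def generate_fixture(
    n_genes: int,
    groups: Mapping[str, Mapping],
    isoforms_per_gene: int = 2,
    overdispersion: float = 0.0,
    seed: int = 0,
) -> tuple[CellCountMatrix, pd.DataFrame]:
    """Cell x isoform UMI counts with planted WUI and expression levels.

    ``groups`` maps a group label to a spec with keys:

    n_cells
        number of cells in the group;
    wui
        target WUI, scalar or per-gene array (mutually exclusive with
        ``fractions``);
    fractions
        explicit per-gene isoform fraction matrix (n_genes, isoforms);
    mean_counts
        mean UMIs per cell per gene (scalar or per-gene), Poisson distributed.

    Per cell and gene, the total count is Poisson(mean_counts) and the
    isoform split is multinomial around the target fractions; with
    ``overdispersion`` > 0 the per-cell fractions are first drawn from a
    Dirichlet with concentration ``fractions / overdispersion``
    (biological cell-to-cell variability in isoform usage).

    Returns the count matrix and a ground-truth table with the planted WUI
    and mean expression per (group, gene).
    """
    rng = np.random.default_rng(seed)
    k = isoforms_per_gene
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    iso_ids = [f"{g}.iso{j}" for g in gene_ids for j in range(k)]
    iso_gene = [g for g in gene_ids for _ in range(k)]
    weights = np.arange(k) / (k - 1)

    blocks = []
    barcodes: list[str] = []
    labels: list[str] = []
    truth_rows = []
    for group, spec in groups.items():
        n_cells = int(spec["n_cells"])
        mean_counts = np.broadcast_to(
            np.asarray(spec.get("mean_counts", 20.0), dtype=float), (n_genes,)
        )
        if "fractions" in spec:
            fractions = np.asarray(spec["fractions"], dtype=float)
            if fractions.shape != (n_genes, k):
                raise ValueError("fractions must have shape (n_genes, isoforms)")
        else:
            wui = np.broadcast_to(np.asarray(spec["wui"], dtype=float), (n_genes,))
            fractions = np.stack([wui_fractions(w, k) for w in wui])
        if (fractions < 0).any() or not np.allclose(fractions.sum(axis=1), 1.0):
            raise ValueError("isoform fractions must be a probability vector per gene")

        counts = np.zeros((n_cells, n_genes * k), dtype=np.int64)
        totals = rng.poisson(mean_counts, size=(n_cells, n_genes))
        for gi in range(n_genes):
            frac = fractions[gi]
            support = frac > 0
            tot = totals[:, gi]
            if overdispersion > 0 and support.sum() > 1:
                alpha = frac[support] / overdispersion
                p = rng.dirichlet(alpha, size=n_cells)
            else:
                p = np.broadcast_to(frac[support], (n_cells, int(support.sum())))
            draws = np.zeros((n_cells, int(support.sum())), dtype=np.int64)
            nz = tot > 0
            if nz.any():
                draws[nz] = _vectorized_multinomial(tot[nz], p[nz] if p.ndim == 2 else p, rng)
            cols = np.flatnonzero(support) + gi * k
            counts[:, cols] = draws
            truth_rows.append({
                "group": group, "gene_id": gene_ids[gi],
                "true_wui": float(fractions[gi] @ weights),
                "mean_counts": float(mean_counts[gi]),
            })
        blocks.append(counts)
        barcodes.extend(f"{group}-{i:05d}" for i in range(n_cells))
        labels.extend([group] * n_cells)

    full = sparse.csr_matrix(np.vstack(blocks))
    ccm = CellCountMatrix(full, barcodes, labels, iso_ids, iso_gene)
    return ccm, pd.DataFrame(truth_rows)


def _vectorized_multinomial(totals: np.ndarray, p: np.ndarray,
                            rng: np.random.Generator) -> np.ndarray:
    """Row-wise multinomial draws via sequential binomial conditioning."""
    n = totals.copy()
    if p.ndim == 1:
        p = np.broadcast_to(p, (totals.size, p.size))
    k = p.shape[1]
    out = np.zeros((totals.size, k), dtype=np.int64)
    remaining_p = np.ones(totals.size)
    for j in range(k - 1):
        with np.errstate(divide="ignore", invalid="ignore"):
            cond = np.where(remaining_p > 0, np.clip(p[:, j] / remaining_p, 0, 1), 0.0)
        out[:, j] = rng.binomial(n, cond)
        n = n - out[:, j]
        remaining_p = remaining_p - p[:, j]
    out[:, k - 1] = n
    return out


def make_planted_effect_matrix(
    n_perturbations: int = 60,
    n_genes: int = 300,
    n_modules: int = 3,
    noise_sd: float = 0.3,
    signal: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Planted-module perturbation x gene effect matrix.

    Perturbations are split evenly into ``n_modules`` modules; genes into as
    many blocks. Module m responds with a distinct sign pattern over the
    gene blocks (+signal on its own block, alternating -signal/0 elsewhere),
    plus Gaussian noise. Returns (matrix, perturbation module labels, gene
    block labels).
    """
    rng = np.random.default_rng(seed)
    pert_labels = np.arange(n_perturbations) % n_modules
    gene_labels = np.arange(n_genes) % n_modules
    patterns = np.full((n_modules, n_modules), 0.0)
    for m in range(n_modules):
        for b in range(n_modules):
            if m == b:
                patterns[m, b] = signal
            elif (m + b) % 2 == 0:
                patterns[m, b] = -signal
    mat = patterns[pert_labels][:, gene_labels] + rng.normal(
        0.0, noise_sd, size=(n_perturbations, n_genes)
    )
    frame = pd.DataFrame(
        mat,
        index=[f"pert{p:03d}" for p in range(n_perturbations)],
        columns=[f"g{g:04d}" for g in range(n_genes)],
    )
    return frame, pert_labels, gene_labels


def generate_toy_annotation(
    n_genes: int = 3,
    isoforms_per_gene: int = 2,
    utr_spacing: int = 400,
    gene_length: int = 2500,
    gene_gap: int = 12_000,
    chrom: str = "chrT",
    seed: int = 0,
    strands: Optional[Sequence[str]] = None,
) -> tuple[list[TranscriptModel], dict[str, str]]:
    """A toy single-chromosome annotation plus matching random genome.

    Each gene gets ``isoforms_per_gene`` single-exon transcripts sharing a
    5' end, with 3' ends spaced ``utr_spacing`` nt apart (5'->3'), a CDS
    ending well upstream of the proximal 3' end, and alternating strands by
    default.
    """
    rng = np.random.default_rng(seed)
    transcripts: list[TranscriptModel] = []
    strands = list(strands) if strands is not None else None
    cursor = 1000
    for gi in range(n_genes):
        strand = (strands[gi % len(strands)] if strands else ("+" if gi % 2 == 0 else "-"))
        gene_id = f"G{gi:03d}"
        start = cursor
        for j in range(isoforms_per_gene):
            extra = j * utr_spacing
            if strand == "+":
                exons = [(start, start + gene_length + extra)]
                cds_start = start + 100
                cds_end = start + gene_length - 800
            else:
                total = gene_length + (isoforms_per_gene - 1) * utr_spacing
                exons = [(start + (isoforms_per_gene - 1 - j) * utr_spacing,
                          start + total)]
                cds_start = start + total - 100
                cds_end = start + (isoforms_per_gene - 1) * utr_spacing + 800
            transcripts.append(TranscriptModel(
                transcript_id=f"{gene_id}.t{j}", gene_id=gene_id, chrom=chrom,
                strand=strand, exons=exons, cds_start=cds_start, cds_end=cds_end,
            ))
        cursor += gene_gap
    genome_len = cursor + 5000
    genome = {chrom: "".join(rng.choice(list("ACGT"), size=genome_len))}
    return transcripts, genome
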