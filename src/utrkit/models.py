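"""Core domain types shared across the package.

Coordinate convention: all genomic intervals are 0-based half-open
``[start, end)`` in ascending genomic order, regardless of strand. The
cleavage site (CS) of a transcript is the genomic coordinate of its last
transcribed nucleotide: ``end - 1`` of the last exon on the plus strand and
``start`` of the first exon on the minus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript with a defined 3' end.

    Parameters
    ----------
    exons
        Genomic intervals, 0-based half-open, non-overlapping, sorted in
        ascending genomic order (irrespective of strand).
    cds_start, cds_end
        Genomic positions of the first and last coding base (strand-aware:
        ``cds_end`` is the stop-codon side), if known.
    source
        Provenance of the 3' end: ``gencode`` for annotated transcripts,
        ``upstream`` for isoforms truncated at an interior-3'UTR CS,
        ``downstream`` for isoforms extended to a downstream CS.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    tags: frozenset[str] = field(default_factory=frozenset)
    source: str = "gencode"
    is_ipa: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        exons = [(int(s), int(e)) for s, e in self.exons]
        for s, e in exons:
            if e <= s:
                raise ValueError(
                    f"transcript {self.transcript_id}: empty/inverted exon [{s},{e})"
                )
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or unsorted"
                )
        self.exons = exons
        self.tags = frozenset(self.tags)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the last transcribed nucleotide (the CS)."""
        if self.strand == "+":
            return self.exons[-1][1] - 1
        return self.exons[0][0]

    @property
    def five_prime_end(self) -> int:
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1] - 1

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [(e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])]

    def with_exons(self, exons: Sequence[tuple[int, int]], **kw) -> "TranscriptModel":
        return replace(self, exons=list(exons), **kw)


@dataclass
class CleavageSite:
    """A single-nucleotide mRNA 3' end with read support and labels."""

    chrom: str
    strand: str
    position: int
    support: int = 0
    n_celltypes_used: int = 0
    class_label: str = "unclassified"  # validated | supported | likely | discarded
    region_label: str = "unassigned"
    gene_id: Optional[str] = None
    usage_score: Optional[float] = None
    usage_class: Optional[str] = None  # major | minor

    def __post_init__(self) -> None:
        if self.usage_score is not None and not (0.0 <= self.usage_score <= 1.0):
            raise ValueError("usage_score must lie in [0, 1]")


REGION_LABELS = (
    "three_prime_UTR",
    "five_prime_UTR",
    "exon",
    "intron",
    "extended_five_prime_UTR",
    "extended_three_prime_UTR",
    "intergenic",
)


class CellCountMatrix:
    """Sparse cells x isoforms UMI counts with per-cell group labels.

    The canonical in-memory carrier for all UMI-count computations: rows are
    cell barcodes, columns are 3'UTR isoforms, each column knows its gene.
    """

    def __init__(
        self,
        counts,
        barcodes: Sequence[str],
        groups: Sequence[str],
        isoform_ids: Sequence[str],
        gene_ids: Sequence[str],
    ) -> None:
        counts = sparse.csr_matrix(counts)
        if counts.shape != (len(barcodes), len(isoform_ids)):
            raise ValueError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(barcodes)} barcodes x {len(isoform_ids)} isoforms"
            )
        if len(groups) != len(barcodes):
            raise ValueError("one group label required per barcode")
        if len(gene_ids) != len(isoform_ids):
            raise ValueError("one gene id required per isoform")
        if counts.nnz and (counts.data < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.nnz and not np.allclose(counts.data, np.round(counts.data)):
            raise ValueError("counts must be integer")
        self.counts = counts
        self.barcodes = list(barcodes)
        self.groups = np.asarray(groups, dtype=object)
        self.isoform_ids = list(isoform_ids)
        self.gene_ids = np.asarray(gene_ids, dtype=object)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_isoforms(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask) -> "CellCountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CellCountMatrix(
            self.counts[idx],
            [self.barcodes[i] for i in idx],
            self.groups[idx],
            self.isoform_ids,
            self.gene_ids,
        )

    def cells_in_group(self, group: str) -> np.ndarray:
        return np.flatnonzero(self.groups == group)

    def pseudobulk(self, by_group: bool = True) -> pd.DataFrame:
        """Sum counts over cells, optionally per group label.

        Returns a DataFrame indexed by group (or a single row 'all') with one
        column per isoform.
        """
        if not by_group:
            total = np.asarray(self.counts.sum(axis=0)).ravel()
            return pd.DataFrame([total], index=["all"], columns=self.isoform_ids)
        rows = {}
        for g in pd.unique(self.groups):
            idx = np.flatnonzero(self.groups == g)
            rows[g] = np.asarray(self.counts[idx].sum(axis=0)).ravel()
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.isoform_ids)

    def apply_merge_table(self, merge_table: Mapping[str, str]) -> "CellCountMatrix":
        """Collapse isoform columns onto their merge-table representatives.

        Total counts are conserved exactly: every column is added to the
        column of its representative (identity for unmapped isoforms).
        """
        rep_of = {i: merge_table.get(i, i) for i in self.isoform_ids}
        reps = sorted(set(rep_of.values()), key=lambda r: self.isoform_ids.index(r)
                      if r in self.isoform_ids else len(self.isoform_ids))
        rep_index = {r: j for j, r in enumerate(reps)}
        gene_of = dict(zip(self.isoform_ids, self.gene_ids))
        cols = np.array([rep_index[rep_of[i]] for i in self.isoform_ids])
        proj = sparse.csr_matrix(
            (np.ones(len(cols)), (np.arange(len(cols)), cols)),
            shape=(self.n_isoforms, len(reps)),
        )
        merged = self.counts @ proj
        rep_genes = [gene_of.get(r, gene_of[self.isoform_ids[0]]) for r in reps]
        return CellCountMatrix(merged, self.barcodes, self.groups, reps, rep_genes)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CellCountMatrix({self.n_cells} cells x {self.n_isoforms} isoforms, "
            f"{len(set(self.gene_ids))} genes, nnz={self.counts.nnz})"
        )


@dataclass
class UTRome:
    """Truncated 3'UTR isoform models plus the proximal->distal merge table."""

    isoforms: list[TranscriptModel]
    merge_table: dict[str, str] = field(default_factory=dict)

    def isoform(self, tx_id: str) -> TranscriptModel:
        for tx in self.isoforms:
            if tx.transcript_id == tx_id:
                return tx
        raise KeyError(tx_id)


@dataclass
class HalfLifeFit:
    """First-order decay fit for one isoform from conversion-rate kinetics."""

    isoform_id: str
    k: float  # decay rate, per minute
    half_life: float  # minutes, ln(2)/k
    c_max: float
    residual: float
    reliable: bool
    note: str = ""


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgtNn", "TGCAtgcaNn"))[::-1]


def spliced_sequence(tx: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Strand-oriented spliced sequence of a transcript from a genome dict."""
    if tx.chrom not in genome:
        raise KeyError(f"chromosome {tx.chrom!r} missing from genome")
    chrom_seq = genome[tx.chrom]
    parts = [str(chrom_seq[s:e]) for s, e in tx.exons]
    seq = "".join(parts)
    if tx.strand == "-":
        seq = reverse_complement(seq)
    return seq
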