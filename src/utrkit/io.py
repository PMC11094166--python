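"""Readers and writers for the on-disk formats the toolkit touches.

All conversions between file conventions and the internal 0-based half-open
convention happen here and nowhere else: GTF is 1-based closed on disk, BED
and the internal model are 0-based half-open.
"""

from __future__ import annotations

import io as _io
import os
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import io as spio
from scipy import sparse

from .models import CellCountMatrix, CleavageSite, TranscriptModel, spliced_sequence


class GtfParseError(ValueError):
    """Raised for malformed GTF input; carries the offending line number."""

    def __init__(self, lineno: int, message: str) -> None:
        super().__init__(f"GTF line {lineno}: {message}")
        self.lineno = lineno


def _parse_attributes(field: str) -> dict[str, list[str]]:
    attrs: dict[str, list[str]] = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs.setdefault(key, []).append(value.strip().strip('"'))
    return attrs


def read_transcript_annotation(
    path,
    filters: Optional[Callable[[TranscriptModel], bool]] = None,
    exclude_tags: Iterable[str] = (),
    biotypes: Optional[Iterable[str]] = None,
    return_rejected: bool = False,
):
    """Read a GENCODE-dialect GTF into :class:`TranscriptModel` records.

    GTF coordinates (1-based closed) are converted to 0-based half-open.
    ``filters`` is an arbitrary predicate applied after the tag/biotype
    filters. Transcript records with no exon lines are reported as rejected
    rather than raising.
    """
    exclude_tags = frozenset(exclude_tags)
    biotypes = frozenset(biotypes) if biotypes is not None else None
    tx_meta: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cds_bounds: dict[str, list[int]] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(lineno, f"expected 9 fields, got {len(fields)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attr_str = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise GtfParseError(lineno, f"non-integer coordinates {start!r}/{end!r}")
            if end_i < start_i:
                raise GtfParseError(lineno, f"end < start ({end_i} < {start_i})")
            if strand not in ("+", "-"):
                if feature in ("transcript", "exon", "CDS", "stop_codon"):
                    raise GtfParseError(lineno, f"bad strand {strand!r}")
                continue
            attrs = _parse_attributes(attr_str)
            tx_id = attrs.get("transcript_id", [None])[0]
            if feature == "transcript":
                if tx_id is None:
                    raise GtfParseError(lineno, "transcript record lacks transcript_id")
                gene_id = attrs.get("gene_id", ["NA"])[0]
                tx_meta[tx_id] = {
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "strand": strand,
                    "tags": frozenset(attrs.get("tag", [])),
                    "biotype": attrs.get(
                        "transcript_type", attrs.get("transcript_biotype", [None])
                    )[0],
                    "source": attrs.get("cs_source", ["gencode"])[0],
                    "is_ipa": attrs.get("is_ipa", ["false"])[0].lower() == "true",
                }
                order.append(tx_id)
            elif feature == "exon":
                if tx_id is None:
                    raise GtfParseError(lineno, "exon record lacks transcript_id")
                # 1-based closed -> 0-based half-open
                exons.setdefault(tx_id, []).append((start_i - 1, end_i))
            elif feature in ("CDS", "stop_codon"):
                if tx_id is None:
                    raise GtfParseError(lineno, f"{feature} record lacks transcript_id")
                cds_bounds.setdefault(tx_id, []).extend([start_i - 1, end_i - 1])

    transcripts: list[TranscriptModel] = []
    rejected: list[str] = []
    for tx_id in order:
        meta = tx_meta[tx_id]
        tx_exons = sorted(exons.get(tx_id, []))
        if not tx_exons:
            rejected.append(tx_id)
            continue
        cds_start = cds_end = None
        if tx_id in cds_bounds:
            lo, hi = min(cds_bounds[tx_id]), max(cds_bounds[tx_id])
            cds_start, cds_end = (lo, hi) if meta["strand"] == "+" else (hi, lo)
        tx = TranscriptModel(
            transcript_id=tx_id,
            gene_id=meta["gene_id"],
            chrom=meta["chrom"],
            strand=meta["strand"],
            exons=tx_exons,
            cds_start=cds_start,
            cds_end=cds_end,
            tags=meta["tags"],
            source=meta["source"],
            is_ipa=meta["is_ipa"],
        )
        if exclude_tags and tx.tags & exclude_tags:
            continue
        if biotypes is not None and meta["biotype"] not in biotypes:
            continue
        if filters is not None and not filters(tx):
            continue
        transcripts.append(tx)
    if return_rejected:
        return transcripts, rejected
    return transcripts


def write_transcript_annotation(transcripts: Sequence[TranscriptModel], path) -> None:
    """Write transcripts as a GENCODE-dialect GTF (transcript + exon lines)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            for tag in sorted(tx.tags):
                attrs += f' tag "{tag}";'
            attrs += f' cs_source "{tx.source}";'
            if tx.is_ipa:
                attrs += ' is_ipa "true";'
            fh.write(
                "\t".join(
                    [
                        tx.chrom,
                        "utrkit",
                        "transcript",
                        str(tx.start + 1),
                        str(tx.end),
                        ".",
                        tx.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for s, e in tx.exons:
                fh.write(
                    "\t".join(
                        [tx.chrom, "utrkit", "exon", str(s + 1), str(e), ".",
                         tx.strand, ".", attrs]
                    )
                    + "\n"
                )
            if tx.cds_end is not None:
                lo = tx.cds_end if tx.cds_start is None else min(tx.cds_start, tx.cds_end)
                hi = tx.cds_end if tx.cds_start is None else max(tx.cds_start, tx.cds_end)
                fh.write(
                    "\t".join(
                        [tx.chrom, "utrkit", "CDS", str(lo + 1), str(hi + 1), ".",
                         tx.strand, ".", attrs]
                    )
                    + "\n"
                )


def read_genome_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_utrome_annotation(
    isoforms: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    gtf_path,
    fasta_path,
) -> None:
    """Export truncated isoforms as GTF plus spliced, strand-oriented FASTA.

    FASTA ids match GTF transcript ids one-to-one; sequences on the minus
    strand are reverse-complemented.
    """
    for tx in isoforms:
        if tx.chrom not in genome:
            raise KeyError(
                f"chromosome {tx.chrom!r} (transcript {tx.transcript_id}) "
                "missing from genome"
            )
    write_transcript_annotation(isoforms, gtf_path)
    write_fasta(
        ((tx.transcript_id, spliced_sequence(tx, genome)) for tx in isoforms),
        fasta_path,
    )


# ---------------------------------------------------------------------------
# UMI count matrices (MTX triplet + TSVs)
# ---------------------------------------------------------------------------

def read_umi_counts(
    mtx_path,
    barcodes_path,
    features_path,
    annotations_path=None,
) -> CellCountMatrix:
    """Load an MTX triplet into a :class:`CellCountMatrix`.

    The matrix on disk is features x barcodes (10x convention) and is
    transposed on read. When an annotation table (barcode, group) is given,
    cells lacking an annotation row are dropped.
    """
    mat = sparse.csr_matrix(spio.mmread(str(mtx_path)))
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    feats = pd.read_csv(features_path, sep="\t", header=None)
    isoform_ids = feats[0].astype(str).tolist()
    gene_ids = (feats[1] if feats.shape[1] > 1 else feats[0]).astype(str).tolist()
    if mat.shape == (len(isoform_ids), len(barcodes)):
        mat = mat.T.tocsr()
    elif mat.shape != (len(barcodes), len(isoform_ids)):
        raise ValueError(
            f"matrix shape {mat.shape} matches neither "
            f"{len(isoform_ids)} features x {len(barcodes)} barcodes nor its transpose"
        )
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise ValueError("UMI count matrix contains non-integer entries")
    groups = np.array(["all"] * len(barcodes), dtype=object)
    ccm = CellCountMatrix(mat, barcodes, groups, isoform_ids, gene_ids)
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep="\t", header=None, names=["barcode", "group"])
        ann["barcode"] = ann["barcode"].astype(str)
        lookup = dict(zip(ann["barcode"], ann["group"].astype(str)))
        keep = np.array([bc in lookup for bc in barcodes])
        ccm = ccm.subset_cells(keep)
        ccm.groups = np.array([lookup[bc] for bc in ccm.barcodes], dtype=object)
    return ccm


def write_umi_counts(ccm: CellCountMatrix, mtx_path, barcodes_path, features_path,
                     annotations_path=None) -> None:
    spio.mmwrite(str(mtx_path), sparse.coo_matrix(ccm.counts.T))
    pd.Series(ccm.barcodes).to_csv(barcodes_path, sep="\t", header=False, index=False)
    pd.DataFrame({"isoform": ccm.isoform_ids, "gene": ccm.gene_ids}).to_csv(
        features_path, sep="\t", header=False, index=False
    )
    if annotations_path is not None:
        pd.DataFrame({"barcode": ccm.barcodes, "group": ccm.groups}).to_csv(
            annotations_path, sep="\t", header=False, index=False
        )


# ---------------------------------------------------------------------------
# Coverage, atlas, merge-table TSVs
# ---------------------------------------------------------------------------

COVERAGE_COLUMNS = ["chrom", "position", "strand", "count", "cell_type"]


def read_coverage(path) -> pd.DataFrame:
    """Read strand-specific 3'-end coverage (read 5'-end positions, BED-like)."""
    cov = pd.read_csv(path, sep="\t", header=0)
    missing = set(COVERAGE_COLUMNS) - set(cov.columns)
    if missing:
        raise ValueError(f"coverage table missing columns: {sorted(missing)}")
    if (cov["count"] <= 0).any():
        raise ValueError("coverage counts must be positive")
    return cov[COVERAGE_COLUMNS]


def write_coverage(cov: pd.DataFrame, path) -> None:
    cov[COVERAGE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_merge_table(path) -> dict[str, str]:
    tbl = pd.read_csv(path, sep="\t", header=0)
    return dict(zip(tbl["isoform_id"].astype(str), tbl["representative_id"].astype(str)))


def write_merge_table(merge_table: Mapping[str, str], gene_of: Mapping[str, str], path) -> None:
    """Write the 3-column merge table (isoform_id, representative_id, gene_id)."""
    pd.DataFrame(
        {
            "isoform_id": list(merge_table.keys()),
            "representative_id": [merge_table[i] for i in merge_table],
            "gene_id": [gene_of.get(i, "NA") for i in merge_table],
        }
    ).to_csv(path, sep="\t", index=False)


def atlas_to_frame(sites: Sequence[CleavageSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "position": [s.position for s in sites],
            "strand": [s.strand for s in sites],
            "support": [s.support for s in sites],
            "n_celltypes_used": [s.n_celltypes_used for s in sites],
            "class_label": [s.class_label for s in sites],
            "region_label": [s.region_label for s in sites],
            "gene_id": [s.gene_id for s in sites],
            "usage_score": [s.usage_score for s in sites],
            "usage_class": [s.usage_class for s in sites],
        }
    )


def write_atlas(sites: Sequence[CleavageSite], tsv_path, bed_path=None) -> None:
    frame = atlas_to_frame(sites)
    frame.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        bed = pd.DataFrame(
            {
                "chrom": frame["chrom"],
                "start": frame["position"],
                "end": frame["position"] + 1,
                "name": frame["class_label"],
                "score": frame["support"],
                "strand": frame["strand"],
            }
        )
        bed.to_csv(bed_path, sep="\t", index=False, header=False)


def read_external_clusters(path) -> pd.DataFrame:
    """Read a PolyASite-like cluster table (chrom, position, strand, tpm)."""
    tbl = pd.read_csv(path, sep="\t", header=0)
    missing = {"chrom", "position", "strand", "tpm"} - set(tbl.columns)
    if missing:
        raise ValueError(f"cluster table missing columns: {sorted(missing)}")
    return tbl
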