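"""Calling, filtering, classifying, and scoring mRNA 3'-end cleavage sites.

The atlas is built per cell type from strand-specific coverage of read
5' ends (each covered position is a candidate cleavage site), merged to
local modes within a fixed radius, thresholded on reads-per-million,
harmonized across cell types, and then classified against annotated
transcript ends, an external poly(A)-site atlas, and an internal-priming
sequence filter.
"""

from __future__ import annotations

import re
from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import CleavageSite, TranscriptModel, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def merge_local_modes(positions, counts, radius: int = 30):
    """Greedy local-mode merging of single-nucleotide coverage.

    Repeatedly the highest-count remaining position becomes a mode and
    absorbs all remaining positions within ``radius`` nucleotides; ties in
    count are broken toward the leftmost (smallest) position. Returns
    (mode_positions, mode_supports, assignment) where ``assignment[i]`` is
    the index of the mode that absorbed input position ``i``.
    """
    positions = np.asarray(positions, dtype=np.int64)
    counts = np.asarray(counts, dtype=np.int64)
    if positions.size == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    sort_pos = np.argsort(positions, kind="stable")
    pos_sorted = positions[sort_pos]
    cnt_sorted = counts[sort_pos]
    # process in descending count, ascending position order
    order = np.lexsort((pos_sorted, -cnt_sorted))
    absorbed = np.full(pos_sorted.size, -1, dtype=np.int64)
    modes: list[int] = []
    supports: list[int] = []
    for i in order:
        if absorbed[i] >= 0:
            continue
        mode_idx = len(modes)
        lo = np.searchsorted(pos_sorted, pos_sorted[i] - radius, side="left")
        hi = np.searchsorted(pos_sorted, pos_sorted[i] + radius, side="right")
        members = np.arange(lo, hi)[absorbed[lo:hi] < 0]
        absorbed[members] = mode_idx
        modes.append(int(pos_sorted[i]))
        supports.append(int(cnt_sorted[members].sum()))
    assignment = np.empty(positions.size, dtype=np.int64)
    assignment[sort_pos] = absorbed
    return np.asarray(modes), np.asarray(supports), assignment


def call_peaks(
    coverage: pd.DataFrame,
    radius: int = 30,
    rpm_threshold: float = 5.0,
    library_size: Optional[int] = None,
) -> list[CleavageSite]:
    """Call cleavage-site peaks for one cell type.

    ``coverage`` holds columns chrom, position, strand, count (a single
    group). Positions are merged to local modes within ``radius`` per
    (chrom, strand), and modes are retained only when their support exceeds
    ``rpm_threshold`` reads per million (strict inequality). ``library_size``
    defaults to the total read count of the coverage table.
    """
    if library_size is None:
        library_size = int(coverage["count"].sum()) if len(coverage) else 0
    if len(coverage) == 0:
        return []
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    peaks: list[CleavageSite] = []
    for (chrom, strand), sub in coverage.groupby(["chrom", "strand"], sort=True):
        modes, supports, _ = merge_local_modes(
            sub["position"].to_numpy(), sub["count"].to_numpy(), radius
        )
        for pos, sup in zip(modes, supports):
            rpm = sup * 1e6 / library_size
            if rpm > rpm_threshold:
                peaks.append(
                    CleavageSite(chrom=chrom, strand=strand, position=int(pos),
                                 support=int(sup), n_celltypes_used=1)
                )
    peaks.sort(key=lambda s: (s.chrom, s.strand, s.position))
    return peaks


def harmonize_peaks(
    per_group_peaks: Mapping[str, Sequence[CleavageSite]],
    radius: int = 30,
) -> list[CleavageSite]:
    """Pool per-cell-type peaks and re-merge to local modes.

    Counts at identical positions are summed across cell types before the
    final local-mode pass; ``n_celltypes_used`` counts the cell types that
    contributed at least one read to the harmonized site.
    """
    pooled: dict[tuple[str, str, int], int] = defaultdict(int)
    contributors: dict[tuple[str, str, int], set[str]] = defaultdict(set)
    for group, peaks in per_group_peaks.items():
        for p in peaks:
            key = (p.chrom, p.strand, p.position)
            pooled[key] += p.support
            contributors[key].add(group)
    by_cs: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    for (chrom, strand, pos), cnt in pooled.items():
        by_cs[(chrom, strand)].append((pos, cnt))
    out: list[CleavageSite] = []
    for (chrom, strand), entries in sorted(by_cs.items()):
        entries.sort()
        positions = np.array([p for p, _ in entries])
        counts = np.array([c for _, c in entries])
        modes, supports, assignment = merge_local_modes(positions, counts, radius)
        groups_per_mode: list[set[str]] = [set() for _ in modes]
        for i, mode_idx in enumerate(assignment):
            groups_per_mode[mode_idx] |= contributors[(chrom, strand, int(positions[i]))]
        for pos, sup, grps in zip(modes, supports, groups_per_mode):
            out.append(
                CleavageSite(chrom=chrom, strand=strand, position=int(pos),
                             support=int(sup), n_celltypes_used=len(grps))
            )
    out.sort(key=lambda s: (s.chrom, s.strand, s.position))
    return out


def downstream_sequence(
    chrom_seq: str, position: int, strand: str, length: int = 20
) -> str:
    """Genomic sequence immediately downstream of a CS in transcript direction.

    Windows extending beyond the contig end are truncated.
    """
    n = len(chrom_seq)
    if strand == "+":
        return chrom_seq[min(position + 1, n): min(position + 1 + length, n)].upper()
    seq = chrom_seq[max(position - length, 0): max(position, 0)].upper()
    return reverse_complement(seq)


def internal_priming_filter(
    site: CleavageSite,
    genome: Mapping[str, str],
    window_down: int = 20,
    max_a_fraction: float = 0.65,
    max_a_run: int = 8,
) -> bool:
    """True when the site passes (is not an internal-priming artifact).

    A site fails when the downstream genomic window is adenosine-rich:
    A-fraction >= ``max_a_fraction`` or any run of >= ``max_a_run``
    consecutive A. This transparent heuristic captures the oligo(dT)
    mispriming signature (priming at genomic A stretches).
    """
    if site.chrom not in genome:
        raise KeyError(f"chromosome {site.chrom!r} missing from genome")
    seq = downstream_sequence(genome[site.chrom], site.position, site.strand, window_down)
    if not seq:
        return True
    a_fraction = seq.count("A") / len(seq)
    longest_run = max((len(m.group()) for m in re.finditer("A+", seq)), default=0)
    return not (a_fraction >= max_a_fraction or longest_run >= max_a_run)


def _nearest_distance(position: int, sorted_positions: np.ndarray) -> float:
    if sorted_positions.size == 0:
        return np.inf
    i = np.searchsorted(sorted_positions, position)
    best = np.inf
    if i < sorted_positions.size:
        best = min(best, abs(int(sorted_positions[i]) - position))
    if i > 0:
        best = min(best, abs(int(sorted_positions[i - 1]) - position))
    return best


def classify_sites(
    candidates: Sequence[CleavageSite],
    gencode_ends: pd.DataFrame,
    external_clusters: pd.DataFrame,
    genome: Mapping[str, str],
    window: int = 40,
    cluster_tpm_min: float = 3.0,
    priming_kwargs: Optional[dict] = None,
) -> list[CleavageSite]:
    """Classify candidate sites as validated / supported / likely / discarded.

    A candidate within ``window/2`` nt of an annotated transcript 3' end
    (same chrom and strand) is *validated*; otherwise, within ``window/2`` nt
    of an external poly(A)-site cluster with TPM >= ``cluster_tpm_min`` it is
    *supported*; otherwise it is *likely* if it passes the internal-priming
    filter and *discarded* if not. The retained atlas is the union of
    supported and likely sites; validated sites are tracked separately
    (they are already annotated).
    """
    priming_kwargs = priming_kwargs or {}
    half = window // 2
    ends_by = {
        key: np.sort(sub["position"].to_numpy())
        for key, sub in gencode_ends.groupby(["chrom", "strand"])
    }
    strong = external_clusters[external_clusters["tpm"] >= cluster_tpm_min]
    clusters_by = {
        key: np.sort(sub["position"].to_numpy())
        for key, sub in strong.groupby(["chrom", "strand"])
    }
    out = []
    for site in candidates:
        key = (site.chrom, site.strand)
        if _nearest_distance(site.position, ends_by.get(key, np.array([]))) <= half:
            label = "validated"
        elif _nearest_distance(site.position, clusters_by.get(key, np.array([]))) <= half:
            label = "supported"
        elif internal_priming_filter(site, genome, **priming_kwargs):
            label = "likely"
        else:
            label = "discarded"
        out.append(CleavageSite(
            chrom=site.chrom, strand=site.strand, position=site.position,
            support=site.support, n_celltypes_used=site.n_celltypes_used,
            class_label=label, region_label=site.region_label,
            gene_id=site.gene_id,
        ))
    return out


def retained_atlas(sites: Iterable[CleavageSite]) -> list[CleavageSite]:
    """The supported + likely union that forms the novel-site atlas."""
    return [s for s in sites if s.class_label in ("supported", "likely")]


def annotate_region(
    site: CleavageSite,
    transcripts: Sequence[TranscriptModel],
    five_ext: int = 1000,
    three_ext: int = 5000,
) -> CleavageSite:
    """Assign the highest-precedence region label over all overlapping transcripts.

    Precedence: three_prime_UTR > five_prime_UTR > exon > intron >
    extended_five_prime_UTR > extended_three_prime_UTR > intergenic.
    Transcript 5' ends are extended ``five_ext`` upstream and 3' ends
    ``three_ext`` downstream. Opposite-strand transcripts never match.
    """
    precedence = {
        "three_prime_UTR": 0, "five_prime_UTR": 1, "exon": 2, "intron": 3,
        "extended_five_prime_UTR": 4, "extended_three_prime_UTR": 5,
    }
    best_label, best_gene, best_rank = "intergenic", None, len(precedence)
    pos = site.position
    for tx in transcripts:
        if tx.chrom != site.chrom or tx.strand != site.strand:
            continue
        label = None
        in_exon = any(s <= pos < e for s, e in tx.exons)
        if in_exon:
            label = "exon"
            if tx.cds_end is not None:
                after_stop = pos > tx.cds_end if tx.strand == "+" else pos < tx.cds_end
                if after_stop:
                    label = "three_prime_UTR"
            if label == "exon" and tx.cds_start is not None:
                before_start = (pos < tx.cds_start if tx.strand == "+"
                                else pos > tx.cds_start)
                if before_start:
                    label = "five_prime_UTR"
        elif tx.start <= pos < tx.end:
            label = "intron"
        else:
            if tx.strand == "+":
                up = tx.start - five_ext <= pos < tx.start
                down = tx.end <= pos < tx.end + three_ext
            else:
                up = tx.end <= pos < tx.end + five_ext
                down = tx.start - three_ext <= pos < tx.start
            if up:
                label = "extended_five_prime_UTR"
            elif down:
                label = "extended_three_prime_UTR"
        if label is not None and precedence[label] < best_rank:
            best_rank = precedence[label]
            best_label = label
            best_gene = tx.gene_id
    site.region_label = best_label
    if best_gene is not None:
        site.gene_id = best_gene
    return site


def usage_score(
    site_usage: Iterable[str],
    gene_expression: Iterable[str],
    minor_max_celltypes: int = 10,
    minor_rule: str = "count",
    minor_fraction: float = 0.10,
) -> tuple[float, str]:
    """CS usage score and major/minor class.

    The score is the number of cell types using the site divided by the
    number of cell types expressing the gene. Under the default ``count``
    rule a site used in fewer than ``minor_max_celltypes`` expressing cell
    types is minor; the alternative ``fraction`` rule calls a site minor when
    its usage score is below ``minor_fraction``.
    """
    used = set(site_usage)
    expressing = set(gene_expression)
    if not expressing:
        raise ValueError("gene expressed in zero cell types: usage score undefined")
    if not used <= expressing:
        raise ValueError("site usage must be a subset of gene-expressing cell types")
    score = len(used) / len(expressing)
    if minor_rule == "count":
        klass = "minor" if len(used) < minor_max_celltypes else "major"
    elif minor_rule == "fraction":
        klass = "minor" if score < minor_fraction else "major"
    else:
        raise ValueError(f"unknown minor_rule {minor_rule!r}")
    return score, klass


def iupac_to_regex(motif: str) -> str:
    try:
        return "".join(IUPAC[ch] for ch in motif.upper())
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC symbol {exc.args[0]!r} in motif {motif!r}")


def motif_positional_density(
    sites: Sequence[CleavageSite],
    genome: Mapping[str, str],
    motifs: Mapping[str, tuple[str, tuple[int, int]]],
) -> dict[str, pd.Series]:
    """Positional histograms of motif centers relative to the CS (position 0).

    ``motifs`` maps a motif name to (IUPAC pattern, (window_lo, window_hi))
    with offsets relative to the CS. Occurrences are pooled over all sites;
    each histogram is scaled so its global mode equals 1 (all zeros when the
    motif never occurs).
    """
    out: dict[str, pd.Series] = {}
    for name, (pattern, (lo, hi)) in motifs.items():
        regex = re.compile(f"(?=({iupac_to_regex(pattern)}))")
        k = len(pattern)
        offsets = np.arange(lo, hi + 1)
        hist = np.zeros(offsets.size, dtype=float)
        for site in sites:
            chrom_seq = genome[site.chrom]
            if site.strand == "+":
                start = site.position + lo
                seq = chrom_seq[max(start, 0): site.position + hi + 1].upper()
                if start < 0:
                    seq = "N" * (-start) + seq
            else:
                end = site.position - lo + 1
                seq = chrom_seq[max(site.position - hi, 0): max(end, 0)].upper()
                seq = reverse_complement(seq)
                pad = hi - site.position if site.position < hi else 0
                if pad > 0:
                    seq = seq + "N" * pad
            for m in regex.finditer(seq):
                center = lo + m.start() + (k - 1) // 2
                if lo <= center <= hi:
                    hist[center - lo] += 1
        if hist.max() > 0:
            hist = hist / hist.max()
        out[name] = pd.Series(hist, index=offsets, name=name)
    return out
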