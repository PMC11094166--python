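"""Truncated-UTRome construction.

Annotated transcripts are augmented with novel atlas cleavage sites (new
isoforms truncated at interior-3'UTR sites or extended to downstream sites),
truncated to a fixed spliced length anchored at the 3' end, deduplicated
when 3' ends are too close to be distinct, and summarized in a merge table
that collapses unresolvable neighbors onto the distal representative.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .models import CleavageSite, TranscriptModel, UTRome


def _signed_end(tx: TranscriptModel) -> int:
    """3'-end coordinate signed so that ascending order is 5' -> 3'."""
    return tx.three_prime_end if tx.strand == "+" else -tx.three_prime_end


def truncate_at_position(tx: TranscriptModel, cs: int, **kw) -> TranscriptModel:
    """New transcript ending at genomic position ``cs`` (inclusive, strand-aware)."""
    new_exons: list[tuple[int, int]] = []
    if tx.strand == "+":
        for s, e in tx.exons:
            if s > cs:
                break
            new_exons.append((s, min(e, cs + 1)))
    else:
        for s, e in tx.exons:
            if e <= cs:
                continue
            new_exons.append((max(s, cs), e))
    if not new_exons:
        raise ValueError(
            f"cleavage site {cs} upstream of all exons of {tx.transcript_id}"
        )
    return tx.with_exons(new_exons, **kw)


def extend_to_position(tx: TranscriptModel, cs: int, **kw) -> TranscriptModel:
    """New transcript whose last exon is extended to ``cs`` (strand-aware)."""
    exons = list(tx.exons)
    if tx.strand == "+":
        s, e = exons[-1]
        if cs + 1 <= e:
            raise ValueError("extension target not downstream of transcript end")
        exons[-1] = (s, cs + 1)
    else:
        s, e = exons[0]
        if cs >= s:
            raise ValueError("extension target not downstream of transcript end")
        exons[0] = (cs, e)
    return tx.with_exons(exons, **kw)


def _in_three_prime_utr(tx: TranscriptModel, pos: int) -> bool:
    if not any(s <= pos < e for s, e in tx.exons):
        return False
    if tx.cds_end is None:
        return True
    return pos > tx.cds_end if tx.strand == "+" else pos < tx.cds_end


def augment_transcripts(
    transcripts: Sequence[TranscriptModel],
    atlas_sites: Sequence[CleavageSite],
    three_ext: int = 5000,
    return_rejected: bool = False,
):
    """Add novel-CS isoforms to an annotation.

    For every atlas site labeled ``three_prime_UTR`` that falls inside a
    transcript's 3'UTR, a new *upstream* isoform ending at the site is
    created; for every ``extended_three_prime_UTR`` site within ``three_ext``
    nt downstream of a transcript 3' end, a *downstream* isoform with an
    extended last exon is created. Original transcripts are retained.
    Sites labeled three_prime_UTR that land upstream of a transcript's stop
    codon are rejected for that transcript and reported.
    """
    out = list(transcripts)
    rejected: list[tuple[str, int, str]] = []
    for site in atlas_sites:
        for tx in transcripts:
            if tx.chrom != site.chrom or tx.strand != site.strand:
                continue
            if site.gene_id is not None and tx.gene_id != site.gene_id:
                continue
            pos = site.position
            if site.region_label == "three_prime_UTR":
                in_exon = any(s <= pos < e for s, e in tx.exons)
                if not in_exon or pos == tx.three_prime_end:
                    continue
                if not _in_three_prime_utr(tx, pos):
                    rejected.append((tx.transcript_id, pos, "upstream of stop codon"))
                    continue
                out.append(
                    truncate_at_position(
                        tx, pos,
                        transcript_id=f"{tx.transcript_id}.UP{pos}",
                        source="upstream",
                    )
                )
            elif site.region_label == "extended_three_prime_UTR":
                end = tx.three_prime_end
                dist = pos - end if tx.strand == "+" else end - pos
                if 0 < dist <= three_ext:
                    out.append(
                        extend_to_position(
                            tx, pos,
                            transcript_id=f"{tx.transcript_id}.DN{pos}",
                            source="downstream",
                        )
                    )
    if return_rejected:
        return out, rejected
    return out


def truncate_transcriptome(
    transcripts: Sequence[TranscriptModel], length: int = 500
) -> list[TranscriptModel]:
    """Keep the 3'-most ``length`` spliced nucleotides of every transcript.

    Exon structure is intersected with the kept spliced window; transcripts
    already at or below ``length`` are returned unchanged. The 3' end is
    preserved exactly.
    """
    out = []
    for tx in transcripts:
        if tx.spliced_length <= length:
            out.append(tx)
            continue
        remaining = length
        kept: list[tuple[int, int]] = []
        if tx.strand == "+":
            for s, e in reversed(tx.exons):
                take = min(e - s, remaining)
                kept.append((e - take, e))
                remaining -= take
                if remaining == 0:
                    break
            kept.reverse()
        else:
            for s, e in tx.exons:
                take = min(e - s, remaining)
                kept.append((s, s + take))
                remaining -= take
                if remaining == 0:
                    break
        out.append(tx.with_exons(kept))
    return out


def flag_ipa(
    isoforms: Sequence[TranscriptModel],
    annotation: Sequence[TranscriptModel],
) -> list[TranscriptModel]:
    """Mark isoforms whose 3' end falls in an annotated intron of their gene."""
    introns_by_gene: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for tx in annotation:
        introns_by_gene[tx.gene_id].extend(tx.introns())
    out = []
    for iso in isoforms:
        end = iso.three_prime_end
        is_ipa = any(s <= end < e for s, e in introns_by_gene.get(iso.gene_id, ()))
        out.append(iso.with_exons(iso.exons, is_ipa=is_ipa))
    return out


def deduplicate_truncated(
    isoforms: Sequence[TranscriptModel], min_distinct: int = 50
) -> list[TranscriptModel]:
    """Collapse same-gene isoforms whose 3' ends are < ``min_distinct`` nt apart.

    Chains are formed transitively on 3'-end distance; each chain keeps a
    single representative, the most 3' member, with downstream-sourced
    isoforms outranking gencode/upstream ones at the same position. The
    surviving record carries the lexicographically smallest transcript id of
    its chain.
    """
    by_gene: dict[tuple[str, str, str], list[TranscriptModel]] = defaultdict(list)
    for iso in isoforms:
        by_gene[(iso.gene_id, iso.chrom, iso.strand)].append(iso)
    out: list[TranscriptModel] = []
    for members in by_gene.values():
        members.sort(key=_signed_end)
        chains: list[list[TranscriptModel]] = []
        for iso in members:
            if chains and abs(_signed_end(iso) - _signed_end(chains[-1][-1])) < min_distinct:
                chains[-1].append(iso)
            else:
                chains.append([iso])
        for chain in chains:
            max_send = max(_signed_end(i) for i in chain)
            at_end = [i for i in chain if _signed_end(i) == max_send]
            at_end.sort(key=lambda i: (i.source != "downstream", i.transcript_id))
            survivor = at_end[0]
            rep_id = min(i.transcript_id for i in chain)
            out.append(survivor.with_exons(survivor.exons, transcript_id=rep_id))
    out.sort(key=lambda i: (i.chrom, i.strand, i.start, i.transcript_id))
    return out


def build_merge_table(
    isoforms: Sequence[TranscriptModel], merge_distance: int = 200
) -> dict[str, str]:
    """Map each isoform to the most 3' same-gene isoform < ``merge_distance`` away.

    Raw pointers (each isoform to the most downstream isoform within the
    merge distance) are resolved to a fixed point, so every chain collapses
    onto its distal representative; pointers always move 3'-ward, so
    resolution terminates.
    """
    table: dict[str, str] = {}
    by_gene: dict[tuple[str, str, str], list[TranscriptModel]] = defaultdict(list)
    for iso in isoforms:
        by_gene[(iso.gene_id, iso.chrom, iso.strand)].append(iso)
    for members in by_gene.values():
        members.sort(key=lambda i: (_signed_end(i), i.transcript_id))
        sends = [_signed_end(i) for i in members]
        raw: list[int] = []
        for idx, send in enumerate(sends):
            target = idx
            for j in range(idx + 1, len(members)):
                if sends[j] - send < merge_distance:
                    target = j
                else:
                    break
            raw.append(target)
        resolved = list(raw)
        for idx in range(len(members) - 1, -1, -1):
            while resolved[resolved[idx]] != resolved[idx]:
                resolved[idx] = resolved[resolved[idx]]
        for idx, iso in enumerate(members):
            table[iso.transcript_id] = members[resolved[idx]].transcript_id
    return table


def build_utrome(
    transcripts: Sequence[TranscriptModel],
    atlas_sites: Sequence[CleavageSite] = (),
    truncation_length: int = 500,
    dedup_distance: int = 50,
    merge_distance: int = 200,
    three_ext: int = 5000,
) -> UTRome:
    """Full UTRome pipeline: augment, truncate, flag IPA, deduplicate, merge."""
    augmented = augment_transcripts(transcripts, atlas_sites, three_ext=three_ext)
    truncated = truncate_transcriptome(augmented, length=truncation_length)
    truncated = flag_ipa(truncated, transcripts)
    dedup = deduplicate_truncated(truncated, min_distinct=dedup_distance)
    merge_table = build_merge_table(dedup, merge_distance=merge_distance)
    return UTRome(isoforms=dedup, merge_table=merge_table)
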