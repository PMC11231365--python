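"""Post-mapping processing of per-cell alignments.

Filters alignments (primary, nuclear, MAPQ >= 30), marks PCR duplicates by
same-strand edge similarity (< 20 bp at both coordinates, transitive
closure), and annotates reads with their haplotype of origin from phased
hetSNPs (a read is tagged only when every informative allele it covers
agrees with a single haplotype).
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np

from .core import CRICK, HP1, HP2, WATSON, DirectionalRead, PhasedVariant

DEFAULT_MITO = frozenset({"chrM", "MT", "chrMT", "M"})

_CIGAR_OPS = "MIDNSHP=XB"


def filter_alignments(
    alignments: Iterable,
    min_mapq: int = 30,
    mito_names: frozenset = DEFAULT_MITO,
    cell_id: Optional[str] = None,
) -> list[DirectionalRead]:
    """Convert a coordinate-sorted stream of pysam alignments to
    DirectionalReads, dropping unmapped / secondary / supplementary /
    mitochondrial / low-MAPQ records.

    The cell identity comes from ``cell_id`` if given, else the RG tag,
    else the first ':'-separated read-name token.
    """
    out: list[DirectionalRead] = []
    last = None
    for aln in alignments:
        if aln.is_unmapped:
            continue
        key = (aln.reference_id, aln.reference_start)
        if last is not None and key < last:
            raise ValueError("input alignments are not coordinate-sorted")
        last = key
        if aln.is_secondary or aln.is_supplementary:
            continue
        chrom = aln.reference_name
        if chrom in mito_names:
            continue
        if aln.mapping_quality < min_mapq:
            continue
        cell = cell_id
        if cell is None:
            cell = aln.get_tag("RG") if aln.has_tag("RG") else aln.query_name.split(":")[0]
        cigar = None
        if aln.cigartuples:
            cigar = [
                (_CIGAR_OPS[op], ln)
                for op, ln in aln.cigartuples
                if _CIGAR_OPS[op] in "MID"
            ]
        out.append(
            DirectionalRead(
                cell_id=cell,
                chrom=chrom,
                start=aln.reference_start,
                end=aln.reference_end,
                strand=WATSON if aln.is_reverse else CRICK,
                mapq=aln.mapping_quality,
                seq=aln.query_alignment_sequence,
                cigar=cigar,
                name=aln.query_name,
            )
        )
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def mark_duplicates(
    reads: Sequence[DirectionalRead], edge_tol: int = 20
) -> list[DirectionalRead]:
    """Flag PCR duplicates in place and return the list.

    Two reads are direct duplicates iff they share cell, chromosome and
    strand and both |dstart| and |dend| are strictly below ``edge_tol``;
    duplicate groups are the transitive closure of this relation. One
    representative per group stays unflagged: highest MAPQ, ties broken by
    length then leftmost start.
    """
    for r in reads:
        r.duplicate = False
    groups: dict[tuple, list[int]] = {}
    for i, r in enumerate(reads):
        groups.setdefault((r.cell_id, r.chrom, r.strand), []).append(i)
    for idxs in groups.values():
        idxs.sort(key=lambda i: (reads[i].start, reads[i].end))
        uf = _UnionFind(len(idxs))
        for a in range(len(idxs)):
            ra = reads[idxs[a]]
            for b in range(a + 1, len(idxs)):
                rb = reads[idxs[b]]
                if rb.start - ra.start >= edge_tol:
                    break
                if abs(rb.end - ra.end) < edge_tol:
                    uf.union(a, b)
        clusters: dict[int, list[int]] = {}
        for a in range(len(idxs)):
            clusters.setdefault(uf.find(a), []).append(idxs[a])
        for members in clusters.values():
            if len(members) == 1:
                continue
            keep = max(
                members,
                key=lambda i: (reads[i].mapq, reads[i].length, -reads[i].start),
            )
            for i in members:
                reads[i].duplicate = i != keep
    return list(reads)


class PhasedVariantIndex:
    """Sorted per-chromosome index of phased hetSNPs for fast allele lookup."""

    def __init__(self, variants: Iterable[PhasedVariant]):
        by_chrom: dict[str, list[PhasedVariant]] = {}
        for v in variants:
            if v.is_het:
                by_chrom.setdefault(v.chrom, []).append(v)
        self.pos: dict[str, np.ndarray] = {}
        self.hp1: dict[str, list[str]] = {}
        self.hp2: dict[str, list[str]] = {}
        for chrom, vs in by_chrom.items():
            vs.sort(key=lambda v: v.pos)
            self.pos[chrom] = np.array([v.pos for v in vs], dtype=np.int64)
            self.hp1[chrom] = [v.hp1_allele for v in vs]
            self.hp2[chrom] = [v.hp2_allele for v in vs]

    def swapped(self) -> "PhasedVariantIndex":
        idx = PhasedVariantIndex([])
        idx.pos = self.pos
        idx.hp1, idx.hp2 = self.hp2, self.hp1
        return idx


def annotate_haplotype(
    read: DirectionalRead, index: PhasedVariantIndex
) -> Optional[str]:
    """Haplotype tag for one read: HP1/HP2 when *all* informative covered
    alleles agree with that haplotype, None when mixed or uninformative.
    Alleles matching neither haplotype count as uninformative."""
    pos = index.pos.get(read.chrom)
    if pos is None or pos.size == 0:
        read.haplotype = None
        return None
    lo = int(np.searchsorted(pos, read.start))
    hi = int(np.searchsorted(pos, read.end))
    v1 = v2 = 0
    hp1, hp2 = index.hp1[read.chrom], index.hp2[read.chrom]
    for i in range(lo, hi):
        a = read.allele_at(int(pos[i]))
        if a is None:
            continue
        if a == hp1[i]:
            v1 += 1
        elif a == hp2[i]:
            v2 += 1
    tag = None
    if v1 > 0 and v2 == 0:
        tag = HP1
    elif v2 > 0 and v1 == 0:
        tag = HP2
    read.haplotype = tag
    return tag


def annotate_all(
    reads: Iterable[DirectionalRead], variants: Iterable[PhasedVariant]
) -> PhasedVariantIndex:
    index = variants if isinstance(variants, PhasedVariantIndex) else PhasedVariantIndex(variants)
    for r in reads:
        annotate_haplotype(r, index)
    return index


# ---------------------------------------------------------------------------
# SAM interop


def reads_to_sam(
    reads: Sequence[DirectionalRead],
    chrom_lengths: dict[str, int],
    path: str,
) -> None:
    """Write DirectionalReads as a (text) SAM file for round-tripping."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in chrom_lengths.items()],
    }
    order = {c: i for i, c in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for r in sorted(reads, key=lambda r: (order[r.chrom], r.start)):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.name or f"{r.cell_id}:read"
            a.reference_id = order[r.chrom]
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            a.flag = 16 if r.strand == WATSON else 0
            if r.duplicate:
                a.flag |= 1024
            seq = r.seq if r.seq is not None else "N" * r.length
            cigar = r.effective_cigar()
            a.cigartuples = [(_CIGAR_OPS.index(op), ln) for op, ln in cigar]
            a.query_sequence = seq
            a.set_tag("RG", r.cell_id)
            if r.haplotype:
                a.set_tag("HP", 1 if r.haplotype == HP1 else 2)
            fh.write(a)


def reads_from_sam(path: str, **kwargs) -> list[DirectionalRead]:
    import pysam

    with pysam.AlignmentFile(path) as fh:
        return filter_alignments(fh, **kwargs)
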