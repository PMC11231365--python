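"""Calling, filtering, genotyping and phasing of structural variants.

Candidate deletions/insertions (>= 50 bp) are extracted from read CIGARs
and merged across reads (breakpoints within 500 bp, lengths within 25%).
A blacklist removes SVs within 1 kb of a neighbour, longer than 10 kb,
inside extreme-coverage regions (< 10x or > 80x in all provided coverage
tracks) or overlapping annotated difficult/tandem intervals longer than
200 bp. Genotyping uses the haplotype read sets from phasing: a haplotype
supports an SV when its reads carry a matching CIGAR signature and
opposes it when they span the locus without one; homozygous SVs are
supported by both haplotypes, heterozygous SVs supported by one and
opposed by the other. Heterozygous SVs inside homozygous inversions have
their haplotype switched; SVs inside heterozygous inversions are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import HP1, HP2, DirectionalRead, PhasedVariant, SVCall
from .phasing import _interval_lookup


def _signature_match(
    type_a: str, pos_a: int, len_a: int, type_b: str, pos_b: int, len_b: int,
    pos_tol: int = 500, len_ratio: float = 0.25,
) -> bool:
    if type_a != type_b:
        return False
    if abs(pos_a - pos_b) > pos_tol:
        return False
    lo, hi = min(len_a, len_b), max(len_a, len_b)
    return lo >= (1 - len_ratio) * hi


def extract_candidate_svs(
    reads: Iterable[DirectionalRead],
    min_len: int = 50,
    pos_tol: int = 500,
    len_ratio: float = 0.25,
    min_reads: int = 1,
) -> list[SVCall]:
    """DEL/INS candidates from CIGAR operations, merged across reads.

    Events of the same type whose positions are within ``pos_tol`` bp and
    whose lengths agree within ``len_ratio`` are merged; the candidate
    takes the median position and length of its cluster.
    """
    events: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for r in reads:
        for typ, pos, ln in r.cigar_events(min_len):
            events.setdefault((r.chrom, typ), []).append((pos, ln))
    out: list[SVCall] = []
    for (chrom, typ), evs in sorted(events.items()):
        evs.sort()
        cluster: list[tuple[int, int]] = []
        for pos, ln in evs + [(10**15, 0)]:
            if cluster and not _signature_match(
                typ, cluster[-1][0], int(np.median([l for _, l in cluster])),
                typ, pos, ln, pos_tol, len_ratio,
            ):
                if len(cluster) >= min_reads:
                    p = int(np.median([p for p, _ in cluster]))
                    l = int(np.median([l for _, l in cluster]))
                    out.append(SVCall(chrom, p, typ, l, n_support_reads=len(cluster)))
                cluster = []
            if ln >= min_len:
                cluster.append((pos, ln))
    out.sort(key=lambda s: (s.chrom, s.pos))
    return out


def _overlaps(sv: SVCall, intervals: Sequence[tuple[int, int]]) -> bool:
    lo, hi = sv.pos, max(sv.end, sv.pos + 1)
    return any(lo < e and hi > s for s, e in intervals)


def filter_blacklist(
    svs: Sequence[SVCall],
    coverage_tracks: Sequence[dict[str, np.ndarray]] = (),
    difficult_bed: Optional[dict[str, list[tuple[int, int]]]] = None,
    tandem_bed: Optional[dict[str, list[tuple[int, int]]]] = None,
    adjacency: int = 1_000,
    max_len: int = 10_000,
    low_cov: float = 10.0,
    high_cov: float = 80.0,
    min_region_len: int = 200,
) -> list[SVCall]:
    """Apply the SV blacklist rules; order-independent and idempotent.

    Removes: both members of any pair of SVs whose breakpoints lie within
    ``adjacency`` bp; SVs longer than ``max_len``; SVs overlapping regions
    below ``low_cov`` or above ``high_cov`` mean coverage in *all* provided
    per-base coverage tracks; SVs overlapping difficult/tandem intervals
    longer than ``min_region_len``. Missing annotation inputs simply skip
    the corresponding rule.
    """
    svs = sorted(svs, key=lambda s: (s.chrom, s.pos))
    drop = set()
    for i, sv in enumerate(svs):
        if sv.length > max_len:
            drop.add(i)
    for i in range(len(svs)):
        for j in range(i + 1, len(svs)):
            if svs[j].chrom != svs[i].chrom:
                break
            if svs[j].pos - svs[i].pos > adjacency:
                break
            drop.add(i)
            drop.add(j)
    if coverage_tracks:
        for i, sv in enumerate(svs):
            lo, hi = sv.pos, max(sv.end, sv.pos + 1)
            extreme_in_all = True
            for track in coverage_tracks:
                cov = track.get(sv.chrom)
                if cov is None:
                    extreme_in_all = False
                    break
                seg = cov[max(lo, 0) : min(hi, len(cov))]
                m = float(seg.mean()) if seg.size else 0.0
                if low_cov <= m <= high_cov:
                    extreme_in_all = False
                    break
            if extreme_in_all:
                drop.add(i)
    for bed in (difficult_bed, tandem_bed):
        if bed is None:
            continue
        for i, sv in enumerate(svs):
            ivs = [
                (s, e)
                for s, e in bed.get(sv.chrom, ())
                if e - s > min_region_len
            ]
            if _overlaps(sv, ivs):
                drop.add(i)
    return [sv for i, sv in enumerate(svs) if i not in drop]


def genotype_sv(
    sv: SVCall,
    hp1_reads: Sequence[DirectionalRead],
    hp2_reads: Sequence[DirectionalRead],
    min_support: int = 2,
    pos_tol: int = 500,
    len_ratio: float = 0.25,
    span_flank: int = 50,
) -> SVCall:
    """Genotype one SV from the haplotype read sets (in place).

    Support: a read of that haplotype carrying a CIGAR signature matching
    the SV. Oppose: a read spanning the locus with ``span_flank`` bp on
    both sides and no matching signature. Genotype rules: HOM when both
    haplotypes support; HET-HPk when HPk supports and the other opposes;
    unresolved otherwise (thresholded at ``min_support`` reads).
    """
    results = {}
    for hp, reads in ((HP1, hp1_reads), (HP2, hp2_reads)):
        support = oppose = 0
        for r in reads:
            if r.chrom != sv.chrom:
                continue
            has_sig = any(
                _signature_match(sv.type, sv.pos, sv.length, t, p, l, pos_tol, len_ratio)
                for t, p, l in r.cigar_events(1)
            )
            if has_sig:
                support += 1
            elif r.start + span_flank <= sv.pos and r.end - span_flank >= sv.end:
                oppose += 1
        results[hp] = (support, oppose)
    sv.support_hp1, sv.oppose_hp1 = results[HP1]
    sv.support_hp2, sv.oppose_hp2 = results[HP2]
    if sv.support_hp1 >= min_support and sv.support_hp2 >= min_support:
        sv.genotype = "HOM"
    elif sv.support_hp1 >= min_support and sv.oppose_hp2 >= min_support:
        sv.genotype = "HET-HP1"
    elif sv.support_hp2 >= min_support and sv.oppose_hp1 >= min_support:
        sv.genotype = "HET-HP2"
    else:
        sv.genotype = "unresolved"
    return sv


def genotype_all(
    svs: Sequence[SVCall],
    hp1_reads: Sequence[DirectionalRead],
    hp2_reads: Sequence[DirectionalRead],
    **kwargs,
) -> list[SVCall]:
    return [genotype_sv(sv, hp1_reads, hp2_reads, **kwargs) for sv in svs]


def switch_phase_in_inversions(svs: Sequence[SVCall], inversions) -> list[SVCall]:
    """HET-HP1 <-> HET-HP2 inside homozygous inversions; SVs inside
    heterozygous inversions are dropped (mirroring the SNP rule);
    homozygous/unresolved SVs inside homozygous inversions are unchanged."""
    table = _interval_lookup(inversions)
    out = []
    for sv in svs:
        action = None
        for start, end, gt in table.get(sv.chrom, ()):
            if start <= sv.pos < end:
                action = gt
                break
        if action == "HET":
            continue
        if action == "HOM" and sv.genotype in ("HET-HP1", "HET-HP2"):
            sv.genotype = "HET-HP2" if sv.genotype == "HET-HP1" else "HET-HP1"
            sv.support_hp1, sv.support_hp2 = sv.support_hp2, sv.support_hp1
            sv.oppose_hp1, sv.oppose_hp2 = sv.oppose_hp2, sv.oppose_hp1
        out.append(sv)
    return out


DISTANCE_BUCKETS = ((0, 2_000, "<=2kb"), (2_000, 10_000, "2-10kb"), (10_000, None, ">10kb"))


def nearest_hetsnp_distances(
    svs: Sequence[SVCall], hetsnps: Sequence[PhasedVariant]
) -> dict[str, int]:
    """Annotate each SV with the distance from its nearest breakpoint to
    the nearest phased hetSNP; returns the bucket histogram
    (<=2kb / 2-10kb / >10kb). Distances stay None when no hetSNP exists
    on the chromosome."""
    pos_by_chrom: dict[str, np.ndarray] = {}
    for v in hetsnps:
        if v.is_het:
            pos_by_chrom.setdefault(v.chrom, []).append(v.pos)
    pos_by_chrom = {c: np.array(sorted(p)) for c, p in pos_by_chrom.items()}
    hist = {label: 0 for _, _, label in DISTANCE_BUCKETS}
    for sv in svs:
        pos = pos_by_chrom.get(sv.chrom)
        if pos is None or pos.size == 0:
            sv.nearest_hetsnp_distance = None
            continue
        d = min(
            int(np.abs(pos - bp).min()) for bp in {sv.pos, sv.end}
        )
        sv.nearest_hetsnp_distance = d
        for lo, hi, label in DISTANCE_BUCKETS:
            if d >= lo and (hi is None or d < hi):
                hist[label] += 1
                break
    return hist


def write_sv_vcf(
    svs: Sequence[SVCall], chrom_lengths: dict[str, int], path: str
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, ln in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        for line in (
            '##ALT=<ID=DEL,Description="Deletion">',
            '##ALT=<ID=INS,Description="Insertion">',
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
            '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
            '##INFO=<ID=SNPDIST,Number=1,Type=Integer,Description="Distance to nearest phased hetSNP">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        ):
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        gt_map = {"HOM": "1|1", "HET-HP1": "1|0", "HET-HP2": "0|1", "unresolved": "./."}
        for sv in sorted(svs, key=lambda s: (s.chrom, s.pos)):
            svlen = -sv.length if sv.type == "DEL" else sv.length
            info = f"SVTYPE={sv.type};SVLEN={svlen}"
            if sv.nearest_hetsnp_distance is not None:
                info += f";SNPDIST={sv.nearest_hetsnp_distance}"
            fh.write(
                f"{sv.chrom}\t{sv.pos + 1}\t.\tN\t<{sv.type}>\t.\tPASS\t{info}\tGT\t"
                f"{gt_map[sv.genotype]}\n"
            )
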