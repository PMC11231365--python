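"""Inversion detection from a directional composite read set.

Cells whose chromosome is in a single-strand state (Crick fraction
P_c > 0.8, or P_c < 0.2 with all read directions flipped) are pooled into
a Crick-Crick composite. Each cell contributes only its "pure" regions --
1-Mb bins whose binned P_c agrees with the cross-cell consensus -- which
excludes sister-chromatid-exchange segments. Inversions appear in the
composite as runs of Watson reads and are genotyped by the Watson fraction
P_w: homozygous when P_w > 0.9, heterozygous when 0.4 < P_w < 0.6; regions
with fewer than 20 reads or P_w < 0.1 are filtered, everything else is an
ungenotyped candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import CRICK, WATSON, DirectionalRead, InversionCall, StrandState


@dataclass(frozen=True)
class CompositeCell:
    cell_id: str
    flip: bool  # True for WW chromosomes (read directions switched)


@dataclass
class PureRegionSet:
    cell_id: str
    chrom: str
    intervals: list[tuple[int, int]]  # bin-aligned, sorted, non-overlapping


def select_composite_cells(
    states: Iterable[StrandState],
    chrom: str,
    cc_threshold: float = 0.8,
    ww_threshold: float = 0.2,
) -> list[CompositeCell]:
    """Cells usable for the CC composite of ``chrom``: CC cells as-is,
    WW cells flagged for strand flipping. WC cells are excluded."""
    out = []
    for s in states:
        if s.chrom != chrom:
            continue
        if s.pattern == "CC" and s.p_c > cc_threshold:
            out.append(CompositeCell(s.cell_id, flip=False))
        elif s.pattern == "WW" and s.p_c < ww_threshold:
            out.append(CompositeCell(s.cell_id, flip=True))
    return out


def _binned_pc(
    reads: Sequence[DirectionalRead], flip: bool, n_bins: int, bin_width: int
) -> tuple[np.ndarray, np.ndarray]:
    """(p_c per bin, total reads per bin); reads binned by midpoint."""
    crick = np.zeros(n_bins)
    total = np.zeros(n_bins)
    for r in reads:
        if r.duplicate:
            continue
        b = min(((r.start + r.end) // 2) // bin_width, n_bins - 1)
        is_crick = r.strand == CRICK
        if flip:
            is_crick = not is_crick
        total[b] += 1
        if is_crick:
            crick[b] += 1
    with np.errstate(invalid="ignore"):
        pc = np.where(total > 0, crick / np.maximum(total, 1), np.nan)
    return pc, total


def _cluster_profiles(profiles: np.ndarray, cut: float) -> np.ndarray:
    """Average-linkage clustering of per-cell bin profiles; the distance
    between two cells is the mean |dP_c| over bins both cover."""
    n = profiles.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(profiles[i]) & ~np.isnan(profiles[j])
            if both.sum() == 0:
                d = 1.0
            else:
                d = float(np.abs(profiles[i][both] - profiles[j][both]).mean())
            dist[i, j] = dist[j, i] = d
    z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(z, t=cut, criterion="distance") - 1


def pure_cc_regions(
    cells: Sequence[CompositeCell],
    reads_by_cell: dict[str, Sequence[DirectionalRead]],
    chrom_length: int,
    bin_width: int = 1_000_000,
    tolerance: float = 0.1,
    min_bin_reads: int = 10,
    cluster_cut: float = 0.15,
) -> list[PureRegionSet]:
    """Per-cell bin-aligned intervals where the cell's binned P_c (after
    any flip) matches the consensus profile of its cell cluster.

    Bins with fewer than ``min_bin_reads`` reads are never pure; maximal
    runs of pure bins become intervals. A chromosome shorter than one bin
    is treated as a single bin.
    """
    n_bins = max(1, -(-chrom_length // bin_width))
    if not cells:
        return []
    profiles = []
    totals = []
    for c in cells:
        pc, tot = _binned_pc(
            reads_by_cell.get(c.cell_id, ()), c.flip, n_bins, bin_width
        )
        pc = np.where(tot >= min_bin_reads, pc, np.nan)
        profiles.append(pc)
        totals.append(tot)
    profiles = np.array(profiles)
    labels = _cluster_profiles(profiles, cluster_cut)

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        global_expected = np.nanmedian(profiles, axis=0)
        expected_by_label: dict[int, np.ndarray] = {}
        for lab in np.unique(labels):
            members = profiles[labels == lab]
            if members.shape[0] >= 3:
                expected_by_label[lab] = np.nanmedian(members, axis=0)
            else:
                expected_by_label[lab] = global_expected

    out = []
    for c, pc, tot, lab in zip(cells, profiles, totals, labels):
        expected = expected_by_label[lab]
        pure = (
            (tot >= min_bin_reads)
            & ~np.isnan(pc)
            & ~np.isnan(expected)
            & (np.abs(pc - expected) <= tolerance)
        )
        intervals = []
        start = None
        for b in range(n_bins):
            if pure[b] and start is None:
                start = b
            elif not pure[b] and start is not None:
                intervals.append((start * bin_width, b * bin_width))
                start = None
        if start is not None:
            intervals.append((start * bin_width, min(n_bins * bin_width, chrom_length)))
        out.append(PureRegionSet(c.cell_id, "", intervals))
    return out


def build_composite(
    cells: Sequence[CompositeCell],
    reads_by_cell: dict[str, Sequence[DirectionalRead]],
    pure_regions: Sequence[PureRegionSet],
) -> list[DirectionalRead]:
    """Pool reads overlapping each cell's pure intervals; reads from
    flipped (WW) cells have their strand inverted. Returns new read
    objects sorted by start."""
    regions = {p.cell_id: p.intervals for p in pure_regions}
    out: list[DirectionalRead] = []
    for c in cells:
        ivs = regions.get(c.cell_id, [])
        for r in reads_by_cell.get(c.cell_id, ()):
            if r.duplicate:
                continue
            if not any(r.start < e and r.end > s for s, e in ivs):
                continue
            strand = r.strand
            if c.flip:
                strand = WATSON if strand == CRICK else CRICK
            out.append(
                DirectionalRead(
                    cell_id=r.cell_id,
                    chrom=r.chrom,
                    start=r.start,
                    end=r.end,
                    strand=strand,
                    mapq=r.mapq,
                    name=r.name,
                )
            )
    out.sort(key=lambda r: (r.start, r.end))
    return out


def scan_inversions(
    composite: Sequence[DirectionalRead],
    min_reads: int = 20,
    max_gap: int = 5_000,
    hom_pw: float = 0.9,
    het_pw: tuple[float, float] = (0.4, 0.6),
    noise_pw: float = 0.1,
) -> list[InversionCall]:
    """Scan the CC composite for runs of Watson reads and genotype them.

    A candidate is a maximal chain of Watson reads in which consecutive
    reads overlap or are separated by at most ``max_gap`` bp; chain
    termini are then eroded while the outermost read overlaps no other
    Watson read in the chain (isolated flanking reads are background, not
    inverted coverage). Candidates are classified by total read count and
    Watson fraction P_w.
    """
    watson = sorted(
        (r for r in composite if r.strand == WATSON), key=lambda r: r.start
    )
    if not watson:
        return []
    all_sorted = sorted(composite, key=lambda r: r.start)
    starts = np.array([r.start for r in all_sorted])
    ends = np.array([r.end for r in all_sorted])
    is_watson = np.array([r.strand == WATSON for r in all_sorted])

    chains: list[list[DirectionalRead]] = []
    cur = [watson[0]]
    cur_e = watson[0].end
    for r in watson[1:]:
        if r.start <= cur_e + max_gap:
            cur.append(r)
            cur_e = max(cur_e, r.end)
        else:
            chains.append(cur)
            cur = [r]
            cur_e = r.end
    chains.append(cur)

    def _erode(chain: list[DirectionalRead]) -> list[DirectionalRead]:
        chain = list(chain)
        while len(chain) > 1:
            if not any(r.start < chain[0].end and r.end > chain[0].start for r in chain[1:]):
                chain.pop(0)
                continue
            if not any(r.start < chain[-1].end and r.end > chain[-1].start for r in chain[:-1]):
                chain.pop()
                continue
            break
        return chain

    candidates = []
    for chain in chains:
        chain = _erode(chain)
        candidates.append((min(r.start for r in chain), max(r.end for r in chain)))

    chrom = composite[0].chrom
    calls = []
    for s, e in candidates:
        overlap = (starts < e) & (ends > s)
        n_w = int((overlap & is_watson).sum())
        n_c = int((overlap & ~is_watson).sum())
        total = n_w + n_c
        p_w = n_w / total if total else 0.0
        if total < min_reads:
            gt = "filtered"
        elif p_w > hom_pw:
            gt = "HOM"
        elif het_pw[0] < p_w < het_pw[1]:
            gt = "HET"
        elif p_w < noise_pw:
            gt = "filtered"
        else:
            gt = "ungenotyped"
        calls.append(InversionCall(chrom, s, e, n_c, n_w, gt))
    return calls


def detect_inversions(
    states: Iterable[StrandState],
    reads_by_cell: dict[str, Sequence[DirectionalRead]],
    chrom: str,
    chrom_length: int,
    **scan_kwargs,
) -> list[InversionCall]:
    """Convenience wrapper running the full per-chromosome detection:
    composite cell selection, pure-region extraction, composite pooling
    and the Watson-run scan."""
    cells = select_composite_cells(states, chrom)
    if not cells:
        return []
    per_chrom = {
        c.cell_id: [r for r in reads_by_cell.get(c.cell_id, ()) if r.chrom == chrom]
        for c in cells
    }
    pure = pure_cc_regions(cells, per_chrom, chrom_length)
    composite = build_composite(cells, per_chrom, pure)
    if not composite:
        return []
    return scan_inversions(composite, **scan_kwargs)
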