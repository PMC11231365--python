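"""Barcode demultiplexing of multiplexed strand-specific long reads.

Reads carry a 24-nt combinatorial barcode pair and a 33-bp linker. A
template-strand read shows the forward 2nd barcode at its head and the
reverse-complemented 1st barcode at its tail; a non-template read shows the
mirror layout and is normalized by reverse complement. Barcodes are matched
by minimal Levenshtein distance (semi-global, via edlib) within 200-bp end
windows; hits with distance > 5 are discarded. After barcode removal the
linker must be found within 40 bp of both ends (edit distance <= 8) and is
trimmed; a second full-length linker scan removes chimeric reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import edlib

from .core import revcomp
from .simulate import DEFAULT_LINKER

TEMPLATE = "template"
NONTEMPLATE = "nontemplate"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class BarcodeHit:
    barcode_id: str
    orientation: str  # "forward" | "reverse"
    edit_distance: int
    span: tuple[int, int]  # half-open interval of the match in the window


def _best_infix(query: str, target: str) -> tuple[int, tuple[int, int]]:
    res = edlib.align(query, target, mode="HW", task="locations")
    loc = res["locations"][0]
    return res["editDistance"], (loc[0], loc[1] + 1)


def match_barcode(
    window: str,
    barcode_set: dict[str, str],
    max_edit: int = 5,
) -> Optional[BarcodeHit]:
    """Best barcode hit in ``window`` (both orientations) or None.

    Returns None when the minimal distance exceeds ``max_edit`` or when two
    *different* barcodes tie for the minimum (ambiguous identity).
    """
    if not barcode_set:
        raise ValueError("empty barcode set")
    best: Optional[BarcodeHit] = None
    tie = False
    for bc_id, bc in barcode_set.items():
        for orientation, query in (("forward", bc), ("reverse", revcomp(bc))):
            d, span = _best_infix(query, window)
            if best is None or d < best.edit_distance:
                best = BarcodeHit(bc_id, orientation, d, span)
                tie = False
            elif d == best.edit_distance and bc_id != best.barcode_id:
                tie = True
    if best is None or best.edit_distance > max_edit or tie:
        return None
    return best


def classify_orientation(
    head_bc1: Optional[BarcodeHit],
    head_bc2: Optional[BarcodeHit],
    tail_bc1: Optional[BarcodeHit],
    tail_bc2: Optional[BarcodeHit],
) -> str:
    """Template / non-template / ambiguous from the four window hits.

    template     <=> forward 2nd barcode at head AND reverse 1st at tail
    non-template <=> forward 1st barcode at head AND reverse 2nd at tail
    Everything else (including reads satisfying both) is ambiguous.
    """
    is_template = (
        head_bc2 is not None
        and head_bc2.orientation == "forward"
        and tail_bc1 is not None
        and tail_bc1.orientation == "reverse"
    )
    is_nontemplate = (
        head_bc1 is not None
        and head_bc1.orientation == "forward"
        and tail_bc2 is not None
        and tail_bc2.orientation == "reverse"
    )
    if is_template and not is_nontemplate:
        return TEMPLATE
    if is_nontemplate and not is_template:
        return NONTEMPLATE
    return AMBIGUOUS


def trim_and_dechimera(
    seq: str,
    qual: Optional[str],
    linker: str = DEFAULT_LINKER,
    max_edit: int = 8,
    search_window: int = 40,
) -> tuple[Optional[str], Optional[str], Optional[str]]:
    """Trim linkers from both ends and reject chimeric reads.

    Returns (trimmed_seq, trimmed_qual, rejection_reason); the reason is
    None on success, "no-linker" when either end lacks a linker within
    ``search_window`` bp, or "chimera" when an internal linker copy remains
    in the trimmed read (edit distance <= ``max_edit``).
    """
    w = min(search_window + len(linker), len(seq))
    d_head, span_head = _best_infix(linker, seq[:w])
    d_tail, span_tail = _best_infix(revcomp(linker), seq[-w:])
    if d_head > max_edit or d_tail > max_edit:
        return None, None, "no-linker"
    lo = span_head[1]
    hi = len(seq) - w + span_tail[0]
    if hi <= lo:
        return None, None, "no-linker"
    trimmed = seq[lo:hi]
    tq = qual[lo:hi] if qual is not None else None
    for probe in (linker, revcomp(linker)):
        if len(trimmed) >= 1:
            d, _ = _best_infix(probe, trimmed)
            if d <= max_edit:
                return None, None, "chimera"
    return trimmed, tq, None


@dataclass
class DemuxRecord:
    name: str
    cell_id: Optional[str]
    status: str  # "assigned" | "ambiguous" | "no-linker" | "chimera"
    orientation: Optional[str] = None
    seq: Optional[str] = None
    qual: Optional[str] = None
    bc1_distance: Optional[int] = None
    bc2_distance: Optional[int] = None


@dataclass
class DemuxSummary:
    total: int = 0
    assigned: int = 0
    ambiguous: int = 0
    discarded: int = 0  # no-linker + chimera
    by_reason: dict = field(default_factory=dict)

    def check_conservation(self) -> bool:
        return self.assigned + self.ambiguous + self.discarded == self.total


def _read_fastq(path: str) -> Iterable[tuple[str, str, str]]:
    import pysam

    with pysam.FastxFile(path) as fh:
        for rec in fh:
            yield rec.name, rec.sequence, rec.quality or "F" * len(rec.sequence)


def demultiplex_run(
    reads: Union[str, Iterable[tuple[str, str, str]]],
    barcodes: dict[str, tuple[str, str]],
    linker: str = DEFAULT_LINKER,
    max_bc_edit: int = 5,
    max_linker_edit: int = 8,
    window: int = 200,
    outdir: Optional[str] = None,
) -> tuple[dict[str, list[DemuxRecord]], DemuxSummary, list[DemuxRecord]]:
    """Assign multiplexed reads to cells and normalize them.

    ``reads`` is a FASTQ path or an iterable of (name, seq, qual).
    ``barcodes`` maps cell_id -> (barcode1, barcode2); pairs must be unique.
    Returns (per-cell assigned records, summary, all per-read records).
    Assigned records hold the template-orientation, barcode- and
    linker-trimmed sequence.
    """
    pairs = list(barcodes.values())
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate barcode pair across cells")
    if not barcodes:
        raise ValueError("empty barcode table")
    bc1_set = {cell: b1 for cell, (b1, _) in barcodes.items()}
    bc2_set = {cell: b2 for cell, (_, b2) in barcodes.items()}
    pair_to_cell = {(b1, b2): cell for cell, (b1, b2) in barcodes.items()}

    if isinstance(reads, str):
        reads = _read_fastq(reads)

    per_cell: dict[str, list[DemuxRecord]] = {c: [] for c in barcodes}
    summary = DemuxSummary()
    records: list[DemuxRecord] = []
    for name, seq, qual in reads:
        summary.total += 1
        rec = _demux_one(
            name, seq, qual, bc1_set, bc2_set, barcodes, linker,
            max_bc_edit, max_linker_edit, window,
        )
        records.append(rec)
        if rec.status == "assigned":
            summary.assigned += 1
            per_cell[rec.cell_id].append(rec)
        elif rec.status == AMBIGUOUS:
            summary.ambiguous += 1
        else:
            summary.discarded += 1
            summary.by_reason[rec.status] = summary.by_reason.get(rec.status, 0) + 1

    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        for cell, recs in per_cell.items():
            with open(os.path.join(outdir, f"{cell}.fastq"), "w") as fh:
                for r in recs:
                    fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")
    return per_cell, summary, records


def _demux_one(
    name, seq, qual, bc1_set, bc2_set, barcodes, linker,
    max_bc_edit, max_linker_edit, window,
) -> DemuxRecord:
    w = min(window, len(seq) // 2)
    if w < 1:
        return DemuxRecord(name, None, AMBIGUOUS)
    head, tail = seq[:w], seq[-w:]
    h1 = match_barcode(head, bc1_set, max_bc_edit)
    h2 = match_barcode(head, bc2_set, max_bc_edit)
    t1 = match_barcode(tail, bc1_set, max_bc_edit)
    t2 = match_barcode(tail, bc2_set, max_bc_edit)
    orientation = classify_orientation(h1, h2, t1, t2)
    if orientation == AMBIGUOUS:
        return DemuxRecord(name, None, AMBIGUOUS)

    L = len(seq)
    if orientation == TEMPLATE:
        cell_bc1, cell_bc2 = t1.barcode_id, h2.barcode_id
        d1, d2 = t1.edit_distance, h2.edit_distance
        norm_seq, norm_qual = seq, qual
        head_span = h2.span  # head window starts at 0
        tail_span = (L - w + t1.span[0], L - w + t1.span[1])
    else:
        cell_bc1, cell_bc2 = h1.barcode_id, t2.barcode_id
        d1, d2 = h1.edit_distance, t2.edit_distance
        norm_seq = revcomp(seq)
        norm_qual = qual[::-1] if qual is not None else None
        # mirror the original-read hit spans into normalized coordinates
        head_span = (w - t2.span[1], w - t2.span[0])  # t2 sat in the tail window
        tail_span = (L - h1.span[1], L - h1.span[0])  # h1 sat in the head window

    if cell_bc1 != cell_bc2:
        # head and tail barcodes point at different cells
        return DemuxRecord(name, None, AMBIGUOUS)
    cell = cell_bc1

    # remove everything up to the end of the head barcode match and from
    # the start of the tail barcode match onward
    lo = head_span[1]
    hi = max(tail_span[0], lo)
    core = norm_seq[lo:hi]
    core_q = norm_qual[lo:hi] if norm_qual is not None else None
    if not core:
        return DemuxRecord(name, cell, "no-linker")
    trimmed, tq, reason = trim_and_dechimera(
        core, core_q, linker, max_linker_edit
    )
    if reason is not None:
        return DemuxRecord(name, cell, reason, orientation, bc1_distance=d1, bc2_distance=d2)
    return DemuxRecord(
        name, cell, "assigned", orientation, trimmed, tq, d1, d2
    )
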