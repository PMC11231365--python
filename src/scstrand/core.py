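"""Core domain types shared by all pipeline stages.

Coordinates are 0-based half-open on the reference. Strand follows the
Strand-seq convention: Crick = forward (+) strand of the reference,
Watson = reverse (-) strand. A directional read reports which template
strand the cell inherited at that locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CRICK = "C"
WATSON = "W"

HP1 = "HP1"
HP2 = "HP2"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class DirectionalRead:
    """One aligned, strand-normalized single-cell read.

    ``seq`` is the aligned sequence in reference orientation (as a BAM
    stores it); ``cigar`` is a list of (op, length) with op in
    {"M", "I", "D"}. Both are optional: strand/coordinate-level stages
    (QC, inversion scan, duplicate marking) work without them.
    """

    cell_id: str
    chrom: str
    start: int
    end: int
    strand: str  # CRICK or WATSON
    mapq: int = 60
    duplicate: bool = False
    haplotype: Optional[str] = None  # HP1 / HP2 / None
    seq: Optional[str] = None
    cigar: Optional[list[tuple[str, int]]] = None
    name: str = ""
    _mm_cache: Optional[tuple[np.ndarray, np.ndarray]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in (CRICK, WATSON):
            raise ValueError(f"strand must be {CRICK!r} or {WATSON!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def effective_cigar(self) -> list[tuple[str, int]]:
        if self.cigar is not None:
            return self.cigar
        return [("M", self.end - self.start)]

    def allele_at(self, pos: int) -> Optional[str]:
        """Base observed at reference position ``pos`` (None if not covered
        or deleted in this read)."""
        if self.seq is None or not (self.start <= pos < self.end):
            return None
        ref = self.start
        q = 0
        for op, ln in self.effective_cigar():
            if op == "M":
                if ref <= pos < ref + ln:
                    return self.seq[q + (pos - ref)].upper()
                ref += ln
                q += ln
            elif op == "D":
                if ref <= pos < ref + ln:
                    return None
                ref += ln
            elif op == "I":
                q += ln
            else:  # pragma: no cover - guarded by construction
                raise ValueError(f"unsupported CIGAR op {op!r}")
        return None

    def mismatch_sites(self, ref_seq: str) -> tuple[np.ndarray, np.ndarray]:
        """Reference positions where this read differs from ``ref_seq``
        within M segments, with the observed bases (uint8 ASCII codes).

        Cached per read; callers must pass the same reference each time.
        """
        if self._mm_cache is not None:
            return self._mm_cache
        pos_parts, base_parts = [], []
        ref = self.start
        q = 0
        seq = self.seq.upper()
        for op, ln in self.effective_cigar():
            if op == "M":
                r = np.frombuffer(
                    ref_seq[ref : ref + ln].upper().encode(), dtype=np.uint8
                )
                s = np.frombuffer(seq[q : q + ln].encode(), dtype=np.uint8)
                diff = np.nonzero(r != s)[0]
                if diff.size:
                    pos_parts.append(diff + ref)
                    base_parts.append(s[diff])
                ref += ln
                q += ln
            elif op == "D":
                ref += ln
            elif op == "I":
                q += ln
        if pos_parts:
            out = (np.concatenate(pos_parts), np.concatenate(base_parts))
        else:
            out = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint8))
        self._mm_cache = out
        return out

    def cigar_events(self, min_len: int = 1) -> list[tuple[str, int, int]]:
        """(type, ref_pos, length) for D/I CIGAR operations >= min_len."""
        events = []
        ref = self.start
        for op, ln in self.effective_cigar():
            if op == "M":
                ref += ln
            elif op == "D":
                if ln >= min_len:
                    events.append(("DEL", ref, ln))
                ref += ln
            elif op == "I":
                if ln >= min_len:
                    events.append(("INS", ref, ln))
        return events


@dataclass(frozen=True)
class HetSNP:
    """A (candidate) heterozygous single-nucleotide variant."""

    chrom: str
    pos: int
    ref: str
    alt: str
    source: str = "anchor"

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class PhasedVariant:
    """A called variant with haplotype-assigned alleles.

    ``hp1_allele``/``hp2_allele`` are the consensus alleles on each
    haplotype; a hetSNP has hp1_allele != hp2_allele, a homozygous-alt
    call has both equal to ``alt``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    hp1_allele: str
    hp2_allele: str
    hp1_support: int = 0
    hp2_support: int = 0
    source: str = "consensus-round1"

    @property
    def is_het(self) -> bool:
        return self.hp1_allele != self.hp2_allele

    @property
    def allele_set(self) -> frozenset:
        return frozenset((self.hp1_allele, self.hp2_allele))

    def swapped(self) -> "PhasedVariant":
        return PhasedVariant(
            self.chrom,
            self.pos,
            self.ref,
            self.alt,
            self.hp2_allele,
            self.hp1_allele,
            self.hp2_support,
            self.hp1_support,
            self.source,
        )


@dataclass
class ChromStrandCounts:
    """Per (cell, chromosome) unique-read strand counts."""

    cell_id: str
    chrom: str
    n_crick: int
    n_watson: int

    @property
    def total(self) -> int:
        return self.n_crick + self.n_watson

    @property
    def p_c(self) -> float:
        if self.total == 0:
            return float("nan")
        return self.n_crick / self.total

    @property
    def background(self) -> float:
        """min(crick, watson) / total -- the minority-strand fraction."""
        if self.total == 0:
            return float("nan")
        return min(self.n_crick, self.n_watson) / self.total


@dataclass
class StrandState:
    """Template-strand inheritance call for one (cell, chromosome)."""

    cell_id: str
    chrom: str
    pattern: str  # "WW" | "CC" | "WC" | "unknown"
    p_c: float
    total: int


@dataclass
class InversionCall:
    chrom: str
    start: int
    end: int
    n_crick: int
    n_watson: int
    genotype: str  # "HOM" | "HET" | "ungenotyped" | "filtered"

    @property
    def p_w(self) -> float:
        tot = self.n_crick + self.n_watson
        return self.n_watson / tot if tot else float("nan")


@dataclass
class SVCall:
    chrom: str
    pos: int
    type: str  # "DEL" | "INS"
    length: int
    support_hp1: int = 0
    oppose_hp1: int = 0
    support_hp2: int = 0
    oppose_hp2: int = 0
    genotype: str = "unresolved"  # "HOM" | "HET-HP1" | "HET-HP2" | "unresolved"
    n_support_reads: int = 0
    nearest_hetsnp_distance: Optional[int] = None

    @property
    def end(self) -> int:
        """Reference end of the affected interval (pos for insertions)."""
        return self.pos + (self.length if self.type == "DEL" else 0)
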