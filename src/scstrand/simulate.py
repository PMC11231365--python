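"""Truth-annotated synthetic data for strand-specific single-cell long reads.

The generator produces a diploid genome (reference + two haplotypes carrying
hetSNPs, DEL/INS structural variants and inversions), per-cell read libraries
that follow the template-strand inheritance model (WW / CC / WC per
chromosome, sister-chromatid-exchange breakpoints, background reads on the
wrong strand, per-base substitution errors), and a multiplexed FASTQ stream
decorated with combinatorial cell barcodes and a linker.

Reads are emitted with their true alignment (reference coordinates plus a
CIGAR derived from the haplotype fragment), so downstream stages can be
exercised without running an aligner; truth labels travel in read names.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO, Union

import numpy as np

from .core import CRICK, HP1, HP2, WATSON, DirectionalRead, PhasedVariant, revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# default linker between barcode and insert (Tn5 mosaic-end adaptor sequence)
DEFAULT_LINKER = "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG"

INV_GENOTYPES = ("HOM", "HET-HP1", "HET-HP2")


@dataclass(frozen=True)
class SnpTruth:
    chrom: str
    pos: int
    ref: str
    hp1: str
    hp2: str

    @property
    def is_het(self) -> bool:
        return self.hp1 != self.hp2


@dataclass(frozen=True)
class SVTruth:
    chrom: str
    pos: int
    type: str  # "DEL" | "INS"
    length: int
    seq: str  # inserted sequence for INS, "" for DEL
    on_hp1: bool
    on_hp2: bool

    @property
    def genotype(self) -> str:
        if self.on_hp1 and self.on_hp2:
            return "HOM"
        return "HET-HP1" if self.on_hp1 else "HET-HP2"


@dataclass(frozen=True)
class InversionTruth:
    chrom: str
    start: int
    end: int
    genotype: str  # "HOM" | "HET-HP1" | "HET-HP2"

    def carried_by(self, hp: str) -> bool:
        return self.genotype == "HOM" or self.genotype == f"HET-{hp}"


@dataclass
class DiploidGenomeTruth:
    """Reference sequences plus the full variant truth of both haplotypes."""

    reference: dict[str, str]
    snps: list[SnpTruth]
    svs: list[SVTruth]
    inversions: list[InversionTruth]
    _index: dict = field(default_factory=dict, repr=False)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.reference.items()}

    def het_snps(self) -> list[SnpTruth]:
        return [s for s in self.snps if s.is_het]

    def phased_variants(self) -> list[PhasedVariant]:
        """Truth SNPs as phased variants (for evaluating calls)."""
        out = []
        for s in self.snps:
            alt = s.hp1 if s.hp1 != s.ref else s.hp2
            out.append(
                PhasedVariant(s.chrom, s.pos, s.ref, alt, s.hp1, s.hp2, source="truth")
            )
        return out

    def variants_for(self, chrom: str, hp: str):
        """Cached per-haplotype variant arrays used by fragment extraction."""
        key = (chrom, hp)
        if key not in self._index:
            attr = "hp1" if hp == HP1 else "hp2"
            snps = [
                s
                for s in self.snps
                if s.chrom == chrom and getattr(s, attr) != s.ref
            ]
            snp_pos = np.array([s.pos for s in snps], dtype=np.int64)
            snp_alt = np.frombuffer(
                "".join(getattr(s, attr) for s in snps).encode(), dtype=np.uint8
            ).copy() if snps else np.empty(0, dtype=np.uint8)
            on = "on_hp1" if hp == HP1 else "on_hp2"
            svs = sorted(
                (v for v in self.svs if v.chrom == chrom and getattr(v, on)),
                key=lambda v: v.pos,
            )
            invs = [
                iv
                for iv in self.inversions
                if iv.chrom == chrom and iv.carried_by(hp)
            ]
            self._index[key] = (snp_pos, snp_alt, svs, invs)
        return self._index[key]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def simulate_diploid_genome(
    n_chroms: int = 2,
    chrom_length: int = 1_000_000,
    snp_rate: float = 1e-3,
    sv_rate: float = 0.0,
    inversion_spec: Optional[Sequence[tuple]] = None,
    seed: int = 0,
    sv_length_range: tuple[int, int] = (50, 500),
) -> DiploidGenomeTruth:
    """Generate a random diploid genome with truth-annotated variants.

    ``snp_rate`` and ``sv_rate`` are per-bp expectations; every SNP is
    heterozygous (the alt allele is carried by one random haplotype).
    ``inversion_spec`` lists (chrom, start, end, genotype) with genotype in
    {"HOM", "HET-HP1", "HET-HP2"}; requested inversions must not overlap.
    SVs are placed away from each other and away from inversion breakpoints.
    """
    if chrom_length < 10_000:
        raise ValueError("chromosome length must be >= 10 kb")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    reference = {c: _random_dna(rng, chrom_length) for c in chroms}

    inversions: list[InversionTruth] = []
    for spec in inversion_spec or []:
        chrom, start, end, gt = spec
        if chrom not in reference:
            raise ValueError(f"unknown chromosome {chrom!r} in inversion spec")
        if not (0 <= start < end <= chrom_length):
            raise ValueError(f"inversion {spec} out of bounds")
        if gt not in INV_GENOTYPES:
            raise ValueError(f"inversion genotype must be one of {INV_GENOTYPES}")
        for iv in inversions:
            if iv.chrom == chrom and start < iv.end and end > iv.start:
                raise ValueError(
                    f"requested inversions overlap: {spec} vs "
                    f"({iv.chrom}, {iv.start}, {iv.end})"
                )
        inversions.append(InversionTruth(chrom, start, end, gt))

    svs: list[SVTruth] = []
    margin = 1000
    for chrom in chroms:
        n_sv = rng.poisson(sv_rate * chrom_length)
        placed: list[tuple[int, int]] = []
        chrom_invs = [iv for iv in inversions if iv.chrom == chrom]
        attempts = 0
        while len(placed) < n_sv and attempts < 50 * max(n_sv, 1):
            attempts += 1
            ln = int(rng.integers(sv_length_range[0], sv_length_range[1] + 1))
            pos = int(rng.integers(margin, chrom_length - ln - margin))
            span = (pos - margin, pos + ln + margin)
            if any(span[0] < e and span[1] > s for s, e in placed):
                continue
            if any(
                span[0] < iv.end + margin and span[1] > iv.start - margin
                for iv in chrom_invs
            ):
                continue
            placed.append((pos, pos + ln))
            typ = "DEL" if rng.random() < 0.5 else "INS"
            gt = rng.choice(["HOM", "HET-HP1", "HET-HP2"])
            svs.append(
                SVTruth(
                    chrom,
                    pos,
                    typ,
                    ln,
                    _random_dna(rng, ln) if typ == "INS" else "",
                    on_hp1=gt in ("HOM", "HET-HP1"),
                    on_hp2=gt in ("HOM", "HET-HP2"),
                )
            )
    svs.sort(key=lambda v: (v.chrom, v.pos))
    sv_spans = {
        c: [(v.pos - 1, v.pos + (v.length if v.type == "DEL" else 0) + 1) for v in svs if v.chrom == c]
        for c in chroms
    }

    snps: list[SnpTruth] = []
    for chrom in chroms:
        hits = np.nonzero(rng.random(chrom_length) < snp_rate)[0]
        spans = sv_spans[chrom]
        for pos in hits:
            pos = int(pos)
            if any(s <= pos < e for s, e in spans):
                continue
            ref_base = reference[chrom][pos]
            alt = rng.choice([b for b in "ACGT" if b != ref_base])
            if rng.random() < 0.5:
                snps.append(SnpTruth(chrom, pos, ref_base, str(alt), ref_base))
            else:
                snps.append(SnpTruth(chrom, pos, ref_base, ref_base, str(alt)))
    snps.sort(key=lambda s: (s.chrom, s.pos))
    return DiploidGenomeTruth(reference, snps, svs, inversions)


def haplotype_sequence(truth: DiploidGenomeTruth, chrom: str, hp: str) -> str:
    """Full sequence of one haplotype: SNPs and SVs applied, carried
    inversion intervals reverse-complemented."""
    ref = truth.reference[chrom]
    snp_pos, snp_alt, svs, invs = truth.variants_for(chrom, hp)
    arr = bytearray(ref.encode())
    if snp_pos.size:
        a = np.frombuffer(bytes(arr), dtype=np.uint8).copy()
        a[snp_pos] = snp_alt
        arr = bytearray(a.tobytes())
    # inversions first (they contain no SVs by construction)
    for iv in invs:
        arr[iv.start : iv.end] = revcomp(arr[iv.start : iv.end].decode()).encode()
    parts = []
    cursor = 0
    for sv in svs:
        parts.append(arr[cursor : sv.pos].decode())
        if sv.type == "DEL":
            cursor = sv.pos + sv.length
        else:
            parts.append(sv.seq)
            cursor = sv.pos
    parts.append(arr[cursor:].decode())
    return "".join(parts)


def haplotype_fragment(
    truth: DiploidGenomeTruth, chrom: str, hp: str, start: int, ref_span: int
) -> tuple[str, list[tuple[str, int]], int]:
    """Extract the aligned form of a haplotype fragment.

    Returns (sequence in reference orientation, CIGAR, reference end).
    SNPs become substitutions inside M ops, haplotype SVs become D/I ops.
    ``start`` must not fall inside a deletion on this haplotype.
    """
    ref = truth.reference[chrom]
    snp_pos, snp_alt, svs, _ = truth.variants_for(chrom, hp)
    end = min(start + ref_span, len(ref))

    def m_segment(a: int, b: int) -> str:
        seg = bytearray(ref[a:b].encode())
        lo = np.searchsorted(snp_pos, a)
        hi = np.searchsorted(snp_pos, b)
        for i in range(lo, hi):
            seg[snp_pos[i] - a] = snp_alt[i]
        return seg.decode()

    parts: list[str] = []
    cigar: list[tuple[str, int]] = []
    cursor = start
    for sv in svs:
        if sv.type == "DEL":
            if sv.pos >= end:
                break
            if sv.pos + sv.length <= cursor:
                continue
            if sv.pos > cursor:
                parts.append(m_segment(cursor, sv.pos))
                cigar.append(("M", sv.pos - cursor))
            d_end = min(sv.pos + sv.length, end)
            cigar.append(("D", d_end - max(sv.pos, cursor)))
            cursor = d_end
        else:  # INS
            if sv.pos >= end or sv.pos <= cursor:
                continue
            parts.append(m_segment(cursor, sv.pos))
            cigar.append(("M", sv.pos - cursor))
            parts.append(sv.seq)
            cigar.append(("I", sv.length))
            cursor = sv.pos
    if cursor < end:
        parts.append(m_segment(cursor, end))
        cigar.append(("M", end - cursor))
    return "".join(parts), cigar, end


@dataclass
class CellSimConfig:
    """Per-cell simulation parameters.

    ``patterns`` maps chromosome -> inheritance pattern ("WW"/"CC"/"WC");
    pass "random" to draw per chromosome (WC with probability 1/2, WW and CC
     1/4 each, matching independent segregation of two homologs).
    ``sce_rate`` is the expected number of sister-chromatid-exchange
    breakpoints per chromosome (split evenly between homologs).
    """

    n_reads: int = 500
    read_length_mean: float = 2794.0
    read_length_sigma: float = 0.45
    patterns: Union[str, dict[str, str]] = "random"
    sce_rate: float = 0.2
    background_rate: float = 0.01
    base_error_rate: float = 0.008
    barcode_error_edits: int = 2
    seed: int = 0

    def __post_init__(self):
        for r in (self.background_rate, self.base_error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")


@dataclass
class SimRead:
    """A simulated read with its truth labels, in aligned form."""

    cell_id: str
    chrom: str
    start: int
    end: int
    hp: str
    strand: str  # emitted strand (after background flips)
    true_strand: str  # template strand before background flip
    background: bool
    seq: str
    cigar: list[tuple[str, int]]
    name: str

    def to_directional(self) -> DirectionalRead:
        return DirectionalRead(
            cell_id=self.cell_id,
            chrom=self.chrom,
            start=self.start,
            end=self.end,
            strand=self.strand,
            seq=self.seq,
            cigar=self.cigar,
            name=self.name,
        )

    def template_oriented_seq(self) -> str:
        """The sequence as physically present on the template molecule."""
        return self.seq if self.strand == CRICK else revcomp(self.seq)


@dataclass
class CellLibrary:
    cell_id: str
    reads: list[SimRead]
    patterns: dict[str, str]
    # template strand of each haplotype per chromosome (before SCE flips)
    hp_strands: dict[str, dict[str, str]]
    sce_breakpoints: dict[tuple[str, str], list[int]]

    def directional_reads(self) -> list[DirectionalRead]:
        return [r.to_directional() for r in self.reads]


def simulate_cell_library(
    truth: DiploidGenomeTruth, config: CellSimConfig, cell_id: str = "cell0"
) -> CellLibrary:
    """Simulate one cell's strand-specific read library.

    Each chromosome follows its inheritance pattern; reads from a homolog
    are emitted on that homolog's template strand, flipped downstream of
    SCE breakpoints and inside carried inversion intervals, and flipped
    again with probability ``background_rate`` (background noise).
    """
    rng = np.random.default_rng(config.seed)
    chroms = list(truth.reference)
    lengths = np.array([len(truth.reference[c]) for c in chroms], dtype=float)

    if config.patterns == "random":
        patterns = {
            c: str(rng.choice(["WW", "CC", "WC", "WC"])) for c in chroms
        }
    else:
        patterns = dict(config.patterns)
        missing = [c for c in chroms if c not in patterns]
        if missing:
            raise ValueError(f"no inheritance pattern for chromosomes {missing}")

    hp_strands: dict[str, dict[str, str]] = {}
    for c in chroms:
        pat = patterns[c]
        if pat == "WW":
            hp_strands[c] = {HP1: WATSON, HP2: WATSON}
        elif pat == "CC":
            hp_strands[c] = {HP1: CRICK, HP2: CRICK}
        elif pat == "WC":
            if rng.random() < 0.5:
                hp_strands[c] = {HP1: CRICK, HP2: WATSON}
            else:
                hp_strands[c] = {HP1: WATSON, HP2: CRICK}
        else:
            raise ValueError(f"unknown pattern {pat!r} for {c}")

    sce: dict[tuple[str, str], list[int]] = {}
    for c in chroms:
        for hp in (HP1, HP2):
            n = rng.poisson(config.sce_rate / 2.0)
            bps = sorted(int(b) for b in rng.integers(0, len(truth.reference[c]), n))
            sce[(c, hp)] = bps

    def template_strand(chrom: str, hp: str, mid: int) -> str:
        s = hp_strands[chrom][hp]
        flips = sum(1 for b in sce[(chrom, hp)] if b <= mid)
        _, _, _, invs = truth.variants_for(chrom, hp)
        flips += sum(1 for iv in invs if iv.start <= mid < iv.end)
        if flips % 2:
            return WATSON if s == CRICK else CRICK
        return s

    mu = np.log(config.read_length_mean) - config.read_length_sigma**2 / 2.0
    p_chrom = lengths / lengths.sum()
    reads: list[SimRead] = []
    i = 0
    while len(reads) < config.n_reads:
        chrom = chroms[int(rng.choice(len(chroms), p=p_chrom))]
        hp = HP1 if rng.random() < 0.5 else HP2
        clen = len(truth.reference[chrom])
        span = int(np.clip(rng.lognormal(mu, config.read_length_sigma), 200, clen - 1))
        start = int(rng.integers(0, clen - span))
        _, _, svs, invs = truth.variants_for(chrom, hp)
        # avoid starting/ending inside a deletion or straddling an
        # inversion breakpoint (a real aligner would clip/split there)
        bad = False
        for sv in svs:
            if sv.type == "DEL":
                if sv.pos < start < sv.pos + sv.length:
                    bad = True
                if sv.pos < start + span < sv.pos + sv.length:
                    span = sv.pos + sv.length - start + 50
        for iv in invs:
            for bp in (iv.start, iv.end):
                if start < bp < start + span:
                    # keep the larger side of the breakpoint
                    if bp - start >= start + span - bp:
                        span = bp - start
                    else:
                        start = bp
        if bad or span < 100 or start + span > clen:
            continue
        seq, cigar, end = haplotype_fragment(truth, chrom, hp, start, span)
        if config.base_error_rate > 0:
            seq = _inject_substitutions(rng, seq, config.base_error_rate)
        mid = (start + end) // 2
        strand = template_strand(chrom, hp, mid)
        bg = bool(rng.random() < config.background_rate)
        emitted = strand
        if bg:
            emitted = WATSON if strand == CRICK else CRICK
        name = f"{cell_id}:{i}:{chrom}:{start}:{end}:{hp}:{emitted}:{int(bg)}"
        reads.append(
            SimRead(cell_id, chrom, start, end, hp, emitted, strand, bg, seq, cigar, name)
        )
        i += 1
    return CellLibrary(cell_id, reads, patterns, hp_strands, sce)


def _inject_substitutions(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n_err = rng.binomial(arr.size, rate)
    if n_err == 0:
        return seq
    pos = rng.choice(arr.size, size=n_err, replace=False)
    # shift each hit to a different base
    offsets = rng.integers(1, 4, size=n_err)
    idx = np.searchsorted(BASES, arr[pos])
    idx[idx >= 4] = 0  # non-ACGT safety
    arr[pos] = BASES[(idx + offsets) % 4]
    return arr.tobytes().decode()


def simulate_cells(
    truth: DiploidGenomeTruth,
    n_cells: int,
    config: CellSimConfig,
    seed: int = 0,
) -> list[CellLibrary]:
    """Simulate ``n_cells`` libraries with per-cell seeds derived from
    ``seed`` (byte-reproducible for a fixed seed)."""
    ss = np.random.SeedSequence(seed)
    out = []
    for k, child in enumerate(ss.spawn(n_cells)):
        cfg = CellSimConfig(**{**config.__dict__, "seed": int(child.generate_state(1)[0] % (2**31))})
        out.append(simulate_cell_library(truth, cfg, cell_id=f"cell{k:03d}"))
    return out


# ---------------------------------------------------------------------------
# barcoding / FASTQ emission


def random_barcode_tables(
    n_cells: int, length: int = 24, min_distance: int = 12, seed: int = 0
) -> dict[str, tuple[str, str]]:
    """Well-separated random barcode pairs, one (bc1, bc2) per cell."""
    import edlib

    rng = np.random.default_rng(seed)
    pool: list[str] = []
    while len(pool) < 2 * n_cells:
        cand = _random_dna(rng, length)
        if all(
            edlib.align(cand, b, mode="NW", task="distance")["editDistance"]
            >= min_distance
            for b in pool
        ):
            pool.append(cand)
    return {
        f"cell{k:03d}": (pool[2 * k], pool[2 * k + 1]) for k in range(n_cells)
    }


def _edit_sequence(rng: np.random.Generator, seq: str, n_edits: int) -> str:
    s = list(seq)
    for _ in range(n_edits):
        op = rng.integers(0, 3)
        if op == 0 and s:  # substitution
            i = int(rng.integers(0, len(s)))
            s[i] = str(rng.choice([b for b in "ACGT" if b != s[i]]))
        elif op == 1:  # insertion
            i = int(rng.integers(0, len(s) + 1))
            s.insert(i, str(rng.choice(list("ACGT"))))
        elif s:  # deletion
            i = int(rng.integers(0, len(s)))
            del s[i]
    return "".join(s)


def emit_multiplexed_fastq(
    libraries: Sequence[CellLibrary],
    barcodes: dict[str, tuple[str, str]],
    linker: str = DEFAULT_LINKER,
    barcode_error_edits: int = 0,
    seed: int = 0,
    out: Optional[Union[str, TextIO]] = None,
) -> list[tuple[str, str, str]]:
    """Decorate and multiplex simulated reads into one FASTQ stream.

    Template-orientation layout is
    ``bc2 + linker + insert + revcomp(linker) + revcomp(bc1)``; each read
    is emitted in template or non-template orientation with equal
    probability (recorded as a trailing ``:T``/``:N`` name token). Each
    barcode copy receives 0..``barcode_error_edits`` random edits.
    Returns the records; writes FASTQ if ``out`` is given.
    """
    pairs = list(barcodes.values())
    if len(set(pairs)) != len(pairs):
        raise ValueError("barcode pairs must be unique across cells")
    for lib in libraries:
        if lib.cell_id not in barcodes:
            raise ValueError(f"no barcode pair for cell {lib.cell_id!r}")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str, str]] = []
    for lib in libraries:
        bc1, bc2 = barcodes[lib.cell_id]
        for read in lib.reads:
            k1 = int(rng.integers(0, barcode_error_edits + 1))
            k2 = int(rng.integers(0, barcode_error_edits + 1))
            b1 = _edit_sequence(rng, bc1, k1) if k1 else bc1
            b2 = _edit_sequence(rng, bc2, k2) if k2 else bc2
            insert = read.template_oriented_seq()
            layout = b2 + linker + insert + revcomp(linker) + revcomp(b1)
            if rng.random() < 0.5:
                name = read.name + ":T"
                seq = layout
            else:
                name = read.name + ":N"
                seq = revcomp(layout)
            records.append((name, seq, "F" * len(seq)))
    if out is not None:
        fh = open(out, "w") if isinstance(out, str) else out
        try:
            for name, seq, qual in records:
                fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
        finally:
            if isinstance(out, str):
                fh.close()
    return records


def parse_truth_name(name: str) -> dict:
    """Decode the structured truth token carried in simulated read names."""
    parts = name.split(":")
    d = {
        "cell_id": parts[0],
        "index": int(parts[1]),
        "chrom": parts[2],
        "start": int(parts[3]),
        "end": int(parts[4]),
        "hp": parts[5],
        "strand": parts[6],
        "background": bool(int(parts[7])),
    }
    if len(parts) > 8:
        d["orientation"] = "template" if parts[8] == "T" else "nontemplate"
    return d


# ---------------------------------------------------------------------------
# assembly-contig simulation (for strand-matrix clustering)


@dataclass(frozen=True)
class SimContig:
    """A piece of reference standing in for a de novo assembly contig."""

    contig_id: str
    chrom: str
    start: int
    end: int
    reversed: bool

    @property
    def length(self) -> int:
        return self.end - self.start

    def sequence(self, truth: DiploidGenomeTruth) -> str:
        seq = truth.reference[self.chrom][self.start : self.end]
        return revcomp(seq) if self.reversed else seq


def make_contigs(
    truth: DiploidGenomeTruth, pieces_per_chrom: int, seed: int = 0
) -> list[SimContig]:
    """Cut every chromosome into equal pieces with random orientations."""
    rng = np.random.default_rng(seed)
    contigs = []
    k = 0
    for chrom, seq in truth.reference.items():
        edges = np.linspace(0, len(seq), pieces_per_chrom + 1).astype(int)
        for a, b in zip(edges[:-1], edges[1:]):
            contigs.append(
                SimContig(f"ctg{k:03d}", chrom, int(a), int(b), bool(rng.random() < 0.5))
            )
            k += 1
    return contigs


def contig_strand_counts(
    libraries: Sequence[CellLibrary], contigs: Sequence[SimContig]
) -> dict[tuple[str, str], tuple[int, int]]:
    """(contig_id, cell_id) -> (crick, watson) counts of reads mapped to
    each contig. A read belongs to the contig containing its midpoint;
    its strand relative to the contig flips when the contig is reversed."""
    by_chrom: dict[str, list[SimContig]] = {}
    for c in contigs:
        by_chrom.setdefault(c.chrom, []).append(c)
    for v in by_chrom.values():
        v.sort(key=lambda c: c.start)
    counts: dict[tuple[str, str], list[int]] = {}
    for lib in libraries:
        for read in lib.reads:
            mid = (read.start + read.end) // 2
            for ctg in by_chrom.get(read.chrom, ()):
                if ctg.start <= mid < ctg.end:
                    strand = read.strand
                    if ctg.reversed:
                        strand = WATSON if strand == CRICK else CRICK
                    key = (ctg.contig_id, lib.cell_id)
                    cw = counts.setdefault(key, [0, 0])
                    cw[0 if strand == CRICK else 1] += 1
                    break
    return {k: (v[0], v[1]) for k, v in counts.items()}


# ---------------------------------------------------------------------------
# truth writers (plain-text formats)


def write_fasta(sequences: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth_vcf(truth: DiploidGenomeTruth, path: str) -> None:
    """Truth SNPs and SVs as a minimal phased VCF (1-based positions)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, ln in truth.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ttruth\n")
        rows = []
        for s in truth.snps:
            alt = s.hp1 if s.hp1 != s.ref else s.hp2
            gt = f"{int(s.hp1 == alt)}|{int(s.hp2 == alt)}"
            rows.append((s.chrom, s.pos, s.ref, alt, ".", gt))
        for v in truth.svs:
            ref = truth.reference[v.chrom][v.pos]
            if v.type == "DEL":
                info = f"SVTYPE=DEL;SVLEN=-{v.length}"
                alt = "<DEL>"
            else:
                info = f"SVTYPE=INS;SVLEN={v.length}"
                alt = "<INS>"
            gt = f"{int(v.on_hp1)}|{int(v.on_hp2)}"
            rows.append((v.chrom, v.pos, ref, alt, info, gt))
        for chrom, pos, ref, alt, info, gt in sorted(rows, key=lambda r: (r[0], r[1])):
            fh.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t{gt}\n")


def write_inversions_bed(truth: DiploidGenomeTruth, path: str) -> None:
    with open(path, "w") as fh:
        for iv in truth.inversions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.genotype}\n")


def write_barcode_table(barcodes: dict[str, tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("cell_id\tbarcode1\tbarcode2\n")
        for cell, (b1, b2) in barcodes.items():
            fh.write(f"{cell}\t{b1}\t{b2}\n")
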