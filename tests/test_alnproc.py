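"""Alignment filtering, duplicate marking and haplotype annotation."""

import numpy as np
import pysam
import pytest

from conftest import make_read
from scstrand.alnproc import (
    PhasedVariantIndex,
    annotate_haplotype,
    filter_alignments,
    mark_duplicates,
    reads_from_sam,
    reads_to_sam,
)
from scstrand.core import CRICK, HP1, HP2, WATSON, PhasedVariant


def _header():
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": "chr1", "LN": 100_000},
                {"SN": "chrM", "LN": 16_000},
            ],
        }
    )


def _aln(header, chrom="chr1", start=100, mapq=60, flag=0, name="cellA:1"):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.reference_id = ["chr1", "chrM"].index(chrom)
    a.reference_start = start
    a.mapping_quality = mapq
    a.flag = flag
    a.cigartuples = [(0, 50)]
    a.query_sequence = "A" * 50
    return a

def test_filter_alignment_rules():
    h = _header()
    alns = [
        _aln(h, start=10, mapq=29),          # low MAPQ -> dropped
        _aln(h, start=20, mapq=30),          # boundary MAPQ -> kept
        _aln(h, start=30, flag=256),         # secondary -> dropped
        _aln(h, start=40, flag=2048),        # supplementary -> dropped
        _aln(h, start=50, flag=4),           # unmapped -> dropped
        _aln(h, start=70, flag=16),          # Watson read -> kept
        _aln(h, chrom="chrM", start=60),     # mitochondrial -> dropped
    ]
    reads = filter_alignments(alns)
    assert [(r.start, r.strand) for r in reads] == [(20, CRICK), (70, WATSON)]
    assert all(r.mapq >= 30 for r in reads)


def test_unsorted_input_raises():
    h = _header()
    with pytest.raises(ValueError, match="sorted"):
        filter_alignments([_aln(h, start=500), _aln(h, start=100)])


@pytest.mark.parametrize(
    "d_start,d_end,same_strand,expect_dup",
    [
        (19, 19, True, True),   # inside tolerance on both edges
        (20, 0, True, False),   # strict inequality on start
        (0, 20, True, False),   # strict inequality on end
        (0, 0, False, False),   # opposite strands never duplicate
    ],
)
def test_duplicate_pair_rules(d_start, d_end, same_strand, expect_dup):
    r1 = make_read(start=1000, end=2000, strand=CRICK)
    r2 = make_read(
        start=1000 + d_start,
        end=2000 + d_end,
        strand=CRICK if same_strand else WATSON,
    )
    marked = mark_duplicates([r1, r2])
    assert sum(r.duplicate for r in marked) == (1 if expect_dup else 0)


def brute_force_duplicates(reads, edge_tol=20):
    """O(n^2) oracle: pairwise relation + transitive closure."""
    n = len(reads)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            ri, rj = reads[i], reads[j]
            adj[i][j] = (
                i != j
                and ri.cell_id == rj.cell_id
                and ri.chrom == rj.chrom
                and ri.strand == rj.strand
                and abs(ri.start - rj.start) < edge_tol
                and abs(ri.end - rj.end) < edge_tol
            )
    seen, groups = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], []
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            comp.append(k)
            stack.extend(j for j in range(n) if adj[k][j])
        groups.append(comp)
    flags = [False] * n
    for comp in groups:
        if len(comp) == 1:
            continue
        keep = max(comp, key=lambda i: (reads[i].mapq, reads[i].length, -reads[i].start))
        for i in comp:
            flags[i] = i != keep
    return flags


def _random_reads(rng, n=200):
    reads = []
    for _ in range(n):
        s = int(rng.integers(0, 2000))
        ln = int(rng.integers(50, 150))
        reads.append(
            make_read(
                start=s,
                end=s + ln,
                strand=CRICK if rng.random() < 0.5 else WATSON,
                mapq=int(rng.integers(30, 61)),
            )
        )
    return reads


def test_duplicate_marking_matches_bruteforce_closure(rng):
    reads = _random_reads(rng)
    expected = brute_force_duplicates(reads)
    mark_duplicates(reads)
    assert [r.duplicate for r in reads] == expected
    # exactly one representative per group survives
    assert sum(not f for f in expected) == sum(not r.duplicate for r in reads)


def test_duplicate_marking_is_order_independent(rng):
    reads = _random_reads(rng, 120)
    mark_duplicates(reads)
    ref_flags = {id(r): r.duplicate for r in reads}
    perm = list(rng.permutation(len(reads)))
    shuffled = [reads[i] for i in perm]
    mark_duplicates(shuffled)
    assert all(r.duplicate == ref_flags[id(r)] for r in shuffled)


def _index():
    return PhasedVariantIndex(
        [
            PhasedVariant("chr1", 100, "A", "G", "A", "G"),
            PhasedVariant("chr1", 200, "C", "T", "T", "C"),
            PhasedVariant("chr1", 300, "G", "A", "G", "A"),
        ]
    )


def _spanning_read(bases):
    """Read covering positions 0..400 with given bases at 100/200/300."""
    seq = list("A" * 400)
    for pos, b in bases.items():
        seq[pos] = b
    return make_read(start=0, end=400, seq="".join(seq))


def test_annotate_all_hp1_alleles():
    read = _spanning_read({100: "A", 200: "T", 300: "G"})
    assert annotate_haplotype(read, _index()) == HP1


def test_annotate_mixed_alleles_is_ambiguous():
    read = _spanning_read({100: "A", 200: "T", 300: "A"})  # 2x HP1 + 1x HP2
    assert annotate_haplotype(read, _index()) is None


def test_annotate_no_informative_site():
    read = make_read(start=500, end=600, seq="A" * 100)
    assert annotate_haplotype(read, _index()) is None


def test_annotate_unknown_allele_uninformative():
    # base matching neither haplotype at 100, clean HP2 alleles elsewhere
    read = _spanning_read({100: "C", 200: "C", 300: "A"})
    assert annotate_haplotype(read, _index()) == HP2


def test_annotation_symmetric_under_label_swap():
    idx = _index()
    reads = [
        _spanning_read({100: "A", 200: "T", 300: "G"}),
        _spanning_read({100: "G", 200: "C", 300: "A"}),
        make_read(start=500, end=600, seq="A" * 100),
    ]
    tags = [annotate_haplotype(r, idx) for r in reads]
    swapped = [annotate_haplotype(r, idx.swapped()) for r in reads]
    flip = {HP1: HP2, HP2: HP1, None: None}
    assert swapped == [flip[t] for t in tags]


def test_sam_roundtrip(tmp_path, small_truth):
    from scstrand.simulate import CellSimConfig, simulate_cell_library

    cfg = CellSimConfig(n_reads=50, base_error_rate=0.0, seed=3)
    lib = simulate_cell_library(small_truth, cfg, cell_id="cellZ")
    reads = lib.directional_reads()
    path = str(tmp_path / "cell.sam")
    reads_to_sam(reads, small_truth.chrom_lengths, path)
    back = reads_from_sam(path)
    assert len(back) == len(reads)
    key = lambda r: (r.start, r.end, r.strand, r.cell_id)
    for a, b in zip(sorted(reads, key=key), sorted(back, key=key)):
        assert key(a) == key(b)
        assert a.seq == b.seq
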