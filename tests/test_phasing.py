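"""Anchor calling, orientation clustering, consensus calls and metrics."""

import numpy as np
import pytest

from conftest import make_read
from scstrand.core import CRICK, HP1, HP2, WATSON, HetSNP, PhasedVariant
from scstrand.phasing import (
    OrientationScore,
    apply_inversion_corrections,
    call_anchor_hetsnps,
    call_consensus_snps,
    cluster_orientations,
    evaluate_phasing,
    link_known_snps,
    orientation_score,
    round2_reconstruct,
    strand_allele_profile,
)

REF = "A" * 1000


def _reads_at(pos, bases, strand=CRICK, cell="c"):
    """Reads spanning [0, 1000) with a single given base at ``pos``."""
    out = []
    for b in bases:
        seq = REF[:pos] + b + REF[pos + 1 :]
        out.append(make_read(cell=cell, start=0, end=1000, seq=seq, strand=strand))
    return out


def test_anchor_balanced_het_called():
    reads = _reads_at(500, "A" * 20 + "G" * 20)
    anchors, _ = call_anchor_hetsnps(reads, {"chr1": REF})
    assert [(a.pos, a.ref, a.alt) for a in anchors] == [(500, "A", "G")]


def test_anchor_homozygous_site_not_called():
    reads = _reads_at(500, "A" * 39 + "G")
    anchors, _ = call_anchor_hetsnps(reads, {"chr1": REF})
    assert anchors == []


def test_anchor_low_depth_not_called():
    reads = _reads_at(500, "A" * 4 + "G" * 4)
    anchors, _ = call_anchor_hetsnps(reads, {"chr1": REF})
    assert anchors == []


def test_anchor_zero_depth_genome():
    anchors, blacklist = call_anchor_hetsnps([], {"chr1": REF})
    assert anchors == []


def _profile(crick_codes, watson_codes):
    return {
        CRICK: np.array(crick_codes, dtype=np.int8),
        WATSON: np.array(watson_codes, dtype=np.int8),
    }


def test_orientation_score_hand_computed():
    # 5 anchors; codes -1 = missing
    p1 = _profile([0, 1, 2, -1, 3], [1, 0, 3, 2, -1])
    p2 = _profile([0, 1, -1, 0, 3], [1, 0, 3, -1, 1])
    s = orientation_score(p1, p2)
    # parallel: C-C matches at anchors 0,1,4 = 3; W-W matches at 0,1,2 = 3
    assert s.agree_parallel == 6
    # antiparallel: C1-W2 matches nowhere; W1-C2 at anchor 1? W1[1]=0,C2[1]=1 no;
    # check: C1 vs W2: (0,1)(1,0)(2,3)(x)(3,1) -> 0; W1 vs C2: (1,0)(0,1)(3,x)(2,0)(x,3) -> 0
    assert s.agree_antiparallel == 0
    assert s.log2fc == pytest.approx(np.log2(7.0))


def test_orientation_score_mirror_case():
    p1 = _profile([0, 1, 2, 3], [3, 2, 1, 0])
    p2_flipped = {CRICK: p1[WATSON], WATSON: p1[CRICK]}
    s = orientation_score(p1, p2_flipped)
    assert s.log2fc < 0


def test_orientation_score_no_shared_anchors():
    p1 = _profile([0, -1], [-1, -1])
    p2 = _profile([-1, -1], [-1, 1])
    assert orientation_score(p1, p2) is None


def _score(i, j, fc):
    return OrientationScore(i, j, "chr1", 10, 1, fc)


def test_cluster_orientations_bipartition():
    cells = ["a", "b", "c", "d"]
    truth = {"a": 1, "b": 1, "c": -1, "d": -1}
    scores = []
    for i in range(4):
        for j in range(i + 1, 4):
            ci, cj = cells[i], cells[j]
            scores.append(_score(ci, cj, 3.0 * truth[ci] * truth[cj]))
    ca, cb, excl = cluster_orientations(cells, scores)
    assert excl == []
    assert {frozenset(ca), frozenset(cb)} == {frozenset("ab"), frozenset("cd")}


def test_cluster_single_cell():
    ca, cb, excl = cluster_orientations(["solo"], [])
    assert (ca, cb) == (["solo"], []) or (ca, cb) == ([], ["solo"]) or excl == ["solo"]
    assert len(ca) + len(cb) + len(excl) == 1


def test_inconsistent_cell_excluded():
    # six mutually consistent cells plus one whose scores contradict
    # themselves: half strongly parallel, half strongly antiparallel
    cells = ["a", "b", "c", "d", "e", "f", "x"]
    scores = []
    for i in range(6):
        for j in range(i + 1, 6):
            scores.append(_score(cells[i], cells[j], 4.0))
    for k, c in enumerate(cells[:6]):
        scores.append(_score(c, "x", 3.0 if k < 3 else -3.0))
    ca, cb, excl = cluster_orientations(cells, scores)
    assert excl == ["x"]
    assert set(ca) | set(cb) == set(cells[:6])


def _hp_reads(pos, bases, cell="c"):
    return _reads_at(pos, bases, cell=cell)


def test_consensus_clean_het_site():
    hp1 = _hp_reads(500, "AAAAA")  # 5x ref A
    hp2 = _hp_reads(500, "GGGG")  # 4x alt G
    (v,) = call_consensus_snps(hp1, hp2, REF, "chr1")
    assert (v.pos, v.ref, v.alt) == (500, "A", "G")
    assert (v.hp1_allele, v.hp2_allele) == ("A", "G")
    assert v.is_het


def test_consensus_single_read_insufficient():
    hp1 = _hp_reads(500, "G")  # one supporting read only
    hp2 = _hp_reads(500, "AAAA")
    assert call_consensus_snps(hp1, hp2, REF, "chr1") == []


def test_consensus_low_agreement_no_call():
    hp1 = _hp_reads(500, "AAAGGG")  # 50% < 80% agreement
    hp2 = _hp_reads(500, "GGGG")
    assert call_consensus_snps(hp1, hp2, REF, "chr1") == []


def test_consensus_hom_alt_emitted():
    hp1 = _hp_reads(500, "GGG")
    hp2 = _hp_reads(500, "GGGG")
    (v,) = call_consensus_snps(hp1, hp2, REF, "chr1")
    assert not v.is_het and v.hp1_allele == v.hp2_allele == "G"


def V(pos, hp1="A", hp2="G", chrom="chr1"):
    ref, alt = ("A", "G") if "A" in (hp1, hp2) else (hp1, hp2)
    return PhasedVariant(chrom, pos, "A", "G", hp1, hp2)


def test_inversion_corrections_swap_drop_keep():
    variants = [V(100), V(250), V(400)]
    inversions = [("chr1", 200, 300, "HOM"), ("chr1", 350, 450, "HET")]
    out = apply_inversion_corrections(variants, inversions)
    assert [(v.pos, v.hp1_allele, v.hp2_allele) for v in out] == [
        (100, "A", "G"),   # untouched
        (250, "G", "A"),   # swapped inside HOM inversion
    ]  # 400 dropped inside HET inversion


def test_round2_requires_round1_variants():
    with pytest.raises(ValueError):
        round2_reconstruct([], [], {"chr1": REF})


def test_round2_recovers_extra_haplotype_depth():
    # round-1 variant at 500 phases reads; a second het site at 700 only
    # reaches >= 2 reads per haplotype through re-annotation
    reads = []
    for _ in range(3):
        seq = REF[:500] + "G" + REF[501:700] + "T" + REF[701:]
        reads.append(make_read(start=0, end=1000, seq=seq, strand=CRICK))
    for _ in range(3):
        reads.append(make_read(start=0, end=1000, seq=REF, strand=WATSON))
    r1 = [PhasedVariant("chr1", 500, "A", "G", "G", "A")]
    out = round2_reconstruct(reads, r1, {"chr1": REF})
    assert {(v.pos, v.hp1_allele, v.hp2_allele) for v in out} >= {
        (500, "G", "A"),
        (700, "T", "A"),
    }


def test_link_known_concordant_reads():
    phased = [PhasedVariant("chr1", 500, "A", "G", "G", "A")]
    known = [HetSNP("chr1", 700, "A", "T", source="known-external")]
    reads = []
    for _ in range(3):  # HP1 reads: G at 500 and T at 700
        seq = REF[:500] + "G" + REF[501:700] + "T" + REF[701:]
        reads.append(make_read(start=0, end=1000, seq=seq))
    for _ in range(3):  # HP2 reads: reference at both
        reads.append(make_read(start=0, end=1000, seq=REF))
    out = link_known_snps(phased, known, reads)
    new = [v for v in out if v.pos == 700]
    assert len(new) == 1
    assert (new[0].hp1_allele, new[0].hp2_allele) == ("T", "A")


def test_link_known_single_read_unphased():
    phased = [PhasedVariant("chr1", 500, "A", "G", "G", "A")]
    known = [HetSNP("chr1", 700, "A", "T")]
    seq = REF[:500] + "G" + REF[501:700] + "T" + REF[701:]
    reads = [make_read(start=0, end=1000, seq=seq)] + [
        make_read(start=0, end=1000, seq=REF) for _ in range(3)
    ]
    out = link_known_snps(phased, known, reads)
    assert all(v.pos != 700 for v in out)


def test_link_known_conflicting_votes_unphased():
    phased = [PhasedVariant("chr1", 500, "A", "G", "G", "A")]
    known = [HetSNP("chr1", 700, "A", "T")]
    reads = []
    for alt700 in ("T", "T", "A", "A"):  # 2 vs 2 conflict on HP1
        seq = REF[:500] + "G" + REF[501:700] + alt700 + REF[701:]
        reads.append(make_read(start=0, end=1000, seq=seq))
    reads += [make_read(start=0, end=1000, seq=REF) for _ in range(3)]
    out = link_known_snps(phased, known, reads)
    assert all(v.pos != 700 for v in out)


def test_evaluate_identity():
    truth = [V(i * 10) for i in range(50)]
    m = evaluate_phasing(truth, truth)
    assert m["precision"] == m["recall"] == 1.0
    assert m["hamming_error_rate"] == 0.0
    assert m["genotype_precision"] == 1.0


def test_evaluate_chromosome_flip_is_free():
    truth = [V(i * 10) for i in range(50)]
    flipped = [v.swapped() for v in truth]
    m = evaluate_phasing(flipped, truth)
    assert m["hamming_error_rate"] == 0.0


def test_evaluate_one_percent_error():
    truth = [V(i * 10) for i in range(100)]
    called = [v if v.pos != 0 else v.swapped() for v in truth]
    m = evaluate_phasing(called, truth)
    assert m["hamming_error_rate"] == pytest.approx(0.01)


def test_evaluate_global_label_symmetry():
    truth = [V(i * 10, chrom=c) for c in ("chr1", "chr2") for i in range(30)]
    called = [v if (v.pos % 30) else v.swapped() for v in truth]
    m1 = evaluate_phasing(called, truth)
    m2 = evaluate_phasing([v.swapped() for v in called], truth)
    for k in ("precision", "recall", "genotype_precision", "hamming_error_rate"):
        assert m1[k] == pytest.approx(m2[k])


def test_evaluate_zero_overlap_flagged():
    m = evaluate_phasing([], [V(0)])
    assert np.isnan(m["hamming_error_rate"]) and m["n_compared"] == 0
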