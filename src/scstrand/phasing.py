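"""Two-round reconstruction of chromosome-scale haplotypes.

Round 1: heterozygous anchor SNPs are called from the pseudobulk pileup of
all cells (duplicates included); for every chromosome, cells in the WC
state carry the two haplotypes on opposite strands, so comparing the
Crick/Watson allele vectors of every cell pair yields a log2 fold-change
score whose sign says whether the pair is oriented parallel (CC-WW,
log2FC > 0) or antiparallel (CW-WC, log2FC < 0). A sign-consistent
bipartition of the cells then merges Crick reads of one cluster with
Watson reads of the other into two haplotype read sets, and consensus
alleles (>= 2 supporting reads and >= 80% agreement per haplotype) give
phased SNPs.

Round 2: all reads from all cells -- whatever their strand state -- are
re-annotated against the round-1 phased hetSNPs; reads assigned
unambiguously to one haplotype rebuild deeper haplotype read sets and the
consensus calling is repeated, increasing recall.

Phase corrections for inversions: variants inside homozygous-inversion
intervals have their haplotype assignment reversed, variants inside
heterozygous-inversion intervals are excluded (round 1 is strand-based and
therefore confounded by inversions; round 2 is allele-based and is not).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.stats import binom

from .alnproc import PhasedVariantIndex, annotate_haplotype
from .core import CRICK, HP1, HP2, WATSON, DirectionalRead, HetSNP, PhasedVariant

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_CODE_BASE = "ACGT"


# ---------------------------------------------------------------------------
# pileup machinery


class Pileup:
    """Depth and mismatch counts for one chromosome's read set.

    Depth counts reads covering each position through their M segments;
    mismatches are (position, base) pairs pooled across reads. Built once,
    queried at candidate positions.
    """

    def __init__(self, reads: Sequence[DirectionalRead], ref_seq: str):
        length = len(ref_seq)
        delta = np.zeros(length + 1, dtype=np.int32)
        pos_parts, base_parts = [], []
        for r in reads:
            if r.seq is None:
                continue
            ref = r.start
            for op, ln in r.effective_cigar():
                if op == "M":
                    delta[ref] += 1
                    delta[ref + ln] -= 1
                    ref += ln
                elif op == "D":
                    ref += ln
            p, b = r.mismatch_sites(ref_seq)
            if p.size:
                pos_parts.append(p)
                base_parts.append(b)
        self.depth = np.cumsum(delta[:-1]).astype(np.int32)
        if pos_parts:
            pos = np.concatenate(pos_parts)
            codes = _BASE_CODE[np.concatenate(base_parts)]
            ok = codes >= 0
            keys = pos[ok] * 4 + codes[ok]
            self.keys, self.key_counts = np.unique(keys, return_counts=True)
        else:
            self.keys = np.empty(0, dtype=np.int64)
            self.key_counts = np.empty(0, dtype=np.int64)
        self.ref_codes = _BASE_CODE[
            np.frombuffer(ref_seq.upper().encode(), dtype=np.uint8)
        ]

    def candidate_positions(self) -> np.ndarray:
        return np.unique(self.keys // 4)

    def allele_counts(self, positions: np.ndarray) -> np.ndarray:
        """(n_positions, 4) base-count matrix at the given positions."""
        counts = np.zeros((positions.size, 4), dtype=np.int64)
        if self.keys.size:
            for c in range(4):
                want = positions * 4 + c
                idx = np.minimum(
                    np.searchsorted(self.keys, want), self.keys.size - 1
                )
                hit = self.keys[idx] == want
                counts[hit, c] = self.key_counts[idx[hit]]
        nonref_total = counts.sum(axis=1)
        refc = self.ref_codes[positions]
        valid = refc >= 0
        counts[np.arange(positions.size)[valid], refc[valid]] = (
            self.depth[positions][valid] - nonref_total[valid]
        )
        return counts


# ---------------------------------------------------------------------------
# anchor hetSNP calling (pseudobulk)


def call_anchor_hetsnps(
    reads: Sequence[DirectionalRead],
    reference: dict[str, str],
    min_depth: int = 10,
    maf_range: tuple[float, float] = (0.25, 0.75),
    error_rate: float = 0.05,
    alpha: float = 0.01,
    blacklist_bin: int = 10_000,
    blacklist_sd: float = 5.0,
) -> tuple[list[HetSNP], dict[str, list[tuple[int, int]]]]:
    """Call heterozygous anchor SNPs from the merged (pseudobulk) pileup.

    A site is an anchor when depth >= ``min_depth``, the leading non-
    reference allele fraction lies in ``maf_range`` and exceeds what the
    sequencing error rate explains (one-sided binomial test at ``alpha``).
    10-kb bins whose mean depth exceeds mean + ``blacklist_sd`` * SD across
    bins form the high-coverage blacklist; anchors inside it are dropped.
    Returns (anchors, blacklist intervals per chromosome).
    """
    by_chrom: dict[str, list[DirectionalRead]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    anchors: list[HetSNP] = []
    blacklist: dict[str, list[tuple[int, int]]] = {}
    for chrom, rs in sorted(by_chrom.items()):
        ref_seq = reference[chrom]
        pile = Pileup(rs, ref_seq)
        n_bins = max(1, -(-len(ref_seq) // blacklist_bin))
        bin_means = np.array(
            [
                pile.depth[b * blacklist_bin : (b + 1) * blacklist_bin].mean()
                for b in range(n_bins)
            ]
        )
        cutoff = bin_means.mean() + blacklist_sd * bin_means.std()
        bad_bins = np.nonzero(bin_means > cutoff)[0]
        blacklist[chrom] = [
            (int(b) * blacklist_bin, (int(b) + 1) * blacklist_bin) for b in bad_bins
        ]
        cand = pile.candidate_positions()
        if cand.size == 0:
            continue
        counts = pile.allele_counts(cand)
        depth = pile.depth[cand]
        refc = pile.ref_codes[cand]
        nonref = counts.copy()
        ok = refc >= 0
        nonref[np.arange(cand.size)[ok], refc[ok]] = 0
        alt_code = nonref.argmax(axis=1)
        alt_count = nonref.max(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = alt_count / np.maximum(depth, 1)
        pvals = binom.sf(alt_count - 1, np.maximum(depth, 1), error_rate)
        keep = (
            (depth >= min_depth)
            & (frac >= maf_range[0])
            & (frac <= maf_range[1])
            & (pvals <= alpha)
            & ok
        )
        bad = set()
        for s, e in blacklist[chrom]:
            bad.update(range(s // blacklist_bin, e // blacklist_bin))
        for i in np.nonzero(keep)[0]:
            pos = int(cand[i])
            if pos // blacklist_bin in bad:
                continue
            anchors.append(
                HetSNP(
                    chrom,
                    pos,
                    _CODE_BASE[refc[i]],
                    _CODE_BASE[alt_code[i]],
                    source="anchor",
                )
            )
    return anchors, blacklist


def filter_blacklisted_reads(
    reads: Iterable[DirectionalRead],
    blacklist: dict[str, list[tuple[int, int]]],
) -> list[DirectionalRead]:
    out = []
    for r in reads:
        ivs = blacklist.get(r.chrom, ())
        if any(r.start < e and r.end > s for s, e in ivs):
            continue
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# WC-cell orientation clustering


@dataclass
class OrientationScore:
    cell_i: str
    cell_j: str
    chrom: str
    agree_parallel: int
    agree_antiparallel: int
    log2fc: float


def strand_allele_profile(
    reads: Sequence[DirectionalRead], anchor_pos: np.ndarray
) -> dict[str, np.ndarray]:
    """Majority allele code per anchor for the Crick and Watson reads of
    one (cell, chromosome); -1 where uncovered or tied."""
    votes = {
        CRICK: np.zeros((anchor_pos.size, 4), dtype=np.int32),
        WATSON: np.zeros((anchor_pos.size, 4), dtype=np.int32),
    }
    for r in reads:
        if r.seq is None:
            continue
        lo = int(np.searchsorted(anchor_pos, r.start))
        hi = int(np.searchsorted(anchor_pos, r.end))
        for k in range(lo, hi):
            a = r.allele_at(int(anchor_pos[k]))
            if a is None:
                continue
            c = _BASE_CODE[ord(a)]
            if c >= 0:
                votes[r.strand][k, c] += 1
    out = {}
    for strand, v in votes.items():
        best = v.argmax(axis=1).astype(np.int8)
        top = v.max(axis=1)
        runner = np.sort(v, axis=1)[:, -2]
        best[(top == 0) | (top == runner)] = -1
        out[strand] = best
    return out


def _matches(x: np.ndarray, y: np.ndarray) -> int:
    both = (x >= 0) & (y >= 0)
    return int(np.count_nonzero(both & (x == y)))


def orientation_score(
    profile_i: dict[str, np.ndarray],
    profile_j: dict[str, np.ndarray],
    cell_i: str = "i",
    cell_j: str = "j",
    chrom: str = "",
    epsilon: float = 1.0,
) -> Optional[OrientationScore]:
    """Pairwise orientation score between two WC cells.

    agree_parallel counts allele matches Crick-Crick plus Watson-Watson,
    agree_antiparallel Crick-Watson plus Watson-Crick;
    log2FC = log2((parallel + eps) / (antiparallel + eps)). Returns None
    when the cells share no informative anchors.
    """
    par = _matches(profile_i[CRICK], profile_j[CRICK]) + _matches(
        profile_i[WATSON], profile_j[WATSON]
    )
    anti = _matches(profile_i[CRICK], profile_j[WATSON]) + _matches(
        profile_i[WATSON], profile_j[CRICK]
    )
    if par == 0 and anti == 0:
        return None
    fc = math.log2((par + epsilon) / (anti + epsilon))
    return OrientationScore(cell_i, cell_j, chrom, par, anti, fc)


class _ParityUF:
    """Union-find tracking relative orientation (parity) between cells."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.parity = [0] * n  # parity relative to parent

    def find(self, i: int) -> tuple[int, int]:
        if self.parent[i] == i:
            return i, 0
        root, p = self.find(self.parent[i])
        self.parent[i] = root
        self.parity[i] ^= p
        return root, self.parity[i]

    def union(self, i: int, j: int, rel: int) -> bool:
        ri, pi = self.find(i)
        rj, pj = self.find(j)
        if ri == rj:
            return (pi ^ pj) == rel
        self.parent[rj] = ri
        self.parity[rj] = pi ^ pj ^ rel
        return True


def cluster_orientations(
    cells: Sequence[str],
    scores: Sequence[OrientationScore],
    min_agreement: float = 0.6,
) -> tuple[list[str], list[str], list[str]]:
    """Sign-consistent bipartition of WC cells from pairwise log2FC scores.

    Edges are consumed by decreasing |log2FC| into a parity union-find
    (log2FC > 0: same cluster; < 0: opposite). Cells whose weighted sign
    agreement with the final assignment falls below ``min_agreement``, and
    cells disconnected from the main component, are excluded.
    Deterministic given the input order of ``cells``.
    """
    index = {c: k for k, c in enumerate(cells)}
    n = len(cells)
    if n == 0:
        return [], [], []
    edges = [
        s
        for s in scores
        if s.cell_i in index and s.cell_j in index and s.log2fc != 0.0
    ]
    edges.sort(key=lambda s: (-abs(s.log2fc), s.cell_i, s.cell_j))
    uf = _ParityUF(n)
    for s in edges:
        uf.union(index[s.cell_i], index[s.cell_j], 0 if s.log2fc > 0 else 1)

    comp: dict[int, list[int]] = {}
    for k in range(n):
        root, _ = uf.find(k)
        comp.setdefault(root, []).append(k)
    main = max(comp.values(), key=len) if comp else []
    in_main = set(main)

    sign = {}
    for k in main:
        _, p = uf.find(k)
        sign[k] = 1 if p == 0 else -1

    # local refinement + consistency screening
    for _ in range(10):
        changed = False
        for k in list(sign):
            tot = 0.0
            for s in edges:
                i, j = index[s.cell_i], index[s.cell_j]
                if k == i and j in sign:
                    tot += s.log2fc * sign[k] * sign[j]
                elif k == j and i in sign:
                    tot += s.log2fc * sign[k] * sign[i]
            if tot < 0:
                sign[k] = -sign[k]
                changed = True
        if not changed:
            break

    excluded = [c for c in cells if index[c] not in in_main]
    cluster_a, cluster_b = [], []
    for c in cells:
        k = index[c]
        if k not in sign:
            continue
        agree = disagree = 0.0
        for s in edges:
            i, j = index[s.cell_i], index[s.cell_j]
            if k not in (i, j):
                continue
            other = j if k == i else i
            if other not in sign:
                continue
            if s.log2fc * sign[k] * sign[other] > 0:
                agree += abs(s.log2fc)
            else:
                disagree += abs(s.log2fc)
        total = agree + disagree
        if total == 0 or agree / total < min_agreement:
            excluded.append(c)
            continue
        (cluster_a if sign[k] > 0 else cluster_b).append(c)
    return cluster_a, cluster_b, excluded


def build_haplotype_readsets(
    cluster_a: Sequence[str],
    cluster_b: Sequence[str],
    reads_by_cell: dict[str, Sequence[DirectionalRead]],
) -> tuple[list[DirectionalRead], list[DirectionalRead]]:
    """Merge Crick reads of cluster A with Watson reads of cluster B into
    one haplotype read set, and vice versa for the other haplotype."""
    hp1: list[DirectionalRead] = []
    hp2: list[DirectionalRead] = []
    for cell in cluster_a:
        for r in reads_by_cell.get(cell, ()):
            (hp1 if r.strand == CRICK else hp2).append(r)
    for cell in cluster_b:
        for r in reads_by_cell.get(cell, ()):
            (hp1 if r.strand == WATSON else hp2).append(r)
    return hp1, hp2


# ---------------------------------------------------------------------------
# consensus calling


def call_consensus_snps(
    hp1_reads: Sequence[DirectionalRead],
    hp2_reads: Sequence[DirectionalRead],
    ref_seq: str,
    chrom: str,
    min_support: int = 2,
    min_agreement: float = 0.8,
    source: str = "consensus-round1",
) -> list[PhasedVariant]:
    """Call phased variants from the two haplotype read sets.

    At every candidate position each haplotype must have a consensus
    allele backed by >= ``min_support`` reads and >= ``min_agreement``
    within-haplotype fraction; a variant is emitted when both haplotypes
    pass and at least one consensus allele differs from the reference.
    """
    p1 = Pileup(hp1_reads, ref_seq)
    p2 = Pileup(hp2_reads, ref_seq)
    cand = np.union1d(p1.candidate_positions(), p2.candidate_positions())
    if cand.size == 0:
        return []
    out: list[PhasedVariant] = []
    c1 = p1.allele_counts(cand)
    c2 = p2.allele_counts(cand)
    refc = p1.ref_codes[cand]
    for i in range(cand.size):
        if refc[i] < 0:
            continue
        alleles = []
        for counts in (c1[i], c2[i]):
            total = int(counts.sum())
            best = int(counts.argmax())
            n_best = int(counts[best])
            if n_best < min_support or total == 0 or n_best / total < min_agreement:
                alleles = None
                break
            alleles.append((best, n_best))
        if alleles is None:
            continue
        (a1, n1), (a2, n2) = alleles
        if a1 == refc[i] and a2 == refc[i]:
            continue
        alt = a1 if a1 != refc[i] else a2
        out.append(
            PhasedVariant(
                chrom,
                int(cand[i]),
                _CODE_BASE[refc[i]],
                _CODE_BASE[alt],
                _CODE_BASE[a1],
                _CODE_BASE[a2],
                n1,
                n2,
                source=source,
            )
        )
    return out


# ---------------------------------------------------------------------------
# round 2 + corrections


def round2_reconstruct(
    reads: Sequence[DirectionalRead],
    round1_variants: Sequence[PhasedVariant],
    reference: dict[str, str],
    min_support: int = 2,
    min_agreement: float = 0.8,
) -> list[PhasedVariant]:
    """Re-annotate every read (any cell, any strand state) against the
    round-1 phased hetSNPs and repeat consensus calling on the deeper
    haplotype read sets. Reads consistent with both haplotypes (no
    informative site) are excluded."""
    if not round1_variants:
        raise ValueError("round 2 requires phased variants from round 1")
    index = PhasedVariantIndex(round1_variants)
    hp_sets: dict[str, dict[str, list[DirectionalRead]]] = {}
    for r in reads:
        tag = annotate_haplotype(r, index)
        if tag is None:
            continue
        hp_sets.setdefault(r.chrom, {HP1: [], HP2: []})[tag].append(r)
    out: list[PhasedVariant] = []
    for chrom in sorted(hp_sets):
        out.extend(
            call_consensus_snps(
                hp_sets[chrom][HP1],
                hp_sets[chrom][HP2],
                reference[chrom],
                chrom,
                min_support,
                min_agreement,
                source="consensus-round2",
            )
        )
    return out


def _interval_lookup(inversions) -> dict[str, list[tuple[int, int, str]]]:
    """Normalize inversion inputs (InversionCall objects or tuples) into
    chrom -> [(start, end, HOM|HET)]."""
    table: dict[str, list[tuple[int, int, str]]] = {}
    for iv in inversions:
        if hasattr(iv, "genotype"):
            chrom, start, end, gt = iv.chrom, iv.start, iv.end, iv.genotype
        else:
            chrom, start, end, gt = iv
        gt = "HET" if str(gt).startswith("HET") else str(gt)
        if gt not in ("HOM", "HET"):
            continue
        table.setdefault(chrom, []).append((start, end, gt))
    return table


def apply_inversion_corrections(
    variants: Sequence[PhasedVariant], inversions
) -> list[PhasedVariant]:
    """Swap haplotype alleles inside homozygous inversions; drop variants
    inside heterozygous inversions; leave everything else untouched."""
    table = _interval_lookup(inversions)
    out = []
    for v in variants:
        action = None
        for start, end, gt in table.get(v.chrom, ()):
            if start <= v.pos < end:
                action = gt
                break
        if action == "HET":
            continue
        out.append(v.swapped() if action == "HOM" else v)
    return out


def link_known_snps(
    phased: Sequence[PhasedVariant],
    known: Sequence[HetSNP],
    reads: Sequence[DirectionalRead],
    min_support: int = 2,
) -> list[PhasedVariant]:
    """Phase known-but-unphased hetSNPs through read linkage.

    Reads are annotated against the already-phased variants; a known site
    is phased when each haplotype's reads give a unanimous allele with
    >= ``min_support`` observations and the two alleles are exactly
    {ref, alt}. Conflicting votes leave the site unphased.
    Returns the extended phased set (originals first).
    """
    index = PhasedVariantIndex(phased)
    by_chrom: dict[str, list[DirectionalRead]] = {}
    for r in reads:
        tag = annotate_haplotype(r, index)
        if tag is not None:
            by_chrom.setdefault(r.chrom, []).append(r)
    already = {(v.chrom, v.pos) for v in phased}
    out = list(phased)
    for snp in known:
        if (snp.chrom, snp.pos) in already:
            continue
        votes: dict[str, dict[str, int]] = {HP1: {}, HP2: {}}
        for r in by_chrom.get(snp.chrom, ()):
            if not (r.start <= snp.pos < r.end):
                continue
            a = r.allele_at(snp.pos)
            if a in (snp.ref, snp.alt):
                votes[r.haplotype][a] = votes[r.haplotype].get(a, 0) + 1
        alleles = {}
        for hp in (HP1, HP2):
            v = votes[hp]
            if len(v) != 1:
                continue
            allele, n = next(iter(v.items()))
            if n >= min_support:
                alleles[hp] = allele
        if len(alleles) == 2 and set(alleles.values()) == {snp.ref, snp.alt}:
            out.append(
                PhasedVariant(
                    snp.chrom,
                    snp.pos,
                    snp.ref,
                    snp.alt,
                    alleles[HP1],
                    alleles[HP2],
                    source="known-linked",
                )
            )
    return out


# ---------------------------------------------------------------------------
# evaluation


def evaluate_phasing(
    called: Sequence[PhasedVariant], truth: Sequence[PhasedVariant]
) -> dict:
    """Precision / recall / genotype precision / Hamming error rate.

    Precision and recall compare (chrom, pos, allele set); genotype
    precision additionally requires the het/hom class to match. The
    Hamming error rate is computed per chromosome over het variants shared
    with the truth, minimized over the two global haplotype labelings of
    that chromosome, then aggregated across chromosomes weighted by
    compared counts (per-chromosome values are also returned).
    """
    truth_by_key = {(v.chrom, v.pos): v for v in truth}
    n_correct = 0
    n_geno = 0
    n_pos_match = 0
    per_chrom_mismatch: dict[str, list[int]] = {}
    for v in called:
        t = truth_by_key.get((v.chrom, v.pos))
        if t is None:
            continue
        n_pos_match += 1
        if v.allele_set == t.allele_set:
            n_correct += 1
            if v.is_het == t.is_het:
                n_geno += 1
            if v.is_het and t.is_het:
                m = per_chrom_mismatch.setdefault(v.chrom, [0, 0])
                m[1] += 1
                if v.hp1_allele != t.hp1_allele:
                    m[0] += 1
    if not called or not truth:
        return {
            "precision": float("nan"),
            "recall": float("nan"),
            "genotype_precision": float("nan"),
            "hamming_error_rate": float("nan"),
            "hamming_per_chrom": {},
            "n_called": len(called),
            "n_truth": len(truth),
            "n_compared": 0,
        }
    num = den = 0
    per_chrom = {}
    for chrom, (mm, n) in per_chrom_mismatch.items():
        err = min(mm, n - mm)
        per_chrom[chrom] = err / n if n else float("nan")
        num += err
        den += n
    return {
        "precision": n_correct / len(called),
        "recall": n_correct / len(truth),
        "genotype_precision": n_geno / n_pos_match if n_pos_match else float("nan"),
        "hamming_error_rate": num / den if den else float("nan"),
        "hamming_per_chrom": per_chrom,
        "n_called": len(called),
        "n_truth": len(truth),
        "n_compared": den,
    }


# ---------------------------------------------------------------------------
# driver


def largest_wc_segment(
    reads: Sequence[DirectionalRead],
    chrom_length: int,
    bin_width: int = 500_000,
    min_bin_reads: int = 20,
) -> tuple[int, int]:
    """Largest contiguous interval of a WC chromosome without an internal
    strand-state switch (sister-chromatid exchange guard). Bins whose
    Crick fraction leaves the WC range mark switch points; sparse bins are
    transparent."""
    n_bins = max(1, -(-chrom_length // bin_width))
    crick = np.zeros(n_bins)
    total = np.zeros(n_bins)
    for r in reads:
        b = min(((r.start + r.end) // 2) // bin_width, n_bins - 1)
        total[b] += 1
        if r.strand == CRICK:
            crick[b] += 1
    classes = []
    for b in range(n_bins):
        if total[b] < min_bin_reads:
            classes.append(None)
        else:
            pc = crick[b] / total[b]
            classes.append("WC" if 0.2 < pc < 0.8 else "notWC")
    best = (0, 0)
    run_start = None
    weight = 0.0
    for b in range(n_bins + 1):
        cls = classes[b] if b < n_bins else "notWC"
        if cls != "notWC":
            if run_start is None:
                run_start = b
                weight = 0.0
            weight += total[b] if b < n_bins else 0
        else:
            if run_start is not None and weight > best[0]:
                best = (weight, (run_start, b))
            run_start = None
    if best[0] == 0:
        return 0, chrom_length
    s, e = best[1]
    return s * bin_width, min(e * bin_width, chrom_length)


@dataclass
class PhasingResult:
    anchors: list[HetSNP]
    blacklist: dict[str, list[tuple[int, int]]]
    round1: list[PhasedVariant]
    round2: list[PhasedVariant]
    excluded_cells: dict[str, list[str]] = field(default_factory=dict)

    @property
    def variants(self) -> list[PhasedVariant]:
        return self.round2 if self.round2 else self.round1


def reconstruct_haplotypes(
    reads: Sequence[DirectionalRead],
    reference: dict[str, str],
    states: Sequence,
    inversions: Sequence = (),
    rounds: int = 2,
    min_support: int = 2,
    min_agreement: float = 0.8,
    sce_guard: bool = True,
    anchor_kwargs: Optional[dict] = None,
    anchors: Optional[Sequence[HetSNP]] = None,
) -> PhasingResult:
    """Run the full two-round haplotype reconstruction.

    ``reads`` should include duplicates (they contribute to pileups);
    ``states`` are per-(cell, chromosome) strand-state calls. External
    anchor hetSNPs may be supplied via ``anchors`` instead of the internal
    pseudobulk caller. Each chromosome forms its own phase set; the
    HP1/HP2 labeling per chromosome is arbitrary.
    """
    blacklist: dict[str, list[tuple[int, int]]] = {}
    if anchors is None:
        anchors, blacklist = call_anchor_hetsnps(
            reads, reference, **(anchor_kwargs or {})
        )
        reads_used = filter_blacklisted_reads(reads, blacklist)
    else:
        reads_used = list(reads)
    anchor_pos: dict[str, np.ndarray] = {}
    for a in anchors:
        anchor_pos.setdefault(a.chrom, []).append(a.pos)
    anchor_pos = {c: np.array(sorted(p), dtype=np.int64) for c, p in anchor_pos.items()}

    wc_cells: dict[str, list[str]] = {}
    for s in states:
        if s.pattern == "WC":
            wc_cells.setdefault(s.chrom, []).append(s.cell_id)

    by_cell_chrom: dict[tuple[str, str], list[DirectionalRead]] = {}
    for r in reads_used:
        by_cell_chrom.setdefault((r.cell_id, r.chrom), []).append(r)

    round1: list[PhasedVariant] = []
    excluded: dict[str, list[str]] = {}
    for chrom in sorted(reference):
        cells = sorted(wc_cells.get(chrom, []))
        pos = anchor_pos.get(chrom)
        if not cells or pos is None or pos.size == 0:
            continue
        per_cell: dict[str, list[DirectionalRead]] = {}
        for cell in cells:
            rs = by_cell_chrom.get((cell, chrom), [])
            if sce_guard and rs:
                s0, e0 = largest_wc_segment(rs, len(reference[chrom]))
                rs = [r for r in rs if s0 <= (r.start + r.end) // 2 < e0]
            per_cell[cell] = rs
        profiles = {
            cell: strand_allele_profile(per_cell[cell], pos) for cell in cells
        }
        scores = []
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                s = orientation_score(
                    profiles[cells[i]], profiles[cells[j]], cells[i], cells[j], chrom
                )
                if s is not None:
                    scores.append(s)
        ca, cb, excl = cluster_orientations(cells, scores)
        excluded[chrom] = excl
        hp1, hp2 = build_haplotype_readsets(ca, cb, per_cell)
        round1.extend(
            call_consensus_snps(
                hp1, hp2, reference[chrom], chrom, min_support, min_agreement
            )
        )
    if inversions:
        round1 = apply_inversion_corrections(round1, inversions)

    round2: list[PhasedVariant] = []
    if rounds >= 2 and round1:
        round2 = round2_reconstruct(
            reads_used, round1, reference, min_support, min_agreement
        )
    return PhasingResult(list(anchors), blacklist, round1, round2, excluded)


def write_phased_vcf(
    variants: Sequence[PhasedVariant],
    chrom_lengths: dict[str, int],
    path: str,
    sample: str = "sample",
) -> None:
    """Write phased variants as a VCF with one phase set per chromosome."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, ln in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            gt = f"{int(v.hp1_allele == v.alt)}|{int(v.hp2_allele == v.alt)}"
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT:PS\t{gt}:1\n"
            )
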