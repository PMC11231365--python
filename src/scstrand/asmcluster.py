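"""Strand-matrix clustering of de novo assembly contigs.

Each contig x cell entry is (Crick - Watson)/(Crick + Watson) computed
from filtered, duplicate-marked reads aligned to the contigs; contigs
shorter than 100 kb are dropped. Agglomerative clustering (complete
linkage) on the absolute matrix groups contigs by chromosome (|value| is
invariant to a contig's assembly orientation); a second 2-way clustering
on the signed rows splits each chromosome cluster into its two reference
orientations. Sub-cluster sequences are concatenated (one sub-cluster
reverse-complemented) with 1-kb N gaps into a cluster sequence, with a
coordinate map that lifts cluster-based variant calls back through
contig coordinates to the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering

from .core import PhasedVariant, revcomp


def build_matrix(
    counts: dict[tuple[str, str], tuple[int, int]],
    contig_lengths: dict[str, int],
    min_contig_len: int = 100_000,
) -> pd.DataFrame:
    """Contig x cell strand matrix.

    ``counts`` maps (contig_id, cell_id) -> (crick, watson). Entries with
    zero reads are NaN (masked as 0 during clustering). Contigs shorter
    than ``min_contig_len`` are excluded.
    """
    contigs = sorted(c for c, ln in contig_lengths.items() if ln >= min_contig_len)
    if not contigs:
        raise ValueError("no contigs pass the minimum length filter")
    cells = sorted({cell for _, cell in counts})
    mat = pd.DataFrame(np.nan, index=contigs, columns=cells)
    for (ctg, cell), (c, w) in counts.items():
        if ctg in mat.index and c + w > 0:
            mat.loc[ctg, cell] = (c - w) / (c + w)
    return mat


def cluster_contigs(matrix: pd.DataFrame, n_clusters: int = 30) -> pd.Series:
    """Complete-linkage agglomerative clustering of |matrix| rows."""
    if n_clusters > matrix.shape[0]:
        raise ValueError(
            f"n_clusters={n_clusters} exceeds contig count {matrix.shape[0]}"
        )
    x = matrix.abs().fillna(0.0).to_numpy()
    model = AgglomerativeClustering(
        n_clusters=n_clusters, linkage="complete", compute_distances=True
    )
    labels = model.fit_predict(x)
    return pd.Series(labels, index=matrix.index, name="cluster")


def split_orientation(
    cluster_contig_ids: Sequence[str], matrix: pd.DataFrame
) -> tuple[list[str], list[str]]:
    """Split one chromosome cluster into its two orientation sub-clusters
    using the signed matrix rows; contigs in opposite orientations have
    anti-correlated strand profiles. If the 2-way split does not actually
    separate orientations (the two centroids correlate positively), all
    contigs stay in one sub-cluster."""
    ids = list(cluster_contig_ids)
    if len(ids) <= 1:
        return ids, []
    x = matrix.loc[ids].fillna(0.0).to_numpy()
    model = AgglomerativeClustering(n_clusters=2, linkage="complete")
    labels = model.fit_predict(x)
    a = [i for i, l in zip(ids, labels) if l == 0]
    b = [i for i, l in zip(ids, labels) if l == 1]
    if not a or not b:
        return ids, []
    ca = x[labels == 0].mean(axis=0)
    cb = x[labels == 1].mean(axis=0)
    denom = np.linalg.norm(ca) * np.linalg.norm(cb)
    if denom == 0 or float(ca @ cb) / denom >= 0:
        return ids, []
    return a, b


@dataclass(frozen=True)
class MapEntry:
    contig_id: str
    orientation: str  # "+" kept as-is, "-" reverse-complemented
    offset: int  # start of this contig inside the cluster sequence
    length: int


def build_cluster_sequence(
    forward_ids: Sequence[str],
    reverse_ids: Sequence[str],
    contig_seqs: dict[str, str],
    gap: int = 1_000,
) -> tuple[str, list[MapEntry]]:
    """Concatenate a cluster's contigs into one sequence.

    Contigs in ``reverse_ids`` are reverse-complemented; contigs are
    joined with ``gap`` N bases. Returns (sequence, coordinate map).
    """
    parts: list[str] = []
    entries: list[MapEntry] = []
    offset = 0
    items = [(cid, "-") for cid in reverse_ids] + [(cid, "+") for cid in forward_ids]
    for k, (cid, orient) in enumerate(items):
        seq = contig_seqs[cid]
        if orient == "-":
            seq = revcomp(seq)
        if k > 0:
            parts.append("N" * gap)
            offset += gap
        parts.append(seq)
        entries.append(MapEntry(cid, orient, offset, len(seq)))
        offset += len(seq)
    return "".join(parts), entries


def cluster_to_contig(
    pos: int, entries: Sequence[MapEntry]
) -> Optional[tuple[str, int, str]]:
    """Map a cluster-sequence position to (contig_id, contig position,
    orientation); None inside a gap."""
    for e in entries:
        if e.offset <= pos < e.offset + e.length:
            local = pos - e.offset
            if e.orientation == "-":
                local = e.length - 1 - local
            return e.contig_id, local, e.orientation
    return None


@dataclass(frozen=True)
class ContigAlignment:
    """Placement of a full contig on the reference (simple colinear map)."""

    contig_id: str
    chrom: str
    ref_start: int
    strand: str  # "+" | "-"
    length: int


def lift_variants(
    variants: Sequence[PhasedVariant],
    entries: Sequence[MapEntry],
    alignments: dict[str, ContigAlignment],
) -> tuple[list[PhasedVariant], list[PhasedVariant]]:
    """Lift cluster-based variants to reference coordinates.

    Composes cluster -> contig -> reference; alleles are complemented when
    the net orientation is reverse. Returns (lifted, unmapped).
    """
    lifted: list[PhasedVariant] = []
    unmapped: list[PhasedVariant] = []
    comp = str.maketrans("ACGT", "TGCA")
    for v in variants:
        hit = cluster_to_contig(v.pos, entries)
        if hit is None:
            unmapped.append(v)
            continue
        cid, local, cluster_orient = hit
        aln = alignments.get(cid)
        if aln is None:
            unmapped.append(v)
            continue
        flip = (cluster_orient == "-") != (aln.strand == "-")
        if aln.strand == "+":
            ref_pos = aln.ref_start + local
        else:
            ref_pos = aln.ref_start + aln.length - 1 - local
        if flip:
            tr = lambda a: a.translate(comp)
        else:
            tr = lambda a: a
        lifted.append(
            PhasedVariant(
                aln.chrom,
                ref_pos,
                tr(v.ref),
                tr(v.alt),
                tr(v.hp1_allele),
                tr(v.hp2_allele),
                v.hp1_support,
                v.hp2_support,
                v.source,
            )
        )
    return lifted, unmapped
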