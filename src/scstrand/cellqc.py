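"""Per-cell library quality control.

Strand counts per (cell, chromosome), the background-noise metric
(minority-strand fraction; cell background = mean of the four smallest
autosomal values), library retention thresholds, and template-strand
inheritance state calls (WW / CC / WC) from the Crick fraction P_c.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import pandas as pd

from .core import CRICK, ChromStrandCounts, DirectionalRead, StrandState

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


def chrom_counts(reads: Iterable[DirectionalRead]) -> list[ChromStrandCounts]:
    """Unique (non-duplicate) Crick/Watson read counts per (cell, chrom)."""
    acc: dict[tuple[str, str], list[int]] = {}
    for r in reads:
        if r.duplicate:
            continue
        cw = acc.setdefault((r.cell_id, r.chrom), [0, 0])
        cw[0 if r.strand == CRICK else 1] += 1
    return [
        ChromStrandCounts(cell, chrom, c, w)
        for (cell, chrom), (c, w) in sorted(acc.items())
    ]


def cell_background(
    counts: Sequence[ChromStrandCounts],
    autosomes: Optional[frozenset] = None,
    n_min: int = 4,
) -> float:
    """Background noise of one cell: the mean of the ``n_min`` smallest
    per-autosome minority-strand fractions."""
    vals = []
    for c in counts:
        if autosomes is not None:
            if c.chrom not in autosomes:
                continue
        elif c.chrom in SEX_CHROMS:
            continue
        if c.total > 0:
            vals.append(c.background)
    if len(vals) < n_min:
        raise ValueError(
            f"need at least {n_min} autosomes with reads, got {len(vals)}"
        )
    vals.sort()
    return sum(vals[:n_min]) / n_min


def cell_stats(
    counts: Sequence[ChromStrandCounts], **bg_kwargs
) -> pd.DataFrame:
    """Per-cell summary: unique read count and background noise."""
    rows = []
    by_cell: dict[str, list[ChromStrandCounts]] = {}
    for c in counts:
        by_cell.setdefault(c.cell_id, []).append(c)
    for cell, cs in sorted(by_cell.items()):
        rows.append(
            {
                "cell_id": cell,
                "unique_reads": sum(c.total for c in cs),
                "background": cell_background(cs, **bg_kwargs),
            }
        )
    return pd.DataFrame(rows)


def filter_cells(
    stats: pd.DataFrame,
    min_unique_reads: int = 80_000,
    max_background: float = 0.05,
) -> list[str]:
    """Retained cells: unique_reads >= minimum AND background strictly
    below the maximum (the human preset is 80,000 / 5%; the mouse preset
    uses 70,000)."""
    keep = stats[
        (stats["unique_reads"] >= min_unique_reads)
        & (stats["background"] < max_background)
    ]
    return list(keep["cell_id"])


def call_strand_state(
    counts: ChromStrandCounts,
    min_reads: int = 50,
    cc_threshold: float = 0.8,
    ww_threshold: float = 0.2,
    wc_band: tuple[float, float] = (0.35, 0.65),
) -> StrandState:
    """Template-strand inheritance pattern from the Crick fraction.

    CC when P_c > 0.8, WW when P_c < 0.2, WC inside the configured band
    around 0.5; chromosomes with fewer than ``min_reads`` unique reads or
    a P_c between the cutoffs are 'unknown'.
    """
    p = counts.p_c
    if counts.total < min_reads or math.isnan(p):
        pattern = "unknown"
    elif p > cc_threshold:
        pattern = "CC"
    elif p < ww_threshold:
        pattern = "WW"
    elif wc_band[0] <= p <= wc_band[1]:
        pattern = "WC"
    else:
        pattern = "unknown"
    return StrandState(counts.cell_id, counts.chrom, pattern, p, counts.total)


def call_all_states(
    counts: Iterable[ChromStrandCounts], **kwargs
) -> list[StrandState]:
    return [call_strand_state(c, **kwargs) for c in counts]


def states_table(states: Iterable[StrandState]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": s.cell_id,
                "chrom": s.chrom,
                "pattern": s.pattern,
                "p_c": s.p_c,
                "total": s.total,
            }
            for s in states
        ]
    )
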