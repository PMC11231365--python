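"""Barcode matching, orientation logic, linker trimming and round trips."""

import numpy as np
import pytest

from scstrand import simulate as sim
from scstrand.core import revcomp
from scstrand.demux import (
    AMBIGUOUS,
    NONTEMPLATE,
    TEMPLATE,
    BarcodeHit,
    classify_orientation,
    demultiplex_run,
    match_barcode,
    trim_and_dechimera,
)
from scstrand.simulate import (
    DEFAULT_LINKER,
    CellSimConfig,
    parse_truth_name,
    simulate_cell_library,
)


def infix_levenshtein(query: str, target: str) -> int:
    """Independent DP oracle: minimal Levenshtein distance of ``query``
    against any substring of ``target`` (semi-global)."""
    prev = [0] * (len(target) + 1)
    for i, q in enumerate(query, 1):
        cur = [i] + [0] * len(target)
        for j, t in enumerate(target, 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (q != t),
            )
        prev = cur
    return min(prev)


@pytest.fixture(scope="module")
def bc_set(barcode_tables):
    # three well-separated 24-nt barcodes
    return {cell: pair[0] for cell, pair in barcode_tables.items()}


def _substitute(seq, positions, rng):
    s = list(seq)
    for p in positions:
        s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
    return "".join(s)


def test_exact_barcode_match(bc_set, rng):
    bc = bc_set["cell000"]
    window = sim._random_dna(rng, 80) + bc + sim._random_dna(rng, 80)
    hit = match_barcode(window, bc_set)
    assert hit is not None
    assert hit.barcode_id == "cell000"
    assert hit.edit_distance == 0
    assert hit.orientation == "forward"


def test_five_substitutions_accepted_at_threshold(bc_set, rng):
    bc = bc_set["cell001"]
    mutated = _substitute(bc, [1, 5, 10, 15, 20], rng)
    window = "T" * 40 + mutated + "A" * 40
    hit = match_barcode(window, bc_set)
    assert hit is not None and hit.barcode_id == "cell001"
    assert hit.edit_distance <= 5
    # accepted distances agree with the DP oracle
    assert hit.edit_distance == min(
        infix_levenshtein(bc, window), infix_levenshtein(revcomp(bc), window)
    )


def test_six_edit_barcode_rejected(bc_set):
    bc = bc_set["cell002"]
    rng = np.random.default_rng(3)
    # craft a corruption whose oracle distance is exactly 6
    for _ in range(100):
        pos = sorted(rng.choice(24, size=6, replace=False))
        mutated = _substitute(bc, pos, rng)
        window = "G" * 30 + mutated + "C" * 30
        oracle = min(
            min(infix_levenshtein(b, window), infix_levenshtein(revcomp(b), window))
            for b in bc_set.values()
        )
        if oracle == 6:
            assert match_barcode(window, bc_set) is None
            return
    pytest.fail("could not craft a distance-6 corruption")


def test_reverse_orientation_recorded(bc_set, rng):
    bc = bc_set["cell000"]
    window = sim._random_dna(rng, 50) + revcomp(bc) + sim._random_dna(rng, 50)
    hit = match_barcode(window, bc_set)
    assert hit is not None and hit.orientation == "reverse"


def test_empty_barcode_set_raises():
    with pytest.raises(ValueError):
        match_barcode("ACGT" * 20, {})


def _hit(orientation):
    return BarcodeHit("x", orientation, 0, (0, 24))


@pytest.mark.parametrize(
    "h1,h2,t1,t2,expected",
    [
        (None, _hit("forward"), _hit("reverse"), None, TEMPLATE),
        (_hit("forward"), None, None, _hit("reverse"), NONTEMPLATE),
        (None, _hit("forward"), None, None, AMBIGUOUS),  # head only
        (None, None, None, None, AMBIGUOUS),
        # both layouts satisfied at once -> cannot decide
        (_hit("forward"), _hit("forward"), _hit("reverse"), _hit("reverse"), AMBIGUOUS),
    ],
)
def test_classify_orientation(h1, h2, t1, t2, expected):
    assert classify_orientation(h1, h2, t1, t2) == expected


def test_trim_clean_layout(rng):
    insert = sim._random_dna(rng, 500)
    read = DEFAULT_LINKER + insert + revcomp(DEFAULT_LINKER)
    seq, qual, reason = trim_and_dechimera(read, "F" * len(read))
    assert reason is None
    assert seq == insert
    assert len(qual) == len(seq)


def test_head_only_linker_rejected(rng):
    read = DEFAULT_LINKER + sim._random_dna(rng, 500)
    seq, _, reason = trim_and_dechimera(read, None)
    assert seq is None and reason == "no-linker"


def test_internal_linker_flags_chimera(rng):
    # internal linker copy with 7 substitutions: still within distance 8
    inner = list(DEFAULT_LINKER)
    for p in (2, 6, 10, 14, 18, 22, 26):
        inner[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[inner[p]]
    inner = "".join(inner)
    assert infix_levenshtein(inner, DEFAULT_LINKER) <= 8
    insert = sim._random_dna(rng, 200) + inner + sim._random_dna(rng, 200)
    read = DEFAULT_LINKER + insert + revcomp(DEFAULT_LINKER)
    seq, _, reason = trim_and_dechimera(read, None)
    assert seq is None and reason == "chimera"


@pytest.fixture(scope="module")
def noisefree_multiplexed(small_truth, barcode_tables):
    libs = []
    for k, cell in enumerate(barcode_tables):
        cfg = CellSimConfig(
            n_reads=100, base_error_rate=0.0, background_rate=0.0,
            sce_rate=0.0, seed=k,
        )
        libs.append(simulate_cell_library(small_truth, cfg, cell_id=cell))
    recs = sim.emit_multiplexed_fastq(
        libs, barcode_tables, barcode_error_edits=0, seed=17
    )
    return libs, recs


def test_zero_error_roundtrip_full_recovery(noisefree_multiplexed, barcode_tables):
    libs, recs = noisefree_multiplexed
    per_cell, summary, _ = demultiplex_run(iter(recs), barcode_tables)
    assert summary.check_conservation()
    assert summary.assigned == summary.total == 300
    assert summary.ambiguous == 0
    truth_seq = {
        ":".join(r.name.split(":")[:8]): r for lib in libs for r in lib.reads
    }
    for cell, rs in per_cell.items():
        for rec in rs:
            t = parse_truth_name(rec.name)
            assert t["cell_id"] == cell
            # orientation classification matches the emission truth
            assert (t["orientation"] == "template") == (rec.orientation == TEMPLATE)
            # recovered insert is exactly the template-oriented read
            key = ":".join(rec.name.split(":")[:8])
            assert rec.seq == truth_seq[key].template_oriented_seq()


def test_orientation_involution(noisefree_multiplexed, barcode_tables):
    _, recs = noisefree_multiplexed
    name, seq, qual = recs[0]
    _, _, fwd = demultiplex_run(iter([(name, seq, qual)]), barcode_tables)
    _, _, rev = demultiplex_run(
        iter([(name, revcomp(seq), qual[::-1])]), barcode_tables
    )
    assert fwd[0].status == rev[0].status == "assigned"
    assert fwd[0].orientation != rev[0].orientation
    assert fwd[0].seq == rev[0].seq


def test_noisy_assignment_matches_truth(small_truth, barcode_tables):
    libs = []
    for k, cell in enumerate(barcode_tables):
        cfg = CellSimConfig(n_reads=60, base_error_rate=0.0, sce_rate=0.0, seed=k + 30)
        libs.append(simulate_cell_library(small_truth, cfg, cell_id=cell))
    recs = sim.emit_multiplexed_fastq(libs, barcode_tables, barcode_error_edits=2, seed=31)
    per_cell, summary, _ = demultiplex_run(iter(recs), barcode_tables)
    assert summary.check_conservation()
    assert summary.assigned == summary.total
    for cell, rs in per_cell.items():
        assert all(parse_truth_name(r.name)["cell_id"] == cell for r in rs)


def test_empty_input(barcode_tables):
    per_cell, summary, records = demultiplex_run(iter([]), barcode_tables)
    assert summary.total == 0 and summary.check_conservation()
    assert all(len(v) == 0 for v in per_cell.values())
    assert records == []


def test_duplicate_pairs_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        demultiplex_run(iter([]), {"a": ("A" * 24, "C" * 24), "b": ("A" * 24, "C" * 24)})
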