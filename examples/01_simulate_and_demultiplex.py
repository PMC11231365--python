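"""Simulate a barcoded multiplexed run and demultiplex it back to cells.

Builds a 100-kb diploid genome, three single-cell strand-specific
libraries decorated with 24-nt combinatorial barcodes and the 33-bp
linker, injects up to 3 random edits per barcode copy, and recovers the
cells by minimal-Levenshtein barcode matching.
"""

from scstrand import simulate as sim
from scstrand.demux import demultiplex_run
from scstrand.simulate import CellSimConfig, parse_truth_name

truth = sim.simulate_diploid_genome(n_chroms=1, chrom_length=100_000, snp_rate=1e-3, seed=1)
barcodes = sim.random_barcode_tables(3, seed=2)
libs = [
    sim.simulate_cell_library(
        truth, CellSimConfig(n_reads=400, read_length_mean=1000, seed=10 + k), cell_id=cell
    )
    for k, cell in enumerate(barcodes)
]
records = sim.emit_multiplexed_fastq(libs, barcodes, barcode_error_edits=3, seed=3)

per_cell, summary, _ = demultiplex_run(iter(records), barcodes)
correct = sum(
    parse_truth_name(r.name)["cell_id"] == cell
    for cell, rs in per_cell.items()
    for r in rs
)
print(f"reads in:   {summary.total}")
print(f"assigned:   {summary.assigned}  (ambiguous {summary.ambiguous}, discarded {summary.discarded})")
print(f"correct:    {correct}/{summary.assigned} assigned reads match their true cell")
# Every assigned read is barcode/linker-trimmed and normalized to
# template-strand orientation, ready for genome mapping.
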