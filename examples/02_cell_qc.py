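"""Per-cell quality control: strand counts, background noise, retention.

The background of a chromosome is its minority-strand read fraction
(min(Crick, Watson) / total); a cell's background is the mean of the four
smallest autosomal values. Cells are retained when they have enough
unique reads and background below 5%.
"""

from scstrand import simulate as sim
from scstrand.alnproc import mark_duplicates
from scstrand.cellqc import call_all_states, cell_stats, chrom_counts, filter_cells
from scstrand.simulate import CellSimConfig

# enough autosomes that each cell has >= 4 single-strand-state
# chromosomes for the four-minima background statistic
truth = sim.simulate_diploid_genome(n_chroms=12, chrom_length=120_000, snp_rate=0, seed=5)
cfg = CellSimConfig(n_reads=2400, background_rate=0.01)
libs = sim.simulate_cells(truth, 6, cfg, seed=6)
reads = [r for lib in libs for r in lib.directional_reads()]
mark_duplicates(reads)

counts = chrom_counts(reads)
stats = cell_stats(counts)
# thresholds scaled to this toy depth (the human preset is 80,000 reads)
retained = filter_cells(stats, min_unique_reads=1000, max_background=0.05)
print(stats.to_string(index=False))
print(f"retained cells: {retained}")

states = call_all_states(counts)
one = [s for s in states if s.cell_id == libs[0].cell_id]
print("\ntemplate-strand states of", libs[0].cell_id)
for s in one:
    print(f"  {s.chrom}: {s.pattern}  (P_c={s.p_c:.2f}, {s.total} reads)")
# WW/CC chromosomes inherited both template strands on the same strand;
# WC chromosomes carry the two haplotypes on opposite strands and drive
# phasing.
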