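"""Two-round chromosome-scale haplotype phasing on a synthetic genome.

Simulates one 1-Mb chromosome with hetSNPs across 30 cells, calls anchor
hetSNPs from the pseudobulk pileup, orients the WC cells by pairwise
log2 fold-change clustering, builds haplotype read sets, and calls
consensus phased SNPs in two rounds. Metrics are evaluated against the
simulator's truth.
"""

from scstrand import simulate as sim
from scstrand.alnproc import mark_duplicates
from scstrand.cellqc import call_all_states, chrom_counts
from scstrand.phasing import evaluate_phasing, reconstruct_haplotypes
from scstrand.simulate import CellSimConfig

truth = sim.simulate_diploid_genome(n_chroms=1, chrom_length=1_000_000, snp_rate=1e-3, seed=7)
cfg = CellSimConfig(n_reads=360)  # defaults: 1% background, 0.8% base error
libs = sim.simulate_cells(truth, 30, cfg, seed=8)
reads = [r for lib in libs for r in lib.directional_reads()]
mark_duplicates(reads)
states = call_all_states(chrom_counts(reads))

result = reconstruct_haplotypes(reads, truth.reference, states, rounds=2)
truth_variants = truth.phased_variants()
for name, calls in (("round 1", result.round1), ("round 2", result.round2)):
    m = evaluate_phasing(calls, truth_variants)
    print(
        f"{name}: {m['n_called']} phased SNPs | precision {m['precision']:.4f} | "
        f"recall {m['recall']:.4f} | Hamming error {m['hamming_error_rate']:.4f}"
    )
# Round 2 re-annotates every read (any strand state) with the round-1
# phased hetSNPs, deepening both haplotype read sets: recall rises while
# the Hamming error rate (fraction of het sites phased to the wrong
# haplotype, up to one global label swap per chromosome) stays near zero.
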