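"""Call, genotype and phase structural variants (deletions/insertions).

Candidates come from read CIGARs (events >= 50 bp merged across reads);
genotyping counts supporting vs opposing reads per haplotype read set:
homozygous SVs are supported by both haplotypes, heterozygous SVs by one
and opposed by the other. Each phased SV is annotated with the distance
to its nearest phased hetSNP.
"""

from scstrand import simulate as sim
from scstrand.svphase import extract_candidate_svs, genotype_all, nearest_hetsnp_distances
from scstrand.simulate import CellSimConfig

truth = sim.simulate_diploid_genome(
    n_chroms=1, chrom_length=1_000_000, snp_rate=2e-4, sv_rate=2e-5, seed=11
)
cfg = CellSimConfig(n_reads=3000, base_error_rate=0.0, background_rate=0.0)
libs = sim.simulate_cells(truth, 8, cfg, seed=12)
allreads = [r for lib in libs for r in lib.reads]
# haplotype read sets (from truth labels here; in a real run they come
# from the phasing stage)
hp1 = [r.to_directional() for r in allreads if r.hp == "HP1"]
hp2 = [r.to_directional() for r in allreads if r.hp == "HP2"]

candidates = extract_candidate_svs([r.to_directional() for r in allreads])
genotype_all(candidates, hp1, hp2)
hist = nearest_hetsnp_distances(candidates, truth.phased_variants())

print(f"truth SVs: {len(truth.svs)} | candidates: {len(candidates)}")
for sv in candidates[:8]:
    print(
        f"  {sv.chrom}:{sv.pos} {sv.type} {sv.length} bp -> {sv.genotype:10s} "
        f"(support {sv.support_hp1}/{sv.support_hp2}, "
        f"oppose {sv.oppose_hp1}/{sv.oppose_hp2}, "
        f"nearest hetSNP {sv.nearest_hetsnp_distance} bp)"
    )
print("distance histogram:", hist)
# Direct strand-based phasing does not depend on SNP linkage, so SVs in
# long homozygous stretches (nearest hetSNP >10 kb) are still phased.
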