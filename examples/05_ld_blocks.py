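"""Pairwise r^2 within 200 kb and LD block calling over a region.

Uses the gene-dropped population (recombination by physical distance), so
nearby SNP are in strong LD and blocks emerge naturally.
"""

from lactgwas.kinship import qc_maf
from lactgwas.ldmap import find_blocks, pairwise_r2
from lactgwas.simulate import (SimulationConfig, drop_genotypes,
                               simulate_pedigree, subset_genotypes)

cfg = SimulationConfig(n_founders=100, n_generations=3, n_animals_target=600,
                       n_snp=400, n_chromosomes=2, chromosome_length_bp=800_000,
                       seed=9)
rng = cfg.rng()
ped = simulate_pedigree(cfg, rng)
gs = qc_maf(subset_genotypes(drop_genotypes(ped, cfg, rng),
                             ped["animal"].to_numpy()), 0.05)

region = (1, 1, 400_000)
ld = pairwise_r2(gs, region=region, window_bp=200_000)
blocks = find_blocks(ld, gs, r2_threshold=0.7)

print(f"region chr{region[0]}:{region[1]}-{region[2]}: "
      f"{len(ld.pairs)} SNP pairs within 200 kb")
print(f"mean r^2 = {ld.pairs['r2'].mean():.3f} "
      f"(adjacent pairs: {ld.pairs[ld.pairs['dist_bp'] < 5000]['r2'].mean():.3f})")
print(f"\nLD blocks at r^2 >= 0.7 on chromosome 1 ({len(blocks[blocks.chrom == 1])}):")
print(blocks[blocks["chrom"] == 1].head(10).to_string(index=False))
# r^2 decays with distance; blocks are maximal runs of adjacent SNP whose
# neighbouring pairs all exceed the threshold (>= 2 SNP each).
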