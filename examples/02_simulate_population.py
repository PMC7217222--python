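"""Generate a small pedigreed, genotyped dairy population with known genetics.

Prints the population layout, the ground-truth QTL and the first test-day
records.  Everything downstream (REML, GWAS, LD) can run on these tables.
"""

from lactgwas.simulate import SimulationConfig, simulate_population

cfg = SimulationConfig(n_founders=80, n_generations=2, n_animals_target=400,
                       n_snp=500, n_chromosomes=3, seed=7)
pop = simulate_population(cfg)

ped, geno = pop["pedigree"], pop["genotypes"]
print(f"pedigree: {len(ped)} animals over {ped['generation'].max() + 1} generations")
print(f"genotypes: {geno.n_animals} animals x {geno.n_snp} SNP "
      f"on {geno.marker_map['chrom'].nunique()} chromosomes")
print(f"true QTL at marker indices: {pop['truth'].qtl_positions.tolist()}")
print(f"test-day records: {len(pop['records'])} "
      f"({pop['n_truncated']} negative yields truncated)")
print(pop["records"].head(6).to_string(index=False))
# Each lactation is a MilkBot curve at the animal's true parameters
# (mean + breeding value + permanent environment) plus 2.5 kg/day noise.
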