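"""Weighted single-step GWAS: find a planted QTL by window variance.

Simulates a trait with one common QTL explaining 10% of the additive
variance, runs two iterations of the SNP-reweighting loop, and prints the
windows of 50 consecutive SNP that explain more than 0.50% of the additive
genetic variance — the candidate-QTL rule.
"""

from lactgwas.kinship import qc_maf
from lactgwas.reml import ModelSpec, VarianceComponents
from lactgwas.simulate import (SimulationConfig, drop_genotypes,
                               simulate_pedigree, simulate_single_trait,
                               subset_genotypes)
from lactgwas.ssgwas import candidate_windows, iterate_weights, window_variance

cfg = SimulationConfig(n_founders=150, n_generations=2, n_animals_target=800,
                       n_snp=1000, n_qtl=1, qtl_variance_fraction=0.10, seed=4)
rng = cfg.rng()
ped = simulate_pedigree(cfg, rng)
geno = drop_genotypes(ped, cfg, rng)
pheno, truth = simulate_single_trait(ped, geno, cfg, sigma_a2=100.0,
                                     sigma_e2=170.0, rng=rng)
gs = qc_maf(subset_genotypes(geno, ped[ped["generation"] > 0]["animal"].to_numpy()),
            0.05)
comp = VarianceComponents(sigma_a2=100.0, sigma_p2=0.0, sigma_e2=170.0,
                          converged=True)
iters = iterate_weights(ModelSpec(response="y"), pheno, ped, gs, comp,
                        n_iterations=2)
effects, gebv = iters[1]                      # iteration 2: reporting default
scan = window_variance(effects, gs, sigma_a2=100.0)
flagged = candidate_windows(scan, threshold=0.50)

qtl_bp = geno.marker_map.loc[truth.qtl_positions[0]]
print(f"planted QTL: chromosome {qtl_bp['chrom']} at {qtl_bp['bp']:,} bp")
print(f"mean GEBV accuracy: {gebv.accuracy.mean():.3f}")
print(f"\n{len(flagged)} windows exceed the 0.50% threshold; top 5 by variance:")
top = flagged.sort_values("pct_variance", ascending=False).head(5)
print(top[["chrom", "start_bp", "end_bp", "n_snp", "pct_variance"]]
      .to_string(index=False))
# The QTL's window should sit at or near the head of this list.  With only
# 20 windows the 90%
# polygenic background leaves each window ~4.5% on average, so many clear
# the absolute 0.50% rule; at genome scale (thousands of windows) the same
# rule isolates major regions.
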