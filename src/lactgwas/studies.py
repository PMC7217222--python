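"""Seeded simulation studies: parameter recovery, detection power, LD blocks.

Each function simulates populations at fixed study conditions, runs the
corresponding estimation machinery and returns summary metrics.  They back
both the test suite and the reproduction script, so the study conditions
live in one place.
"""

from __future__ import annotations

import numpy as np

from .kinship import build_h_system, qc_maf
from .ldmap import find_blocks, pairwise_r2
from .reml import ModelSpec, VarianceComponents, aireml
from .simulate import (
    SimulationConfig,
    drop_genotypes,
    simulate_pedigree,
    simulate_single_trait,
    subset_genotypes,
)
from .ssgwas import iterate_weights, window_variance

__all__ = [
    "heritability_recovery",
    "qtl_power_study",
    "ld_block_recovery",
]


def heritability_recovery(
    seeds,
    sigma_a2: float = 526_630.0,
    sigma_e2: float = 892_670.0,
    n_founders: int = 300,
    n_generations: int = 2,
    n_animals: int = 1800,
    n_genotyped: int = 800,
    n_snp: int = 2000,
) -> dict:
    """AI-REML h2 recovery with the combined H matrix.

    For each seed: simulate ~``n_animals - n_founders`` phenotyped animals
    with the given additive and residual variances (herd-year-season,
    country and age effects active), genotype ``n_genotyped`` of them, build
    H and estimate the variance components.  Returns per-seed estimates and
    their mean; the true h2 is sigma_a2 / (sigma_a2 + sigma_e2).
    """
    h2s = []
    for seed in seeds:
        sc = SimulationConfig(n_founders=n_founders, n_generations=n_generations,
                              n_animals_target=n_animals, n_snp=n_snp,
                              seed=int(seed))
        rng = sc.rng()
        ped = simulate_pedigree(sc, rng)
        geno = drop_genotypes(ped, sc, rng)
        ph, _ = simulate_single_trait(ped, geno, sc, sigma_a2=sigma_a2,
                                      sigma_e2=sigma_e2, rng=rng)
        phen_ids = ped[ped["generation"] > 0]["animal"].to_numpy()
        gen_ids = np.sort(rng.choice(phen_ids, size=min(n_genotyped, len(phen_ids)),
                                     replace=False))
        gs = qc_maf(subset_genotypes(geno, gen_ids), 0.05)
        hs = build_h_system(ped, gs)
        vc = aireml(ModelSpec(response="y"), ph, hs.H_inv, hs.all_ids)
        h2s.append(vc.heritability)
    h2s = np.array(h2s)
    return {
        "h2_estimates": h2s,
        "h2_mean": float(h2s.mean()),
        "h2_true": sigma_a2 / (sigma_a2 + sigma_e2),
        "n_phenotyped": n_animals - n_founders,
    }


def qtl_power_study(
    seeds,
    qtl_fraction: float = 0.10,
    sigma_a2: float = 100.0,
    sigma_e2: float = 170.0,
    n_founders: int = 200,
    n_animals: int = 1500,
    n_snp: int = 2000,
    window_size: int = 50,
    threshold: float = 0.50,
) -> dict:
    """Detection of one planted QTL by the weighted window scan.

    Per seed: one common QTL explaining ``qtl_fraction`` of the additive
    variance, iteration-2 weighted scan, all phenotyped animals genotyped.
    Counts how often the QTL's 50-SNP window (i) is the top-variance window
    or adjacent to it, (ii) exceeds the candidate threshold, and (iii) has
    its QTL SNP weight increase from iteration 1 to 2.
    """
    top_hits = above = weight_up = 0
    qtl_pcts = []
    for seed in seeds:
        sc = SimulationConfig(n_founders=n_founders, n_generations=2,
                              n_animals_target=n_animals, n_snp=n_snp,
                              n_qtl=1, qtl_variance_fraction=qtl_fraction,
                              founder_ld=False, seed=int(seed))
        rng = sc.rng()
        ped = simulate_pedigree(sc, rng)
        geno = drop_genotypes(ped, sc, rng)
        ph, truth = simulate_single_trait(ped, geno, sc, sigma_a2=sigma_a2,
                                          sigma_e2=sigma_e2, rng=rng)
        gs = qc_maf(subset_genotypes(
            geno, ped[ped["generation"] > 0]["animal"].to_numpy()), 0.05)
        qtl_name = geno.marker_map.loc[truth.qtl_positions[0], "snp"]
        q = int(gs.marker_map.index[gs.marker_map["snp"] == qtl_name][0])
        vc = VarianceComponents(sigma_a2=sigma_a2, sigma_p2=0.0,
                                sigma_e2=sigma_e2, converged=True)
        iters = iterate_weights(ModelSpec(response="y"), ph, ped, gs, vc,
                                n_iterations=2)
        eff2, _ = iters[1]
        scan = window_variance(eff2, gs, sigma_a2=sigma_a2, window_size=window_size)
        tab = scan.table
        top = int(tab["pct_variance"].idxmax())
        wq = int(tab.index[(tab["snp_start"] <= q) & (tab["snp_stop"] >= q)][0])
        top_hits += abs(top - wq) <= 1
        above += tab.loc[wq, "pct_variance"] > threshold
        weight_up += iters[1][0].weights[q] > iters[0][0].weights[q]
        qtl_pcts.append(float(tab.loc[wq, "pct_variance"]))
    n = len(list(seeds))
    return {
        "n_runs": n,
        "top_or_adjacent": int(top_hits),
        "above_threshold": int(above),
        "weight_increased": int(weight_up),
        "qtl_window_pct": np.array(qtl_pcts),
    }


def ld_block_recovery(
    seeds,
    block_size: int = 10,
    n_animals: int = 300,
    r2_threshold: float = 0.7,
) -> dict:
    """Recovery of two planted haplotype blocks by the adjacent-r2 caller.

    Each replicate builds two ``block_size``-SNP blocks of near-perfect LD
    (two ancestral haplotypes per block, small mutation noise) separated by
    free recombination, and checks that exactly two >=5-SNP blocks are
    called at the r2 threshold.
    """
    import pandas as pd

    from .kinship import GenotypeSet

    recovered = 0
    for seed in seeds:
        rng = np.random.default_rng(int(seed))
        cols = []
        for b in range(2):
            h0 = rng.integers(0, 2, size=block_size)
            anc = np.stack([h0, 1 - h0])  # two complementary haplotypes
            which = rng.integers(0, 2, size=(n_animals, 2))
            block = anc[which[:, 0]] + anc[which[:, 1]]
            flip = rng.random((n_animals, block_size)) < 0.02  # mutation noise
            block = np.clip(block + flip * rng.choice([-1, 1], (n_animals, block_size)), 0, 2)
            cols.append(block.astype(float))
        dos = np.hstack(cols)
        mm = pd.DataFrame({
            "snp": [f"s{i}" for i in range(2 * block_size)],
            "chrom": 1,
            "bp": np.r_[np.arange(block_size) * 1000 + 1,
                        np.arange(block_size) * 1000 + 500_000],
        })
        gs = GenotypeSet(dosages=dos, marker_map=mm,
                         animal_ids=np.arange(1, n_animals + 1))
        ld = pairwise_r2(gs, window_bp=600_000)
        blocks = find_blocks(ld, gs, r2_threshold=r2_threshold)
        big = blocks[blocks["n_snp"] >= 5]
        recovered += len(big) == 2
    return {"n_runs": len(list(seeds)), "recovered_both": int(recovered)}
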