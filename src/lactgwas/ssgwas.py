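"""Weighted single-step GWAS: GEBV solution, SNP back-solving, iterative
reweighting and 50-SNP window variance decomposition.

The procedure treats the additive effects of genotyped animals as a linear
function of SNP effects, a_g = Z u, so that after solving single-step GBLUP
for GEBVs the SNP effects are recovered by the back-solution

    u_hat = lambda * D Z' G*^-1 a_hat_g

with lambda = 1 / sum(2 p_i (1 - p_i)) the variance-normalizing constant,
D the diagonal SNP weight matrix and G* the (tuned, blended) weighted
genomic relationship matrix built from the same Z and D.  The iterative
weighting loop starts at D = I, refreshes d_i = u_hat_i^2 * 2 p_i (1 - p_i)
after each solve, normalizes the weights to keep total genetic variance
constant, and repeats.

Inference is by variance decomposition, not p-values: the genetic score of
each run of 50 consecutive SNP is Z_w u_hat_w, its variance across genotyped
animals is expressed as a percentage of the additive genetic variance, and
windows above 0.50% are candidate QTL regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import GenotypeSet, HSystem, build_h_system
from .reml import ModelSpec, VarianceComponents, build_mme

__all__ = [
    "GEBVSolution",
    "SNPEffectSet",
    "WindowScan",
    "solve_ssgblup",
    "backsolve_snp_effects",
    "iterate_weights",
    "window_variance",
    "candidate_windows",
]


@dataclass
class GEBVSolution:
    """BLUP breeding values with prediction error variance and accuracy.

    ``accuracy`` uses the square-root convention sqrt(max(0, 1 - PEV/sigma_a2));
    ``reliability`` (= accuracy squared before flooring) is kept alongside
    because the literature sometimes reports 1 - PEV/sigma_a2 directly.
    """

    animal_ids: np.ndarray
    gebv: np.ndarray
    pev: np.ndarray
    accuracy: np.ndarray
    reliability: np.ndarray
    fixed_solutions: np.ndarray


@dataclass
class SNPEffectSet:
    u_hat: np.ndarray          # per-SNP allele substitution effect
    weights: np.ndarray        # d_i, normalized to sum to M
    iteration: int
    allele_freq: np.ndarray
    lam: float
    marker_map: pd.DataFrame = None


@dataclass
class WindowScan:
    """Per-window percentage of additive genetic variance, tiling each chromosome."""

    table: pd.DataFrame        # chrom, start_bp, end_bp, snp_start, snp_stop, n_snp, pct_variance
    window_size: int = 50
    threshold: float = 0.50
    trait: str = ""


def solve_ssgblup(
    model: ModelSpec,
    phenotypes: pd.DataFrame,
    H_inv: np.ndarray,
    all_ids: np.ndarray,
    components: VarianceComponents,
) -> GEBVSolution:
    """Solve Henderson's MME for GEBVs of every animal in the pedigree.

    PEV comes from the additive diagonal block of the inverted coefficient
    matrix times sigma_e2 (exact, dense).
    """
    mme = build_mme(
        model, phenotypes, H_inv, all_ids,
        sigma_a2=components.sigma_a2, sigma_e2=components.sigma_e2,
        sigma_p2=components.sigma_p2 if model.permanent_env else 0.0,
    )
    sol, C_inv = mme.solve_with_inverse()
    add = mme.slices["additive"]
    pev = np.diag(C_inv)[add] * components.sigma_e2
    rel = 1.0 - pev / components.sigma_a2
    acc = np.sqrt(np.maximum(0.0, rel))
    return GEBVSolution(
        animal_ids=np.asarray(all_ids),
        gebv=sol["additive"],
        pev=pev,
        accuracy=acc,
        reliability=rel,
        fixed_solutions=sol["fixed"],
    )


def backsolve_snp_effects(
    gebv_genotyped: np.ndarray,
    genotypes: GenotypeSet,
    weights: np.ndarray,
    G_star: np.ndarray,
    iteration: int = 1,
) -> SNPEffectSet:
    """Convert genotyped-animal GEBVs to SNP effects: u_hat = lambda D Z' G*^-1 a_g.

    With G* built from the same Z, D and lambda this is the minimum-norm
    (in the D^-1 metric) preimage of a_g under a_g = Z u, so Z u_hat
    reproduces the genomic part of the GEBVs.
    """
    a_g = np.asarray(gebv_genotyped, dtype=float)
    if a_g.size != genotypes.n_animals:
        raise ValueError(
            f"GEBV vector length {a_g.size} != genotyped animals {genotypes.n_animals}")
    Z = genotypes.centered()
    p = genotypes.allele_freq
    lam = 1.0 / float(np.sum(2.0 * p * (1.0 - p)))
    w = np.asarray(weights, dtype=float)
    u_hat = lam * w * (Z.T @ np.linalg.solve(G_star, a_g))
    return SNPEffectSet(u_hat=u_hat, weights=w, iteration=iteration,
                        allele_freq=p, lam=lam, marker_map=genotypes.marker_map)


def _normalize_weights(d: np.ndarray) -> np.ndarray:
    """Rescale weights to sum to the number of SNP (keeps total genetic variance)."""
    total = float(np.sum(d))
    if total <= 0:
        raise ValueError("all SNP weights collapsed to zero")
    return d * (len(d) / total)


def iterate_weights(
    model: ModelSpec,
    phenotypes: pd.DataFrame,
    pedigree: pd.DataFrame,
    genotypes: GenotypeSet,
    components: VarianceComponents,
    n_iterations: int = 3,
    blend_fraction: float = 0.05,
) -> list[tuple[SNPEffectSet, GEBVSolution]]:
    """Run the iterative SNP-weighting loop of weighted single-step GWAS.

    Each iteration: (1) build G with current weights, tune/blend and form
    H^-1; (2) solve ssGBLUP for GEBVs; (3) back-solve SNP effects; (4) set
    d_i = u_hat_i^2 * 2 p_i (1 - p_i); (5) normalize so sum d_i = M.  The
    first iteration uses D = I and is therefore plain (unweighted) ssGWAS.
    All iterations are returned; by convention iteration 2 (1-based) gives
    the most accurate evaluation and is the reporting default downstream.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    d = np.ones(genotypes.n_snp)
    out: list[tuple[SNPEffectSet, GEBVSolution]] = []
    for it in range(1, n_iterations + 1):
        hs: HSystem = build_h_system(pedigree, genotypes, snp_weights=d,
                                     blend_fraction=blend_fraction)
        gebv = solve_ssgblup(model, phenotypes, hs.H_inv, hs.all_ids, components)
        a_g = gebv.gebv[hs.genotyped_idx]
        eff = backsolve_snp_effects(a_g, genotypes, d, hs.G_star, iteration=it)
        out.append((eff, gebv))
        d_next = eff.u_hat ** 2 * 2.0 * eff.allele_freq * (1.0 - eff.allele_freq)
        d = _normalize_weights(d_next)
    return out


def _window_bounds(marker_map: pd.DataFrame, window_size: int) -> list[tuple]:
    """Non-overlapping runs of ``window_size`` consecutive SNP within chromosome."""
    bounds = []
    for chrom, grp in marker_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        for s in range(0, len(idx), window_size):
            block = idx[s:s + window_size]
            bounds.append((chrom, block))
    return bounds


def window_variance(
    effects: SNPEffectSet,
    genotypes: GenotypeSet,
    sigma_a2: float,
    window_size: int = 50,
    trait: str = "",
) -> WindowScan:
    """Percentage of additive genetic variance per window of consecutive SNP.

    For window w the genetic score of each genotyped animal is
    sum_{j in w} Z_j u_hat_j; the sample variance (ddof=1) of that score
    across animals, divided by sigma_a2 and multiplied by 100, is the
    window's share (column ``pct_variance``).  Because windows in mutual LD
    have correlated scores, these shares do not sum exactly to the variance
    of the total genomic score; the companion column ``pct_covariance``
    attributes Cov(score_w, total score)/sigma_a2 * 100 to each window,
    which partitions 100 * Var(Z u_hat)/sigma_a2 exactly.  Windows tile
    each chromosome without overlap (the last window on a chromosome may
    hold fewer SNP).
    """
    mm = genotypes.marker_map
    if not mm.sort_values(["chrom", "bp"], kind="stable").index.equals(mm.index):
        raise ValueError("marker map must be sorted by (chrom, bp)")
    if sigma_a2 <= 0:
        raise ValueError("sigma_a2 must be positive")
    Z = genotypes.centered()
    total_score = Z @ effects.u_hat
    total_c = total_score - total_score.mean()
    n = Z.shape[0]
    rows = []
    for chrom, block in _window_bounds(mm, window_size):
        score = Z[:, block] @ effects.u_hat[block]
        var = float(np.var(score, ddof=1))
        cov = float((score - score.mean()) @ total_c) / (n - 1)
        rows.append({
            "chrom": chrom,
            "start_bp": int(mm.loc[block[0], "bp"]),
            "end_bp": int(mm.loc[block[-1], "bp"]),
            "snp_start": int(block[0]),
            "snp_stop": int(block[-1]),
            "n_snp": len(block),
            "pct_variance": 100.0 * var / sigma_a2,
            "pct_covariance": 100.0 * cov / sigma_a2,
        })
    return WindowScan(table=pd.DataFrame(rows), window_size=window_size, trait=trait)


def candidate_windows(scan: WindowScan, threshold: float = 0.50) -> pd.DataFrame:
    """Windows explaining more than ``threshold`` percent of additive variance."""
    tab = scan.table.copy()
    tab["candidate"] = tab["pct_variance"] > threshold
    return tab[tab["candidate"]].reset_index(drop=True)
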