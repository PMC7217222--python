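"""Linkage disequilibrium: pairwise r^2 within a bp window and block calling.

r^2 is the squared Pearson correlation of genotype dosage vectors
(genotypic LD — no phasing is required anywhere in this pipeline).  Pairs
are restricted to the same chromosome within a sliding physical window
(default 200 kb).  LD blocks are maximal runs of physically consecutive SNP
in which every adjacent pair exceeds an r^2 threshold; only runs of at
least two SNP count as blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd

from .kinship import GenotypeSet

logger = logging.getLogger(__name__)

__all__ = ["LDResult", "pairwise_r2", "find_blocks"]


@dataclass
class LDResult:
    pairs: pd.DataFrame          # snp_i, snp_j, chrom, dist_bp, r2
    window_bp: int
    blocks: pd.DataFrame | None = None


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def pairwise_r2(
    genotypes: GenotypeSet,
    region: tuple | None = None,
    window_bp: int = 200_000,
) -> LDResult:
    """r^2 for every same-chromosome SNP pair within ``window_bp``.

    ``region`` optionally restricts to (chrom, start_bp, end_bp).
    Monomorphic SNP yield undefined correlations; those pairs are skipped
    with a log message.
    """
    mm = genotypes.marker_map
    mask = np.ones(len(mm), dtype=bool)
    if region is not None:
        chrom, start, end = region
        mask = (mm["chrom"] == chrom) & (mm["bp"] >= start) & (mm["bp"] <= end)
        if not mask.any():
            raise ValueError(f"no SNP in region {region}")
    idx = np.flatnonzero(mask)
    X = genotypes.dosages[:, idx]
    sub = mm.loc[idx].reset_index(drop=True)
    rows = []
    n_skipped = 0
    for chrom, grp in sub.groupby("chrom", sort=False):
        local = grp.index.to_numpy()
        bp = grp["bp"].to_numpy()
        for a in range(len(local)):
            for b in range(a + 1, len(local)):
                dist = int(bp[b] - bp[a])
                if dist > window_bp:
                    break
                r2 = _r2(X[:, local[a]], X[:, local[b]])
                if np.isnan(r2):
                    n_skipped += 1
                    continue
                rows.append({
                    "snp_i": int(idx[local[a]]), "snp_j": int(idx[local[b]]),
                    "chrom": chrom, "bp_i": int(bp[a]), "bp_j": int(bp[b]),
                    "dist_bp": dist, "r2": r2,
                })
    if n_skipped:
        logger.info("skipped %d pairs with a monomorphic member", n_skipped)
    return LDResult(pairs=pd.DataFrame(rows), window_bp=window_bp)


def find_blocks(
    ld: LDResult,
    genotypes: GenotypeSet,
    r2_threshold: float = 0.7,
) -> pd.DataFrame:
    """Call LD blocks as maximal runs of adjacent SNP with r^2 >= threshold.

    Adjacency is physical order on the marker map.  Each reported block has
    >= 2 SNP and carries its bp span and mean internal adjacent r^2.  The
    block table is also stored on ``ld.blocks``.
    """
    pairs = ld.pairs
    adj = {}
    for _, row in pairs.iterrows():
        adj[(int(row["snp_i"]), int(row["snp_j"]))] = row["r2"]
    mm = genotypes.marker_map
    blocks = []
    for chrom, grp in mm.groupby("chrom", sort=False):
        snps = grp.index.to_numpy()
        run = [snps[0]] if len(snps) else []
        run_r2 = []
        for k in range(1, len(snps)):
            r2 = adj.get((int(snps[k - 1]), int(snps[k])), np.nan)
            if np.isfinite(r2) and r2 >= r2_threshold:
                run.append(snps[k])
                run_r2.append(r2)
            else:
                if len(run) >= 2:
                    blocks.append(_block_row(chrom, run, run_r2, mm))
                run, run_r2 = [snps[k]], []
        if len(run) >= 2:
            blocks.append(_block_row(chrom, run, run_r2, mm))
    out = pd.DataFrame(blocks, columns=["chrom", "start_bp", "end_bp", "n_snp",
                                        "snp_first", "snp_last", "mean_adjacent_r2"])
    ld.blocks = out
    return out


def _block_row(chrom, run, run_r2, mm):
    return {
        "chrom": chrom,
        "start_bp": int(mm.loc[run[0], "bp"]),
        "end_bp": int(mm.loc[run[-1], "bp"]),
        "n_snp": len(run),
        "snp_first": int(run[0]),
        "snp_last": int(run[-1]),
        "mean_adjacent_r2": float(np.mean(run_r2)),
    }
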