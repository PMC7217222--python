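"""Relationship matrices for single-step evaluation: A, A22, G, tuned G* and H^-1.

Single-step GBLUP evaluates genotyped and ungenotyped animals jointly through
the H matrix, whose inverse is the pedigree relationship inverse plus a
correction on the genotyped block::

    H^-1 = A^-1 + [[0, 0], [0, G*^-1 - A22^-1]]

where A is the pedigree numerator relationship matrix (NRM), A22 its
restriction to genotyped animals, and G* a genomic relationship matrix tuned
so that its diagonal and off-diagonal means match those of A22 (putting
genomic and pedigree relationships on the same base) and blended with a
small fraction of A22 to guarantee invertibility.

All algebra here is dense; the intended scale is tens of thousands of
animals at most.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeSet",
    "HSystem",
    "allele_frequencies",
    "qc_maf",
    "a_matrix",
    "a_submatrix",
    "g_matrix",
    "tune_and_blend",
    "h_inverse",
    "build_h_system",
]


@dataclass
class GenotypeSet:
    """Animals x SNP dosage matrix ({0,1,2}) with a physical marker map.

    ``dosages`` rows follow ``animal_ids``; ``marker_map`` is a DataFrame with
    columns (snp, chrom, bp) sorted by (chrom, bp).  ``allele_freq`` holds the
    frequency of the allele counted by the dosage coding, computed from the
    genotyped sample.
    """

    dosages: np.ndarray
    marker_map: pd.DataFrame
    animal_ids: np.ndarray
    allele_freq: np.ndarray = field(default=None)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.animal_ids = np.asarray(self.animal_ids)
        if self.dosages.shape[0] != len(self.animal_ids):
            raise ValueError("dosage rows must match animal_ids")
        if self.dosages.shape[1] != len(self.marker_map):
            raise ValueError("dosage columns must match marker map length")
        mm = self.marker_map.reset_index(drop=True)
        if not mm.sort_values(["chrom", "bp"], kind="stable").index.equals(mm.index):
            raise ValueError("marker map must be sorted by (chrom, bp)")
        self.marker_map = mm
        if self.allele_freq is None:
            self.allele_freq = allele_frequencies(self.dosages)

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snp(self) -> int:
        return self.dosages.shape[1]

    def centered(self) -> np.ndarray:
        """Z = dosage - 2p, columnwise (allele-frequency adjusted gene content)."""
        return self.dosages - 2.0 * self.allele_freq


@dataclass
class HSystem:
    """The combined relationship structure used by single-step evaluation."""

    A: np.ndarray
    A22: np.ndarray
    G_star: np.ndarray
    H_inv: np.ndarray
    genotyped_idx: np.ndarray  # positions of genotyped animals in A's order
    all_ids: np.ndarray
    snp_weights: np.ndarray
    lam: float  # variance-normalizing constant 1 / sum(2 p_i (1 - p_i))


def allele_frequencies(dosages: np.ndarray) -> np.ndarray:
    """Observed frequency of the counted allele, per SNP, with missing (NaN) ignored."""
    return np.nanmean(np.asarray(dosages, dtype=float), axis=0) / 2.0


def qc_maf(genotypes: GenotypeSet, threshold: float = 0.05) -> GenotypeSet:
    """Drop SNP whose minor allele frequency is below ``threshold``.

    A SNP with min(p, 1-p) < threshold is excluded (so monomorphic SNP always
    go).  Raises if nothing survives.
    """
    p = genotypes.allele_freq
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= threshold
    n_drop = int((~keep).sum())
    logger.info("MAF filter at %.3f: retained %d / %d SNP (%d removed)",
                threshold, int(keep.sum()), len(keep), n_drop)
    if not keep.any():
        raise ValueError("no SNP pass the MAF filter; panel is effectively monomorphic")
    return GenotypeSet(
        dosages=genotypes.dosages[:, keep],
        marker_map=genotypes.marker_map.loc[keep].reset_index(drop=True),
        animal_ids=genotypes.animal_ids,
        allele_freq=p[keep],
    )


def a_matrix(pedigree: pd.DataFrame) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    ``pedigree`` has columns (animal, sire, dam) with 0 meaning unknown and
    parents listed before their offspring.  Diagonals are 1 + F (F the
    inbreeding coefficient); founder rows are identity.
    """
    animals = pedigree["animal"].to_numpy()
    pos = {int(a): i for i, a in enumerate(animals)}
    n = len(animals)
    sires = pedigree["sire"].to_numpy()
    dams = pedigree["dam"].to_numpy()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = int(sires[i]), int(dams[i])
        if s != 0 and pos[s] >= i:
            raise ValueError(f"sire {s} of animal {animals[i]} appears after it")
        if d != 0 and pos[d] >= i:
            raise ValueError(f"dam {d} of animal {animals[i]} appears after it")
        si = pos.get(s, -1) if s != 0 else -1
        di = pos.get(d, -1) if d != 0 else -1
        if si >= 0 and di >= 0:
            A[i, i] = 1.0 + 0.5 * A[si, di]
            A[i, :i] = 0.5 * (A[si, :i] + A[di, :i])
        elif si >= 0:
            A[i, i] = 1.0
            A[i, :i] = 0.5 * A[si, :i]
        elif di >= 0:
            A[i, i] = 1.0
            A[i, :i] = 0.5 * A[di, :i]
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return A


def a_submatrix(A: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """A22: the NRM restricted to the (genotyped) animals at positions ``idx``."""
    idx = np.asarray(idx)
    return A[np.ix_(idx, idx)]


def g_matrix(genotypes: GenotypeSet, weights: np.ndarray | None = None) -> np.ndarray:
    """VanRaden genomic relationship matrix G = Z D Z' / sum(2 p_i (1 - p_i)).

    Z is the allele-frequency-centered dosage matrix; D is a positive diagonal
    of per-SNP weights (identity for plain GBLUP).  The denominator scales G
    so its expected diagonal is ~1 in the base population.
    """
    p = genotypes.allele_freq
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("sum 2p(1-p) is zero: all SNP monomorphic")
    Z = genotypes.centered()
    if weights is None:
        return (Z @ Z.T) / denom
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size != genotypes.n_snp:
        raise ValueError("weights must be a vector with one entry per SNP")
    if np.any(w < 0):
        raise ValueError("SNP weights must be nonnegative")
    return (Z * w) @ Z.T / denom


def tune_and_blend(G: np.ndarray, A22: np.ndarray, blend_fraction: float = 0.05) -> np.ndarray:
    """Rescale G to A22's base and blend for invertibility.

    Solves the 2x2 system for (alpha, beta) in G_tuned = alpha + beta*G such
    that mean(diag G_tuned) = mean(diag A22) and mean(offdiag G_tuned) =
    mean(offdiag A22), then returns
    G* = (1 - blend_fraction)*G_tuned + blend_fraction*A22.
    """
    n = G.shape[0]
    if G.shape != A22.shape:
        raise ValueError("G and A22 must be conformable")
    diag_g = float(np.mean(np.diag(G)))
    diag_a = float(np.mean(np.diag(A22)))
    if n > 1:
        off = ~np.eye(n, dtype=bool)
        off_g = float(np.mean(G[off]))
        off_a = float(np.mean(A22[off]))
    else:
        off_g = off_a = 0.0
    # [1 diag_g; 1 off_g] @ [alpha, beta] = [diag_a, off_a]
    M = np.array([[1.0, diag_g], [1.0, off_g]])
    if abs(np.linalg.det(M)) < 1e-12:
        raise ValueError("cannot tune: G has equal diagonal and off-diagonal means (constant G?)")
    alpha, beta = np.linalg.solve(M, np.array([diag_a, off_a]))
    G_tuned = alpha + beta * G
    if n == 1:
        G_tuned = G * (diag_a / diag_g)
    return (1.0 - blend_fraction) * G_tuned + blend_fraction * A22


def h_inverse(
    A: np.ndarray,
    A22: np.ndarray,
    G_star: np.ndarray,
    genotyped_idx: np.ndarray,
    condition_cap: float = 1e10,
) -> np.ndarray:
    """H^-1 = A^-1 + correction G*^-1 - A22^-1 on the genotyped block.

    With no genotyped animals (or G* == A22) this is exactly A^-1.  An
    ill-conditioned G* is rejected with a pointer to the blending remedy.
    """
    A_inv = np.linalg.inv(A)
    idx = np.asarray(genotyped_idx)
    if idx.size == 0:
        return A_inv
    cond = np.linalg.cond(G_star)
    if cond > condition_cap:
        raise np.linalg.LinAlgError(
            f"G* condition number {cond:.3g} exceeds cap {condition_cap:.3g}; "
            "increase blend_fraction"
        )
    corr = np.linalg.inv(G_star) - np.linalg.inv(A22)
    H_inv = A_inv.copy()
    H_inv[np.ix_(idx, idx)] += corr
    return 0.5 * (H_inv + H_inv.T)


def build_h_system(
    pedigree: pd.DataFrame,
    genotypes: GenotypeSet,
    snp_weights: np.ndarray | None = None,
    blend_fraction: float = 0.05,
) -> HSystem:
    """Assemble the full single-step relationship structure from pedigree + genotypes.

    Genotyped animals are matched to pedigree rows by id; genotyped animals
    absent from the pedigree are an error.
    """
    all_ids = pedigree["animal"].to_numpy()
    pos = {int(a): i for i, a in enumerate(all_ids)}
    try:
        idx = np.array([pos[int(a)] for a in genotypes.animal_ids])
    except KeyError as e:
        raise KeyError(f"genotyped animal {e} not in pedigree") from None
    A = a_matrix(pedigree)
    A22 = a_submatrix(A, idx)
    w = snp_weights if snp_weights is not None else np.ones(genotypes.n_snp)
    G = g_matrix(genotypes, w)
    G_star = tune_and_blend(G, A22, blend_fraction)
    H_inv = h_inverse(A, A22, G_star, idx)
    p = genotypes.allele_freq
    lam = 1.0 / float(np.sum(2.0 * p * (1.0 - p)))
    return HSystem(A=A, A22=A22, G_star=G_star, H_inv=H_inv,
                   genotyped_idx=idx, all_ids=all_ids,
                   snp_weights=np.asarray(w, dtype=float), lam=lam)
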