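"""Positional candidate genes and gene-set enrichment for candidate windows.

Candidate windows (those above the variance threshold) are intersected with
a local gene annotation (GFF3 or BED); any gene overlapping a window by at
least 1 bp is a positional candidate.  Enrichment of the candidate list in
named gene sets (GMT format) is tested with the one-sided hypergeometric
upper tail against an explicit background universe, with Benjamini-Hochberg
adjustment across terms; following common post-GWAS practice only terms
sharing at least four genes with the candidate list are reported.

Coordinates: GFF3 input is 1-based inclusive, BED is 0-based half-open;
both are stored internally as 0-based half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneAnnotation",
    "read_gff3",
    "read_bed",
    "read_gmt",
    "genes_in_windows",
    "enrichment",
]


@dataclass
class GeneAnnotation:
    """Gene intervals: columns (gene_id, symbol, chrom, start, end, strand),
    start/end 0-based half-open."""

    genes: pd.DataFrame

    def __post_init__(self):
        g = self.genes
        if (g["start"] > g["end"]).any():
            bad = g[g["start"] > g["end"]]
            raise ValueError(f"gene intervals with start > end: {bad['gene_id'].tolist()[:5]}")

    def trees(self) -> dict:
        out: dict[str, IntervalTree] = {}
        for chrom, grp in self.genes.groupby("chrom", sort=False):
            t = IntervalTree()
            for row in grp.itertuples():
                if row.end > row.start:
                    t[row.start:row.end] = row.gene_id
            out[str(chrom)] = t
        return out


def _gff_attr(attrs: str, keys=("ID", "gene_id", "Name", "gene_name")) -> dict:
    d = {}
    for part in attrs.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            d[k.strip()] = v.strip()
    return d


def read_gff3(path, feature: str = "gene") -> GeneAnnotation:
    """Load gene records from a GFF3 file (1-based inclusive -> half-open)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["seqid", "source", "type", "start", "end",
                            "score", "strand", "phase", "attributes"],
                     dtype={"seqid": str})
    df = df[df["type"] == feature]
    rows = []
    for row in df.itertuples():
        a = _gff_attr(row.attributes)
        gid = a.get("ID") or a.get("gene_id") or f"{row.seqid}:{row.start}-{row.end}"
        rows.append({
            "gene_id": gid.removeprefix("gene:"),
            "symbol": a.get("Name") or a.get("gene_name") or gid,
            "chrom": str(row.seqid),
            "start": int(row.start) - 1,   # to 0-based half-open
            "end": int(row.end),
            "strand": row.strand,
        })
    return GeneAnnotation(genes=pd.DataFrame(rows))


def read_bed(path) -> GeneAnnotation:
    """Load gene intervals from BED (already 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    out = pd.DataFrame({
        "chrom": df[0].astype(str),
        "start": df[1].astype(int),
        "end": df[2].astype(int),
        "gene_id": df[3] if df.shape[1] > 3 else [f"iv{i}" for i in range(len(df))],
        "strand": df[5] if df.shape[1] > 5 else ".",
    })
    out["symbol"] = out["gene_id"]
    return GeneAnnotation(genes=out[["gene_id", "symbol", "chrom", "start", "end", "strand"]])


def read_gmt(path) -> dict:
    """GMT gene sets: term -> set of gene ids (description column ignored)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def genes_in_windows(
    windows: pd.DataFrame,
    annotation: GeneAnnotation,
    dedupe: bool = False,
) -> pd.DataFrame:
    """Genes overlapping each candidate window by >= 1 bp.

    ``windows`` needs columns (chrom, start_bp, end_bp) with bp positions
    interpreted as 1-based inclusive SNP coordinates (converted internally).
    Returns one row per (window, gene); with ``dedupe`` genes seen in an
    earlier window are dropped from later ones.  Unknown chromosome names
    are an error so assembly mismatches fail loudly.
    """
    trees = annotation.trees()
    known = set(trees)
    asked = set(str(c) for c in windows["chrom"].unique())
    missing = sorted(asked - known)
    if missing:
        raise ValueError(f"window chromosomes absent from annotation: {missing}")
    gene_info = annotation.genes.set_index("gene_id")
    rows = []
    seen: set[str] = set()
    for w in windows.itertuples():
        lo, hi = int(w.start_bp) - 1, int(w.end_bp)   # 1-based inclusive -> half-open
        hits = sorted(trees[str(w.chrom)].overlap(lo, hi), key=lambda iv: iv.begin)
        for iv in hits:
            gid = iv.data
            if dedupe and gid in seen:
                continue
            seen.add(gid)
            g = gene_info.loc[gid]
            rows.append({
                "chrom": w.chrom, "window_start_bp": int(w.start_bp),
                "window_end_bp": int(w.end_bp), "gene_id": gid,
                "symbol": g["symbol"], "gene_start": int(g["start"]) + 1,
                "gene_end": int(g["end"]),
            })
    return pd.DataFrame(rows, columns=["chrom", "window_start_bp", "window_end_bp",
                                       "gene_id", "symbol", "gene_start", "gene_end"])


def enrichment(
    candidate_genes,
    gene_sets: dict,
    background,
    min_overlap: int = 4,
) -> pd.DataFrame:
    """Hypergeometric over-representation of candidate genes in each gene set.

    For a term containing K of the N background genes, with n candidates of
    which k are in the term, the p-value is P(X >= k) for
    X ~ Hypergeom(N, K, n).  BH adjustment is applied across all tested
    terms; terms with overlap below ``min_overlap`` are excluded from the
    report (after testing, mirroring a report-side filter).
    """
    background = set(background)
    if not background:
        raise ValueError("background gene universe is empty")
    cand = set(candidate_genes) & background
    if set(candidate_genes) - background:
        extra = sorted(set(candidate_genes) - background)
        raise ValueError(f"candidate genes outside background: {extra[:5]}")
    N, n = len(background), len(cand)
    rows = []
    for term, members in gene_sets.items():
        members = set(members) & background
        K = len(members)
        if K == 0:
            continue
        overlap = cand & members
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "term_size": K, "overlap": k,
                     "overlap_genes": ",".join(sorted(overlap)), "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df = df[df["overlap"] >= min_overlap].sort_values("p_adjusted").reset_index(drop=True)
    return df
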