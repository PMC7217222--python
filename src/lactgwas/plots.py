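"""Manhattan-style window plots and LD heatmaps (matplotlib, file output)."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_window_scan", "plot_ld_heatmap"]


def plot_window_scan(scan, path, threshold: float = 0.50):
    """Percent additive variance per 50-SNP window along the genome, with the
    candidate threshold drawn as a horizontal line."""
    tab = scan.table
    fig, ax = plt.subplots(figsize=(9, 3.2))
    x = np.arange(len(tab))
    for i, (chrom, grp) in enumerate(tab.groupby("chrom", sort=False)):
        ax.bar(x[grp.index], grp["pct_variance"],
               color="tab:blue" if i % 2 == 0 else "tab:cyan", width=0.9)
    ax.axhline(threshold, color="red", lw=1, ls="--",
               label=f"{threshold}% threshold")
    ax.set_xlabel("50-SNP window (genome order)")
    ax.set_ylabel("% additive genetic variance")
    if scan.trait:
        ax.set_title(scan.trait)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ld_heatmap(ld, genotypes, region, path):
    """Triangle heatmap of pairwise r^2 for a (chrom, start_bp, end_bp) region."""
    chrom, start, end = region
    mm = genotypes.marker_map
    sel = mm[(mm["chrom"] == chrom) & (mm["bp"] >= start) & (mm["bp"] <= end)]
    snps = sel.index.to_numpy()
    k = len(snps)
    M = np.full((k, k), np.nan)
    pos = {int(s): i for i, s in enumerate(snps)}
    for row in ld.pairs.itertuples():
        i, j = pos.get(int(row.snp_i)), pos.get(int(row.snp_j))
        if i is not None and j is not None:
            M[j, i] = row.r2  # lower triangle
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(M, cmap="Reds", vmin=0, vmax=1)
    fig.colorbar(im, ax=ax, label="$r^2$")
    ax.set_title(f"chr{chrom}:{start}-{end}")
    ax.set_xlabel("SNP")
    ax.set_ylabel("SNP")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
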