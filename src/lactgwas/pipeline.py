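"""End-to-end orchestration: simulate -> fit curves -> variance components ->
weighted single-step GWAS -> LD -> annotation, with a run manifest.

Each stage reads and writes plain delimited files inside the run directory,
so any stage can be rerun or inspected in isolation; ``run_pipeline`` chains
them and records a manifest (inputs, parameters, package version, seed)
sufficient to re-derive every output.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as lio
from .annotate import enrichment, genes_in_windows, read_bed, read_gff3, read_gmt
from .kinship import build_h_system, qc_maf
from .ldmap import find_blocks, pairwise_r2
from .milkbot import DECAY_DISPLAY_SCALE, fit_many
from .reml import ModelSpec, VarianceComponents, aireml
from .simulate import SimulationConfig, simulate_population, subset_genotypes
from .ssgwas import candidate_windows, iterate_weights, window_variance
from .plots import plot_ld_heatmap, plot_window_scan

logger = logging.getLogger(__name__)

DEFAULTS = {
    "seed": 2024,
    "parity": "primi",              # primi | multi
    "traits": ["m305"],
    "maf_threshold": 0.05,
    "blend_fraction": 0.05,
    "iterations": 3,
    "report_iteration": 2,          # 1-based; most accurate evaluation
    "window_size": 50,
    "threshold": 0.50,
    "ld_window_bp": 200_000,
    "ld_r2_threshold": 0.7,
    "min_testdays": 5,
    "genotyped_fraction": 0.5,
    "simulate": {},
    "annotation": None,             # GFF3/BED path
    "gene_sets": None,              # GMT path
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {**DEFAULTS, **user}
    return cfg


def validate_config(cfg: dict, require=()) -> None:
    for key in require:
        p = cfg.get(key)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"config path {key!r} = {p!r} does not exist")


def stage_simulate(cfg: dict, outdir: Path) -> dict:
    sim_kwargs = dict(cfg.get("simulate") or {})
    sim_kwargs.setdefault("seed", cfg["seed"])
    sc = SimulationConfig(**sim_kwargs)
    pop = simulate_population(sc)
    lio.write_pedigree(pop["pedigree"], outdir / "pedigree.csv")
    lio.write_records(pop["records"], outdir / "testday_records.csv")
    pop["covariates"].to_csv(outdir / "covariates.csv", index=False)
    # genotype the configured fraction of non-founder animals
    rng = np.random.default_rng(sc.seed + 1)
    nonf = pop["pedigree"][pop["pedigree"]["generation"] > 0]["animal"].to_numpy()
    k = max(2, int(cfg["genotyped_fraction"] * len(nonf)))
    geno_ids = np.sort(rng.choice(nonf, size=min(k, len(nonf)), replace=False))
    gset = subset_genotypes(pop["genotypes"], geno_ids)
    lio.write_dosage_tsv(gset, outdir / "dosages.tsv", outdir / "marker_map.tsv")
    lio.write_plink(gset, outdir / "genotypes")
    truth = pop["truth"]
    pd.DataFrame(truth.true_breeding_values,
                 index=pop["pedigree"]["animal"]).to_csv(outdir / "true_bv.csv")
    pd.DataFrame({"qtl_index": truth.qtl_positions}).to_csv(
        outdir / "true_qtl.csv", index=False)
    logger.info("simulate: %d animals, %d genotyped, %d test-day records "
                "(%d negative yields truncated)",
                len(pop["pedigree"]), len(geno_ids), len(pop["records"]),
                pop["n_truncated"])
    return {"n_animals": len(pop["pedigree"]), "n_genotyped": len(geno_ids)}


def stage_fit_curves(cfg: dict, outdir: Path) -> dict:
    records = lio.read_records(outdir / "testday_records.csv")
    fits = fit_many(records, min_testdays=cfg["min_testdays"])
    fits["decay_x1000"] = fits.get("decay_d", np.nan) * DECAY_DISPLAY_SCALE
    fits.to_csv(outdir / "lactation_fits.csv", index=False)
    n_bad = int((fits["status"] != "ok").sum())
    logger.info("fit-curves: %d lactations fitted, %d excluded", len(fits), n_bad)
    return {"n_lactations": len(fits), "n_excluded": n_bad}


def _phenotype_table(cfg: dict, outdir: Path) -> pd.DataFrame:
    fits = pd.read_csv(outdir / "lactation_fits.csv")
    cov = pd.read_csv(outdir / "covariates.csv")
    ph = fits[fits["status"] == "ok"].merge(cov, on=["animal", "parity"], how="inner")
    ph = ph.rename(columns={"scale_a": "scale", "ramp_b": "ramp"})
    ph["decay"] = ph["decay_d"] * DECAY_DISPLAY_SCALE
    if cfg["parity"] == "primi":
        ph = ph[ph["parity"] == 1]
    else:
        ph = ph[ph["parity"] > 1]
    return ph.reset_index(drop=True)


def _model_for(cfg: dict, trait: str) -> ModelSpec:
    multi = cfg["parity"] == "multi"
    fixed = ["hys", "country"] + (["parity"] if multi else [])
    return ModelSpec(response=trait, fixed_effects=fixed,
                     covariates=("age", "age_sq"), permanent_env=multi)


def _h_system(cfg: dict, outdir: Path):
    pedigree = lio.read_pedigree(outdir / "pedigree.csv")
    gset = lio.read_dosage_tsv(outdir / "dosages.tsv", outdir / "marker_map.tsv")
    gset = qc_maf(gset, cfg["maf_threshold"])
    hs = build_h_system(pedigree, gset, blend_fraction=cfg["blend_fraction"])
    return pedigree, gset, hs


def stage_reml(cfg: dict, outdir: Path) -> dict:
    ph = _phenotype_table(cfg, outdir)
    pedigree, gset, hs = _h_system(cfg, outdir)
    rows = []
    for trait in cfg["traits"]:
        model = _model_for(cfg, trait)
        vc = aireml(model, ph, hs.H_inv, hs.all_ids)
        rows.append({
            "trait": trait, "sigma_a2": vc.sigma_a2, "sigma_p2": vc.sigma_p2,
            "sigma_e2": vc.sigma_e2, "h2": vc.heritability,
            "repeatability": vc.repeatability, "logL": vc.log_likelihood,
            "converged": vc.converged, "n_iterations": vc.n_iterations,
        })
        logger.info("reml %s: h2=%.3f (converged=%s)", trait,
                    vc.heritability, vc.converged)
    out = pd.DataFrame(rows)
    out.to_csv(outdir / "variance_components.csv", index=False)
    return {"traits": list(cfg["traits"])}


def stage_wssgwas(cfg: dict, outdir: Path) -> dict:
    ph = _phenotype_table(cfg, outdir)
    pedigree, gset, hs = _h_system(cfg, outdir)
    vcs = pd.read_csv(outdir / "variance_components.csv").set_index("trait")
    report_it = int(cfg["report_iteration"])
    n_candidates = {}
    for trait in cfg["traits"]:
        row = vcs.loc[trait]
        vc = VarianceComponents(sigma_a2=row["sigma_a2"], sigma_p2=row["sigma_p2"],
                                sigma_e2=row["sigma_e2"], converged=True)
        model = _model_for(cfg, trait)
        iters = iterate_weights(model, ph, pedigree, gset, vc,
                                n_iterations=cfg["iterations"],
                                blend_fraction=cfg["blend_fraction"])
        eff, gebv = iters[min(report_it, len(iters)) - 1]
        pd.DataFrame({
            "snp": gset.marker_map["snp"], "chrom": gset.marker_map["chrom"],
            "bp": gset.marker_map["bp"], "u_hat": eff.u_hat, "weight": eff.weights,
        }).to_csv(outdir / f"snp_effects_{trait}.tsv", sep="\t", index=False)
        pd.DataFrame({
            "animal": gebv.animal_ids, "gebv": gebv.gebv, "pev": gebv.pev,
            "accuracy": gebv.accuracy, "reliability": gebv.reliability,
        }).to_csv(outdir / f"gebv_{trait}.tsv", sep="\t", index=False)
        scan = window_variance(eff, gset, sigma_a2=row["sigma_a2"],
                               window_size=cfg["window_size"], trait=trait)
        tab = scan.table.copy()
        tab["candidate"] = tab["pct_variance"] > cfg["threshold"]
        tab.to_csv(outdir / f"window_scan_{trait}.tsv", sep="\t", index=False)
        plot_window_scan(scan, outdir / f"manhattan_{trait}.png", cfg["threshold"])
        n_candidates[trait] = int(tab["candidate"].sum())
        logger.info("wssgwas %s: %d candidate windows (>%.2f%%)",
                    trait, n_candidates[trait], cfg["threshold"])
    return {"candidates": n_candidates}


def stage_ld(cfg: dict, outdir: Path) -> dict:
    gset = lio.read_dosage_tsv(outdir / "dosages.tsv", outdir / "marker_map.tsv")
    gset = qc_maf(gset, cfg["maf_threshold"])
    trait = cfg["traits"][0]
    scan = pd.read_csv(outdir / f"window_scan_{trait}.tsv", sep="\t")
    top = scan.sort_values("pct_variance", ascending=False).iloc[0]
    region = (int(top["chrom"]), int(top["start_bp"]), int(top["end_bp"]))
    ld = pairwise_r2(gset, region=region, window_bp=cfg["ld_window_bp"])
    ld.pairs.to_csv(outdir / "ld_pairs.tsv", sep="\t", index=False)
    blocks = find_blocks(ld, gset, r2_threshold=cfg["ld_r2_threshold"])
    blocks.to_csv(outdir / "ld_blocks.tsv", sep="\t", index=False)
    plot_ld_heatmap(ld, gset, region, outdir / "ld_heatmap.png")
    logger.info("ld: region chr%s:%d-%d, %d pairs, %d blocks",
                *region, len(ld.pairs), len(blocks))
    return {"region": list(region), "n_blocks": len(blocks)}


def stage_annotate(cfg: dict, outdir: Path) -> dict:
    if not cfg.get("annotation"):
        logger.info("annotate: no annotation file configured; skipping")
        return {"skipped": True}
    path = Path(cfg["annotation"])
    ann = read_bed(path) if path.suffix == ".bed" else read_gff3(path)
    trait = cfg["traits"][0]
    scan = pd.read_csv(outdir / f"window_scan_{trait}.tsv", sep="\t")
    cand = scan[scan["candidate"]]
    genes = genes_in_windows(cand, ann)
    genes.to_csv(outdir / "candidate_genes.tsv", sep="\t", index=False)
    out = {"n_candidate_genes": int(genes["gene_id"].nunique()) if len(genes) else 0}
    if cfg.get("gene_sets"):
        sets = read_gmt(cfg["gene_sets"])
        background = set(ann.genes["gene_id"])
        cand_genes = set(genes["gene_id"])
        enr = enrichment(cand_genes, sets, background)
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        out["n_enriched_terms"] = len(enr)
    return out


STAGES = {
    "simulate": stage_simulate,
    "fit-curves": stage_fit_curves,
    "reml": stage_reml,
    "wssgwas": stage_wssgwas,
    "ld": stage_ld,
    "annotate": stage_annotate,
}


def run_pipeline(cfg: dict, outdir, stages=None) -> dict:
    """Run the configured stages in order, writing a manifest at the end.

    Raises on the first failing stage (partial outputs are kept on disk).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.get("annotation"):
        validate_config(cfg, require=["annotation"])
    if cfg.get("gene_sets"):
        validate_config(cfg, require=["gene_sets"])
    manifest = {"version": __version__, "seed": cfg["seed"],
                "config": {k: v for k, v in cfg.items() if not isinstance(v, Path)},
                "stages": {}}
    for name in (stages or list(STAGES)):
        t0 = time.time()
        try:
            info = STAGES[name](cfg, outdir)
        except Exception:
            logger.error("stage %s failed", name)
            raise
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 2), **info}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
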