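"""Readers and writers for the pipeline's tabular formats.

Pedigree, test-day records, covariates and result tables travel as
CSV/TSV with headers.  Genotypes round-trip either as a plain TSV dosage
matrix plus a (snp, chrom, bp) map, or as PLINK text .ped/.map (dosages are
expanded to A/B allele pairs on write and re-counted on read).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kinship import GenotypeSet

__all__ = [
    "read_pedigree", "write_pedigree",
    "read_records", "write_records",
    "read_dosage_tsv", "write_dosage_tsv",
    "read_plink", "write_plink",
    "write_matrix", "read_matrix",
]


def read_pedigree(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("animal", "sire", "dam"):
        if col not in df.columns:
            raise ValueError(f"pedigree file missing column {col!r}")
        df[col] = df[col].fillna(0).astype(int)
    return df


def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    pedigree.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"animal", "parity", "dim", "milk_kg"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"test-day file missing columns {sorted(missing)}")
    return df


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def write_dosage_tsv(genotypes: GenotypeSet, dosage_path, map_path) -> None:
    df = pd.DataFrame(genotypes.dosages.astype(int),
                      columns=genotypes.marker_map["snp"])
    df.insert(0, "animal", genotypes.animal_ids)
    df.to_csv(dosage_path, sep="\t", index=False)
    genotypes.marker_map.to_csv(map_path, sep="\t", index=False)


def read_dosage_tsv(dosage_path, map_path) -> GenotypeSet:
    df = pd.read_csv(dosage_path, sep="\t")
    mm = pd.read_csv(map_path, sep="\t")
    animals = df["animal"].to_numpy()
    dos = df.drop(columns=["animal"]).to_numpy(dtype=float)
    return GenotypeSet(dosages=dos, marker_map=mm, animal_ids=animals)


def write_plink(genotypes: GenotypeSet, prefix) -> None:
    """PLINK text .ped/.map; dosage 0/1/2 -> allele pairs (A A / A B / B B)."""
    prefix = Path(prefix)
    mm = genotypes.marker_map
    with open(prefix.with_suffix(".map"), "w") as fh:
        for row in mm.itertuples():
            fh.write(f"{row.chrom}\t{row.snp}\t0\t{row.bp}\n")
    pairs = {0: "A A", 1: "A B", 2: "B B"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, animal in enumerate(genotypes.animal_ids):
            geno = " ".join(pairs[int(d)] for d in genotypes.dosages[i])
            fh.write(f"FAM1 {animal} 0 0 0 -9 {geno}\n")


def read_plink(prefix) -> GenotypeSet:
    prefix = Path(prefix)
    mm = pd.read_csv(prefix.with_suffix(".map"), sep="\t", header=None,
                     names=["chrom", "snp", "cm", "bp"])[["snp", "chrom", "bp"]]
    animals, rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            animals.append(int(parts[1]))
            alleles = parts[6:]
            dos = [(1 if alleles[2 * j] == "B" else 0) + (1 if alleles[2 * j + 1] == "B" else 0)
                   for j in range(len(alleles) // 2)]
            rows.append(dos)
    return GenotypeSet(dosages=np.array(rows, dtype=float), marker_map=mm,
                       animal_ids=np.array(animals))


def write_matrix(M: np.ndarray, path, ids=None) -> None:
    """Symmetric matrix as labelled TSV (readable back with read_matrix)."""
    ids = ids if ids is not None else np.arange(M.shape[0])
    pd.DataFrame(M, index=ids, columns=ids).to_csv(path, sep="\t")


def read_matrix(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=float)
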