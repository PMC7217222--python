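"""Synthetic pedigreed, genotyped dairy populations with known curve genetics.

The generator emulates the structure of a multi-country test-day recording
scheme: a pedigreed Holstein-like population across discrete generations,
biallelic SNP genotypes dropped through the pedigree with recombination
(creating realistic within-chromosome LD), additive genetic and permanent
environmental variation in the four MilkBot parameters, herd-year-season /
country / age-at-calving fixed effects, and noisy test-day milk records
produced from each animal's true lactation curve.  Every quantity a
downstream stage estimates (breeding values, variance components, QTL
positions) is retained as ground truth.

Environmental and age effects act on the scale parameter ``a``; because both
the daily curve and M305 are linear in ``a``, these translate into additive
fixed effects on yield traits, matching the linear model fitted downstream.

All randomness flows from one generator seeded by ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import GenotypeSet
from .milkbot import MilkBotParams, evaluate

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_pedigree",
    "drop_genotypes",
    "subset_genotypes",
    "simulate_breeding_values",
    "simulate_lactations",
    "simulate_single_trait",
    "simulate_population",
]

# Table-style defaults for a primiparous Holstein population: curve parameter
# means (a kg/day, b days, c days, d 1/day) and additive / permanent
# environmental variances on the same scales (decay in natural units).
DEFAULT_TRAIT_MEANS = (35.57, 30.60, 0.0, 0.00142)
DEFAULT_GENETIC_COV = np.diag([7.58, 0.0056, 0.25, 0.02228e-6])
DEFAULT_PE_COV = np.diag([4.85, 0.0145, 0.10, 0.01143e-6])


@dataclass
class SimulationConfig:
    n_founders: int = 200
    n_generations: int = 3
    n_animals_target: int = 2000
    n_snp: int = 2000
    n_chromosomes: int = 5
    chromosome_length_bp: int = 1_650_000
    n_qtl: int = 10
    qtl_variance_fraction: float = 0.3
    qtl_maf_min: float = 0.2          # plant QTL at common variants
    founder_maf_range: tuple = (0.05, 0.5)
    trait_means: tuple = DEFAULT_TRAIT_MEANS
    genetic_covariance: np.ndarray = field(default_factory=lambda: DEFAULT_GENETIC_COV.copy())
    pe_covariance: np.ndarray = field(default_factory=lambda: DEFAULT_PE_COV.copy())
    residual_sd_milk: float = 2.5
    herds: int = 10
    years: int = 3
    seasons: int = 4
    countries: int = 4
    hys_effect_sd: float = 2.0       # kg/day on the scale parameter
    country_effect_sd: float = 1.0   # kg/day on the scale parameter
    age_linear: float = 0.15         # kg/day per month of age at calving
    age_quadratic: float = -0.003
    test_day_schedule: tuple = tuple(range(5, 306, 30))
    parity_distribution: tuple = (0.47, 0.19, 0.18, 0.16)  # P(1..4 lactations)
    cm_per_mb: float = 1.0
    polygenic_mode: str = "genomic"   # "genomic" | "pedigree" background
    founder_ld: bool = True           # coalescent founder haplotypes (real LD)
    ancestral_ne: int = 1000          # effective size behind founder LD
    seed: int = 2024

    def validate(self) -> None:
        lo, hi = self.founder_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range must lie within (0, 0.5]")
        for name in ("n_founders", "n_generations", "n_animals_target", "n_snp",
                     "n_chromosomes", "chromosome_length_bp"):
            if getattr(self, name) < 0 or (name != "n_generations" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders (one of each sex)")
        for M in (np.asarray(self.genetic_covariance), np.asarray(self.pe_covariance)):
            if not np.allclose(M, M.T):
                raise ValueError("covariance matrices must be symmetric")
            if np.min(np.linalg.eigvalsh(M)) < -1e-10:
                raise ValueError("covariance matrices must be positive semidefinite")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthSet:
    """Ground truth retained from a simulation for recovery tests."""

    true_breeding_values: np.ndarray      # animals x n_traits (curve-parameter scale)
    qtl_positions: np.ndarray             # marker indices
    qtl_effects: np.ndarray               # n_qtl x n_traits
    polygenic_covariance: np.ndarray      # covariance of the non-QTL background
    background_effects: np.ndarray | None = None  # n_snp x n_traits (genomic mode)


def simulate_pedigree(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Discrete-generation pedigree: columns (animal, sire, dam, sex, generation).

    Founders (generation 0) have unknown parents coded 0; each later animal
    draws a random sire and dam from the previous generation, so parents
    always precede offspring and no animal is its own ancestor.
    """
    config.validate()
    rng = rng or config.rng()
    rows = []
    nf = config.n_founders
    sexes = np.array(["M", "F"])[rng.integers(0, 2, nf)]
    # force both sexes among founders
    if (sexes == "M").all():
        sexes[0] = "F"
    if (sexes == "F").all():
        sexes[0] = "M"
    for i in range(nf):
        rows.append({"animal": i + 1, "sire": 0, "dam": 0, "sex": sexes[i], "generation": 0})
    if config.n_generations > 0:
        per_gen = max(1, (config.n_animals_target - nf) // config.n_generations)
        next_id = nf + 1
        prev = [r for r in rows]
        for g in range(1, config.n_generations + 1):
            males = [r["animal"] for r in prev if r["sex"] == "M"]
            females = [r["animal"] for r in prev if r["sex"] == "F"]
            if not males or not females:
                raise ValueError(f"generation {g - 1} lacks one sex; cannot mate")
            cur = []
            for _ in range(per_gen):
                sire = int(rng.choice(males))
                dam = int(rng.choice(females))
                sex = "M" if rng.random() < 0.5 else "F"
                cur.append({"animal": next_id, "sire": sire, "dam": dam,
                            "sex": sex, "generation": g})
                next_id += 1
            rows.extend(cur)
            prev = cur
    return pd.DataFrame(rows)


def _marker_map(config: SimulationConfig) -> pd.DataFrame:
    per_chrom = config.n_snp // config.n_chromosomes
    counts = [per_chrom] * config.n_chromosomes
    counts[-1] += config.n_snp - per_chrom * config.n_chromosomes
    rows = []
    snp = 0
    for c, k in enumerate(counts, start=1):
        bp = np.linspace(1, config.chromosome_length_bp, k).astype(int)
        for b in bp:
            rows.append({"snp": f"snp{snp}", "chrom": c, "bp": int(b)})
            snp += 1
    return pd.DataFrame(rows)


def _recomb_fractions(marker_map: pd.DataFrame, cm_per_mb: float) -> np.ndarray:
    """Haldane recombination fraction between adjacent markers; 0.5 across
    chromosome boundaries (independent assortment)."""
    bp = marker_map["bp"].to_numpy()
    chrom = marker_map["chrom"].to_numpy()
    d_morgan = np.abs(np.diff(bp)) * cm_per_mb * 1e-8  # bp -> Morgans
    r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    r[np.diff(chrom) != 0] = 0.5
    return r


def _gamete(haplos: np.ndarray, r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One meiosis: start on a random parental haplotype, switch at crossovers."""
    cross = rng.random(r.size) < r
    which = np.empty(r.size + 1, dtype=np.int8)
    which[0] = rng.integers(0, 2)
    which[1:] = cross
    which = np.cumsum(which) % 2
    return haplos[which, np.arange(r.size + 1)]


def _coalescent_founder_panel(config: SimulationConfig, n_founders: int,
                              rng: np.random.Generator):
    """Founder haplotypes with realistic LD from a neutral coalescent.

    One tree sequence per chromosome (effective size ``ancestral_ne``,
    recombination from ``cm_per_mb``); biallelic segregating sites with MAF
    inside ``founder_maf_range`` are thinned evenly to the per-chromosome
    marker count.  Returns (haplotypes [2*n_founders x n_snp], marker map).
    """
    import msprime

    per_chrom = config.n_snp // config.n_chromosomes
    counts = [per_chrom] * config.n_chromosomes
    counts[-1] += config.n_snp - per_chrom * config.n_chromosomes
    lo, hi = config.founder_maf_range
    L = float(config.chromosome_length_bp)
    rec = config.cm_per_mb * 1e-8
    a_n = np.log(2 * n_founders) + 0.5772
    haps, map_rows = [], []
    for c, n_mark in enumerate(counts, start=1):
        # mutation rate aimed at ~8x the needed qualifying sites
        mu = 8.0 * n_mark / max(4.0 * config.ancestral_ne * L * a_n, 1.0)
        for attempt in range(4):
            seed_a = int(rng.integers(1, 2**31 - 1))
            seed_m = int(rng.integers(1, 2**31 - 1))
            ts = msprime.sim_ancestry(
                samples=n_founders, population_size=config.ancestral_ne,
                sequence_length=L, recombination_rate=rec, random_seed=seed_a)
            ts = msprime.sim_mutations(ts, rate=mu, random_seed=seed_m)
            G = ts.genotype_matrix()          # sites x haplotypes
            if G.size == 0:
                mu *= 4.0
                continue
            freq = G.mean(axis=1)
            ok = (G.max(axis=1) <= 1) & (np.minimum(freq, 1 - freq) >= lo) \
                 & (np.minimum(freq, 1 - freq) <= hi)
            if ok.sum() >= n_mark:
                break
            mu *= 4.0
        else:
            raise RuntimeError(
                f"could not simulate {n_mark} polymorphic founder sites on "
                f"chromosome {c}; widen founder_maf_range or shorten the panel")
        idx = np.flatnonzero(ok)
        pick = idx[np.linspace(0, len(idx) - 1, n_mark).astype(int)]
        bp = np.floor(ts.tables.sites.position[pick]).astype(int) + 1
        # enforce strictly increasing positions after flooring
        for j in range(1, len(bp)):
            if bp[j] <= bp[j - 1]:
                bp[j] = bp[j - 1] + 1
        haps.append(G[pick].T.astype(np.int8))  # haplotypes x sites
        for b in bp:
            map_rows.append({"snp": None, "chrom": c, "bp": int(b)})
    mm = pd.DataFrame(map_rows)
    mm["snp"] = [f"snp{i}" for i in range(len(mm))]
    return np.hstack(haps), mm[["snp", "chrom", "bp"]]


def drop_genotypes(pedigree: pd.DataFrame, config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> GenotypeSet:
    """Gene-drop biallelic SNP through the pedigree.

    Founder haplotypes come from a neutral coalescent (``founder_ld=True``,
    the default), so the founder generation carries realistic decaying LD;
    with ``founder_ld=False`` founders are in linkage equilibrium with
    per-SNP frequencies uniform on ``founder_maf_range`` and markers on an
    even physical grid.  Offspring receive one recombinant gamete per
    parent (Haldane map, ``cm_per_mb`` cM/Mb).  Returns dosages for every
    pedigree animal; use :func:`subset_genotypes` for the genotyped subset.
    """
    config.validate()
    rng = rng or config.rng()
    founder_rows = np.flatnonzero((pedigree["sire"].to_numpy() == 0)
                                  & (pedigree["dam"].to_numpy() == 0))
    founder_pool = None
    if config.founder_ld:
        founder_pool, mm = _coalescent_founder_panel(config, len(founder_rows), rng)
    else:
        mm = _marker_map(config)
    r = _recomb_fractions(mm, config.cm_per_mb)
    lo, hi = config.founder_maf_range
    p = rng.uniform(lo, hi, config.n_snp)
    n = len(pedigree)
    haplo = np.zeros((n, 2, config.n_snp), dtype=np.int8)
    pos = {int(a): i for i, a in enumerate(pedigree["animal"])}
    sires = pedigree["sire"].to_numpy()
    dams = pedigree["dam"].to_numpy()
    founder_no = 0
    for i in range(n):
        s, d = int(sires[i]), int(dams[i])
        if s == 0 and d == 0 and founder_pool is not None:
            haplo[i, 0] = founder_pool[2 * founder_no]
            haplo[i, 1] = founder_pool[2 * founder_no + 1]
            founder_no += 1
            continue
        if s == 0:
            haplo[i, 0] = rng.random(config.n_snp) < p
        else:
            haplo[i, 0] = _gamete(haplo[pos[s]], r, rng)
        if d == 0:
            haplo[i, 1] = rng.random(config.n_snp) < p
        else:
            haplo[i, 1] = _gamete(haplo[pos[d]], r, rng)
    dosages = haplo.sum(axis=1).astype(float)
    return GenotypeSet(dosages=dosages, marker_map=mm,
                       animal_ids=pedigree["animal"].to_numpy())


def subset_genotypes(genotypes: GenotypeSet, animal_ids) -> GenotypeSet:
    """Restrict a GenotypeSet to the given animals (allele freqs recomputed)."""
    pos = {int(a): i for i, a in enumerate(genotypes.animal_ids)}
    idx = np.array([pos[int(a)] for a in animal_ids])
    return GenotypeSet(dosages=genotypes.dosages[idx],
                       marker_map=genotypes.marker_map.copy(),
                       animal_ids=np.asarray(animal_ids))


def _safe_cholesky(M: np.ndarray) -> np.ndarray:
    """Cholesky factor of a PSD matrix; jitter scaled to the diagonal so a
    zero matrix factors to zero (degenerate no-variance simulations)."""
    M = np.atleast_2d(M).astype(float)
    d = np.diag(M)
    if np.all(d == 0):
        return np.zeros_like(M)
    jitter = 1e-10 * np.maximum(d, d[d > 0].min() if (d > 0).any() else 1.0)
    return np.linalg.cholesky(M + np.diag(jitter))


def _drop_polygenic(pedigree: pd.DataFrame, cov: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Polygenic breeding values flowing through the pedigree:
    founders ~ N(0, cov); offspring = parent average + Mendelian N(0, cov/2)."""
    cov = np.atleast_2d(cov)
    k = cov.shape[0]
    L = _safe_cholesky(cov)
    Lm = _safe_cholesky(0.5 * cov)
    n = len(pedigree)
    bv = np.zeros((n, k))
    pos = {int(a): i for i, a in enumerate(pedigree["animal"])}
    sires = pedigree["sire"].to_numpy()
    dams = pedigree["dam"].to_numpy()
    for i in range(n):
        s, d = int(sires[i]), int(dams[i])
        if s == 0 and d == 0:
            bv[i] = L @ rng.standard_normal(k)
        else:
            pa = 0.5 * (bv[pos[s]] if s else 0) + 0.5 * (bv[pos[d]] if d else 0)
            bv[i] = pa + Lm @ rng.standard_normal(k)
    return bv


def _scaled_marker_part(Z, cols, cov, target_var, rng, founder_rows, freqs=None):
    """Gaussian marker effects rescaled so each trait's realized variance
    across founders matches ``target_var`` (correlation structure from cov).

    With ``freqs`` given, allele-substitution effects are standardized by
    1/sqrt(2p(1-p)) so every locus contributes equal expected variance (the
    usual standardized-effects architecture); otherwise effects are iid.
    """
    k = len(target_var)
    d = np.sqrt(np.maximum(np.diag(cov), 1e-30))
    corr = cov / np.outer(d, d)
    Lc = np.linalg.cholesky(corr + 1e-10 * np.eye(k))
    effects = rng.standard_normal((len(cols), k)) @ Lc.T
    if freqs is not None:
        het = 2.0 * freqs[cols] * (1.0 - freqs[cols])
        effects = effects / np.sqrt(np.maximum(het, 1e-6))[:, None]
    score = Z[:, cols] @ effects
    sv = np.var(score[founder_rows], axis=0, ddof=1)
    scale = np.sqrt(np.where(sv > 0, target_var / np.maximum(sv, 1e-30), 0.0))
    return effects * scale


def simulate_breeding_values(
    pedigree: pd.DataFrame,
    genotypes: GenotypeSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    covariance: np.ndarray | None = None,
) -> TruthSet:
    """True breeding values from a whole-genome additive architecture.

    ``n_qtl`` markers from the simulated panel act as large-effect QTL
    contributing ``qtl_variance_fraction`` of each trait's additive variance
    (so the window scan can find them); in the default ``genomic`` mode the
    remainder is spread as small Gaussian effects over every other marker,
    making breeding values a linear function of the dropped genomes —
    Mendelian sampling then arises from recombination, and realized genomic
    relationships carry the full additive signal.  In ``pedigree`` mode the
    background is instead an infinitesimal polygenic term flowing through the
    pedigree (untagged by markers).  Variances are calibrated on founders.
    """
    rng = rng or config.rng()
    cov = np.atleast_2d(covariance if covariance is not None else config.genetic_covariance)
    cov = cov.astype(float)
    k = cov.shape[0]
    target_var = np.diag(cov).astype(float)
    frac = float(config.qtl_variance_fraction)
    n_qtl = min(config.n_qtl, genotypes.n_snp)
    founder_rows = np.flatnonzero(pedigree["generation"].to_numpy() == 0) \
        if "generation" in pedigree.columns else np.arange(len(pedigree))
    Z = genotypes.centered()
    freqs = genotypes.allele_freq
    maf = np.minimum(freqs, 1.0 - freqs)
    eligible = np.flatnonzero(maf >= config.qtl_maf_min)
    if len(eligible) < n_qtl:
        eligible = np.arange(genotypes.n_snp)
    qtl_pos = np.sort(rng.choice(eligible, size=n_qtl, replace=False))
    qtl_effects = _scaled_marker_part(Z, qtl_pos, cov, frac * target_var, rng,
                                      founder_rows, freqs)
    qtl_part = Z[:, qtl_pos] @ qtl_effects
    background_effects = None
    if config.polygenic_mode == "genomic":
        bg_cols = np.setdiff1d(np.arange(genotypes.n_snp), qtl_pos)
        bg_effects = _scaled_marker_part(Z, bg_cols, cov, (1.0 - frac) * target_var,
                                         rng, founder_rows, freqs)
        background = Z[:, bg_cols] @ bg_effects
        background_effects = np.zeros((genotypes.n_snp, k))
        background_effects[bg_cols] = bg_effects
        background_effects[qtl_pos] += qtl_effects
    elif config.polygenic_mode == "pedigree":
        background = _drop_polygenic(pedigree, (1.0 - frac) * cov, rng)
    else:
        raise ValueError(f"unknown polygenic_mode {config.polygenic_mode!r}")
    tbv = background + qtl_part
    tbv = tbv - tbv.mean(axis=0)
    return TruthSet(true_breeding_values=tbv, qtl_positions=qtl_pos,
                    qtl_effects=qtl_effects, polygenic_covariance=(1.0 - frac) * cov,
                    background_effects=background_effects)


def _assign_covariates(pedigree: pd.DataFrame, config: SimulationConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    n = len(pedigree)
    herd = rng.integers(1, config.herds + 1, n)
    year = rng.integers(1, config.years + 1, n)
    season = rng.integers(1, config.seasons + 1, n)  # calendar quarter of calving
    # herds nested within countries
    herd_country = {h: 1 + (h - 1) % config.countries for h in range(1, config.herds + 1)}
    country = np.array([herd_country[h] for h in herd])
    age = rng.normal(26.0, 2.0, n)  # age at first calving, months
    return pd.DataFrame({
        "animal": pedigree["animal"].to_numpy(),
        "herd": herd, "year": year, "season": season,
        "hys": [f"h{h}_y{y}_s{s}" for h, y, s in zip(herd, year, season)],
        "country": country, "age": age, "age_sq": age ** 2,
    })


def _fixed_effect_values(config: SimulationConfig, rng: np.random.Generator):
    hys_levels = {}
    country_eff = rng.normal(0.0, config.country_effect_sd, config.countries)
    return hys_levels, country_eff


def simulate_lactations(
    pedigree: pd.DataFrame,
    genotypes: GenotypeSet,
    truth: TruthSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    phenotyped_ids=None,
):
    """Noisy test-day records from each animal's true MilkBot curve.

    Each phenotyped female gets 1-4 lactations (``parity_distribution``);
    its curve parameters are trait means + true breeding values, plus (for
    animals with repeated lactations) one permanent environmental deviate
    shared across parities.  Herd-year-season, country and age effects shift
    the scale parameter; parity raises the mean curve toward the multiparous
    means.  Daily records are curve value + N(0, residual_sd_milk), with
    negative yields truncated at 0 and counted.

    Returns (records, covariates, n_truncated): records has columns
    (animal, parity, dim, milk_kg); covariates one row per lactation.
    """
    rng = rng or config.rng()
    cov = _assign_covariates(pedigree, config, rng)
    if phenotyped_ids is None:
        phen = pedigree[(pedigree["generation"] > 0) & (pedigree["sex"] == "F")]["animal"]
        phenotyped_ids = phen.to_numpy()
    pos = {int(a): i for i, a in enumerate(pedigree["animal"])}
    covm = cov.set_index("animal")
    _, country_eff = _fixed_effect_values(config, rng)
    hys_eff: dict[str, float] = {}
    Lpe = _safe_cholesky(np.atleast_2d(config.pe_covariance))
    means = np.asarray(config.trait_means, dtype=float)
    n_lact_choices = np.arange(1, len(config.parity_distribution) + 1)
    schedule = np.asarray(config.test_day_schedule, dtype=float)
    rec_rows, cov_rows = [], []
    n_truncated = 0
    for a in phenotyped_ids:
        i = pos[int(a)]
        n_lact = int(rng.choice(n_lact_choices, p=config.parity_distribution))
        pe = Lpe @ rng.standard_normal(4) if n_lact > 1 else np.zeros(4)
        base = covm.loc[int(a)]
        hys = str(base["hys"])
        if hys not in hys_eff:
            hys_eff[hys] = rng.normal(0.0, config.hys_effect_sd)
        for parity in range(1, n_lact + 1):
            params_vec = means + truth.true_breeding_values[i] + pe
            age = float(base["age"]) + 12.0 * (parity - 1)
            a_shift = (hys_eff[hys] + country_eff[int(base["country"]) - 1]
                       + config.age_linear * age + config.age_quadratic * age ** 2)
            pv = params_vec.copy()
            pv[0] = max(pv[0] + a_shift, 0.1)
            pv[1] = max(pv[1], 0.5)
            pv[3] = max(pv[3], 1e-6)
            p = MilkBotParams(pv[0], pv[1], pv[2], pv[3])
            y = evaluate(p, schedule)
            if config.residual_sd_milk > 0:
                y = y + rng.normal(0.0, config.residual_sd_milk, y.size)
            neg = y < 0
            n_truncated += int(neg.sum())
            y = np.where(neg, 0.0, y)
            for t, yy in zip(schedule, y):
                rec_rows.append({"animal": int(a), "parity": parity,
                                 "dim": float(t), "milk_kg": float(yy)})
            cov_rows.append({"animal": int(a), "parity": parity, "hys": hys,
                             "country": int(base["country"]), "age": age,
                             "age_sq": age ** 2})
    return pd.DataFrame(rec_rows), pd.DataFrame(cov_rows), n_truncated


def simulate_single_trait(
    pedigree: pd.DataFrame,
    genotypes: GenotypeSet,
    config: SimulationConfig,
    sigma_a2: float,
    sigma_e2: float,
    mean: float = 0.0,
    n_records_per_animal: int = 1,
    sigma_p2: float = 0.0,
    phenotyped_ids=None,
    rng: np.random.Generator | None = None,
):
    """Phenotypes for one trait directly on the trait scale.

    y = mean + HYS + country + b1*age + b2*age^2 + a + (p) + e with additive
    variance ``sigma_a2`` (QTL + polygenic split per config), permanent
    environmental variance ``sigma_p2`` when records repeat, and residual
    ``sigma_e2``.  Fixed-effect magnitudes scale with the phenotypic SD.
    Returns (phenotypes DataFrame, TruthSet).
    """
    rng = rng or config.rng()
    truth = simulate_breeding_values(pedigree, genotypes, config, rng,
                                     covariance=np.array([[float(sigma_a2)]]))
    tbv = truth.true_breeding_values[:, 0]
    cov = _assign_covariates(pedigree, config, rng)
    if phenotyped_ids is None:
        phenotyped_ids = pedigree[pedigree["generation"] > 0]["animal"].to_numpy()
    pos = {int(a): i for i, a in enumerate(pedigree["animal"])}
    covm = cov.set_index("animal")
    sd_p = np.sqrt(sigma_a2 + sigma_p2 + sigma_e2)
    _, country_eff = _fixed_effect_values(config, rng)
    country_eff = country_eff / max(config.country_effect_sd, 1e-12) * 0.3 * sd_p
    hys_eff: dict[str, float] = {}
    b1 = 0.02 * sd_p
    b2 = -0.0004 * sd_p
    rows = []
    for a in phenotyped_ids:
        i = pos[int(a)]
        base = covm.loc[int(a)]
        hys = str(base["hys"])
        if hys not in hys_eff:
            hys_eff[hys] = rng.normal(0.0, 0.3 * sd_p)
        pdev = rng.normal(0.0, np.sqrt(sigma_p2)) if sigma_p2 > 0 else 0.0
        for _rec in range(n_records_per_animal):
            age = float(base["age"])
            y = (mean + hys_eff[hys] + country_eff[int(base["country"]) - 1]
                 + b1 * age + b2 * age ** 2 + tbv[i] + pdev
                 + rng.normal(0.0, np.sqrt(sigma_e2)))
            rows.append({"animal": int(a), "y": y, "hys": hys,
                         "country": int(base["country"]), "age": age,
                         "age_sq": age ** 2})
    return pd.DataFrame(rows), truth


def simulate_population(config: SimulationConfig):
    """Full bundle: pedigree, genotypes (all animals), truth, test-day records
    and lactation covariates, from one seeded stream."""
    rng = config.rng()
    pedigree = simulate_pedigree(config, rng)
    genotypes = drop_genotypes(pedigree, config, rng)
    truth = simulate_breeding_values(pedigree, genotypes, config, rng)
    records, covariates, n_trunc = simulate_lactations(
        pedigree, genotypes, truth, config, rng)
    return {
        "pedigree": pedigree,
        "genotypes": genotypes,
        "truth": truth,
        "records": records,
        "covariates": covariates,
        "n_truncated": n_trunc,
    }
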