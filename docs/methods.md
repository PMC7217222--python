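# Methods

`lactgwas` implements a weighted single-step GBLUP association workflow for
dairy lactation traits end to end: lactation-curve fitting, relationship
matrices, AI-REML variance components, iterative SNP reweighting with
50-SNP window variance decomposition, LD mapping and positional gene
annotation, driven by a synthetic-data generator with full ground truth.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic populations do and do not show about real data.

## Lactation-curve model

Daily milk yield at `t` days in milk follows the four-parameter MilkBot
curve

    y(t) = a (1 - exp((c - t)/b) / 2) exp(-d t)

with scale `a` (kg/day, theoretical maximum daily yield), ramp `b` (days,
speed of the early rise), offset `c` (days, lag between parturition and the
onset of lactation) and decay `d` (1/day, senescence rate; persistency is
low decay). Derived traits used as phenotypes:

- **M305**, cumulative yield to day 305, closed form
  `(a - a e^{-305 d})/d + a b e^{c/b}(e^{-305(1/b + d)} - 1)/(2 + 2bd)`;
  verified against adaptive quadrature to <1e-6 relative error across the
  parameter space in the test suite.
- **t_peak** `= -b ln(2db/(db+1)) + c`, the unique stationary point of
  `y`; it exists only when `db < 1`, otherwise the curve declines from
  onset and the fit is flagged. The expression is validated against a
  numeric argmax oracle rather than trusted as printed, because published
  renderings of this formula are easily garbled.
- **peak yield** `= y(t_peak)`.

Decay is stored in natural 1/day units everywhere; the conventional "decay
x 1000" appears only in formatted reports.

Fitting is bounded trust-region least squares with an analytic Jacobian.
Starting values: `a0 = 1.05 max(y)`, `b0 = 20 d`, `c0 = 0`, `d0` from the
log-linear decline between the observed peak and the last record; up to
three jittered restarts on failure. The (b, c) pair is weakly identified
from sparse test days, which is visible in the worked examples: scale and
decay recover well from 11 monthly records at 1.5 kg noise, ramp and
offset less so. Lactations need at least 5 test days spanning 100 DIM
(four free parameters), otherwise they are excluded with a logged reason.

## Relationship matrices

- `A`: pedigree numerator relationship matrix by the tabular method
  (diagonal `1 + F`), checked against an independent recursive
  implementation.
- `G = Z D Z' / Σ 2 p_i (1 - p_i)` with `Z` the allele-frequency-centred
  dosages and `D` per-SNP weights (identity unless reweighted). Allele
  frequencies are computed from the genotyped sample — the base-population
  frequencies of real data are unknowable, and observed-sample centring is
  the common single-step practice.
- Tuning: solve the 2x2 system so `alpha + beta G` matches the mean
  diagonal and mean off-diagonal of `A22`, then blend
  `G* = 0.95 G_tuned + 0.05 A22` by default. Blending guards against a
  singular `G` (duplicate genotypes, fewer SNP than animals); the fraction
  is configurable down to 0. An ill-conditioned `G*` is rejected with a
  pointer to increase the blend.
- `H^-1 = A^-1 + [[0,0],[0, G*^-1 - A22^-1]]`; equals `A^-1` exactly when
  no animals are genotyped or when `G* = A22`.

All algebra is dense; the intended scale is up to roughly 20,000 animals
on one workstation. SNP with MAF < 5% are removed before any genomic
computation.

## Variance components (AI-REML)

Single-trait animal model for once-recorded (primiparous) animals:

    y = mu + HYS + country + b1 age + b2 age^2 + a + e,
    a ~ N(0, sigma_a^2 H), e ~ N(0, sigma_e^2 I)

For repeated-records (multiparous) data the model adds the fixed effect of
parity and an identity-structured permanent environmental term `p`.
Heritability `h2 = sigma_a^2 / total`; repeatability
`r = (sigma_a^2 + sigma_p^2) / total`.

Estimation maximizes the restricted likelihood on the record-level
covariance `V = Σ theta_i K_i` (with `K_a = Z H Z'`, `K_p = W W'`,
`K_e = I`): average-information updates with step-halving so the accepted
log-likelihood never decreases, and a ratio-type EM-style fallback when an
AI step cannot be made to improve. Variances are floored at 1e-8 of the
phenotypic variance (AI steps can propose negative components).
Convergence: relative parameter change < 1e-8 or a stalled likelihood with
a scaled gradient < 1e-6, max 200 iterations; in practice 5-10 AI
iterations suffice. Standard errors come from the inverse AI matrix.
Fixed-effect design matrices are dummy-coded and pruned to full column
rank by pivoted QR, which transparently handles nested effects (herds
within countries confound HYS with country dummies).

BLUP solutions and prediction error variances are extracted from
Henderson's mixed-model equations with `H^-1 (sigma_e^2/sigma_a^2)` on the
additive block, inverting the coefficient matrix directly — exact PEV at
desk scale. The bivariate extension stacks two traits, parameterizes 2x2
genetic and residual covariance matrices (residual covariance only between
records of the same animal), and projects each matrix to the PSD cone when
an update leaves it. It exists for genetic-correlation recovery; the
pipeline's headline path is single-trait.

GEBV accuracy is reported as `sqrt(max(0, 1 - PEV/sigma_a^2))` (the
square-root convention), with the unrooted reliability `1 - PEV/sigma_a^2`
kept alongside, because published accuracy formulas appear in both forms.

## Weighted single-step GWAS

The 6-step loop: start `D = I`; build `G` with current weights, tune,
blend; solve ssGBLUP for all animals; back-solve SNP effects
`u_hat = lambda D Z' G*^-1 a_hat_g` with
`lambda = 1/Σ 2 p_i (1 - p_i)`; refresh `d_i = u_hat_i^2 2 p_i (1 - p_i)`;
normalize `Σ d_i = M`; repeat. All iterations are retained; the reporting
default is iteration 2 (the most accurate evaluation in this scheme —
later iterations overfit large-effect regions), configurable.

Windows are non-overlapping runs of 50 consecutive SNP within a
chromosome (tiling, not sliding: tiling keeps the decomposition
well-defined; the final window on a chromosome may be shorter). Per
window, the genetic score `Σ Z_j u_hat_j` is computed for every genotyped
animal and its sample variance (denominator n-1), divided by the additive
variance and x100, is the percentage reported (`pct_variance`). Windows in
mutual LD have correlated scores, so these percentages do not sum to the
variance of the total genomic score; the companion `pct_covariance`
column (covariance of window score with total score, same scaling)
partitions the total exactly and is what the partition test asserts.
Windows above 0.50% are candidate QTL regions.

## LD and blocks

`r^2` is the squared Pearson correlation of dosage vectors (genotypic LD —
the pipeline has no phasing stage), computed for same-chromosome pairs
within a 200-kb sliding window. Blocks are maximal runs of physically
adjacent SNP whose every adjacent pair has `r^2 >=` threshold (default
0.7), reported when >= 2 SNP. Haplotype-based callers (e.g.
confidence-interval methods) need phased data and are out of scope;
adjacent-pair runs are the simplest well-defined genotypic analogue.

## Annotation and enrichment

Candidate windows are intersected with a local GFF3/BED annotation
(1-based inclusive input, half-open internally; >= 1 bp overlap counts;
strand ignored). Enrichment of the candidate gene list in GMT gene sets is
the one-sided hypergeometric upper tail against an explicit background
universe — the background is a required input because any implicit default
(whole genome? array genes?) changes the answer — with Benjamini-Hochberg
adjustment and a reporting filter of >= 4 shared genes. Because the
hypergeometric tail is discrete, the null p-values are super-uniform
(conservative), not exactly uniform; the test suite asserts
super-uniformity and bounds the distance from uniformity by the support's
discreteness.

## Synthetic populations

The generator emulates a multi-country milk-recording scheme: discrete
generations from a founder cohort, random mating; herd-year-season
(season = calendar quarter of calving, the standard dairy convention,
4 levels), country (herds nested within countries) and quadratic
age-at-calving effects; 1-4 lactations per cow with one permanent
environmental deviate shared across parities; monthly test days (DIM 5,
35, ..., 305) with 2.5 kg/day residual noise and negative yields truncated
at 0 with a count. Environmental effects act on the scale parameter `a`;
both `y(t)` and M305 are linear in `a`, so they are exactly additive fixed
effects on yield traits. Curve-parameter means and genetic/permanent
environmental variances default to published primiparous Holstein values
(scale 35.57 kg/day, ramp 30.60 d, decay 1.42e-3 /day; the offset is a
nuisance parameter simulated with small variance around 0).

Genetics: founder haplotypes come from a per-chromosome neutral coalescent
(msprime) so the founder generation carries realistically decaying LD;
segregating sites are filtered to the configured MAF range and thinned to
the marker count. Offspring receive recombinant gametes (Haldane map,
1 cM/Mb). The additive architecture is whole-genome by default: `n_qtl`
large-effect QTL drawn from markers with MAF >= 0.2 plus standardized
small effects (per-locus variance equalized by `1/sqrt(2pq)`) on every
other marker, calibrated on founders so realized variances match the
configured covariance matrix. QTL are restricted to common variants
because GBLUP-backsolved effects cannot localize rare large-effect
variants — a known property of the method, visible in the package's own
power experiments. A pedigree-flow infinitesimal background
(`polygenic_mode="pedigree"`) is available but makes 70%+ of the genetic
variance invisible to the markers, which is the wrong model for testing
genomic machinery.

**Genome scale-down.** The default panel is 2,000 SNP on five 1.65-Mb
chromosomes (~4 kb spacing, so a 50-SNP window spans ~200 kb, matching the
real-data window scale). A compressed genome cannot preserve both
within-window and between-window LD simultaneously: the ancestral
effective size defaults to 1,000, which places the LD decay length at the
window scale. The planted-QTL power study therefore uses
linkage-equilibrium founders (pedigree LD only); with coalescent founders
on the mini-genome, founder LD between windows is artificially long-range
relative to window size and delocalizes the QTL — an artifact of the
scale-down, not of the method.

**What passing tests show.** Recovery results on these populations
demonstrate the estimators' correctness under the generating model
(additive biallelic genetics, random mating, no selection, no genotyping
error or imputation, complete genotypes, homogeneous residuals). They do
not establish performance under selection-driven LD, rare-variant
architectures, genotyping error, or the pedigree-depth and family
structures of real recording schemes.

## Study problem sizes

Chosen for single-workstation turnaround: heritability recovery simulates
~1,500 phenotyped animals (300 founders + 2 generations), 800 genotyped at
2,000 SNP, 5 replicates — the mean estimate lands within ~0.02 of the
simulated truth; the QTL power study uses ~1,300 phenotyped/genotyped
animals with one QTL at 10% of the additive variance, 10 replicates;
bivariate correlation recovery runs at ~480 recorded animals over 5
replicates with a +-0.1 band. Unit tests use populations of a few hundred.

## Known limitations

- Dense linear algebra throughout: no sparse `A^-1`, no APY; practical cap
  around 2e4 animals.
- No metafounders or unknown-parent groups; missing dosages are
  mean-imputed (2p) with a logged count, imputation proper is out of scope.
- The bivariate REML is a correlation-recovery tool, not a general
  multi-trait engine (max 2 traits, PSD projection rather than a
  parameterized Cholesky).
- Enrichment models an adjusted p-value as BH over hypergeometric tails;
  rank-combined scores used by some web services are not reproduced.
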