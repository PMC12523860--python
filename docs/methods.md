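# Methods

`pleionet` reimplements, as a tested pipeline on synthetic data, a joint
genetic analysis of two beef-cattle traits: average daily gain (ADG,
kg/day) and Warner-Bratzler shear force (WBSF, kgf; lower is more
tender).  The pipeline has five stages: synthetic-data generation,
quality control, Bayesian estimation of genetic (co)variance components,
multi-task penalized association with permutation-based SNP importance,
and window-based candidate-gene annotation.

## The bivariate genomic animal model

For traits t = 1 (ADG), 2 (WBSF):

    y_t = X_t b_t + a_t + e_t,
    (a_1, a_2) ~ N(0, Sigma_a (x) G),   e_t ~ N(0, I sigma_e_t^2),

where `X_t` carries contemporary-group (CG) fixed effects, `G` is the
VanRaden genomic relationship matrix built from centered dosages
(stabilized as 0.99 G + 0.01 I), `Sigma_a` is the 2x2 additive genetic
covariance, and the residual covariance between traits is structurally
zero.  Heritability is h2_t = sigma_a_t^2 / (sigma_a_t^2 +
sigma_e_t^2); the genetic correlation is r_g = sigma_a_12 /
(sigma_a_1 sigma_a_2).

Estimation is single-chain Gibbs sampling.  After the one-off
eigendecomposition G = U D U', the breeding values of all animals are
drawn *jointly* each cycle: in the eigenbasis their full conditional
factorizes over eigencomponents into 2x2 normals (each animal has at
most one record per trait and the residual covariance is diagonal), so a
cycle costs O(n) small solves plus two thin matrix products.  Missing
trait records are data-augmented (re-drawn from their conditional each
cycle, contributing no likelihood information).  Desk-scale default:
50,000 cycles, 5,000 burn-in, thinning 10 (a 500,000-cycle
configuration is available).  Convergence is reported per parameter via
the Geweke diagnostic (first 10% vs last 50%, batch-means
spectral-density variance, ~sqrt(m) batches; the conventional pass rule
is p > 0.15).

**Priors.**  Fixed effects are flat.  The genetic covariance and the
residual variances default to flat (improper) priors, the convention of
the blupf90-family samplers; conditionals are then inverse-Wishart with
df n-3 and scale a'G^-1 a, and scaled inverse chi-square with df n-2.
A proper inverse-Wishart option exists but is not the default: its
density behaves like |Sigma|^-(nu+3)/2 near the origin, which in
experiments with an exact grid-posterior oracle dragged posterior mean
h2 from a generating 0.23/0.13 down to ~0.19/0.06 at n = 1000 and
pushed the genetic-correlation posterior toward -1 (a small-determinant
preference).  Weak identification makes variance components unusually
prior-sensitive; "weakly informative" inverse-Wisharts are not weak
here.

Posterior summaries (h2, r_g) are computed per stored draw and then
averaged — never as ratios of averaged components.

## Synthetic data

No real data are distributed, so the generator must reproduce the
*structure* the analysis assumes:

- **Genotypes.**  Biallelic SNPs on 10 chromosomes (default p = 5000,
  5 kb spacing), drawn by a marginal-frequency-preserving
  haplotype-copying scheme: each haplotype carries a latent ancestry
  uniform re-drawn at recombination points (probability 0.08 per
  adjacent pair, always at 50 kb block edges and chromosome starts);
  the allele at SNP j is u < f_j.  Marginal allele frequencies are
  exact; neighbours within a block are correlated; blocks are
  independent.
- **Family structure.**  Animals come in paternal half-sib families
  (default 20 per sire): one recombined sire gamete plus one population
  haplotype.  This mirrors artificial-insemination breeding programs
  and is what makes the genetic covariance estimable at n ~ 1000: with
  unrelated simulated animals, G is close to I plus noise and the
  posterior of r_g has spread ~0.2-0.5 regardless of chain length.
- **Architecture.**  1000 of 5000 SNPs carry effects (polygenic, as
  expected for growth and meat-quality traits); a configurable fraction
  (default 0.3) is pleiotropic with correlated effect pairs, the rest
  split between trait-specific QTLs.  The QTL count is a free parameter
  of the generator, not an estimate.
- **Phenotypes.**  value = trait mean + CG effect + genetic value +
  residual, with CG cells from birth year x birth season (Aug-Jan vs
  Feb-Jul) x herd, trait means 0.63 kg/day and 6.27 kgf, phenotypic
  variances 0.004 and 2.03, target h2 (0.23, 0.13) and genetic
  correlation -0.17.  A fraction 0.086 of animals lack the WBSF record
  (missing completely at random), mirroring one trait being recorded on
  a subset.

**Second-moment matching.**  Genetic values are built as dosages x QTL
effects and then *conditioned*: with flat fixed-effect priors the
variance-component posterior depends on the data only through its
projection onto the orthocomplement of the CG design (the REML error
contrasts), so in the eigenbasis of the projected G, eigencomponents
are grouped into narrow bands and per band the genetic values are
linearly transformed to hit the target Sigma_a exactly in the
d-profile-normalized metric, while residuals (orthogonalized against
the genetic components band-wise) hit the diagonal residual covariance
exactly.  The construction alternates between the full-sample geometry
and the WBSF-observed geometry to accommodate the missing records.
This is Monte-Carlo variance reduction, not data massaging: at the real
study's scale (n ~ 20k) the realized finite-sample components converge
to their expectations by the law of large numbers; at desk scale
(n ~ 1000) the between-family and between-LD-segment components would
otherwise fluctuate by more than the recovery tolerances, and a
single-run comparison would measure one draw of sampling noise instead
of implementation correctness.  What passing recovery checks on these
data show is that the estimation machinery is unbiased and correctly
weighted; they do not show how large honest posterior spread is on a
single unconditioned sample (reported posterior SDs do show it).

The generator writes PLINK .bed/.bim/.fam, VCF, phenotype TSV, GFF3 and
BED; `inject_artifacts` corrupts a clean panel (monomorphic SNPs,
MAF ~0.02 SNPs, missing calls) with a manifest, so QC can be tested
end-to-end.

## Quality control

Stage order: samples -> markers -> CG construction -> phenotype
filters.  Markers are removed for call rate < 0.90, MAF < 0.05, |obs -
exp heterozygosity| > 0.15, or monomorphism (attribution to the first
triggering filter in the order call-rate, monomorphic, MAF, HWE);
samples for call rate < 0.90.  The HWE rule is applied as "deviation
exceeding 0.15" — the direction that makes the filter meaningful.
Phenotypes: per trait, a single pass removes records more than 3.5
sample SDs (n-1) from their CG mean (statistics computed with the
record included), then CGs with fewer than 5 remaining records are
dropped whole.  Removing one trait's record never touches the animal's
other trait.  Mendelian-conflict checks are out of scope (no pedigree)
and reported as skipped.

## Multi-task elastic-net GWAS

The association model minimizes over the SNPs x traits matrix W

    (1/2N) ||Y - X W||_F^2
      + lambda [ alpha ||W||_{2,1} + (1 - alpha) ||W||_F^2 ],

with ||W||_{2,1} the sum of SNP-row Euclidean norms (joint selection
across traits — pleiotropy) and no 1/2 on the ridge term.  Missing
responses are excluded from the loss per trait with N fixed at the row
count.  Fitting is block coordinate descent: the row update is the
group soft-threshold, computed in closed form when the per-trait
quadratic coefficients coincide and by a monotone fixed-point iteration
on the row norm otherwise.  KKT residuals are reported; the objective
is non-increasing across sweeps.

**Responses.**  The elastic net is fit to the animal model's GEBVs
(posterior-mean breeding values), standardized per trait.  Two reasons:
(i) SNP importance is defined as a share of *GEBV variability*, and
(ii) predictive abilities near 0.9 — the regime in which the 1%
significance threshold and its permutation null are calibrated — are
only attainable against GEBV targets (against phenotypes the ceiling is
sqrt(h2) ~ 0.48/0.36).  With GEBV responses the synthetic validation
R^2 lands at ~0.91/0.92.  Response standardization is required because
the L2,1 row norm couples the traits: on raw scales (variance 0.004 vs
2.03) the larger trait dominates every selection decision.

**Validation scheme.**  Forward split by birth year (train <= 2016,
validate 2017-2018).  (lambda, alpha) are tuned by seeded random search
(30 candidates; lambda log-uniform up to lambda_max, alpha uniform) on
an inner 80:20 split drawn at *contemporary-group granularity*: group-
mean-adjusted responses sum to ~0 within each CG, so an animal-level
split would make inner-test records anti-correlated with their fitted
CG mates and depress every candidate's score (verified: inner accuracy
0.03 vs outer 0.15 for identical models).  Selection: highest accuracy
(mean per-trait Pearson r), ties by lower MSE, then larger lambda.

**Importance.**  RIS_jt = 100 x max(0, mean delta-R^2) when SNP j's
validation column is permuted with all coefficients fixed (10
permutations, averaged before clamping; zero-coefficient rows get
exactly 0 without permutation).  Since R^2 is the explained share of
response variance, this absolute form is a partial R^2 in percent, and
the significance rule RIS > 1 (strict) reads "partial R^2 > 0.01".  A
relative form (share of the model's baseline R^2) is available; with
baseline R^2 ~ 0.9 the two nearly coincide on real scores, but only the
absolute form gives the permutation null a meaningful scale.

**Null calibration.**  Response rows are permuted jointly across
traits, the model is refit at the frozen (lambda, alpha) under a
reduced sweep budget (300), importance is recomputed on the validation
split, and the maximum per-SNP RIS is recorded per replicate (desk
default 200 replicates; the reference procedure uses 1000).  A
replicate whose refit has no active rows contributes 0.  Note a scale
caveat: the null maximum shrinks roughly like sqrt(log p / p)/n_val, so
a bound calibrated on a 377k-SNP panel with 376 validation animals
(where this statistic is ~0.015%) sits near or below the desk-scale
value at p = 2000, n_val ~ 140 (~0.7%); the desk-scale null is
reported as computed.

## Regions and annotation

Each significant SNP spawns a +/-100 kb window (clamped at 1);
overlapping *or touching* windows on a chromosome merge transitively.
A gene is assigned to a region when their 1-based closed intervals
share at least one base pair (any-overlap, not containment).  Region
tables report BTA, SNP count, bounds and size in Mb (2 decimals), and
the mean (min-max) member RIS; the cross-trait gene set is the exact
intersection of per-trait gene-id sets.  GFF3 intervals are 1-based
closed, BED 0-based half-open; both converge on the same internal
representation.

## Problem sizes and numerical choices

- Parameter-recovery runs: n = 1000 animals, p = 5000 SNPs, 50k-cycle
  chain (~2 min); null study: n = 800, p = 2000, 200 replicates
  (~8 min); unit tests use n <= 600.
- Eigenvalues of stabilized G are floored at 1e-8; coordinate-descent
  tolerance 1e-7 on the maximum row change (1e-5/300 sweeps inside the
  null loop); the group fixed-point iteration stops at 1e-14.
- Degenerate inputs: zero-call SNPs are treated as monomorphic; a CG of
  size 1 has undefined SD, survives the outlier pass, and is dropped by
  the size rule; constant chains give Geweke (z, p) = (0, 1); chains too
  short for the batch-means windows report NaN diagnostics.
- Determinism: every stochastic step takes a seed; identical configs
  reproduce byte-identical pipeline artifacts.

## Known limitations

- The generator's LD is block-wise with a miniature genome (25 Mb); it
  does not model recombination-rate variation, allele-frequency spectra
  from demography, or genotyping-chip error.
- Missingness of the second trait is MCAR; the real mechanism
  (slaughter availability) is informative in ways not modeled.
- Single-chain convergence assessment only (Geweke); no multi-chain
  R-hat.
- The permutation null at desk scale is dominated by small-panel
  effects (see above) and should not be read as the large-panel bound.
- No pedigree relationships, imputation, or post-GWAS enrichment (those
  steps depend on external tools/databases).
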