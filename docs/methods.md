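# Methods

## The problem

Polyploid microsatellite data are *dosage-ambiguous*: electrophoresis shows
which fragment lengths an individual carries at a locus (1 up to its ploidy
in distinct alleles) but not the copy number of each. Classical genotype-
based estimators (heterozygosity, F-statistics) are therefore undefined,
and every statistic in this package is built on **presence weighting**:
each distinct allele in an individual's set contributes exactly one
observation. This is the simplest documented estimator for such data and
is applied uniformly — to allele frequencies, H_E, PIC, and the allele-size
variances behind R_ST — so that all marker-side quantities share one
sampling model.

Consequences worth knowing:

- "Observed heterozygosity" H_O is phenotypic: the fraction of individuals
  showing ≥ 2 distinct alleles at a locus. It is comparable across
  populations of equal ploidy but mechanically increases with ploidy.
- Deduplication biases allele-size variances slightly upward within
  populations (identical draws collapse to one observation, and collisions
  concentrate near the population mean). In simulations with a
  between:within allele-size variance ratio of 1:2 the recovered R_ST
  averages ≈ 0.30 rather than the ratio-implied 1/3; this is a property of
  dosage-ambiguous data, not an estimator defect, and stays well inside the
  ±0.05 recovery band used in the tests.

## Trait model and variance decomposition

Traits are modelled by the fully nested random-effects model

    Y_ijkl = μ + region_i + population_j(i) + haplotype_k(ij) + plant_l(ijk) [+ ε]

All effects are independent zero-mean normals. The haplotype term is
treated as a *random* component by default even though one may equally
regard lineage as fixed: the reference decomposition reports a haplotype
variance, and in wild designs each population typically carries a single
lineage, making the term confounded with population anyway. The estimator
detects this confounding (one haplotype label per population), fixes the
component at 0 and flags it; the haplotype variance is then absorbed by the
population component, which is the correct pooling for P_ST.

**Estimation.** Default is REML via a mixed linear model with variance
components for region, population-in-region and haplotype-in-population
(one grouping block; nesting enforced by concatenated labels). A
Henderson-I / nested-ANOVA moment estimator is provided as a cross-check
for balanced designs only — on balanced data with an interior optimum the
two agree to well under 1%, and the restriction keeps the moment formulas
exact. Negative estimates are truncated at zero and flagged. Factors with
a single level are fixed at 0 and flagged.

**Replicates and the residual.** When plants are measured once, the plant
effect and the measurement error are not separable: the model's residual
variance is reported as `v_plant` and `v_residual` is 0, flagged
`confounded_with_plant`. When the table contains replicate rows per plant,
the residual is estimated as the pooled within-plant variance and
subtracted (divided by the replicate count) from the plant-mean-level
residual to give `v_plant`. The upper levels are always fitted on plant
means, which is exact for balanced replication and keeps the mixed-model
design small.

**P_ST** = V_AP / (V_AP + 2·V_WP) takes V_AP from the population component
and V_WP from the plant component — the among-plant, within-population
variance, *not* the replicate-level residual. This choice reproduces the
reference decomposition's printed P_ST for six of seven traits exactly at
two decimals. The implicit assumptions of P_ST as a Q_ST surrogate apply:
all among-population variance is treated as additive-genetic, so plastic
responses to site differences inflate it.

**h²** = v_plant / total variance. Two anomalies in the reference table are
documented rather than matched: its plant-height h² (0.094) is not
reproducible from its printed column by this formula (which gives ≈ 0.620),
and its leaf-width P_ST (0.39) would require the plant component, printed
as 0, to be replaced by the haplotype component. The package computes the
formulas as defined.

**Local adaptation screen.** Traits with h² ≥ 0.25 (configurable) are
flagged as local-adaptation candidates. The threshold was calibrated once
against the qualitative split in the reference analysis (moderately
heritable traits ≈ 0.28–0.69 vs. weakly heritable ≈ 0–0.18) and is a
screening device, not a test.

## R_ST

Allele sizes are converted to repeat units; per locus, S̄ is the total
allele-size variance (unbiased, over presence-weighted observations) and
S_W the (n−1)-weighted mean within-group variance. Loci are combined by
observation-count weighting of both numerator terms, and
R_ST = (S̄ − S_W)/S̄, clipped to [0, 1]. This is the direct
variance-partition form; no permutation machinery is attached, but a
delete-one-locus jackknife standard error is reported. Pairwise R_ST is
the same computation restricted to group pairs. R_ST is invariant under
global allele-size translation and consistent repeat-unit rescaling
(tested properties).

**Contrast.** Each trait's P_ST is compared with overall R_ST under a
tolerance band (default ±0.03): above → divergent selection, below →
uniform selection, inside → drift-consistent. The band width is the
package's reading of the qualitative language "comparable/exceeded" used in
field studies; it is configurable and should be widened when component
standard errors are large.

## Distances

- **Bruvo**: per-allele distance 1 − 2^(−|Δ|/repeat unit); equal-size sets
  matched by minimum-cost perfect matching (Hungarian algorithm); unequal
  sizes handled by averaging the *genome addition* model (pad the smaller
  set from its own alleles) and the *genome loss* model (pad from the
  larger set's alleles), each averaged over every possible padding
  (weighted enumeration of padding multisets — equivalent to, and cheaper
  than, enumerating ordered paddings). Which model the original software
  applied is rarely recorded; the symmetric average is the documented
  default here, and an exhaustive permutation oracle pins the
  implementation for all set pairs of size ≤ 4. Sets are capped at 8
  alleles, keeping enumeration ≤ C(15,7) matchings per pair; a
  translation-invariance cache makes full 500-individual matrices cheap.
- **Nei–Li / GS**: band-sharing on pooled (locus, allele) presence sets;
  GD = 1 − GS identically. The dimensionally inconsistent printed form of
  the GD formula ("1 − (2N_xy/N_x + N_y)") is read in the standard Nei–Li
  way, 1 − 2N_xy/(N_x + N_y).
- **Phenotype**: replicates averaged per plant, traits z-scored over all
  plants, population means on z-scores, Euclidean distance. Zero-variance
  traits are dropped with a warning.
- **Geographic**: haversine with Earth radius 6371.0088 km.
- Population-level genetic distance for trees is the mean inter-individual
  Bruvo distance between populations (mean linkage), recorded in output
  metadata, since aggregation conventions differ across software.

## Ordination, trees, clustering, screening

- **PCoA**: classical scaling of −D²/2 double-centered; negative
  eigenvalues are dropped and their count/magnitude reported (no
  Cailliez/Lingoes correction — Bruvo matrices at this scale are
  near-Euclidean).
- **Neighbor joining**: Saitou–Nei with the Studier–Keppler Q-criterion.
  Two behaviours that reference tools leave implicit are fixed here: Q ties
  break toward the lexicographically smallest pair of (sorted) cluster leaf
  sets, and negative branch lengths are clamped to 0 with the deficit moved
  to the sister branch. Verified to recover random additive 4–8-taxon
  matrices to 1e−9.
- **Hierarchical clustering**: average linkage on the standardized
  phenotype matrix; node support = % of trait-resampled bootstrap
  replicates containing the node's population set. With only 7 traits the
  bootstrap is coarse (support granularity ≈ 1/7 of resampling space);
  multiscale bootstrap refinements are deliberately out of scope.
- **PCA**: eigendecomposition of the trait correlation matrix on plant
  means; loadings unit-norm, signs fixed so each component's largest
  loading is negative (cosmetic orientation only).
- **Bimodality**: 1- vs 2-component Gaussian mixture compared by BIC;
  "bimodal" needs a BIC margin > 10 *and* both weights ≥ 0.1. A mixture
  criterion was chosen over a dip test because it yields an effect-size-like
  statistic (the BIC difference) and a defined decision rule where the
  original assessment was visual. Calibration: N(0,1) samples of n = 500
  pass as unimodal ≥ 95% of seeds; an equal mixture of N(0,1) and N(6,1) is
  flagged essentially always.

## Mantel test

Pearson correlation of upper-triangle entries; the null permutes rows and
columns of the second matrix jointly; p = (1 + #extreme)/(1 + n_perm)
(add-one correction, so p > 0 always), two-sided by default with one-sided
options. Default 10,000 permutations. The genetic covariate in the
pipeline is pairwise population R_ST (a linearized R_ST/(1−R_ST) transform
is available), the geographic covariate haversine km. Type-I error at
α = 0.05 is calibrated to [0.03, 0.07] over 1000 null pairs in the tests.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical skeleton* of the field study:
20 populations × 25 individuals × 9 dinucleotide loci with the published
fragment-size ranges; ploidy caps of 6 / 4 / 2 distinct alleles for the
Kashmir-invasive, Quebec-invasive and Quebec-native groups; allele sizes on
the repeat lattice with a latent population mean (between-population sd
0.75 repeat units) and individual spread (within sd 1.0) — a regime giving
R_ST ≈ 0.34 and per-population allele counts of ~2–6, matching the scale of
the reported diversity tables; a 2% lattice-slip rate adds rare stepwise
mutations. Phenotypes default to the published variance components with
grand means near the reported population means; the design is a balanced
2 regions × 8 populations × 25 plants with one haplotype per population
and one measurement per plant (replicates configurable).

Not emulated: coalescent ancestry and shared drift between groups (group
pairs have no extra divergence beyond their populations, so group-level
R_ST in simulated data is near zero even when population-level R_ST is
high), linkage between loci, null alleles and scoring error, clonal
structure, unbalanced field designs, and spatial autocorrelation of
population means (so simulated isolation-by-distance is null unless
constructed). Passing tests on this generator therefore demonstrate
estimator correctness under the stated model, not robustness to those
real-data features.

## Numerical choices

- Variance components truncated at 0 with flags; REML convergence warnings
  suppressed and the boundary handled by truncation.
- Duncan's multiple range test: studentized-range quantiles at protection
  level 1 − (1−α)^(p−1), pooled within-population mean square, harmonic
  mean group size for unbalanced data; the letter display marks maximal
  homogeneous ranges found by the standard outside-in probe. Zero pooled
  variance ⇒ only exactly equal means share a letter.
- Fisher LD screen binarizes each locus by presence of its most common
  allele (ties toward the smaller fragment, for determinism); degenerate
  margins return p = 1 with a warning.
- Rarefied allelic richness uses hypergeometric expectation in log-gamma
  space; the default rarefaction depth is the smallest population × locus
  observation count.
- All stochastic code takes explicit integer seeds through
  `numpy.random.default_rng`; pipelines derive stage seeds as fixed offsets
  of the run seed.

## Problem sizes in tests

The test suite runs the full statistical checks at reduced but sufficient
sizes chosen for tight Monte-Carlo bounds at interactive runtimes: 20
replicates for the P_ST / h² / R_ST recovery checks, 1000 null pairs × 99
permutations for Mantel calibration, 100 seeds × n = 500 for the
bimodality screen, and 8-individual populations for the full-design shape
checks.

## Known limitations

- Presence weighting is one of several dosage-ambiguity conventions
  (others: de-silva, random-subsampling); results are comparable only
  across analyses using the same convention.
- P_ST inherits the usual caveat that plasticity inflates apparent
  differentiation; no common-garden correction is attempted.
- R_ST standard errors come from a locus jackknife; no permutation p-value
  or Q_ST–F_ST-style significance test is provided.
- The chloroplast-vs-nuclear nomenclature of the source marker set is left
  unresolved: loci are treated as codominant nuclear-style markers with
  ambiguous dosage, which is the only reading consistent with reporting
  heterozygosities and per-individual allele counts above 2.
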