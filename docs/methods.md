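# Methods

`saltspec` implements the statistical workflow used to screen wheat genotypes
for salt tolerance by combining canopy hyperspectral reflectance, destructive
morpho-physiological traits, and binary SSR marker panels from a two-season
randomized complete block (RCBD) field trial. This note documents the models,
the defaults and why they were chosen, the numerical decisions, and what the
synthetic trial generator does and does not emulate.

## Trial model and genetic parameters

The trial is a balanced RCBD: `g` genotypes x `y` seasons x `r` replicates
(defaults 24 x 2 x 3), season treated as fixed, genotype as random (required
for broad-sense heritability to be defined), replication nested in season.
The combined analysis of variance decomposes each trait or index as

    y_ijk = mu + S_j + B_k(j) + G_i + GS_ij + e_ijk

with strata S, R(S), G, SxG, error and degrees of freedom
`y-1, y(r-1), g-1, (y-1)(g-1), remainder` (1, 4, 23, 23, 92 at the default
layout). Because balance is enforced, sums of squares are computed in closed
form from cell means; the decomposition is checked against
`statsmodels.anova_lm` in the test suite. All F ratios are against the pooled
error mean square, matching how such trials are conventionally reported.

Variance components solve the expected mean squares of this model:

    var_g  = (MS_G - MS_GxS) / (r y)
    var_gy = (MS_GxS - MS_e) / r
    var_e  = MS_e

Negative estimates are clipped to zero and flagged (`truncated`). The
phenotypic variance is defined on a genotype-mean basis,
`var_p = var_g + var_gy/y + var_e/(y r)`, which is the denominator of

    h2 = var_g / var_p .

A historically common verbal shortcut, `var_g = (MS_G - MS_e)/r` with
`var_p = var_g + MS_e`, ignores the interaction stratum; it is available via
`variance_components(..., method="single_stratum")` for comparison but is not
the default because it is inconsistent with the heritability denominator
above and breaks the identity `h2 = (GCV/PCV)^2`.

Coefficients of variation are `GCV = 100*sqrt(var_g)/mean` and
`PCV = 100*sqrt(var_p)/mean`, *inheriting the sign of the mean*: several
water indices (NWI, NDMI, DMCI) have negative means, and the signed
convention is the only one under which published tables of this kind show
negative CV and gain entries. Genetic advance under truncation selection is
`GA = k h2 sigma_p` with the standardized selection differential
`k = phi(z_p)/p` (2.06 at p = 0.05), and genetic gain `GG = 100*GA/mean`,
equivalently `GG = k h2 PCV`. These definitions satisfy two internal
identities used as acceptance checks: `h2 = (GCV/PCV)^2` exactly, and
`GG = k h2 PCV` exactly.

Mean separation uses Tukey's HSD: `HSD = q(1-alpha; g, df_e) sqrt(MSE/n)`
with the studentized-range quantile from scipy. Because a single threshold
makes each genotype's non-significance set an interval of the
descending-sorted means, the compact letter display reduces to assigning one
letter per maximal such interval (the insert-and-absorb result); this is
verified against exhaustive pairwise q-tests.

## Spectral indices

Fourteen indices are registered — seven vegetation (BNDVI, GNDVI, RNDVI,
Chl_red-edge, EVI, MTVI, OSAVI) and seven water (RWI, NWI, NDWI, NDMI, DMCI,
NMDI, SWSI) — each simple band arithmetic on raw reflectance. Band lookup is
nearest-neighbour with a 1 nm tolerance (ties to the lower wavelength) and no
interpolation, because the field instrument already delivers a 1 nm grid;
resampling would blur provenance. No smoothing or derivative preprocessing is
applied.

Two definitions need care. NMDI is computed as
`(R860 - (R1640 - R2130)) / (R860 + (R1640 - R2130))`; reading the leading
860 as a constant is dimensionally inconsistent and collapses the index to
~1. SWSI divides by `sqrt(R1326 - R1507)`; real SWIR spectra can order those
bands either way, so a non-positive radicand yields a flagged missing value
(NaN) plus a warning rather than a complex number. Zero denominators anywhere
are likewise flagged, never raised, so a single bad plot cannot abort a
batch.

## Destructive assays

Leaf relative water content is `100 (FW - DW)/(TW - DW)` from fresh, turgid
and dry section weights (unit-free). Total chlorophyll from the 80% acetone
extract is `20.21 A645 + 8.02 A663` in ug per mL of extract; because
published trait tables report mg per g fresh weight without stating the
conversion, the per-gram value `raw * volume / (1000 * mass)` is returned
*alongside* the extract concentration only when volume and mass are supplied,
and no conversion is ever guessed. Out-of-range fresh weights (field noise)
warn but return a value, preserving plot counts for the balanced ANOVA.

## Diversity and congruence

SSR bands are scored 0/1. Genetic dissimilarity is the Jaccard coefficient
`1 - a/(a+b+c)` (joint absences uninformative; a pair with no bands at all
gets distance 0 with a warning). Phenotype-side distances — the trial gives
no metric for these — are Euclidean on column z-scores (sample SD), so traits
and indices on different scales contribute equally.

Clustering is UPGMA: merge the closest pair at height d/2, with the distance
from a merged cluster to any other the size-weighted mean of its parts. Ties
are broken by the lexicographically smallest pair of cluster leader labels,
making the tree deterministic; the output is ultrametric by construction and
the cophenetic matrix is cross-checked against scipy's average linkage.
Newick serialization orders children by smallest leaf label (canonical).
`cut(k)` applies the first `n-k` merges (earliest-merge convention on tied
heights).

Phenotype/genotype congruence uses the Mantel test: Pearson correlation of
the upper-triangle distances, null distribution by simultaneous row/column
permutation of the second matrix, `p = (1 + #{r_perm >= r_obs})/(n_perm + 1)`
one-sided "greater" by default with 9999 permutations, seeded explicitly.
The permutation p-value is checked against exhaustive enumeration on 4x4
matrices, and the null rejection rate against its nominal 5%.

## Marker-trait association

Bidirectional stepwise multiple linear regression of genotype means on the
0/1 marker predictors: forward entry of the candidate with the smallest
partial-F p-value below `alpha_enter` (default 0.05), backward removal of any
entered marker whose drop-test p-value exceeds `alpha_remove` (default 0.10);
perfectly collinear candidates are skipped with a log entry. The per-marker
partial R2 is the increase in model R2 at entry, recomputed sequentially
after any removal, so partials always sum exactly to the cumulative R2. With
the thresholds disabled the procedure reduces to the full OLS fit on the
entered, non-collinear set. Whether the original analysis was forward-only
and its exit rule are not derivable from the published description; the
defaults here are documented choices, not inferences.

## Trait estimation from indices

Univariate calibration fits linear and quadratic least squares. A literal
"keep the higher R2" rule degenerates (the quadratic never loses on nested
models), so `best_univariate` keeps the quadratic only when its R2 gain
exceeds a threshold (default 0.02) or the curvature term is significant at
5%; a zero threshold with the significance guard disabled reproduces the
literal rule.

PLSR regresses one trait at a time on all 14 indices (column-standardized,
via scikit-learn). The latent-factor count minimizes the leave-one-out PRESS
(strict argmin, smallest count on ties). Accuracy is reported over 10
repeated random 75/25 calibration/validation splits — a "10-repeat, 25%
held-out" reading that satisfies both halves of the otherwise contradictory
"10-fold cross-validation with 25% validation" description — with the factor
count re-chosen inside each calibration half. Evaluation uses plot-level
records by default (n = 144 in the default trial); genotype-mean input is
accepted the same way. PCA is an eigendecomposition of the correlation matrix
(constant columns dropped), with scores from the z-scored data; eigenvalues
are normalized to explained-variance fractions.

## The synthetic trial generator

The original field data are not deposited, so every stage is exercised on a
simulated trial with known ground truth. A single latent per-genotype
"tolerance score" T_i ~ N(0,1) drives all four traits and the linked markers
— one knob that reproduces the observed co-clustering of traits, indices and
marker groups. Per trait, `G_i = sqrt(var_g) (rho T_i + sqrt(1-rho^2) U_i)`
with loading rho = 0.9 by default, so Var(G_i) = var_g exactly.

Default variance components are back-solved once from the published
combined-season mean squares of the real trial (e.g. dry weight
`var_g = (1.9068 - 0.0426)/6 = 0.3107`, `var_gy` clipped at 0,
`var_e = 0.0963`; similarly for LRWC, total chlorophyll and grain yield);
grand means sit mid-range of the reported genotype means and season shifts
are back-solved from the season mean squares. The simulated trials are
therefore the study's own conditions, not tuned quantities.

Canopy spectra are a smooth continuum — visible baseline 0.045, logistic red
edge at 712 nm (width 14 nm), NIR plateau saturating in plant dry weight,
dry-matter-driven SWIR decline — multiplied by `1 - sum of Gaussian
absorption features`, each feature's depth saturating Michaelis-style in its
driver: chlorophyll wells at 430/550/670 nm (the weak 550 well leaves the
familiar green reflectance bump), water bands at 970/1200/1450/1940 nm driven
by a canopy-water proxy (LRWC/100 x PDW), and dry-matter features at
2100/2305 nm. The saturating depths reproduce the index-saturation behaviour
of the NDVI family; additive white noise (SD 0.0035) is applied and
reflectance clipped to (0.001, 0.999). Every registered index band responds
to at least one driver. Deliberately *not* emulated: radiative-transfer leaf
optics, soil background mixing, spectrally autocorrelated noise, and
multi-trait genetic correlation beyond the single latent factor — so passing
tests demonstrate statistical correctness of the pipeline, not instrument
realism.

Marker panels give linked loci band probability
`logistic(slope z_i + logit(background))` — the logit offset makes a zero
slope degrade exactly to the background band frequency (0.35 by default)
while a saturating slope turns linked loci into the indicator of a positive
tolerance score — and unlinked loci iid Bernoulli(background). Defaults: 34
markers, 20 linked, slope 1.5.

## Problem sizes and numerics

Simulation-based checks use the default 24 x 2 x 3 trial; distributional
assertions run 2000 seeds for type-I error rates (binomial SE about 0.5%),
120 seeds for heritability recovery (tolerance +-0.10), 200 seeds for
stepwise recovery, and 30 seeds for PLSR factor recovery; Mantel nulls use
199 permutations per seed and 9999 for single reported tests. Oracle
comparisons are exact to 1e-12 (index formulas), 1e-9 (least squares,
ANOVA additivity, cophenetic distances) or 1e-8 (PLSR/OLS equivalence at
full rank). Degenerate inputs (constant responses, zero-variance predictors,
all-zero marker rows, TW = DW samples) are either flagged-and-continued or
rejected with typed exceptions as documented per function.

## Known limitations

The published heritability table cannot be reproduced from the published
mean-square table under any standard expected-mean-squares variant (checked
by hand: dry weight gives h2 = 0.95 vs the printed 77.57%); the printed
tables are internally rounded or used an unstated phenotypic-variance
definition. The package therefore anchors its acceptance checks on the
internally consistent identities (h2 = (GCV/PCV)^2, GG = k h2 PCV) rather
than on table-to-table recomputation. Neighbor-joining trees, bootstrap
support, kinship-corrected association, and full-spectrum (wavelength-level)
PLSR are out of scope.
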