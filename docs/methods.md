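# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limitations of `phenogp`. It is written for a
reader who wants to know exactly what is computed and what passing tests
do and do not demonstrate.

## Genotype coding and relationship matrices

Hybrids are coded 0/1/2 for the reference homozygote, heterozygote and
alternate homozygote at biallelic SNPs (−1 for missing). Loci are
filtered at MAF ≥ 0.05 and ≤ 20% missing calls by default; missing codes
are imputed by the locus mean (2(1−p_j), preserving allele frequencies
exactly) or the locus mode — a deliberate simplification relative to
haplotype-based imputation, adequate for the low missingness the filter
allows, and flagged in logs.

The additive matrix is `G_A = H_a H_a'/(tr(H_a H_a')/N)` where `H_a` is
the coded matrix with column means removed. We center on the
counted-allele frequency (column mean 2(1−p_j)); this makes `G_A`
invariant to which allele is called "reference" at each locus, which is
the property the rest of the pipeline relies on. The dominance matrix
uses the orthogonal parameterization in which the per-locus score for
genotypes (BB, Bb, bb) is

    h_d = (−2 p_Bb p_bb,  4 p_BB p_bb,  −2 p_Bb p_BB) / [p_BB + p_bb − (p_BB − p_bb)²]

built from *genotypic* frequencies, so it is correct away from
Hardy–Weinberg proportions (testcross panels are far from HWE). Loci
with a zero denominator carry no dominance information and are dropped
with a warning by default. Both matrices are scaled to trace N. A
consequence worth knowing: a pure testcross panel with a fully
homozygous tester shows only two genotype classes per locus, all h_d
scores vanish, and G_D is undefined — dominance becomes estimable only
when the panel includes material segregating in all three classes (the
generator's "commercial" component provides this).

PCoA is classical metric scaling (double-centered squared-distance
matrix, eigendecomposition), by default on Euclidean distances between
centered code rows — equivalent to PCA of the coded matrix — with an
identity-by-state option. The Euclidean default was chosen because it
has an exact eigen-oracle; scikit-bio's implementation serves as an
independent cross-check in the tests, never as the implementation.

## Thermal time and trait extraction

Development is measured in equivalent days at 20 °C: each hour
contributes f(T)/f(20)/24, with f a temperature response normalized so
f(20) = 1. The default response is piecewise linear with base 8 °C,
optimum 30 °C and an upper limit of 44 °C — the base and optimum are
standard for maize leaf development, but the exact functional form used
in any given study is rarely printed, so both the shape ("linear" or
"beta") and its parameters are configuration, not assertions. Everything
downstream depends only on the normalization contract f(20) = 1.
Temperature gaps ≤ 3 h are linearly interpolated; out-of-domain
temperatures are clipped with a warning.

Leaf appearance rate (LAR, leaves per d_20°C) is the OLS slope of
visible leaf number on thermal time from emergence to the 12-leaf
stage. Because leaves are scored discretely (weekly indoors, every few
days in the field), the window end is the first observation at or past
12 leaves; the floor-function staircase biases the slope slightly
downward (≈2% at weekly scoring), well inside the 5% round-trip
tolerance. Fewer than 3 observations in the window yields a missing
value, not an error.

Leaf area curves are fitted per genotype with a cubic smoothing spline
(generalized cross-validation penalty); observations from several plants
are pooled and repeated time points averaged, which equals the
genotype-mean curve under a per-plant additive offset model. Maximum
leaf expansion rate (LER, cm² per d_20°C) is extracted from the fitted
curve over the 24–45 d_20°C window either as the maximum first
derivative or as the OLS slope of fitted values across the window. The
two estimators agree only when growth is near-linear across the window;
on saturating curves the window slope is strictly smaller (mean-value
inequality) — both are reported with the method recorded because they
answer slightly different questions.

## Spatial adjustment and heritability

Plot values are adjusted with a mixed model: fixed genotype effects
(cell means, so the BLUE is the genotype's adjusted mean), random row
and column effects, and a random tensor-product cubic B-spline surface
(6×6 basis by default) on the plot coordinates. Variance components are
estimated by REML, optimizing the profiled deviance over log variance
ratios with L-BFGS-B on dense n×n algebra — appropriate for trials of
hundreds to a few thousand plots. Designs with no residual degrees of
freedom (unreplicated) fall back to raw genotype means with the
heritability flagged unavailable.

Broad-sense heritability comes from the refit with genotype random. Two
ratios are reported: the line-mean form H² = s²_g/(s²_g + s²_e/n_rep)
(n_rep = harmonic mean of per-genotype replicate counts; the default)
and the plot-level form s²_g/(s²_g + s²_e). The distinction matters for
null behaviour: with 100 genotypes × 3 replicates of pure noise, the
plot-level ratio exceeds 0.15 in ≈1% of trials, while the line-mean
ratio — which divides the residual by n_rep — does so in ≈20% simply by
the sampling distribution of an F-type ratio. Users comparing daily
heritabilities across experiments should fix one convention.

## Ecophysiology

Whole-plant stomatal conductance is obtained by inverting the big-leaf
Penman–Monteith equation for surface conductance, given transpiration
(mmol H₂O m⁻² s⁻¹ on a leaf-area basis), net radiation, air temperature,
VPD and boundary-layer conductance. Constants are the standard forms
with temperature dependence (Tetens saturation curve and its derivative,
λ(T), ρ_air(T), γ = 0.0665 kPa K⁻¹ at standard pressure); conductances
convert between molar and velocity units at the record's temperature.
The inversion is algebraic, so the forward/inverse round trip is exact
to machine precision; observations above the infinite-conductance limit
are flagged as non-physical rather than silently clipped, and the
zero-VPD/zero-radiation corner is rejected as undefined. gs_max is the
asymptote of a rectangular-hyperbola light response fitted to pooled
(conductance, light) pairs; a high-light quantile is available as an
alternative, with "saturating light" defaulting to 800 µmol m⁻² s⁻¹
PPFD (configurable — the threshold is a convention, not a measurement).

Trait–environment translation lines (e.g. leaf width vs cumulated
intercepted light, leaf length vs VPD) are OLS fits across experiment
means; indoor experiments are not fitted separately — only their
residuals from the field line are reported, because the scientific
question is whether indoor values fall on the field relationship.

The LAI simulator is a deliberately small daily loop: leaves initiate at
rate LAR in thermal time, each expands for a fixed thermal duration
(default 16 d_20°C) at LER_max × max(0, 1 + s_VPD(VPD−VPD_ref)) ×
max(0, 1 + s_ψ(ψ−ψ_ref)), capped by a bell-shaped rank-potential
profile; LAI = plant area × density / 10⁴. It is linear in density (no
competition) and monotone in either stress by construction, and its
constant-environment total area has a closed form used as the test
oracle. It is a simulator convention for propagating indoor genotypic
parameters through a field environment — not a calibrated crop model —
and its absolute LAI values should not be interpreted agronomically.

## GBLUP-AD sampler

The Gibbs sampler works in the eigenbasis of each relationship matrix:
with G = USU' and a = U S^{1/2} α, the prior on α is i.i.d. normal and
its full-conditional precision is diagonal, so each effect vector is
drawn jointly in O(N²) per sweep; eigenvalues below 1e−8 of the largest
are truncated, and matrices with eigenvalues below −1e−6 are rejected
with advice to jitter. Variance components have scaled-inverse-χ²
priors with 5 degrees of freedom and scales set so the prior modes split
half the phenotypic variance equally across the genetic terms and give
the rest to the residual — a weakly-informative default whose influence
vanishes at panel sizes of interest. The intercept has a flat prior;
optional fixed marker effects (known QTL) have flat priors drawn
jointly. Missing phenotypes are data-augmented each sweep, which is also
the prediction mechanism: cross-validation and external validation mask
the test hybrids' phenotypes and fit once on the joint panel. Two chain
profiles are bundled: "test" (6,000 iterations, 1,000 burn-in, thinning
5), the desk-scale default used throughout the tests, and "published"
(60,000/10,000/5) matching common published practice for this model
class. Chains are deterministic given the seed. With variances fixed,
the posterior mean of the additive effects equals the closed-form
GLS/BLUP solution; the test suite verifies this to <0.02·sd(y).

Genomic heritability defaults to the "total" form
(σ²_a+σ²_d)/(σ²_a+σ²_d+σ²_e) — the form that reconstructs published
per-trait tables — with an "additive" (narrow-sense) mode available;
the two differ whenever dominance variance is non-negligible, and the
choice is always explicit in the API.

The bivariate model couples two traits (typically the same trait in two
experiments) through 2×2 additive, dominance and residual covariance
matrices with inverse-Wishart priors (ν₀ = 4; prior means splitting the
phenotypic variances as above). The genetic correlation is
r_g = V_a[0,1]/√(V_a[0,0]V_a[1,1]) from the posterior mean of V_a —
defined on the additive component, because that is the component with a
selection interpretation. At small n the IW prior shrinks |r_g|
noticeably (≈0.88 for identical traits at n = 80, >0.99 at n = 300);
genetic correlations from panels of a few dozen shared hybrids should be
read with their standard errors.

PC-BLUP — the trait regressed on the first five PCoA axes — is included
as the population-structure-only benchmark; GBLUP exceeding it is the
evidence that prediction captures within-group genetic effects.

## Validation machinery

Cross-validation is CV1: whole hybrids are left out. Folds are dealt
round-robin within each stratum after shuffling, with the dealing cursor
carried across strata, so per-stratum fold counts differ by at most one
*and* total fold sizes differ by at most one (302 hybrids at k = 5 give
{61,61,60,60,60}). Metrics (Pearson r, Spearman ρ, Acc = r/√h², RMSE,
CV_RMSE, bias, CV_bias) are computed within each fold and averaged
across folds and iterations; Acc takes h² as an explicit argument and
values above 1.05 are flagged rather than truncated. Correlation
standard errors use the Bonett–Wright approximations, (1−r²)/√(n−3) for
Pearson with the √(1+r²/2) inflation for Spearman. Quartile concordance
uses quartile size ⌈n/4⌉ with stable tie-breaking by genotype order;
its null expectation (0.25) is verified by permutation. Release-period
strata for historical panels default to <1980 / 1980–2000 / >2000 bins.

## The synthetic generator and what it does not emulate

The default panel mirrors the structure the analysis assumes: testcross
hybrids of a common homozygous tester with inbred lines from four
genetic groups (sizes 39/45/55/107) whose allele frequencies drift from
a shared ancestral distribution by a Balding–Nichols model (F = 0.15 by
default), plus 56 "commercial" hybrids with two independently drawn
parents (which make dominance estimable and emulate a historical
series). Trait architectures draw i.i.d. per-SNP additive and dominance
effects and rescale the resulting genetic-value vectors so the realized
variances hit their targets exactly — parameter-recovery tests then have
a sharp truth. Multi-environment values share a common effect component
giving a specified between-environment genetic correlation. Environment
profiles ("constant20", "mild", "hot_dry", "cool") produce hourly
diurnal temperature/light cycles, VPD via the Tetens formula, and a
soil-water-potential sawtooth between irrigation events; "constant20" is
exactly noise-free so normalization contracts can be tested to machine
precision. Field trials add row/column effects, a smooth random surface
and i.i.d. noise, with the spatial share of the non-genetic variance set
by one parameter.

The deliberate omission with the largest consequence is linkage: SNPs
are generated independently, so the effective number of independent
genome segments equals the marker count. With N = 300 hybrids and
L = 2000 unlinked markers at h² = 0.6, the theoretical out-of-sample
ceiling √(h²·Nh²/(Nh² + M_e)) is ≈0.35, and measured cross-validated r
sits there. Real maize panels — hundreds of thousands of markers in
long-range LD tagging a few hundred effective segments — reach r of
0.5–0.85 at the same heritability. Passing recovery tests therefore
demonstrates that the estimators are correct and calibrated, not that
synthetic predictive abilities match field-panel values; any comparison
of absolute r against published panels must account for M_e. Other
non-emulated features: pedigree relationships beyond the group/tester
structure, genotype×environment interaction beyond the linear
environment-response models, selection and ascertainment of real
panels, and spatial autocorrelation shapes other than smooth-surface
plus row/column.

## Problem sizes

Tests and the acceptance script run panels of 80–300 hybrids with
500–2000 SNPs, the reduced chain profile, and 10-seed recovery
experiments — sizes chosen so a complete run finishes in minutes on one
CPU while keeping estimator behaviour in the regime the asymptotic
arguments above describe. The fitted model itself handles panels of a
few thousand hybrids (eigendecomposition and O(N²) sweeps remain cheap);
the "published" chain profile simply multiplies the sweep count by ten.
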