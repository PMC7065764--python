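# Methods

This note records the models, conventions and design choices behind
`fragdep`, in the order data flow through the pipeline.

## Effort model and standardization

Effort is counted in trap-nights (TN). The built-in `TrapDesign`
reproduces the survey's allocation rules: patches under 2 ha receive
one live-trap transect (5 stations × 2 traps) and two pitfall arrays
(4 buckets each); larger patches and continuous forest receive three
transects and four arrays; each patch's adjacent matrix receives one
live-trap transect and **no** pitfalls. All deployments run 10 nights,
so a large forest site accumulates 300 live + 160 pitfall TN, a small
site 100 + 80, a matrix stratum 100 + 0 — exact integer arithmetic.
Real surveys deviate from design defaults, so effort tables are
first-class inputs and `design_effort` only supplies defaults.

Standardized abundance is pooled counts divided by pooled effort,
scaled to captures per 1000 TN (the unit is a knob; it cancels in the
FD ratio only up to the pseudo-count, so FD values computed under
different unit conventions are not exactly comparable — the unit in
force is recorded with the results).
Pooling counts over trap classes before dividing equals the
effort-weighted mean of per-class rates.

Sampling adequacy uses the abundance-based sample-coverage estimator
(singleton/doubleton form). The incidence-based variant is not
implemented because the inputs here are individuals.

## Forest-dependency index

`FD = log10((r_F + c)/(r_M + c))` with pseudo-count `c = 0.01` added to
**both** rates. The usual shorthand for this index — a log10 rate ratio
with a 0.01 offset — leaves open where the offset enters; the
both-sides reading is the default because it (a) is defined
when a species was never caught in the matrix, (b) gives `FD < 0`
exactly when the matrix rate exceeds the forest rate, matching the
verbal classification rule, and (c) is antisymmetric under swapping
strata. The literal alternative `log10(r_F/r_M + 0.01)` is available as
`formula_variant="ratio_then_offset"`.

FD uses live-trap data only (no pitfalls exist in the matrix, so only
live-trap rates are cross-stratum comparable); the community average
weights by all standardized abundances.

Uncertainty is a delta-method propagation of the across-site standard
deviations of the stratum rates,
`se = (1/ln10)·sqrt(sd_F²/(r̄_F+c)² + sd_M²/(r̄_M+c)²)`; a plug-in
variant (half-spread of FD evaluated at mean ± SD) is selectable. The
delta method is the default because it is symmetric and reproducible.

Classification: τ is the maximum FD among species with at least one
matrix record. `FD < 0` → open-habitat; `0 ≤ FD ≤ τ` → matrix-tolerant
(the boundary species is matrix-recorded by construction, hence the
closed upper interval); `FD > τ` → forest-dependent. Pitfall-only
species take a declared donor's FD (imputation is flagged, and chained
imputation is refused).

Observed community FD here is strictly positive on realistic synthetic
surveys, while the projection equation (below) yields negative values
for sub-hectare patches: the two are on different scales (the
projection has no intercept). The package reports both and does not
force them onto one scale.

## Community structure

Bray–Curtis dissimilarity `d = Σ|a_j − a_k| / Σ(a_j + a_k)`; a pair of
empty sites is returned as 0 and flagged rather than NaN. PCoA is Gower
double-centering plus a symmetric eigendecomposition; coordinates are
eigenvectors scaled by sqrt of the non-negative eigenvalues. No
Cailliez/Lingoes correction is applied; the summed magnitude of
negative eigenvalues is reported so metric distortion is visible. Each
axis is oriented so its largest-magnitude loading is positive — a
deterministic convention worth stating because regression coefficients
on PCoA₁ flip sign with orientation.

## Multimodel inference

Gaussian fits use least squares with an always-present intercept.
Log-likelihood uses the ML variance `σ̂² = RSS/n`; the parameter count
`k` includes the intercept, slopes and residual variance, so
`AICc = AIC + 2k(k+1)/(n−k−1)` matches standard information-theoretic
tooling. Reported standard errors use the unbiased `RSS/(n−p)`. A
numerically perfect fit (RSS at rounding level relative to TSS) is
flagged with `AIC = −∞` rather than propagated.

All-subsets enumeration is exact (`2^p`; the analyses of interest have
p ≤ 7). A squared term always accompanies its linear parent
(marginality principle). The confidence set keeps ΔAICc ≤ 2 (the
standard information-theoretic convention, with the best model always
included), with weights renormalized inside the set. Averaging is conditional (natural): a term's estimate averages
only over models containing it; its unconditional SE is
`Σ w̃ᵢ·sqrt(seᵢ² + (βᵢ − β̄)²)`; CIs are normal-approximation ± 1.96 se;
relative importance sums the renormalized confidence-set weights of
models containing the term (renormalized rather than raw weights is a
choice, and it is visible in the output).

Hierarchical partitioning is the exact Chevan–Sutherland algorithm over
all subsets (equivalently the Shapley decomposition of R²); the
independent effects sum to the full-model R² to machine precision,
which the tests assert. Collinearity screening flags |r| > 0.75 pairs
and prunes iteratively by VIF > 5; VIF uses a plain lstsq R² so exactly
collinear sets yield infinite VIF instead of an error.

Outlier handling is deliberately manual: `refit_excluding` takes
declared site ids and reports before/after fits and ΔR². There is no
automatic detection.

## Landscape projection

Patches are 8-connected components by default (4-connectivity is an
option). Patch ids follow
raster-scan order of first pixels, making outputs byte-reproducible.
Projected community FD is `b₀ + b₁·log10(A) + b₂·log10(A)²` with
defaults `(0, 0.35, −0.04)`; the quadratic peaks at
`log10 A = −b₁/2b₂ ≈ 4.4` and is negative below 1 ha. The default
projection has no intercept, but `b₀` is exposed because fitted
regressions include one.

The proximity index is the standard FRAGSTATS form
`Σ area_s/d_s²` over non-touching neighbour patches within the search
radius; the alternative literal reading `(Σ area)/(Σ d)²` sits behind
`form="literal"`. Edge-to-edge distances are between nearest pixel
boundaries (for axis-aligned pixels,
`sqrt(max(|Δr|−1,0)² + max(|Δc|−1,0)²)` pixel sides), not centroids.
The continuous-forest surrogate value 1.00 × 10⁹ is provided as an
assignment constant. The search radius (conventionally 500 or 1000 m)
is always an explicit argument.

The transition metric counts pixels qualifying (forest in a patch with
cfd above threshold) in year A that no longer qualify in year B,
divided by year-A or year-B forest area — both denominators are
exposed because either is a defensible base for "fraction of high-FD
forest lost".

## Synthetic-data generator

The generator's defaults are the study conditions: 19 patches
log-uniform over 1.4–14,480.5 ha, 3 continuous-forest sites with the
surrogate covariates (area 144,800 ha, one order of magnitude above the
largest patch; cover 100%; proximity 10⁹; matrix complexity 10;
circular shape), covariates drawn within the observed field ranges, and
log-area/log-proximity tied through a shared latent factor with target
correlation 0.8, matching the strong area–isolation collinearity such
landscapes show.

Species pools default to 12 forest-dependent / 5 matrix-tolerant /
3 open-habitat species. Expected live-trap rates per 1000 TN at the
continuous-forest reference are 20/0, 15/6 and 4/20 (forest/matrix)
respectively, jittered per species by a clipped lognormal factor
(0.7–1.4) that cannot cross archetype invariants. Covariate effects are
multiplicative exponentials in centered log-area, log-proximity and
matrix complexity (forest-dependent +0.15 per log10 ha; open-habitat
−0.15, so it thrives in small patches). The matrix-tolerant matrix rate
of 6/1000 TN makes the expected number of threshold-defining matrix
records ≈ 11 per survey under the default design, so τ is almost never
estimated from an empty set. Counts are Poisson with mean
rate × TN/1000 × trap-class affinity (pitfall affinity 0.6 by default);
the capture noise model is an assumption, not inherited — an optional
gamma–Poisson overdispersion parameter relaxes it.

Deforestation chronosequences share one seeded clearing order across
years (randomized multi-source region growing, Eden-like), so cleared
pixels are nested across years by construction and the remaining forest
fragments into compact remnants; purely random pixel clearing is an
option.

What the generator does **not** emulate: spatial autocorrelation of
captures within sites, seasonal or trap-shyness effects, inter-species
interactions, real geographic layout, and any taxonomic identity.
Passing recovery tests therefore demonstrates the statistical machinery
is correct under its stated assumptions, not that field data meet them.

## Problem sizes and numerical choices

The validation experiments use 50 simulated surveys for classification
recovery (1000 species classifications), 200 replicates × 100 sites for
quadratic-coefficient CI coverage (noise SD 0.15, comparable to
site-level community-FD scatter), and a 512 × 512 three-year
chronosequence for the projection determinism check; together they run
in seconds. Tolerances: 1e-8 for oracle-vs-implementation coefficient
agreement and for the partition identity; PCoA Euclidean reconstruction
1e-8; exact equality where arithmetic is integer (effort totals, pixel
counts). Ties in AICc comparisons go to the smaller model; the AICc
denominator guard returns +∞ when n ≤ k + 1.

## Known limitations

- FD standard errors ignore within-site sampling (Poisson) error; they
  reflect only across-site spread.
- The ΔAICc ≤ 2 confidence set can be a poor summary when many models
  tie; full-model averaging is not implemented.
- Proximity computation is O(boundary² ) per patch pair and meant for
  survey-scale landscapes, not for all ~10⁵ patches of a full raster.
- Plain-text 0/1 matrices are the only raster format read or written;
  there is no CRS or georeferencing support.
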