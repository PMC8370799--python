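# Methods

This note documents the models, conventions and numerical choices behind
`seepbef`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Sampling design and proxies

The unit of analysis is a *sample*: two pooled push cores of 6.4 cm
internal diameter (area 2 · π · 0.032² ≈ 6.434 × 10⁻³ m²), assigned to one
of three habitat categories — active seep, transitional chemotone,
background sediment — with a default design of 13/13/12 samples. Density
and wet standing stock are raw totals divided by the pooled core area.

Community bioturbation potential is implemented exactly as
BPc = Σᵢ (Bᵢ/Aᵢ)·Aᵢ·Mᵢ·Rᵢ with the sample-mean individual biomass
substituted for every family's Bᵢ/Aᵢ (family-level biomass is rarely
recorded in blind-sorted material). The original Queirós-lineage index
uses √(Bᵢ/Aᵢ); both are available (`bpc_variant: plain | sqrt`, default
`plain`) and the default is pinned by tests. Mobility (Mi) and reworking
(Ri) scores are per-family parameters; when a registry lists several
species-level scores for a family their arithmetic mean is used, and
unregistered families either raise an error or take a configured default
(`family_param_fallback`). The registry shipped under
`data/family_params_synthetic.csv` is a synthetic stand-in with plausible
score ranges — the published family-score compilations are not openly
deposited — and is labelled as such.

Calcification degree is Σ score·abundance over families, scores 0–5.

## Biodiversity

Richness, Shannon *H* (natural log — the convention of the standard
community-ecology software) and Pielou *J* = *H*/ln *S* are computed per
sample on the species matrix and on the trait-weighted matrix
(family-level 0–5 scores × species abundance, summed over taxa; 32 traits
in 7 groupings). *J* is undefined for samples with fewer than two
categories; it is recorded as missing and later 0-imputed on the
standardized scale rather than assigned an arbitrary value.

The 32 trait names and groupings used by the generator
(`simulate.TRAIT_CATALOG`) are an invented placeholder catalog with the
structure of a benthic biological-traits analysis; they are data, not a
claim about any particular published trait set.

## Environmental derivations

Point measurements are interpolated to the bathymetry grid by nearest
neighbour or inverse-distance weighting (power 2 over the k = 8 nearest
points; a coincident cell takes the point's value). Terrain operators
follow the GDAL conventions: Horn's 3×3 weighted-difference slope, the
Wilson TRI (mean |cell − neighbour| over 8 neighbours) and TPI
(cell − neighbour mean). Edge cells are handled by replicating border
values; edge-adjacent results are therefore smoothed estimates, which keeps
all samples usable but should be remembered when samples sit on the margin.

Annual NPP sums 12 monthly values; the default treats them as monthly
totals, with a `mean_times_days` convention (×365/12) available. Export
flux to depth z uses the exponential-plus-refractory form
flux = NPP·(prd·e^(−z/rld) + prr), defaults prd = 0.4, rld = 400 m,
prr = 0.01 — a generic open-ocean-like attenuation: ~41% of production
exported at the surface, ~1% surviving to abyssal depth. These are
configuration values, not a site-specific calibration of any published
flux model.

## Reduction

The fixed order is standardize (z-scores, n−1 denominator) → replace
missing with 0 (the variable's mean) → PCA per variable grouping, with
retained components functioning 2, taxonomic biodiversity 2, trait
biodiversity 2, oceanographic 2, terrain 1; TPI enters the model
unreduced. PCA is SVD-based on the z-scored data; because PCA signs are
arbitrary, each component is oriented so its largest-|loading| variable
loads positively, making outputs platform-reproducible.

## The habitat-stratified GAM

Smooths are cubic B-splines with a second-*divided*-difference penalty at
the Greville abscissae (so constants and straight lines are exactly
unpenalized despite the clamped knots), centered by the usual sum-to-zero
constraint; each smooth's penalty null space is then one linear function,
i.e. a fully penalized term degenerates to a line with edf 1. Biodiversity
axes get a separate smooth per habitat level (zero rows outside the
level); environmental axes get global smooths. Default basis dimension is
k = 4 in the 38-sample pipeline (33 coefficients) and the model refuses to
build when the *penalized* system is unidentifiable (collinear penalty
null spaces), naming the smooth terms involved.

Smoothing parameters minimize GCV with the conventional γ = 1.4 inflation
of the effective-dof cost, which guards against GCV's occasional drastic
undersmoothing; minimization is cyclic per-term descent over a 25-point
log₁₀λ ∈ [−4, 8] grid, scanning from heavy smoothing downward so ties
resolve to the smoother fit. Gaussian/identity models solve in closed
form; gamma/log uses penalized IRLS with the smoothing re-selected on the
working model.

Per-smooth significance is a Wald-type test of the whole coefficient block
against the Bayesian posterior covariance, referred to F(rank, n −
edf_total). The coefficient shrinkage makes this mildly conservative: in
the null simulation built into the acceptance suite (all habitats null,
n = 40/group, 200 replicates) the realized per-smooth rejection rate at
α = 0.05 is ~3%. All reported p-values are approximate, conditional on the
selected smoothing parameters.

Model AIC uses the upper effective-dof measure edf1 = 2 tr(F) − tr(F²)
(F the hat-generating matrix) in its complexity penalty: the conditional
AIC with plain penalized edf ignores smoothing-parameter estimation and is
biased toward retaining spurious wiggle, which showed up directly as
backward selection keeping pure-noise smooths.

Backward selection repeatedly removes the smooth with the largest p-value
above α = 0.05 whose removal does not raise AIC by more than 2 (both
thresholds configurable; the factor is never removed), recording a full
trace. Knot selection, when enabled, greedily picks each smooth's k from
{4, 5, 6} by AIC, excluding candidates exceeding the smooth's group size.
Family/link selection fits the candidate list (default gaussian/identity,
gamma/log), filters by residual diagnostics (Shapiro–Wilk at 0.01; no
|residual|-vs-fitted Spearman trend at 0.05) and takes the lowest AIC,
with candidates within 2 AIC treated as ties resolved to
gaussian/identity. The pipeline's default run uses fixed k = 4 and
gaussian/identity — appropriate for z-scored PC responses at n ≈ 12–13 per
habitat — with both selection steps available as options.

## Shape classification

A smooth absent from the final model, or with p ≥ 0.05, is *null*.
Otherwise its first derivative is evaluated on a 100-point grid spanning
the central 5th–95th percentile range of the covariate within the smooth's
support — boundary regions are excluded because spline estimates there are
dominated by edge variance and boundary bias, and were empirically the
main source of spurious "complex" calls. Grid points whose derivative
interval (±1.96 se) excludes zero carry a credible sign; single-point
credible runs are discarded as flicker. Zero credible sign changes gives
*monotone* (by sign), exactly one gives *unimodal*, more give *complex*.
For unimodal calls the interior extremum is first located as the argmax of
the fitted smooth and then refined by a parabolic mode estimate — a
quadratic least-squares fit to the smooth's partial residuals within a
window of half the observed range, taking the vertex (clipped to the
window; plugin value kept if the local curvature disagrees). The plugin
spline peak alone carries roughly twice the error of the refined estimate.

## Synthetic data generator

Per habitat, each sample's species relative abundances are Dirichlet draws
over the habitat's species pool (default concentrations 0.12/0.25/0.5 for
active/transition/background: stronger dominance at seeps), with a
configurable fraction (default 30%) of the 60-species pool restricted to
active + transition habitat (seep specialists). Total abundance is Poisson
with log-mean = log(base density × habitat multiplier; defaults 80 ×
5/2/1) + BEF signal + lognormal noise (sd 0.3). The BEF signal is a
deterministic function (flat / linear / quadratic / exponential /
saturating) of the sample's habitat-standardized latent diversity, scaled
so that signal sd = effect size × noise sd (default effect size 2) and
recentred so the habitat's mean density honours its multiplier. Body mass
is lognormal per family; per-sample biomass sums mass over individuals.
Bathymetry is a smooth gradient plus band-limited noise; temperature,
salinity and oxygen are depth-linked point measurements with noise; NPP is
a seasonal sinusoid. One integer seed feeds an independent named stream
per sub-generator, so outputs are byte-reproducible and component changes
do not cascade.

What the generator does *not* emulate — and hence what passing tests do
not establish about field data: within-habitat spatial autocorrelation
(samples are exchangeable within habitat), sediment geochemistry,
microbial mats, taxonomic misidentification, gear selectivity, or any
coupling of the environment covariates to the community beyond the habitat
factor itself. Recovery rates measured here are for a correctly specified
generative family and should be read as upper bounds.

## Problem sizes and runtimes

The test suite's simulation studies use: type-I calibration at n = 40 per
habitat × 200 replicates; power/shape recovery at n = 40 per habitat × 100
replicates (effect size 2); end-to-end pattern recovery at 3× the default
design (39/39/36) and at the default design (13/13/12), 50 replicates
each; selection sanity at n = 60 × 100 replicates. The full suite runs in
~2.5 minutes and `scripts/acceptance.py` in ~20 seconds on one CPU. At the
default 13/13/12 design the positive (unimodal) form is under-powered —
recovery of the active-habitat peak is reliable only at the 3× design,
while null habitats are called correctly at either size; this mirrors the
power realities of push-core surveys of this scale.

## Known limitations

- p-values are conditional on GCV-selected smoothing and mildly
  conservative by construction; they are not exact frequentist tests.
- GCV (not REML) is the only smoothing criterion; REML typically smooths
  more at small n.
- The gamma/log path estimates its shape parameter by moments, adequate
  for AIC comparison but not for reporting gamma-model inference.
- Export-flux coefficients are generic defaults; depth gradients in flux
  are therefore qualitatively, not quantitatively, realistic.
- Terrain indices at grid margins use replicated-edge padding.
- By-habitat smooths whose covariate collapses within a habitat group
  (within-group |r| > 0.99 with an already-included axis, or ~zero
  variance) are dropped before fitting and reported as null for that
  habitat — the data carry no independent signal to classify.
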