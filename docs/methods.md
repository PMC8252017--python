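# Methods

`phenoceiling` implements a quantitative account of why leporid lagomorphs
(rabbits and hares) appear to be capped at roughly hare size on continents:
competition with the smallest co-occurring ungulate-type herbivores (UTHs).
The package chains four pieces of machinery — phylogenetic allometry,
energy-line geometry, fossil time-series construction, and information-
theoretic model comparison — and ships a synthetic-data generator that
encodes the study conditions so every stage is testable end to end.

## Local-population energy use

Basal metabolic rate and local population density are modeled as power
laws of body mass M (kg):

    R = a M^b        D = c M^d

so the energy used by a local population is

    E = R D = a c M^(b+d),
    log10 E = (log10 a + log10 c) + (b + d) log10 M = alpha + beta log10 M.

Each guild (lagomorphs; ungulates) has its own density scaling but a
shared metabolic scaling. Because the lagomorph density slope is much
steeper, the two guilds' energy lines cross at an *equilibrial mass*

    log10 M* = (alpha_ung - alpha_lag) / (beta_lag - beta_ung).

Below M* a lagomorph population out-consumes a same-sized ungulate
population; above it the ranking flips, which is the hypothesized
competitive ceiling. For a reference ungulate of mass m the
*energy-equivalent lagomorph mass* solves
E_lag(M_eq) = E_ung(m):

    log10 M_eq = (alpha_ung + beta_ung log10 m - alpha_lag) / beta_lag.

Since |beta_ung| < |beta_lag|, d log10 M_eq / d log10 m =
beta_ung/beta_lag is well below 1: large swings in the smallest
perissodactyl's mass translate into small swings of the implied
lagomorph ceiling.

Uncertainty on M* and M_eq is propagated to first order (delta method)
from the intercept/slope covariance matrices of the underlying fits,
treating the density and metabolic fits as independent because they come
from different trait compilations. The equation being inverted for M_eq
is the log form of the energy-use identity above; the solver works
entirely on the log10 scale.

## Phylogenetic GLS under Pagel's lambda

The allometries are fitted by generalized least squares with residual
covariance `sigma2 * C(lambda)`, where `C(lambda)` is the Brownian-motion
tip correlation matrix of a time-calibrated tree with off-diagonals
scaled by `lambda` constrained to [0, 1]. Choices that were genuinely
open and how they were resolved:

- **lambda estimation.** Full maximum likelihood (not REML), profiled
  over intercept, slope, and residual variance; a 21-point grid scan over
  [0, 1] brackets the optimum, refined by bounded scalar minimization to
  1e-6. The grid stage makes the optimizer robust to the flat or
  boundary-pinned likelihoods common at small n.
- **Residual variance.** `sigma2` is reported with an n-2 bias
  correction, which is what the confidence bands and prediction variances
  use; the ML profile value enters only the likelihood.
- **Measurement error.** Known per-species variance inflation (e.g. the
  sampling variance of a species-mean) adds a diagonal term, making the
  covariance `sigma2*C(lambda) + diag(w)`; `lambda` and `sigma2` are then
  optimized jointly (nested scalar searches) because the profile trick no
  longer applies.
- **Confidence bands** default to parameter-only uncertainty (a band for
  the fitted mean); a flag adds the residual variance for
  prediction-style bands.
- **New-tip prediction** is universal kriging: fixed-effect value plus a
  covariance-weighted adjustment toward the residuals of related tips;
  its variance contains the residual term, the conditioning reduction,
  and the parameter-uncertainty term. Species present in data but not on
  the tree are dropped with a warning rather than an error.

## Fossil body-mass estimation

Species-level log10 mass is regressed on a log10 dental or mandibular
dimension across extant species, with variance inflation
`var_within/n` per species. Model accuracy is the leave-one-out mean
absolute percent prediction error |D| on the kg scale, computed by
refitting without each species. Fossils with a known position on the
reference tree use the kriging prediction; taxa of uncertain affinity
default to the fixed-effect line with full prediction variance — the
conservative choice. Specimen-level estimates are merged into a species
value by inverse-variance weighting. All estimates stay on the log10
scale downstream (the Monte-Carlo mass draws are normal on log10 — a
choice, flagged here, since the arithmetic-scale alternative is equally
consistent with a "normal around the point estimate" description); no
smearing correction is applied because nothing is back-transformed except
for display.

## Fossil time series

- **Bin grid.** 1.5-Myr bins starting at 43.5 Ma (29 bins to the
  present). Bins are half-open; a boundary age belongs to the *older*
  bin, so every age maps to exactly one bin.
- **Locality filter.** Records whose age range exceeds 4.2 Myr (the
  longest land-mammal-age subage) are dropped; exactly 4.2 Myr is kept.
- **Binning age.** Deterministic runs bin by locality midpoint age;
  pseudo-replicate runs bin by the sampled age.
- **Range-through presence.** A taxon occupies every bin between its
  oldest and youngest occurrence bins and carries a single mass estimate
  through them.
- **Guild extrema.** Per bin: maximum lagomorph, minimum artiodactyl,
  minimum perissodactyl log10 mass; absent clades give missing values.
- **Glires sampling probability.** p = (genera sampled in the bin) /
  (genera range-through in the bin), transformed by the empirical logit
  `ln((k+0.5)/(n-k+0.5))` so that fully-sampled bins stay finite. The
  numerator counts in-bin occurrences only, never interpolated presence.
- **Proxies.** Benthic d18O records are averaged within bins (same
  boundary rule); the ungulate hypsodonty index is linearly interpolated
  from interval midpoints to bin midpoints, with no extrapolation.
- **Competitive ceiling.** Perissodactyl-regime windows (37.5–24.0 and
  15.0–1.5 Ma) use the energy-equivalent lagomorph mass of the smallest
  contemporary perissodactyl; the artiodactyl window (24.0–15.0 Ma) uses
  the smallest artiodactyl mass directly. The windows are configuration
  data; identifying them is an upstream judgement, not automated here.

## Model selection

Eleven linear models of per-bin maximum lagomorph log10 mass: five
singletons (ceiling, minimum perissodactyl, d18O, hypsodonty, glires
sampling) and six fixed pairs (ceiling or minimum perissodactyl crossed
with sampling, hypsodonty, d18O). Each model carries a temporal
autocovariate — the residual of the nearest older complete bin from a
first-pass fit that ignores autocorrelation; the autocovariate is
computed once (no fixpoint iteration). The second pass is ordinary least
squares: once the lagged residual is a regressor the model has no
remaining error structure to exploit, and OLS keeps the likelihood
closed-form. The Gaussian profile log-likelihood feeds

    AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1),

with k = intercept + predictors + autocovariate + residual variance.
All models are fitted on the same complete-case row set so their AICc
values share n and are comparable; ties break toward fewer predictors.

**Pseudo-replication.** Locality ages are drawn uniformly within their
bounds — one draw per locality, shared by all taxa at that locality
(preserving within-locality co-occurrence) and independent across
localities and replicates. Taxon masses are drawn normally on log10
around their point estimates with the model-informed standard errors
(both residual and parameter terms included, toggleable). The series is
rebuilt and the roster refit per replicate over the 37.5–1.5 Ma window
(24 bins; the most recent bin is excluded). Replicate RNG substreams are
derived from the master seed by replicate index, so increasing the
replicate count never reshuffles earlier replicates. The headline run
uses 1,000 replicates; the test suite and acceptance script use 200,
which is ample to identify the plurality winner.

## Modern-ecoregion stage

Guild extrema per ecoregion take the largest leporid and the smallest
UTH (artiodactyls, perissodactyls, ungulate-like caviomorphs) after
excluding omnivorous or semiaquatic genera (suids, tayassuids,
hippopotamids, capybara) by a built-in genus list or an explicit flag.
Body-mass distribution shape is summarized by the sample-size-adjusted
Fisher-Pearson skewness `G1 = sqrt(n(n-1))/(n-2) * m3/m2^1.5`, applied
to log10 species masses by default (raw-scale is a switch; the
appropriate scale is itself a judgement call).

The boosted regression-tree stage delegates boosting to scikit-learn's
`GradientBoostingRegressor` with tree complexity (max depth) 3, learning
rate 0.005, and bag fraction (subsample) 0.75; this module owns the
two-pass spatial procedure (first fit without a spatial term, neighbor-
mean residual autocovariate from its residuals, refit with it), the
cross-validated choice of boosting length, and the extraction of
relative influences (normalized to 100%) and partial-dependence curves.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions. Pure-birth trees
stand in for the time-calibrated supertree (sufficient to exercise
lambda-GLS; no extinction or sampling dynamics). Traits evolve as
`response = intercept + slope*log10M + eps` with eps multivariate normal
under `sigma_resid^2 * C(lambda_true)`; masses are uniform on log10 —
matching the log-linear domain of the allometries, not any real mass
distribution. Default scaling parameters — metabolic (0.6, 0.7), density
(2.2, −1.9) for lagomorphs and (1.6, −1.15) for ungulates, residual SD
0.1 dex, lambda 0.5 — compose to energy lines (2.8, −1.2) and
(2.2, −0.45) crossing at ~6.3 kg, reproducing the qualitative geometry
of the continental size ceiling.

The fossil generator realizes per-bin trajectory extrema with single-bin
taxa (one pinned exactly at each clade's extremum), locality ages with
symmetric bounds (half-width capped at 2.1 Myr so every record passes
the 4.2-Myr filter; the generating age is always the bounds' midpoint),
log10-mass errors of 0.05 dex, and multi-bin rodent genera with partial
per-bin sampling anchored at their range ends. The default perissodactyl
minimum rises roughly eightfold across the window while the artiodactyl
minimum starts below the lagomorph maximum and climbs past it; the
lagomorph maximum tracks the implied ceiling minus 0.08 dex with 0.05
dex of tracking noise. What passing tests therefore *do* show: the
pipeline recovers known generating values exactly at zero noise and
identifies the generating model under realistic noise. What they do
*not* show: robustness to taxonomic error, non-uniform fossilization,
range-through violations, or any feature of real occurrence databases
beyond bounded age uncertainty.

Ecoregion tables use a square-lattice adjacency by default, uniform or
log-normal covariates, a response built from user-supplied effect
functions (default: 0.55 × log10 minimum-UTH mass), and spatially
autocorrelated noise made by mixing each region's draw with its
neighbors' mean.

## Numerical choices and degenerate inputs

- lambda optimization tolerance 1e-6; correlation matrices get a 1e-12
  diagonal jitter only inside the trait simulator's Cholesky.
- Zero-noise fits report sigma2 = 0 and zero-width bands; the likelihood
  floor (1e-300) only guards log(0).
- The locality-uncertainty filter uses a 1e-9 tolerance so spans that
  are exactly at the cutoff after floating-point subtraction are kept.
- Evidence-ratio exponents are clipped at 700 to avoid overflow for
  hopeless models.
- Isolated ecoregions get a zero autocovariate with a warning; empty
  bins, missing guilds, and missing proxy coverage all propagate as
  missing values, and model fitting drops incomplete rows pairwise with
  their successors' lags recomputed from the nearest older complete bin.

## Problem sizes

The test suite and the acceptance script run desk-scale versions of
every computation: 500 replicates of 200-tip trees for CI calibration,
29-bin records with ~270 occurrences, 200 pseudo-replicates for model
recovery, 300 ecoregions for the BRT stage. These sizes were chosen so
the full suite completes in well under a minute while keeping
Monte-Carlo error far smaller than the effects being checked.

## Known limitations

- Only Pagel's lambda is supported as a covariance transform (no OU,
  kappa, delta) and only single-response regressions.
- The autocovariate regression assumes the lag-1 residual removes the
  temporal structure; no AR error models are provided.
- Regime windows for the ceiling are inputs, not inferred.
- The generator's fossilization model is deliberately minimal: uniform
  age bounds, no preservation or collection biases.
- GIS raster extraction, taxonomic synonymy curation, and supertree
  construction are out of scope; their products arrive as input tables.
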