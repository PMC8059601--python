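# Methods

## Trait surfaces

Four per-pixel fire-regime traits are built from a fire record (perimeters
with burn year and ignition date, per-fire CBI severity surfaces) on a
north-up square-cell analysis grid. A pixel belongs to a fire when its cell
*center* falls inside the perimeter — the unambiguous convention for 30 m
burn products — and per-fire severity is resampled to the analysis grid by
nearest neighbour.

- **Fire return interval (years).** For burns y₁ < … < yₙ in the record
  window [start, end], the interval sequence, most-recent-first, is
  (end − yₙ), (yₙ − yₙ₋₁), …, (y₁ − start). The open intervals to the
  record's first and final year are included, making the trait a *minimum*
  frequency estimate suited to relative comparison; the open interval since
  the last fire is treated as the most recent so the current regime state
  dominates under recency weighting. A never-burned pixel carries the full
  record length (33 years for 1985–2018).
- **Severity (CBI, 0–3).** Recency-weighted mean of the pixel's per-fire
  CBI values. Unburned pixels carry 0 (no vegetation change).
- **Season (−1 to 1).** Day-of-year d maps to cos(2π(d − 1)/365), so
  Dec 31 and Jan 1 are adjacent; the leap day folds onto the Jan 1 value
  within rounding. Missing for unburned pixels.
- **Patch size (log ha).** Each event's severity mosaic is classified into
  unchanged [0, 0.1), low [0.1, 1.25), moderate [1.25, 2.25) and high
  [2.25, 3] CBI classes; connected components are delineated per class with
  8-connectivity; every burned cell takes ln(component area in ha).
  Missing for unburned pixels.

**Recency weighting.** The k-th most recent event (or interval) gets raw
weight (1 − d)^(k−1), normalized to sum to one. This is the unique
one-parameter geometric family that yields equal weights at d = 0,
successive halving at d = 0.5 (the default) and most-recent-only at d = 1.
Weighting is by fire *order*, not elapsed time, to avoid confounding the
weights with the frequency trait itself.

**Discretization.** Traits are rounded half-even at fixed precisions —
whole years, 0.5 CBI, 0.1 cosine units, 0.1 log-ha — *after* weighted
averaging. Rounding after (not before) averaging keeps per-event information
while still bounding the number of distinct histories; 0.1 log-ha gives
roughly 90 patch-size bins over realistic fire sizes. The precision of the
"log hectares" patch trait and the record-length convention (33 vs 34
years) are configurable.

## Pyrodiversity (FDis)

A landscape unit's community table keys every cell on its discretized
trait tuple. Dissimilarity between histories is the Gower distance: per
trait, |difference| divided by the trait's **fixed global range** (FRI:
[0, record length]; severity: [0, 3]; season: [−1, 1]; patch: configurable,
default [−2.5, 13] log-ha), averaged over traits observed in both histories
with equal weights (configurable) and weight renormalization when a trait
is missing. Global rather than per-unit ranges keep FDis comparable across
units in a regional analysis; missing traits are excluded rather than
imputed so no season or patch values are invented for unburned area.

FDis is computed through a principal-coordinates embedding of the Gower
matrix with the signed correction for negative eigenvalues (squared
centroid distance = positive-axis part − negative-axis part, floored at
zero before the square root), an abundance-weighted centroid, and the
abundance-weighted mean centroid distance. A single-history table returns
exactly 0. The test suite verifies the ordination result against an
ordination-free route — the Lagrange identity
z_j² = Σ_k w_k d_jk² − ½ Σ_kl w_k w_l d_kl² applied directly to the
dissimilarity matrix — which is exact for the signed embedding; the two
agree to better than 1e−10 on random tables. Functional richness (convex
hull volume) is available as a diagnostic only: it is sensitive to outliers
and sample size, which is why dispersion is the headline metric.

## Trait covariance

Because FDis is a multivariate analogue of the weighted mean absolute
deviation, each trait's univariate dispersion (abundance-weighted MAD over
the unit's history table, missing values skipped) can be examined
separately. The sweep correlates per-trait dispersions across units while
raising a minimum-fire-count filter from 1 to 15; a unit's fire count is
the number of record events whose perimeter intersects it. Pearson
correlation is the default ("correlations" unqualified), Spearman by flag.
Pairs with fewer than three surviving units or a zero-variance column are
flagged undefined rather than silently NaN.

## Driver model

Stage one (burn activity) is a hurdle model of the proportion of flammable
area burned over the record (cumulative; may exceed 1 where areas reburn):
a Bernoulli occurrence part and a Gamma amount part with log link, both on
the eight climate/topography/human terms (AET, CWD, AET×CWD, elevation,
roughness, elevation×roughness, population density, proportion wilderness).
Group intercepts enter the Gamma part; the occurrence part is kept
non-hierarchical to hold the parameter count down. The hurdle family is the
package's choice for a zero-inflated, potentially-greater-than-one
proportion; it is pluggable.

Stage two is the Beta pyrodiversity regression (mean-precision
parameterization, logit link) on the same terms plus the standardized
burned proportion and its square, with varying intercepts for the coarse
grouping watersheds. All predictors except the wilderness proportion are
standardized (sample sd, ddof 1); the scaling record is retained so the
quadratic vertex can be mapped back to the raw proportion scale.

**Zero responses.** Observed pyrodiversity can be exactly 0 (a one-history
unit), which the Beta likelihood cannot absorb. The default treats zeros as
*left-censored* below the smallest positive observation, entering the
likelihood through the regularized incomplete beta function P(Y < δ); this
stays honest about how small a zero might be, which matters because the
model itself generates astronomically small responses at extreme burn
activity. A nudge-to-half-minimum alternative is provided; both are logged
loudly.

**Inference.** Default is maximum a posteriori with a Laplace (Gaussian)
approximation — weak N(0, 5) priors on coefficients, a weak normal prior on
log θ — with the group-intercept scale σ handled by *profiling*: the model
is fit at fixed σ, σ is updated from its exact one-dimensional conditional
(on a grid, under a boundary-avoiding Gamma(2) prior with scale 0.5), and
after convergence one σ value is drawn per posterior draw from that
conditional. The profile/conditional scheme avoids the hierarchical funnel
(a centered MAP degenerates at σ → 0; a non-centered Laplace reduces the σ
marginal to its prior) and gives calibrated intervals for σ even with few
groups. An ensemble MCMC backend (emcee, walkers started at the MAP) is
available via `method="emcee"`; its convergence is flagged by split-R-hat.
Central 90% intervals are reported by default.

**Propagation.** Indirect (burn-mediated) effects propagate stage-one
uncertainty by substituting, for each of a set of burn-posterior draws, the
predicted burned proportion (occurrence probability × Gamma mean,
standardized with the original scaling) for X7/X8, refitting stage two and
pooling the posteriors. This widens the burn-effect intervals as intended;
because predicted values have less spread than observations (an
errors-in-variables effect), the pooled quadratic can lose concavity, in
which case the vertex machinery flags the peak as undefined rather than
reporting one. A plug-in-mean mode substitutes the posterior-mean
prediction once, for speed.

**Derived quantities.** Per posterior draw with β₂ < 0, the standardized
vertex −β₁/(2β₂) is back-transformed to the proportion scale and converted
to a fire rotation (record years / peak proportion; record length defaults
to 34 years, the inclusive year count of a 1985–2018 record). Draws are
summarized as mean and central 90% interval; the vertex is declared
undefined when the quadratic is non-concave in most draws.

## Synthetic data

The generator emulates a national large-fire record at desk scale: per-year
Poisson ignitions; lognormal fire sizes (default exp(7) ≈ 1100 ha median,
σ = 0.8); perimeters grown by thresholding a Gaussian-smoothed noise field
minus a radial ramp around the ignition cell, searched to hit the target
area within 5% (4-connected components, so each perimeter unions into a
single polygon); severity as a spatially correlated Gaussian field rescaled
to a given CBI mean/sd and clipped to [0, 3]; ignition dates wrapped-normal
around early August. The default grid uses 1 ha (100 m) cells on 200 × 200
— 40 kha, large enough to hold several >404 ha fires at desk scale; grid
and resolution are configurable. The driver-table generator draws
covariates standard normal (exactly standardized, so stored truths apply to
the fitted columns), wilderness uniform on [0, 1], and responses through
the full two-stage model; the generative spec is returned alongside the
table. Default generative parameters take the reported regional coefficient
estimates as truths (burn effect 2.5, quadratic −0.78, precision 30), with
intercepts chosen to give realistic response levels (median pyrodiversity a
few hundredths).

What the generator does *not* emulate: fire spread physics, climate-driven
interannual ignition variability, topographic controls on severity pattern,
or the spatial autocorrelation of real covariates. Passing tests therefore
demonstrate the correctness and calibration of the *method*, not the
regional conclusions drawn from real records.

## Problem sizes and numerical choices

- Calibration tests fit 500 units in 5 groups over 20 replicates — a
  deliberate scale-down of a ~2000-watershed regional analysis that keeps
  the full hierarchical structure.
- The two-regime landscape uses a 100 × 100 grid of 1 ha cells; the FDis
  acceptance checks use random history tables of up to 12 histories.
- PCoA eigenvalues below 1e−10 of the spectral radius are treated as null;
  Hessians are computed by central finite differences and floored at 1e−8
  of their largest eigenvalue before inversion.
- Round-half-even is used at every trait lattice (so .5 cases do not bias
  upward); severity traits are clipped to [0, 3] after rounding.
- Fires whose sampled size exceeds half the grid are resampled (at most 10
  attempts, with a warning) and then skipped.

## Known limitations

- Shapefile input is not supported; perimeters and units are GeoJSON in a
  projected metric CRS (no reprojection is performed — supply data in the
  grid's CRS).
- The Laplace backend reports Gaussian-approximate posteriors; for final
  inference on real data the emcee backend (or an external sampler) is
  recommended.
- Propagated fits inherit an errors-in-variables attenuation of the
  quadratic burn effect (see above); comparing plain and propagated fits is
  advisable.
- Severity surfaces are taken as given (CBI estimation from imagery is out
  of scope), and pyrodiversity is only as reliable as the severity product,
  which is most robust in forests.
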