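# Methods

## Problem and design

The package implements a cross-sectional ecological analysis: how is the
availability and precision of commercial geospatial data (geocoding,
travel-time, neighbourhood-statistics resources) distributed across
countries relative to health need, measured by age-standardised mortality?
And, at district level, is geocoding success lower in more deprived areas?
Units are populations (countries, districts), never individuals, so all
inferences are ecological.

## Indicator scoring

Provider coverage statements are ordered categories. Scores are the 1-based
position in the worst-to-best level list — arbitrary monotone integers,
because everything downstream is rank-based and only the ordering can
matter (a tested invariance: any strictly monotone transformation of an
indicator's scores leaves every index value unchanged). Countries with no
published coverage statement are scored at the worst level; providers list
absence ("No service", "unavailable") as a level of its own, so absence is
treated as observed worst coverage rather than missingness. Two exceptions:

* the areal-population indicator falls back to the national 2015 population
  when the provider has no data for a country (flagged `fallback`), since a
  country without sub-national statistics is effectively one areal unit;
* a missing areal-attribute count scores zero.

The Google travel indicator is a five-component sum (traffic layer, speed
limits, cycling, walking, driving directions), each scored 2 for good
quality/availability, 1 for approximate, 0 otherwise, giving [0, 10].
Geodemographic availability is a 0–3 count of available products (Mosaic
Global, CAMEO Worldwide, Maptitude). Folding Maptitude into the count
rather than a separate indicator is a design choice; the alternative only
changes K in one domain and the rank-sum absorbs it. A "Not specified"
precision tier ranks below all specified tiers.

## Composite index

Per domain, each country is mid-ranked on each of the K indicators with
rank n = best availability; `lower_better` indicators are inverted before
ranking. Ties take the mean of the tied positions, so ranks always sum to
n(n+1)/2 and a completely tied indicator contributes exactly (n+1)/(2n) per
indicator share — important because with 183 countries and a handful of
ordinal levels, ties dominate. The domain index Σₖ rankₖ(c)/(K·n) lies in
(0, 1]; the overall index sums the three domain indices so a domain with
many indicators cannot dominate. Rank orientation (n = best, so high index
= data-rich) makes the mortality–index relationship come out negative in
sign, matching the geography the index is meant to describe.

## Inequality metrics

Fractional (ridit) ranks: sort units by the exposure (data availability or
affluence) ascending — worst-off first — and give unit i the
cumulative-weight midpoint rᵢ = (W₍<i₎ + wᵢ/2)/W. Tied exposures all
receive their tie group's midpoint, which keeps the weighted mean of r at
exactly 0.5 and makes results invariant to input row order. With equal
weights and no ties, rᵢ = (i − 0.5)/n.

* RCI = 2·cov_w(y, r)/μ, dimensionless in (−1, 1), negative when the
  outcome is concentrated at the worst-off end. A constant-zero outcome has
  no gradient; RCI is defined as 0 with a warning.
* SII = −β from the weighted least-squares fit y = α + β·r: the modelled
  outcome gap worst-off minus best-off, in outcome units. The sign
  convention is fixed once, package-wide: a positive SII always means the
  worst-off (data-poor or most-deprived) end has the higher outcome. Health
  outcomes worse among the data-poor therefore produce positive SII with
  negative RCI; geocoding success higher among the affluent produces
  positive RCI with *negative* SII. Published district-level tables in this
  literature sometimes flip the sub-national sign; we keep one convention
  and document it here.
* CI: SII ∓ t₍1−α/2, n−2₎·SE(β) by default; a seeded case-resampling
  bootstrap (1000 resamples, percentile bounds, re-ranking each resample)
  is available via `ci_method="bootstrap"`.

Countries are unit-weighted by default (each country is one observation);
population or facility-count weighting is available (`weighting`
parameter) and matters mainly sub-nationally, where districts with very few
facilities make success rates noisy.

## Deprivation index and case-study stage

Each census indicator is oriented (+1 if larger = more deprived, −1
otherwise — orientation must be supplied explicitly, since a silent default
would corrupt the index), z-scored across districts with the population
standard deviation (divisor m; the choice cancels in rank-based downstream
use), averaged within its domain, and the six domain means summed. Totals
are invariant to affine rescaling of any raw indicator and sum to zero
across districts. A zero-variance indicator makes z undefined and is a hard
error naming the indicator. Geocoding success is the exact per-district
proportion of attempted place-names returning an in-region location; an
offline bounding-box containment helper is provided, but calling a live
geocoder is out of scope. External development scores (e.g. a district
league table, higher = less deprived) enter through a direction flag.

## Outlier diagnostics

OLS of ln(outcome) on the overall index (natural log; the base only
rescales coefficients, not studentised residuals). Externally
(leave-one-out) studentised residuals — the standard meaning in outlier
screening — with |tᵢ| > 2 flagged two-sided, catching both
high-mortality/data-rich and low-mortality/data-poor countries; internal
studentisation is available. When the fit is numerically exact (residuals
below 1e-10 of the log-outcome scale) residuals are reported as zero rather
than dividing rounding noise by rounding noise. Pearson correlations with
internet use and GDP per capita use pairwise-complete cases with n reported
per covariate.

## Synthetic data

The country generator draws a latent data richness L ~ Uniform(0, 1) per
country that drives *all* indicators — mirroring the empirical fact that
commercial coverage co-varies strongly across providers and with internet
use. Each ordinal indicator observes ρ·L + (1−ρ)·u (fidelity ρ, default
0.9) and is quantile-binned into the indicator's real category set using
the published marginal level frequencies (largest-remainder allocation), so
simulated marginals match the observed coverage snapshot exactly at n = 183.
Component marginals for Google walking/driving directions are not published;
near-universal availability was assumed for those two. Mortality follows
y = exp(a − b·L + N(0, σ)) per cause group with defaults a, b chosen to
give age-standardised rates per 100,000 of realistic magnitude
(all-cause ≈ 500–1300) and a communicable-disease gradient (b = 2.5)
steeper than non-communicable (b = 0.45), so the qualitative cause-specific
ordering is built in and detectable. GDP, internet use and population rise
with L with noise; ~5% of countries lack provider areal statistics
(triggering the population fallback) and ~5% lack GDP.

The district generator draws latent deprivation D ~ N(0, 1), census
indicators loading 0.8 on D with alternating known orientations (2 per
domain × 6 domains), facility counts uniform on 10–80 per district
(≈ 25 districts × ~40 facilities, the scale of a regional facility list),
binomial geocoding success with log-odds c − d·D (defaults c = 0,
d = 0.5), and a development score ≈ 50 − 10·D.

What the generators do *not* emulate: spatial autocorrelation between
neighbouring countries or districts, provider business behaviour,
facility-type heterogeneity in geocodability, and measurement error in the
mortality outcomes themselves. Passing tests therefore demonstrate that the
statistical machinery is correct and well calibrated under the assumed
latent structure — not that real coverage data satisfy that structure.

## Numerical choices and degenerate inputs

Mid-ranks via average-tie ranking; fractional ranks via exact cumulative
midpoints (closed-form identities verified to 1e−12 in tests). Fewer than 2
units cannot be ranked; all-tied exposures make the SII slope undefined
(hard error); n < 3 has no slope standard error; log regression requires
strictly positive outcomes and n ≥ 4. Result CSVs serialise floats with 8
significant digits so write-then-read round-trips to the tested 6.

Problem sizes in the test and acceptance runs — 183 countries, 25
districts, 100–200 replicates for calibration and recovery checks — are the
scales of the analysis the package implements, and run in seconds.

## Known limitations

Inequality indices computed from few ordinal classes are attenuated
relative to ratio-scale indicators (pervasive ties compress the rank
spread), so cross-indicator comparisons of RCI magnitude partly reflect
measurement scale. The composite index weights indicators equally within a
domain; no model-based (e.g. principal-component) alternative is provided.
The analytic SII CI assumes the WLS standard error is adequate at small n;
the bootstrap alternative exists for the 20–25-district case studies.
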