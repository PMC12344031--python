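# Methods

## The occupancy model

The unit of analysis is a site's species × survey-year presence/absence
matrix.  Each species is an independent two-state continuous-time Markov
chain: colonisation at rate *c* (yr⁻¹) from the absent state, local
extinction at rate *e* (yr⁻¹) from the present state, with one shared
(*c*, *e*) pair per site (species equivalence) or per thermal group within
a site.  The generator `[[−c, c], [e, −e]]` has the closed-form transition
kernel

    P(0→1)(Δt) = c/(c+e) · (1 − E),   P(1→1)(Δt) = (c + e·E)/(c+e),
    E = exp(−(c+e)·Δt),

which handles irregular survey gaps exactly: a missing year is a longer Δt
between actual surveys, never an imputed zero.  The stationary occupancy
is c/(c+e); 1/c is the mean waiting time to colonisation and 1/e
("persistence") the mean time to local extinction.

**Likelihood.** The likelihood conditions on each species' first observed
state and multiplies the transition probabilities of all consecutive
observation pairs.  No stationarity assumption is made at series start (a
stationary initial term can be added but is not the default, since
communities near range edges need not start at equilibrium).  Because the
kernel depends only on the interval length and the two states, the per-Δt
transition counts (N00, N01, N10, N11) are a sufficient statistic; the
package computes the NLL from those counts and the test-suite cross-checks
it against a brute-force per-pair product over the raw matrix.

**Estimation.** Rates are optimised on the log scale (L-BFGS-B, NLL
tolerance ~1e−12 on the optimiser's scale) with 5 multi-starts jittered
around an analytic starting point: for a single-Δt (regular) design the
exact closed form

    T01 = N01/(N00+N01),  T10 = N10/(N10+N11),
    c + e = −ln(1 − T01 − T10)/Δt,  c = (c+e)·T01/(T01+T10),

otherwise a smoothed moment analogue pooled over intervals.  T01+T10 ≥ 1
admits no continuous-time chain (embedding failure) and raises.  Rates are
bounded to [1e−6, 1e3] yr⁻¹; a series with no observed colonisations (or
extinctions) has its rate pinned at the lower bound with a boundary flag
and a warning, never silently.  Standard errors come from the
finite-difference observed-information Hessian at the optimum; profile
likelihood was considered and dropped as the Wald intervals already cover
nominally in the recovery checks.

**Covariate links.** Rate–environment relationships use
c_j = exp(β₀c + β₁c·x_j) and e_j = exp(β₀e + β₁e·x_j) with one covariate
at a time (latitude in °N, mean abundance on the natural-log scale, or
species-pool size), the summed per-site NLL minimised over the four βs.
Separate models per covariate are deliberate: the site covariates are
strongly collinear along a latitudinal gradient and a multivariable fit
would be unidentifiable in practice.  Thermal-group models get
group-specific intercepts and slopes.  Covariates are used raw by default
so slopes are per-unit; standardisation is a config switch (the analysis
drivers standardise latitude so slopes are comparable with the generator's
coefficients).  Persistence slopes are reported as −β₁e, i.e. the slope of
log persistence; the sign convention is stated in every output table.

**Species universe per site.** A site's series contains the species
observed there at least once: long-format monitoring data carries no rows
for never-observed species, so this is what observed data can support.
Conditioning on ≥1 occurrence inflates colonisation rates slightly when
occupancy is very low; at the default study's rates the effect is below
the sampling noise (the recovery checks pass with this universe).  A
`species_universe` argument forces a fixed list (used to stress-test the
estimator with structurally absent rows).

## Thermal indices and pools

STI is an input (°C, mean temperature across the species' range); the
package never computes it from atlases or climate grids.  CTI is the
abundance-weighted mean STI over the STI-bearing species of a site-year;
species without STI are excluded from numerator and denominator but are
retained in richness, abundance and pool counts.  Thermal groups are the
STI quartiles (empirical 25/50/75 percentiles, linear interpolation), with
boundary ties assigned to the colder group — a deterministic, documented
rule.  Species pools use whole-dataset latitudinal ranges: a species is in
a site's pool iff its min/max observed latitude brackets the site
(inclusive).  The pool is time-invariant by default, chosen for stability;
a per-year pool is possible in principle and can make observed richness
exceed the pool, which the net-rate code clamps with a warning.

Singletons are defined per site (total count of 1 across the site's whole
series), since the occupancy series are per site; a dataset-wide mode
exists.  Sample coverage uses the abundance-based estimator
Ĉ = 1 − (f₁/n)·[(n−1)f₁/((n−1)f₁ + 2f₂)] from singleton and doubleton
frequencies.  Dataset filters (≥10 surveyed years, first survey ≤2005) are
config values, not hard-coded.

## Equilibrium and trend inference

Equilibrium richness is S\* = Sp·c/(c+e), the balance point of net
colonisations c(Sp−S) and net extinctions e·S.  CTI_pred weights each
group's mean STI by S\*; CTI_obs uses observed group richness.  The group
mean STI per site is taken over the group's *pool members* at that site
(not the observed community): the weighting by richness is already doing
the observational work, and an observed-members mode is available for
sensitivity.  Groups absent from a pool contribute zero weight.

The slope-vs-1 equilibrium test subtracts the prediction as an offset and
tests the slope of (obs − pred) on pred; this is algebraically identical
to testing slope = 1 in the direct regression and the tests verify the two
constructions agree to machine precision.  The latitude divergence test
stacks predicted and observed CTI (2n rows) and tests the
Latitude × PredictionType interaction.

The temporal model is CTI ~ Year·Latitude with a random site intercept,
fitted by REML (statsmodels MixedLM).  Year and latitude are centred
internally for numerical stability — the year coefficient is then the
trend at the mean latitude, and the interaction is unchanged — and
reported slopes are back-transformed to °C/yr at a chosen latitude via
`slope_at()`.  Terms are tested with type II Wald χ²: for block b with
covariance V, χ² = b′V⁻¹b with df = |b|, computed directly from the
fixed-effect covariance so results do not depend on any one library's
ANOVA conventions.  Both per-term tests and the pooled
(Year, Year×Latitude) df=2 test are reported.  If the site variance
collapses the model falls back to fixed-intercept OLS with an explicit
flag; random slopes are out of scope.

## The synthetic study

The generator emulates a national light-trap-style monitoring scheme: 60
sites spaced along 59.8–69.8°N, annual surveys 1993–2022 with 5% of
site-years missing, and 300 species with STIs ~ N(8.0, 2.5²) °C.  Northern
range limits decline with STI at 1.2° latitude per °C (Gaussian noise, sd
1.5°), southern limits sit mostly below the gradient (N(55, 2.5²)), so
warm-affiliated groups drop out towards the north.  Rates follow the
exponential link on standardised latitude with β₀c = −1.0, β₁c = −0.4,
β₀e = −0.8, β₁e = 0.6 — colonisation rarer and extinction commoner at high
latitude, with site-level rates spanning roughly 0.2–0.8 yr⁻¹ for c and
0.16–1.3 yr⁻¹ for e.  Counts given presence are log-normal (ln mean 3.4 at
60°N, declining 0.12 per °N, sd 0.8), rounded with a floor of one
individual — chosen over a negative binomial for simplicity; dispersion is
configurable.  Occupancy chains start at stationarity.  One global seed
drives separate RNG streams for the species pool, occupancy, missingness
and abundances, so stages are independently reproducible and fixed seeds
give byte-identical tables.

What the generator does *not* emulate: detection failure (presence is
observed perfectly), within-year phenology and trap-level sampling,
per-species rate heterogeneity within a group (available only as a
stress-test option), temporal climate forcing (the process is stationary,
so CTI trends act as a negative control), and spatial autocorrelation
beyond the latitude link.  Passing recovery tests therefore show that the
estimators are correct *under the model's assumptions*; they cannot show
robustness to imperfect detection or non-stationary warming, which real
monitoring data will contain.

## Problem sizes and numerical choices

The statistical checks run at the sizes the questions need while staying
desk-scale: likelihood exactness on 200 random small matrices (1e−10),
closed-form/numerical agreement on 50 regular sites (1e−4 relative), link
recovery over 50 replicates of the full 60 × 300 × 30 design (bias <5% of
each β, ≥90% CI coverage), equilibrium-regression calibration and power
over 200 replicates at n=62 sites (pred spread ~1 °C, residual sd 0.1 °C,
the scale of between-site CTI variation), trend recovery over 100
replicates (site intercept sd 0.3 °C, yearly noise sd 0.2 °C, slopes
+0.02→+0.03 °C/yr across 60→70°N), and stationarity at 500 species × 200
years (±0.02).  Ties, degenerate inputs and boundaries all have explicit
behaviour: zero-probability transitions return +∞ NLL rather than raising,
empty pools are valid (zero weight), all-absent matrices raise, and a
zero-residual equilibrium regression reports F = 0 for the slope-vs-1
test.

## Known limitations

Per-species rates, imperfect detection and spatially explicit colonisation
are out of scope by design.  Rate estimates at range edges often sit near
boundaries (few transitions of one kind); these carry flags and should be
filtered or down-weighted downstream.  The "average time to colonisation"
of a dataset is reported as the mean of 1/c across sites; the reciprocal
of the mean rate is also computable from the rates table — the two differ
by Jensen's inequality and the choice is stated where reported.
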