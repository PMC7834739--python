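# Methods

This note records the statistical models implemented in `zooptrends`, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical decisions a maintainer would want to know.

## Anomaly statistic

Zooplankton biomass from vertical net tows is strongly seasonal,
multiplicative and zero-inflated, and the sampling effort is uneven across
seasons and years. The anomaly engine therefore:

* aggregates samples into seasons (winter = December of the previous
  calendar year + January + February; then MAM, JJA, SON), so a December tow
  counts toward the following year;
* computes the **arithmetic mean first, then log10** within each
  season–year (`zbar = log10(mean biomass)`), the convention for biomass
  time series because the mean of a skewed biomass distribution — not the
  geometric mean — is the ecologically meaningful stock; a one-unit change
  in the resulting anomaly is a ten-fold biomass change, and anomalies of
  the base period average exactly to zero per season;
* replaces true zeros, per variable over **all** of its samples (not per
  season), by uniform draws on (0, min_nonzero/2). Replacement happens at
  the per-sample level before averaging, with one RNG stream per variable
  derived from a master seed (stable CRC-based derivation), so runs are
  reproducible and adding a variable does not change another's draws. The
  perturbation of a seasonal mean is bounded by min_nonzero/2 per replaced
  sample;
* uses climatology years 1996–2010 (15 years; the data begin in 1996, so a
  standard 30-year climatology is unavailable) and drops years with no
  spring or summer observation — winter/fall-only years say little about the
  biomass season;
* multiplies daytime adult-euphausiid biomass and abundance by 3 before
  averaging, offsetting visual net avoidance by large, mobile euphausiids
  (night catches of the same animals run roughly three-fold higher);
* keeps tows from the deep (> 50 m) central/northern basins that cover most
  of the water column: start depth > 150 m, or ≥ 70% of the column where the
  bottom is shallower than 150 m.

Collinearity screening computes Pearson correlations on pairwise-complete
years and removes variables with |r| > 0.60 against **two or more** partners,
greedily by descending partner count (alphabetical tie-break), recomputing
partner counts among survivors after each removal. "Two or more" makes the
rule deterministic and reproduces the intended behaviour (a variable with a
single high correlation survives; a hub correlated with many is removed).
Perfectly correlated survivors (|r| = 1) are exact duplicates for any
downstream model, so only the alphabetically first of such a pair is kept.

## Physical drivers

Each series is reduced to seasonal means at its native cadence and
normalized against the 1996–2010 base period: `(v - mean_season)/sd_season`,
sample SD (n−1). Annual anomalies average the seasons available. Wind speed
is converted to stress per observation (`tau = rho_air C_D U^2`, rho_air =
1.22 kg/m³, C_D = 0.0013) *before* averaging, because squaring does not
commute with the mean; annual-event variables (Fraser peak-flow day, spring
bloom day) carry one value per year and are normalized at annual cadence.
Peak-flow day is the ordinal day of the annual maximum daily flow, earliest
day on ties, requiring ≥ 300 daily values per year.

## Dynamic factor analysis

The DFA is the standard Gaussian state-space form: k latent random walks
with identity innovation covariance, free loadings Z with zeros above the
diagonal in the first k rows (the usual identification), and observation
error covariance R constrained to one of: diagonal-equal, diagonal-unequal,
equal variance + common covariance, or unconstrained. Inputs are z-scored by
default (series are anomalies on different scales; z-scoring makes loadings
comparable and is the conventional choice — a `zscore=False` switch exists
and the acceptance script reports the selection under both).

Estimation is EM. The E-step is an exact Kalman filter/smoother; missing
observations are handled by dropping the corresponding observation rows at
each time step, and the complete-data sufficient statistics fill in the
conditional moments of the missing entries (for non-diagonal R this uses the
regression of the missing error block on the observed one). The M-steps are
closed form: a GLS update of the free loading entries and a projection of
the residual moment matrix onto the R structure (each structure is a
quadratic subspace, so the projection is the exact constrained maximizer).
Both are conditional maximizations, so the exact log-likelihood is
non-decreasing across iterations — asserted in the tests. The initial state
is fixed at zero with prior variance 5·I; convergence is a relative
log-likelihood change below 1e-6 with a 2000-iteration default cap
(non-convergence is flagged, never raised); initialization is a
deterministic SVD-based start, with optional seeded jittered restarts.

Model comparison uses AICc with n = the number of non-missing observations
and K = free loadings (mk − k(k−1)/2) plus R parameters (1, m, 2, or
m(m+1)/2). These conventions were validated against a published DFA
comparison table whose AICc deltas they reproduce to the printed precision.
The search grid is k = 1..m−1 over the four structures (44 candidates for 12
series, 36 for 10). The chosen model is varimax-rotated (via
`statsmodels.multivariate.factor_rotation`) with the inverse rotation
applied to the trends, leaving fitted values unchanged to machine precision,
and each trend's sign is set so its largest-|loading| is positive.

## Chronological clustering and broken stick

CONISS-style agglomeration: clusters are contiguous year runs; each step
merges the adjacent pair with the least increase in within-group sum of
squares about the centroid. Merge costs telescope, so the cumulative cost at
k clusters equals that partition's within-group dispersion. Greedy
agglomeration does not guarantee the globally optimal k-partition on
arbitrary data; the tests assert the exhaustive lower bound at every k and
exact agreement of the top split when genuine block structure exists.

The number of significant zones uses a broken-stick comparison estimated by
randomization: the total dispersion is divided among T contiguous groups of
random lengths (uniform stick breaking, 1000 draws by default, seeded), and
the observed proportional dispersion drop of the j-th split must exceed the
mean j-th largest random share; scanning stops at the first failure. On
i.i.d. noise this yields one zone in the large majority of replicates, and
on two well-separated blocks exactly two.

## Regression ladder

Responses are the latent trends, the total-biomass anomaly, and per-stock
salmon survival transformed to a centred/scaled logit
(`alpha = logit(p)`; back-transform `S = exp(beta)/(exp(beta)+1)` with
`beta = alpha*scale + centre`; sample SD, preliminary-status years excluded
from the centring but still transformed). The ladder:

1. **KPSS** trend ('ct') and level ('c') tests on the response; p < 0.05
   triggers first-differencing of response and covariates (p-values in
   [0.045, 0.05) are accepted with a logged warning — the ARIMA stage
   re-checks autocorrelation anyway).
2. **Best subsets**: exhaustive minimum-RSS subset per size 1–5 on complete
   cases, no interactions.
3. **ARMA errors**: each size winner is refit as regression-with-ARMA-errors
   by MLE. The differencing order is fixed by step 1 (information criteria
   are not comparable across differencing); (p, q) ≤ 3 are searched by AICc
   with the conventional stepwise neighbourhood walk from (0,0)/(1,0)/(0,1)/
   (2,2) — a full-grid option exists but multiplies both runtime and the
   chance of spurious MA terms at n ≈ 20.
4. **Validity filter**: every covariate's 95% CI must exclude zero and the
   Ljung-Box residual p (lag min(10, n/5)) must exceed 0.05; lowest AICc
   wins, with a nested-model F-test deciding ties within 2 AICc units.
   No survivor means "no valid model" — a legitimate outcome, returned as
   such.
5. **OLS finalization** for (0,0,0) winners: adjusted R², overall F p-value,
   residual/leverage/QQ diagnostics as data tables.

Predictive skill is 5-repeat 5-fold CV; the per-repeat score is the squared
Pearson correlation of pooled out-of-fold predictions with observations,
averaged over repeats (the convention of the common CV tooling). Prediction
intervals come from the OLS prediction variance (parameter + residual) and
pass monotonically through the survival back-transform.

## Synthetic generator

The generator emulates the monitoring program's statistical structure:

* two latent annual trend shapes with a seeded random-walk wiggle (a U-shape
  with a late-2000s minimum and a rise-then-decline; the physical block has
  a ~decadal sinusoid and an early-2000s dome), standardized to SD 1;
* 12 taxon groups loading on the zooplankton trends on the log10 scale, with
  lognormal per-sample biomass (sigma_log10 = 0.45 — typical order for
  plankton tows), group-specific zero-inflation, and day/night flags and
  depths that satisfy the tow-selection rules;
* the program's historical per-season sample counts (4–27 samples/yr in the
  sparse 1996–2007 era, 61–156 in 2015–2018) as the default effort pattern;
* 16 candidate physical variables at native cadence (hourly wind, daily
  SST/SSS/flow, monthly indices, annual bloom date) as seasonal cycle +
  loadings on the two shared axes + AR(1) noise + year-level idiosyncratic
  noise. The year-level noise keeps the retained variables below the 0.60
  screen while the redundant basin indices shadow the shared axes closely
  enough to be screened out, as in the real data;
* survival drawn from a logistic-linear model of the realized anomaly
  covariates. Relative coefficient weights follow the published model forms;
  the linear predictor is rescaled so the signal explains a per-stock target
  fraction (0.45–0.85) of the standardized-logit variance, putting fits in
  the range reported for such stocks. Generating coefficients, centring constants and the
  noiseless predictor are stored for recovery tests.

What the generator does **not** emulate: spatial station structure, species
composition within groups, within-season dynamics beyond a fixed seasonal
offset, gear or preservation effects, and observation error in the physical
sensors. Passing tests therefore demonstrate that the pipeline recovers
known structure under realistic sampling noise and effort imbalance — not
that the ecological conclusions drawn from the real monitoring data are
correct.

## Effort resampling

The resampling experiment asks whether uneven effort alone could produce an
anomaly pattern: each repetition subsamples every year's pool to a fixed
effort (default 12 tows/yr, the sparse-era average) without replacement,
stratified by season in proportion to the dense-era seasonal profile
(unstratified draws would conflate effort level with seasonal coverage),
recomputes the full anomaly pipeline, and records the annual anomalies. The
summary is per-year means/quantiles and the probability of a run of
`run_length` consecutive years below an anomaly threshold (defaults −0.10
and 5). Census draws (subsample = pool) reproduce the full-data anomalies
exactly — asserted in the tests.

## Problem sizes and determinism

Tests and the acceptance script run program-sized problems (23 years, 12 +
16 variables, 44/36-trial DFA searches, 1000-repetition broken-stick and
effort randomizations) and scale the pure Monte-Carlo experiments (recovery
rates, coverage) to 60–300 seeded replicates, sizes at which the asserted
majorities and tolerances are stable. All randomness flows from explicit
seeds; reruns are bit-reproducible.

## Known limitations

* The DFA EM can converge slowly near flat ridges (high k with little
  residual structure); such fits are flagged `converged=False` but retained
  in comparison tables, mirroring common practice.
* The broken-stick zone count is a null-comparison heuristic, not a formal
  test; its Monte-Carlo form converges to the classical expectation
  (1/T)·Σ_{i≥j} 1/i.
* Best-subsets selection at n ≈ 20 with ~20 collinear candidates is
  intrinsically unstable; neighbouring proxies substitute freely for the
  generating covariates. The package reports what was selected and its
  cross-validated skill rather than pretending selection is consistent.
* KPSS p-values are interpolated within [0.01, 0.1] (the statsmodels
  convention), so "p > 0.1" is reported as 0.1.
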