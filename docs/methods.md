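# Methods

This note records the models, numerical choices, and open design decisions
behind `odbatools`, and what the synthetic-data generator does and does not
establish.

## ODBA processing

Raw tri-axial counts are windowed into non-overlapping 2 s windows tiled
from the first sample; a partial trailing window is dropped. Per window and
channel the dynamic component is `(mean − (max + min)/2) / counts_per_g`;
ODBA is the L1 norm of the three components. Subtracting the within-window
midpoint removes the static (gravity) component, so constant channels give
exactly zero. "Midpoint" is read as the within-window (max + min)/2; a
device-static alternative would change only the gravity removal, and the
within-window reading is the one that makes a motionless logger score zero
regardless of orientation.

Minutes are arithmetic means of member windows, hours are sums; partial
minutes/hours at the series edges are flagged `complete=False` and excluded
from modeling. Boundary semantics are strict throughout: a minute is active
only *strictly above* the threshold, an hour only with *strictly more than*
30 active minutes. The default activity cut is 0.28 g on minute-averaged
ODBA; `threshold_sensitivity` provides an Otsu-style scan (between-class
variance of log minute-ODBA, computed on log(x + 1e-6) so zero minutes are
admissible) whose full table is exposed so a user can override the
recommendation. On well-separated bimodal data the log-scale optimum can
sit close above the resting cluster rather than mid-way between modes; the
scan is a calibration aid, not an oracle.

Nights run noon-to-noon in a single fixed UTC offset (deployments of one
to two weeks within a season never straddle a DST change, so no DST
arithmetic is attempted). A *bout* is a maximal run of active minutes
separated from the next by ≥ 60 consecutive inactive minutes (evaluated at
minute resolution); nights are `single_bout` (activity with no ≥ 60 min
interior gap), `gap_resumed` (activity, a ≥ 60 min gap, renewed activity),
or `other` (no activity). The first deployment day (post-release
disturbance) and the last (uncertain recapture time) are removed as whole
noon-to-noon units.

## Solar events and night weather

Sunset/sunrise use the standard NOAA solar-position equations (fractional
year, equation of time, declination; zenith 90.833°), good to a few
minutes at temperate latitudes and verified against almanac values in the
tests; |latitude| > 66.5° is rejected rather than approximated. Night
weather covariates average hourly values whose hour-start falls in
[sunset, sunrise); rainfall is summed rather than averaged, because a
night's water exposure is an accumulation while temperature is a state —
the one place where an aggregation convention had to be chosen.

## Hourly models

Response: log2 hourly ODBA (hours of zero summed ODBA cannot be logged and
are treated as missing for the Gaussian model; they still count as
inactive hours for the binomial model). Design: intercept, a cyclic cubic
regression spline of hour of day, and standardized covariate terms.

The spline basis is the cardinal (value-at-knot) parameterization of a
periodic natural cubic spline on K = 10 evenly spaced knots (value, first-
and second-derivative continuity across the 0/24 wrap; verified against
scipy's periodic cubic interpolation). The columns sum to one, so one is
dropped against the intercept. The basis is fitted **unpenalized**: at
hourly resolution with thousands of observations a 10-df circadian curve is
not overfit, and an unpenalized basis keeps the AIC parameter count exact
for all-subsets selection. This is a deliberate simplification relative to
a penalized smoother with data-driven smoothing; its cost is a fixed,
modest resolution for the circadian shape.

Weather covariates are z-standardized (sample SD, n−1) within season on
the modeling subset; quadratic terms are squares of the standardized
values, interactions are products. Traits (age, BCI) are standardized at
the individual level. The design-matrix builder rejects unstandardized
weather mains (|mean| > 0.01 or |SD − 1| > 0.01); the check is skipped for
prediction scenarios and cross-validation folds, which inherit the full
data's transform and are not themselves exactly standardized.

**Gaussian fit.** Random intercept per individual, optional independent
random slope on one standardized covariate (no intercept–slope
correlation: with ≤ ~20 individuals the correlation is weakly identified
and the scientific question — is there slope variance at all? — does not
need it), and AR-1 residuals within each contiguous hourly run of an
individual-deployment series; a gap in the record resets the correlation.
Estimation is direct profiled maximum likelihood: the AR-1 precision is
tridiagonal, the random-effect contribution is handled by the Woodbury
identity, and beta is the GLS solution at each variance-parameter trial, so
one likelihood evaluation is O(n·p). Nelder-Mead optimizes
(log σ_e, log σ_b[, log σ_s], atanh ρ). ML rather than REML is used
throughout so AIC is comparable across fixed-effect subsets; the cost is
the usual slight downward bias in variance components at small group
counts. AIC = −2 logLik + 2k with k counting fixed coefficients and every
estimated variance/correlation parameter; ties break toward fewer
parameters. σ_b shrinking below 10⁻³·σ_e is flagged `boundary`, not an
error. R² is the squared correlation between conditional fitted values
(fixed effects + BLUPs) and the observed response.

**Binomial fit.** Logit link, random intercepts, Laplace approximation
with a joint penalized Newton inner loop for (beta, b) and a bounded
scalar search over log σ_b. Classification accuracy (0.5 cut) and the MCC
are computed from *conditional* predictions — each individual's estimated
intercept is used — because the scientific claim is about how well the
model reconstructs that individual's hourly activity. Selection for the
activity response runs without residual autocorrelation (a computational
concession); the selected spec is then refitted as a marginal GEE with an
AR-1 working correlation (statsmodels) and that coefficient table is
attached for comparison.

**Selection.** All subsets of the full term list that respect marginality
(quadratic only with its linear term, interaction only with both mains)
and never contain a forbidden collinear pair (|Pearson r| ≥ 0.7 within
season by default — a conventional screen; the threshold is configurable).
Term importance is the percentage of models within 2 AIC of the best that
contain the term. Enumeration is capped at 12 terms (2^12 subsets).

**Random-slope tests.** One model per candidate covariate; ΔAIC against
the random-intercept base and a likelihood-ratio p-value under the 50:50
χ²₀/χ²₁ boundary mixture (p = 1 by convention when the statistic is ≤ 0).

**Daily prediction.** Per scenario hour, 2^(fixed-effect prediction),
summed over 24 h; uncertainty by the delta method on the linear predictor
(gradient ln2·Σ 2^η·x), cross-checked against Monte-Carlo summation in the
tests. Plasticity surfaces evaluate these daily totals over a temperature
grid at named BCI levels with all other standardized covariates at 0;
points outside the observed temperature range are flagged as
extrapolation.

## Night-scale models and repeatability

Total nightly ODBA (log2) and nightly active minutes are modeled with the
same mixed-model core (no AR-1 across nights), using the night-averaged
covariates selected by the hourly model — including the individual-level
terms (BCI and its interactions), without which genuine trait-driven
differences would masquerade as intercept variance. ICC =
σ²_ind / (σ²_ind + σ²_resid). A replication floor (≥ 5 individuals with
≥ 3 nights, configurable) guards against meaningless variance splits.
Cross-season consistency takes the conditional-mode intercepts per season
and computes Spearman correlations over shared individuals (≥ 3 required).
Nightly disparity is the per-night max/min ratio of total ODBA across
individuals (nights with a zero minimum are excluded and counted).

## Synthetic data: the stated world

Defaults: 2 s windows, 50 Hz sampling (the logger's rate is not fixed by
the analysis, so it is configurable; 50 Hz is typical for collar
accelerometers), counts-per-g 2^14, signed 16-bit counts, gravity as a
constant +1 g on the z axis. Weather presets (spring/summer/autumn) use
temperate-woodland values: e.g. spring mean 11 °C, diurnal half-amplitude
4 °C, day-to-day SD 2.5 °C with AR-1 0.6, 85% dry hours with exponential
wet-hour intensity 0.5 mm. Soil temperatures are exponential smoothings of
air temperature (12 h and 48 h memory), which deliberately induces the
Temp–SoilT collinearity the screen must catch, without an explicit
covariance matrix.

Hourly ODBA: log2 ODBA = circadian profile + Σ β·standardized terms +
individual intercept + AR-1 noise. The default circadian profile is a
bimodal nocturnal curve (cosine-shaped bumps at 22:00 and 04:00 over a
daytime baseline of 2 log2 units), periodic by construction. Default
β: Temp +0.30, Temp² −0.15, Rain +0.15, Rain² −0.08, Wind −0.10,
SoilM +0.10, SoilT30 −0.10, BCI −0.05, BCI×Temp +0.20; σ_ind = 0.30,
σ_resid = 0.50, ρ = 0.40. The binary ground truth thresholds the implied
flat minute ODBA (hourly/60) at 0.28 g; a separate logistic generator
(intercept −1, circadian scale 1.5, Temp +0.8, Temp² −0.3, shared
individual intercepts) provides a stochastic activity response for
binomial recovery tests. With ρ = 0 the generative hourly ICC is
σ_b²/(σ_b² + σ_e²); aggregating H hours gives the night-scale ICC
σ_b²/(σ_b² + σ_e²/H). The measured night-scale residual SD of log2 nightly
totals under the default generator is ≈ 0.18.

Raw-window synthesis inverts the ODBA computation: each window carries a
single-sample integer excursion on two channels (half the target each)
whose mean-minus-midpoint lands on the target; quantization of the
excursion bounds the round-trip error below one count unit (1/2^14 g).

What a green test does **not** establish: the generator has no
biomechanical gait content (dynamic acceleration is statistical), no
missing-data patterns, no device drift or temperature dependence of the
sensor, no behavioural states beyond the circadian/weather structure, and
individuals share one weather series. Recovery results therefore speak to
the correctness of the estimation machinery under the assumed model, not
to robustness against real-world artefacts.

## Degenerate inputs and conventions

- Zero SDs are legal in the weather generator (degenerate, noise-free
  worlds used by the tests); negative SDs and out-of-range probabilities
  are rejected.
- MCC returns 0 (flagged by convention) when any confusion margin is
  empty; an all-one-class response is rejected before fitting.
- Constant minute-ODBA series yield a threshold scan with no
  recommendation rather than an arbitrary cut.
- Deployments of ≤ 2 noon-to-noon days produce an empty, warned result
  from the day filter.
- Identical seeds and configurations give bit-identical generator output
  and bit-reproducible fits.

## Known limitations

- The unpenalized 10-knot circadian spline cannot adapt its smoothness;
  very sharp activity onsets bias σ_e slightly upward.
- The Laplace approximation for the binomial model is first-order
  (lme4-style adaptive quadrature would be more accurate at small group
  sizes); conditional in-sample accuracy carries mild optimism, which the
  grouped cross-validation quantifies.
- The GEE AR-1 refit estimates marginal, not conditional, coefficients;
  the two are attached side by side rather than reconciled.
- All-subsets selection refits every candidate from scratch; beyond ~10
  terms this is the dominant cost.
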