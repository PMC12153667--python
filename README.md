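# odbatools

Accelerometry-to-energetics analysis for nocturnal mammals: from raw
collar-logger counts to overall dynamic body acceleration (ODBA), binary
activity budgets, seasonal hierarchical weather-response models, and
individual repeatability and plasticity. The package was written for
biologging studies of the kind run on European badgers (*Meles meles*) —
short seasonal collar deployments on a wild cohort alongside an hourly
woodland weather station — but every step is generic.

## What it computes

**ODBA.** For each 2 s window of a tri-axial series, each channel's dynamic
component is the difference between its mean and its midpoint
((max + min)/2), divided by the logger's counts-per-g scale (default 2^14);
ODBA is the L1 norm

```
ODBA = |A_x| + |A_y| + |A_z|
```

Window ODBA rolls up to minute means and hourly sums. A minute is *active*
when its ODBA exceeds a calibrated cut (default 0.28 g, and an Otsu-style
between-class-variance scan is provided to calibrate it); an hour is active
when strictly more than 30 of its minutes are; nights run noon-to-noon and
carry total ODBA, active minutes, and a bout category (one unbroken bout
vs. activity resumed after a ≥ 60 min gap).

**Hourly models.** log2 hourly ODBA is modeled as a cyclic cubic regression
spline of hour of day plus standardized weather terms (with quadratic
temperature and rainfall and body-condition interactions), individual
random intercepts, and AR-1 residuals within each contiguous run of hours
— fitted by direct maximum likelihood. Hourly activity gets the analogous
binomial mixed model (Laplace approximation), with an AR-1
working-correlation refit of the selected specification. All-subsets AIC
selection respects marginality and never pairs collinear covariates
(|r| ≥ 0.7 by default).

**Repeatability and plasticity.** Night-scale mixed models yield the
intra-class correlation ICC = var(individual) / (var(individual) +
var(residual)); random-slope comparisons and condition-by-temperature
prediction surfaces quantify how individuals differ in their weather
response; daily ODBA is predicted by summing 2^(hourly prediction) over a
24 h covariate scenario. Body condition is indexed as
BCI = ln(mass in kg) / ln(length in cm). Classifier quality uses the
Matthews correlation coefficient and individual-night-grouped k-fold
cross-validation. A diet module tabulates fecal chaetae counts and monthly
frequency of occurrence (FO) / relative frequency of occurrence (RFO).

**Synthetic data.** `odbatools.synthetic` generates weather (sinusoidal
diurnal cycles, AR-1 day-to-day persistence, zero-inflated rain, soil
temperatures as lagged smoothings of air temperature), trait cohorts,
hourly ODBA/activity with known generative parameters, and raw count-level
windows whose computed ODBA matches prescribed minute values — the ground
truth for all recovery tests.

## Worked example

```python
from odbatools.modeling import ModelSpec, fit_lmm_ar1
from odbatools.synthetic import TrueParameters, make_cohort, simulate_hourly_odba

params = TrueParameters()                      # rho=0.4, sigma_b=0.3, sigma_e=0.5
cohort = make_cohort(n_individuals=20, n_days=9, season="spring", seed=11)
data, record = simulate_hourly_odba(cohort, params, seed=12)
fit = fit_lmm_ar1(data, ModelSpec(fixed_terms=tuple(params.beta), ar1=True, n_knots=10))
print(fit.summary())
```

prints (abridged):

```
lmm_ar1: n=4320, k=22, logLik=-2803.28, AIC=5650.56, R2=0.858
sigma_individual=0.3835  sigma_resid=0.4977  rho=0.389
            Temp    +0.2846  (SE 0.0202)
           Temp2    -0.1490  (SE 0.0099)
      BCI_x_Temp    +0.2030  (SE 0.0109)
```

(the full table also lists the nine spline coefficients and the remaining
weather terms). The AR-1 coefficient (true 0.40), residual SD
(0.50), the quadratic temperature response (+0.30 / −0.15) and the
positive condition-by-temperature interaction (+0.20) are all recovered;
the implied temperature optimum back-transforms to 15.3 °C against a
generative 15.5 °C. `examples/` contains one narrative script per
capability (raw counts → ODBA; nights and bouts; hourly models and CV;
selection with the collinearity screen; repeatability and plasticity;
diet tables).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's analytic endpoint targets from scratch: it
constructs a balanced 100-hour active/inactive label vector, evaluates the
Matthews correlation coefficient of a perfect classifier and of its exact
complement from the confusion counts, and writes the two values as JSON.
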