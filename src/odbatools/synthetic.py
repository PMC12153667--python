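"""Synthetic weather, cohorts, and accelerometry with known generative truth.

The study system this emulates: a nocturnal, burrow-dwelling mustelid
population carrying collar accelerometers for one-to-two-week seasonal
deployments, alongside an hourly woodland weather station.  The generator
reproduces the statistical structure the downstream analysis assumes —
and exposes every generative parameter so model-recovery tests have an
unambiguous ground truth:

- weather with sinusoidal diurnal cycles, AR-1 day-to-day persistence,
  zero-inflated rainfall, and soil temperatures formed as lagged smoothings
  of air temperature (which induces the collinearity the screen must find);
- a bimodal nocturnal circadian ODBA profile (activity peaks shortly after
  dusk and again before dawn, a midnight lull, and near-rest by day);
- log2 hourly ODBA that is linear in standardized weather terms, including
  quadratic temperature/rain and a body-condition-by-temperature
  interaction, with lognormal-scale individual intercepts and AR-1
  residuals;
- raw count-level tri-axial windows whose computed ODBA matches prescribed
  minute values to within one count-quantization unit.

Identical seed and configuration give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .accelerometry import DEFAULT_COUNTS_PER_G, DEFAULT_THRESHOLD, TriaxialSeries
from .modeling.design import expand_terms
from .weather import WeatherSeries, compute_bci, standardize

__all__ = [
    "SeasonConfig", "SEASON_PRESETS", "TraitConfig", "TrueParameters",
    "SyntheticCohort", "bimodal_nocturnal_profile", "simulate_weather",
    "simulate_individuals", "make_cohort", "simulate_hourly_odba",
    "simulate_hourly_activity", "synthesize_raw_windows", "write_dataset",
]

_INT16_MAX = 32767


@dataclass(frozen=True)
class SeasonConfig:
    """Mean/SD/diurnal-amplitude configuration of the weather generator.

    SDs of zero are legal (degenerate, noise-free weather); negative SDs
    and zero-inflation probabilities outside [0, 1] are rejected.
    """

    temp_mean: float = 11.0          # degC
    temp_amp_diurnal: float = 4.0    # degC, half peak-to-trough
    temp_sd_day: float = 2.5         # degC, SD of day-to-day means
    temp_ar1: float = 0.6            # day-to-day persistence
    temp_sd_hour: float = 0.5        # degC, hourly noise
    rain_p_zero: float = 0.85        # zero-inflation probability per hour
    rain_mean_mm: float = 0.5        # mean intensity of wet hours
    wind_mean: float = 3.0           # m/s
    wind_sd: float = 1.5
    rh_mean: float = 82.0            # %
    rh_amp: float = 8.0
    rh_sd: float = 4.0
    soilm_mean: float = 35.0         # % volumetric
    soilm_sd: float = 3.0
    soil_noise_sd: float = 0.2       # degC on soil temperatures
    start_date: str = "2018-05-01"

    def __post_init__(self):
        for name in ("temp_sd_day", "temp_sd_hour", "wind_sd", "rh_sd",
                     "soilm_sd", "soil_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.rain_p_zero <= 1.0:
            raise ValueError("rain_p_zero must lie in [0, 1]")
        if not abs(self.temp_ar1) < 1:
            raise ValueError("temp_ar1 must lie in (-1, 1)")


SEASON_PRESETS: dict[str, SeasonConfig] = {
    "spring": SeasonConfig(temp_mean=11.0, start_date="2018-05-01"),
    "summer": SeasonConfig(temp_mean=16.0, temp_sd_day=2.0, rain_p_zero=0.9,
                           rh_mean=78.0, soilm_mean=28.0, start_date="2018-09-01"),
    "autumn": SeasonConfig(temp_mean=7.0, temp_amp_diurnal=3.0, rain_p_zero=0.78,
                           rain_mean_mm=0.7, rh_mean=88.0, soilm_mean=40.0,
                           start_date="2018-11-01"),
}


@dataclass(frozen=True)
class TraitConfig:
    """Ranges the individual traits are drawn from (uniform)."""

    mass_range: tuple[float, float] = (7.0, 13.5)     # kg
    length_range: tuple[float, float] = (65.0, 80.0)  # cm
    age_range: tuple[float, float] = (2.0, 10.0)      # years
    p_male: float = 0.5


def bimodal_nocturnal_profile(hour) -> np.ndarray:
    """Default circadian log2-ODBA profile: dusk and pre-dawn activity peaks.

    Periodic over 24 h by construction (sum of cosine-shaped bumps at 22:00
    and 04:00 over a daytime resting baseline).
    """
    h = np.asarray(hour, dtype=float)
    bump = lambda center, height, conc: height * np.exp(
        conc * (np.cos(2 * np.pi * (h - center) / 24.0) - 1.0))
    return 2.0 + bump(22.0, 3.0, 3.0) + bump(4.0, 2.5, 3.0)


DEFAULT_BETA: dict[str, float] = {
    "Temp": 0.30, "Temp2": -0.15,
    "Rain": 0.15, "Rain2": -0.08,
    "Wind": -0.10, "SoilM": 0.10, "SoilT30": -0.10,
    "BCI": -0.05, "BCI_x_Temp": 0.20,
}

DEFAULT_ACTIVITY_PARAMS: dict[str, float] = {
    "Intercept": -1.0, "circadian_scale": 1.5, "Temp": 0.8, "Temp2": -0.3,
}


@dataclass
class TrueParameters:
    """Generative ground truth for one simulated study.

    ``circadian_profile`` may be a callable on hours or a length-24 array
    (interpreted as hourly values, wrapped periodically).  ``beta`` maps
    term names (see the design-matrix naming convention) to coefficients on
    standardized covariates.  With ``rho = 0`` the hourly-scale ICC implied
    by the generator is sigma_individual^2 / (sigma_individual^2 +
    sigma_resid^2); aggregating H hours averages the residual down to
    sigma_resid^2 / H, giving the night-scale ICC
    s_b^2 / (s_b^2 + s_e^2 / H).
    """

    circadian_profile: Callable | np.ndarray = bimodal_nocturnal_profile
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    sigma_individual: float = 0.30
    sigma_resid: float = 0.50
    rho: float = 0.40
    activity_logit_params: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_PARAMS))
    threshold_true: float = DEFAULT_THRESHOLD

    def __post_init__(self):
        if self.sigma_individual < 0:
            raise ValueError("sigma_individual must be >= 0")
        if self.sigma_resid <= 0:
            raise ValueError("sigma_resid must be > 0")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        prof = self.profile
        if not np.allclose(prof(0.0), prof(24.0)):
            raise ValueError("circadian profile must be periodic over 24 h")

    @property
    def profile(self) -> Callable:
        if callable(self.circadian_profile):
            return self.circadian_profile
        values = np.asarray(self.circadian_profile, dtype=float)
        if values.size != 24:
            raise ValueError("array circadian profile must have 24 hourly values")
        return lambda h: values[np.asarray(h, dtype=int) % 24]


@dataclass
class SyntheticCohort:
    """Simulated individuals, their shared weather, and deployment windows."""

    individuals: pd.DataFrame        # individual_id, sex, age, mass, length, bci, intercept
    weather: WeatherSeries
    deployments: dict[str, tuple[pd.Timestamp, pd.Timestamp]]

    def __post_init__(self):
        if not np.all(np.isfinite(self.individuals["intercept"])):
            raise ValueError("non-finite individual intercept draw")
        lo, hi = self.weather.span
        for ind, (a, b) in self.deployments.items():
            if not (a < b):
                raise ValueError(f"empty deployment window for {ind}")
            if a < lo or b > hi + pd.Timedelta(hours=1):
                raise ValueError(f"deployment for {ind} outside the weather span")


def simulate_weather(config: SeasonConfig | str = "spring", n_days: int = 14,
                     seed: int = 0) -> WeatherSeries:
    """Hourly weather for ``n_days`` days under a seasonal configuration.

    Air temperature = seasonal mean + AR-1 day-to-day anomaly + sinusoidal
    diurnal cycle (warmest mid-afternoon) + hourly noise.  Rainfall is
    zero-inflated exponential.  Soil temperatures are exponentially
    smoothed versions of air temperature (12 h memory at 10 cm, 48 h at
    30 cm), which makes them strongly — and realistically — collinear with
    it.  Humidity runs in anti-phase with temperature; soil moisture drifts
    slowly and responds to rain.
    """
    if isinstance(config, str):
        config = SEASON_PRESETS[config]
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    n_hours = 24 * n_days
    hours = pd.date_range(config.start_date, periods=n_hours, freq="h")
    hod = hours.hour.to_numpy(dtype=float)

    phi = config.temp_ar1
    innov_sd = config.temp_sd_day * np.sqrt(max(1 - phi**2, 0.0))
    day_anom = np.empty(n_days)
    day_anom[0] = rng.normal(0.0, config.temp_sd_day)
    for d in range(1, n_days):
        day_anom[d] = phi * day_anom[d - 1] + rng.normal(0.0, innov_sd)
    day_idx = np.repeat(np.arange(n_days), 24)
    diurnal = np.cos(2 * np.pi * (hod - 15.0) / 24.0)
    temp = (config.temp_mean + day_anom[day_idx]
            + config.temp_amp_diurnal * diurnal
            + rng.normal(0.0, config.temp_sd_hour, n_hours))

    wet = rng.random(n_hours) >= config.rain_p_zero
    rain = np.where(wet, rng.exponential(config.rain_mean_mm, n_hours), 0.0)

    wind = np.maximum(0.0, config.wind_mean + rng.normal(0.0, config.wind_sd, n_hours))
    rh = np.clip(config.rh_mean - config.rh_amp * diurnal
                 + rng.normal(0.0, config.rh_sd, n_hours), 0.0, 100.0)

    soilm = np.empty(n_hours)
    level = config.soilm_mean
    for t in range(n_hours):
        level += rng.normal(0.0, config.soilm_sd / 24.0) + 0.2 * rain[t] \
            - (level - config.soilm_mean) * 0.01
        soilm[t] = np.clip(level, 0.0, 100.0)

    def smooth(series, memory_h):
        alpha = 1.0 / memory_h
        out = np.empty_like(series)
        state = config.temp_mean
        for t, v in enumerate(series):
            state += alpha * (v - state)
            out[t] = state
        return out

    soilt10 = smooth(temp, 12.0) + rng.normal(0.0, config.soil_noise_sd, n_hours)
    soilt30 = smooth(temp, 48.0) + rng.normal(0.0, config.soil_noise_sd / 2, n_hours)

    return WeatherSeries(pd.DataFrame({
        "hour_start": hours, "Temp": temp, "Rain": rain, "Wind": wind,
        "RH": rh, "SoilM": soilm, "SoilT10": soilt10, "SoilT30": soilt30,
    }))


def simulate_individuals(n: int, trait_config: TraitConfig | None = None,
                         sigma_individual: float = 0.30, seed: int = 0) -> pd.DataFrame:
    """Trait table for ``n`` individuals with Normal(0, sigma^2) intercepts."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = trait_config or TraitConfig()
    rng = np.random.default_rng(seed)
    mass = rng.uniform(*cfg.mass_range, n)
    length = rng.uniform(*cfg.length_range, n)
    sex = np.where(rng.random(n) < cfg.p_male, "M", "F")
    age = np.round(rng.uniform(*cfg.age_range, n), 1)
    intercept = rng.normal(0.0, sigma_individual, n) if sigma_individual > 0 else np.zeros(n)
    return pd.DataFrame({
        "individual_id": [f"B{i:03d}" for i in range(n)],
        "sex": sex, "age": age,
        "mass": np.round(mass, 1), "length": np.round(length * 2) / 2,
        "bci": [compute_bci(m, l) for m, l in zip(np.round(mass, 1), np.round(length * 2) / 2)],
        "intercept": intercept,
    })


def make_cohort(n_individuals: int = 20, season: str | SeasonConfig = "spring",
                n_days: int = 10, sigma_individual: float = 0.30,
                trait_config: TraitConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Cohort with shared weather and one full-span deployment per individual."""
    ss = np.random.SeedSequence(seed)
    s_weather, s_traits = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    weather = simulate_weather(season, n_days=n_days, seed=s_weather)
    individuals = simulate_individuals(n_individuals, trait_config,
                                       sigma_individual, seed=s_traits)
    lo, hi = weather.span
    deployments = {ind: (lo, hi + pd.Timedelta(hours=1))
                   for ind in individuals["individual_id"]}
    return SyntheticCohort(individuals=individuals, weather=weather,
                           deployments=deployments)


def _covariate_table(cohort: SyntheticCohort) -> tuple[pd.DataFrame, object]:
    """Merged per-hour covariate table, standardized for the design convention."""
    from .weather import WEATHER_COVARIATES

    rows = []
    wf = cohort.weather.frame.set_index("hour_start")
    for row in cohort.individuals.itertuples(index=False):
        a, b = cohort.deployments[row.individual_id]
        hours = pd.date_range(a, b, freq="h", inclusive="left", name="hour_start")
        missing = hours.difference(wf.index)
        if len(missing):
            raise ValueError(
                f"weather missing {len(missing)} hours inside deployment of "
                f"{row.individual_id}")
        block = wf.loc[hours, WEATHER_COVARIATES].reset_index()
        block.insert(0, "individual_id", row.individual_id)
        block["series_id"] = f"{row.individual_id}-dep0"
        block["sexM"] = 1.0 if row.sex == "M" else 0.0
        block["age_raw"] = row.age
        block["bci_raw"] = row.bci
        rows.append(block)
    data = pd.concat(rows, ignore_index=True)
    data["hour"] = pd.to_datetime(data["hour_start"]).dt.hour.astype(float)
    for c in WEATHER_COVARIATES:
        data[f"{c}_raw"] = data[c]
    data, record = standardize(data, WEATHER_COVARIATES)
    for name, raw in (("age", "age_raw"), ("BCI", "bci_raw")):
        x = data[raw].to_numpy(dtype=float)
        sd = float(np.std(x, ddof=1))
        data[name] = (x - float(np.mean(x))) / sd if sd > 0 else 0.0
    return data, record


def simulate_hourly_odba(cohort: SyntheticCohort, params: TrueParameters,
                         seed: int = 0):
    """Hourly ODBA table under the generative model.

    log2(ODBA) = circadian(hour) + sum_k beta_k * term_k + intercept_i +
    eps, eps an AR-1(rho, sigma_resid) process per individual-deployment.
    ``active_true`` thresholds the implied flat minute ODBA
    (hourly ODBA / 60) at ``params.threshold_true``.  Returns ``(table,
    standardization_record)``; the table keeps the generative components
    (``mu_true``, ``eps``) for recovery tests.
    """
    data, record = _covariate_table(cohort)
    rng = np.random.default_rng(seed)
    profile = params.profile

    terms = expand_terms(data, list(params.beta)) if params.beta else None
    mu = profile(data["hour"].to_numpy())
    if terms is not None:
        mu = mu + terms.to_numpy() @ np.array(list(params.beta.values()))
    icpt = cohort.individuals.set_index("individual_id")["intercept"]
    mu = mu + icpt.reindex(data["individual_id"]).to_numpy()

    eps = np.empty(len(data))
    rho, se = params.rho, params.sigma_resid
    innov = se * np.sqrt(1 - rho**2)
    for _, idx in data.groupby("series_id", sort=False).indices.items():
        m = len(idx)
        e = np.empty(m)
        e[0] = rng.normal(0.0, se)
        shocks = rng.normal(0.0, innov, m - 1)
        for t in range(1, m):
            e[t] = rho * e[t - 1] + shocks[t - 1]
        eps[idx] = e

    data["mu_true"] = mu
    data["eps"] = eps
    data["log2_odba"] = mu + eps
    data["hourly_odba"] = 2.0 ** data["log2_odba"]
    data["active_true"] = (data["hourly_odba"] / 60.0) > params.threshold_true
    return data, record


def simulate_hourly_activity(data: pd.DataFrame, cohort: SyntheticCohort,
                             params: TrueParameters, seed: int = 0) -> pd.Series:
    """Binary hourly activity drawn from the generative logistic model.

    logit P(active) = Intercept + circadian_scale * (profile(hour) - mean
    profile) + sum_k gamma_k * term_k + intercept_i, sharing the cohort's
    individual intercepts.  Complements the thresholded ``active_true``
    flag with a stochastic response for binomial-model recovery tests.
    """
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    a = dict(params.activity_logit_params)
    intercept = a.pop("Intercept", 0.0)
    scale = a.pop("circadian_scale", 1.0)
    profile = params.profile
    prof = profile(data["hour"].to_numpy())
    prof_mean = float(np.mean(profile(np.arange(24.0))))
    logit = intercept + scale * (prof - prof_mean)
    if a:
        terms = expand_terms(data, list(a))
        logit = logit + terms.to_numpy() @ np.array(list(a.values()))
    icpt = cohort.individuals.set_index("individual_id")["intercept"]
    logit = logit + icpt.reindex(data["individual_id"]).to_numpy()
    return pd.Series(rng.random(len(data)) < expit(logit), index=data.index,
                     name="active").astype(int)


def synthesize_raw_windows(
    minute_odba_targets,
    sample_rate_hz: float = 50.0,
    counts_per_g: float = DEFAULT_COUNTS_PER_G,
    seed: int = 0,
    start_time="2018-05-01T00:00:00",
    window_s: float = 2.0,
    individual_id: str = "synthetic",
) -> TriaxialSeries:
    """Raw tri-axial counts whose per-minute ODBA hits prescribed targets.

    Each 2 s window carries a single-sample excursion on the x and y
    channels (half the target each) against an otherwise constant baseline;
    the dynamic component of such a window is (mean - midpoint) =
    -m (n-2) / (2n) counts for an excursion of m counts over n samples, so
    the integer m is chosen to land each window's ODBA on the minute's
    target.  Quantization of m bounds the round-trip error below one count
    unit (1/counts_per_g).  The z channel carries a constant +1 g gravity
    offset.  The excursion position within each window is randomized
    (seeded) — it does not affect the computed ODBA.
    """
    targets = np.asarray(minute_odba_targets, dtype=float)
    if np.any(targets < 0):
        raise ValueError("minute ODBA targets must be non-negative")
    n = int(round(sample_rate_hz * window_s))
    if n < 2:
        raise ValueError("need at least 2 samples per window")
    if n < 3 and np.any(targets > 0):
        raise ValueError("nonzero targets need >= 3 samples per window")
    windows_per_min = int(round(60.0 / window_s))
    rng = np.random.default_rng(seed)

    n_windows = targets.size * windows_per_min
    ax = np.zeros((n_windows, n), dtype=np.int64)
    ay = np.zeros((n_windows, n), dtype=np.int64)
    factor = 2.0 * n / (n - 2) if n > 2 else np.inf
    for i, target in enumerate(targets):
        m = int(round(target / 2.0 * counts_per_g * factor)) if target > 0 else 0
        if m > _INT16_MAX:
            raise ValueError(f"minute target {target} exceeds the int16 count range")
        for w in range(windows_per_min):
            r = i * windows_per_min + w
            pos = rng.integers(0, n)
            ax[r, pos] = m
            ay[r, pos] = m
    az = np.full(n_windows * n, int(counts_per_g), dtype=np.int64)

    total = n_windows * n
    t0 = pd.Timestamp(start_time)
    timestamps = t0 + pd.to_timedelta(np.arange(total) / sample_rate_hz, unit="s")
    samples = pd.DataFrame({
        "timestamp": timestamps,
        "ax": ax.ravel(), "ay": ay.ravel(), "az": az,
    })
    return TriaxialSeries(individual_id=individual_id, samples=samples,
                          counts_per_g=counts_per_g)


def write_dataset(out_dir, cohort: SyntheticCohort, params: TrueParameters,
                  hourly: pd.DataFrame | None = None,
                  raw: TriaxialSeries | None = None) -> None:
    """Write weather/traits/hourly CSVs plus a TrueParameters JSON sidecar."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.weather.to_csv(out / "weather.csv")
    cohort.individuals.to_csv(out / "traits.csv", index=False)
    if hourly is not None:
        hourly.to_csv(out / "hourly_odba.csv", index=False)
    if raw is not None:
        raw.to_csv(out / f"logger_{raw.individual_id}.csv")
    sidecar = {
        "circadian_profile_hourly": list(np.asarray(params.profile(np.arange(24.0)), dtype=float)),
        "beta": params.beta,
        "sigma_individual": params.sigma_individual,
        "sigma_resid": params.sigma_resid,
        "rho": params.rho,
        "activity_logit_params": params.activity_logit_params,
        "threshold_true": params.threshold_true,
    }
    (out / "true_parameters.json").write_text(json.dumps(sidecar, indent=2))
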