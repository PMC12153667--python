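import numpy as np
import pandas as pd
import pytest

from odbatools.accelerometry import aggregate, compute_window_odba
from odbatools.synthetic import (
    SeasonConfig,
    TraitConfig,
    TrueParameters,
    make_cohort,
    simulate_hourly_odba,
    simulate_individuals,
    simulate_weather,
    synthesize_raw_windows,
)

QUANT = 1.0 / 2**14  # one count-quantization unit in g


class TestWeatherGenerator:
    def test_degenerate_config_is_constant(self):
        cfg = SeasonConfig(temp_sd_day=0, temp_amp_diurnal=0, temp_sd_hour=0,
                           rain_p_zero=1.0, wind_sd=0, rh_amp=0, rh_sd=0,
                           soilm_sd=0, soil_noise_sd=0)
        w = simulate_weather(cfg, n_days=3, seed=0).frame
        np.testing.assert_allclose(w["Temp"], cfg.temp_mean)
        np.testing.assert_allclose(w["Wind"], cfg.wind_mean)
        np.testing.assert_allclose(w["SoilT10"], cfg.temp_mean)

    def test_full_zero_inflation_means_no_rain(self):
        w = simulate_weather(SeasonConfig(rain_p_zero=1.0), n_days=10, seed=1).frame
        assert (w["Rain"] == 0).all()

    def test_day_mean_autocorrelation_near_configured(self):
        cfg = SeasonConfig()
        w = simulate_weather(cfg, n_days=60, seed=42).frame
        day_means = w.groupby(w["hour_start"].dt.date)["Temp"].mean().to_numpy()
        x = day_means - day_means.mean()
        lag1 = float(np.sum(x[1:] * x[:-1]) / np.sum(x * x))
        assert lag1 == pytest.approx(cfg.temp_ar1, abs=0.15)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SeasonConfig(temp_sd_day=-1)
        with pytest.raises(ValueError):
            SeasonConfig(rain_p_zero=1.5)
        with pytest.raises(ValueError):
            simulate_weather("spring", n_days=0)

    def test_seeded_determinism(self):
        a = simulate_weather("summer", n_days=5, seed=7).frame
        b = simulate_weather("summer", n_days=5, seed=7).frame
        pd.testing.assert_frame_equal(a, b)


class TestIndividuals:
    def test_zero_sigma_gives_zero_intercepts(self):
        ind = simulate_individuals(50, sigma_individual=0.0, seed=3)
        assert (ind["intercept"] == 0).all()

    def test_intercept_sd_recovers_sigma(self):
        ind = simulate_individuals(1000, sigma_individual=0.3, seed=11)
        assert ind["intercept"].std(ddof=1) == pytest.approx(0.3, abs=0.03)

    def test_fixed_traits_give_equal_positive_bci(self):
        cfg = TraitConfig(mass_range=(10.0, 10.0), length_range=(75.0, 75.0))
        ind = simulate_individuals(20, cfg, seed=4)
        assert ind["bci"].nunique() == 1
        assert (ind["bci"] > 0).all()

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            simulate_individuals(0)


class TestHourlyOdba:
    def test_null_generator_is_iid_normal(self):
        # flat profile, no covariate effects, no individual or serial structure
        params = TrueParameters(circadian_profile=lambda h: np.full_like(np.asarray(h, float), 3.0),
                                beta={}, sigma_individual=0.0, rho=0.0, sigma_resid=0.5)
        cohort = make_cohort(n_individuals=5, n_days=10, sigma_individual=0.0, seed=0)
        data, _ = simulate_hourly_odba(cohort, params, seed=1)
        y = data["log2_odba"].to_numpy()
        assert y.mean() == pytest.approx(3.0, abs=0.05)
        assert y.std(ddof=1) == pytest.approx(0.5, abs=0.05)
        lag1 = np.corrcoef(y[:-1], y[1:])[0, 1]
        assert abs(lag1) < 0.1

    def test_residual_ar1_recovers_rho(self):
        params = TrueParameters(rho=0.6)
        cohort = make_cohort(n_individuals=4, n_days=40, seed=2)
        data, _ = simulate_hourly_odba(cohort, params, seed=3)
        eps = data.sort_values(["individual_id", "hour_start"])
        acs = []
        for _, g in eps.groupby("individual_id"):
            e = g["eps"].to_numpy()
            acs.append(np.corrcoef(e[:-1], e[1:])[0, 1])
        assert np.mean(acs) == pytest.approx(0.6, abs=0.05)

    def test_intercept_shift_is_linear(self):
        cohort = make_cohort(n_individuals=3, n_days=3, seed=5)
        params = TrueParameters()
        base, _ = simulate_hourly_odba(cohort, params, seed=6)
        shifted_cohort = make_cohort(n_individuals=3, n_days=3, seed=5)
        shifted_cohort.individuals.loc[0, "intercept"] += 1.0
        shifted, _ = simulate_hourly_odba(shifted_cohort, params, seed=6)
        ind0 = base["individual_id"] == base["individual_id"].iloc[0]
        delta = shifted.loc[ind0, "log2_odba"] - base.loc[ind0, "log2_odba"]
        np.testing.assert_allclose(delta, 1.0, atol=1e-12)

    def test_missing_weather_hours_rejected(self):
        cohort = make_cohort(n_individuals=2, n_days=3, seed=7)
        frame = cohort.weather.frame.drop(index=[30]).reset_index(drop=True)
        cohort.weather.frame = frame
        with pytest.raises(ValueError, match="missing"):
            simulate_hourly_odba(cohort, TrueParameters(), seed=0)

    def test_parameter_invariants_enforced(self):
        with pytest.raises(ValueError):
            TrueParameters(sigma_resid=0.0)
        with pytest.raises(ValueError):
            TrueParameters(rho=1.0)
        with pytest.raises(ValueError):
            TrueParameters(circadian_profile=lambda h: np.asarray(h, float))  # not periodic


class TestRawWindows:
    def test_zero_target_gives_constant_windows(self):
        raw = synthesize_raw_windows([0.0], seed=0)
        assert raw.samples["ax"].nunique() == 1
        assert raw.samples["ay"].nunique() == 1
        out = compute_window_odba(raw)
        np.testing.assert_array_equal(out["odba"], 0.0)

    def test_round_trip_within_quantization(self, rng):
        targets = rng.uniform(0.0, 1.5, 50)
        raw = synthesize_raw_windows(targets, seed=1)
        minute = aggregate(compute_window_odba(raw)).minute
        np.testing.assert_allclose(minute["odba"].to_numpy(), targets, atol=QUANT)

    def test_threshold_target_lands_on_threshold(self):
        # a minute engineered at the 0.28 g activity cut
        raw = synthesize_raw_windows([0.28], seed=2)
        minute = aggregate(compute_window_odba(raw)).minute
        assert minute["odba"].iloc[0] == pytest.approx(0.28, abs=QUANT)

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError):
            synthesize_raw_windows([-0.1])

    def test_determinism(self):
        a = synthesize_raw_windows([0.1, 0.5], seed=9).samples
        b = synthesize_raw_windows([0.1, 0.5], seed=9).samples
        pd.testing.assert_frame_equal(a, b)


def test_simulated_tables_are_seed_deterministic():
    c1 = make_cohort(n_individuals=4, n_days=3, seed=21)
    c2 = make_cohort(n_individuals=4, n_days=3, seed=21)
    d1, _ = simulate_hourly_odba(c1, TrueParameters(), seed=22)
    d2, _ = simulate_hourly_odba(c2, TrueParameters(), seed=22)
    pd.testing.assert_frame_equal(d1, d2)
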