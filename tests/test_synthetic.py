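"""Synthetic generator: determinism, moment oracles, disturbance law."""

import math

import numpy as np
import pytest
from scipy.special import expit

from batdisturb.io import read_activity_table
from batdisturb.synthetic import (
    SyntheticConfig,
    generate_baseline_series,
    generate_dataset,
    generate_weather,
    simulate_surveys,
)


def _flat_config(**kw):
    base = dict(
        n_caves=1,
        seasons=("2014/2015",),
        seasonal_amplitude=0.0,
        temp_effect=0.0,
        temp_seasonal_amp=0.0,
        p_detector_off=0.0,
        seed=5,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestWeather:
    def test_deterministic_under_seed(self):
        config = SyntheticConfig(seed=9)
        a = generate_weather(config, 42)
        b = generate_weather(config, 42)
        assert [w.mean_temp_c for w in a] == [w.mean_temp_c for w in b]
        assert [w.mean_wind_ms for w in a] == [w.mean_wind_ms for w in b]

    def test_long_run_mean_temperature(self):
        """Sample mean over ~10,000 nights approaches the configured mean."""
        config = SyntheticConfig(
            seasons=tuple(f"{y}/{y + 1}" for y in range(1950, 2017)),
            seed=1,
        )
        weather = generate_weather(config)
        temps = np.array([w.mean_temp_c for w in weather])
        assert temps.size > 10_000
        # AR(1) noise inflates the SE of the mean by sqrt((1+rho)/(1-rho))
        se = config.temp_sd * math.sqrt(
            (1 + config.temp_ar) / (1 - config.temp_ar) / temps.size
        )
        assert abs(temps.mean() - config.mean_temp_c) < 4 * se

    def test_wind_and_pressure_nonnegative(self):
        weather = generate_weather(SyntheticConfig(seed=3))
        assert all(w.mean_wind_ms >= 0 for w in weather)
        assert all(w.pressure_range_hpa >= 0 for w in weather)

    def test_no_seasons_is_error(self):
        with pytest.raises(ValueError):
            generate_weather(SyntheticConfig(seasons=()))


class TestBaselineSeries:
    def test_flat_mean_matches_closed_form(self):
        """temp_effect=0, amplitude=0: mean count ~ exp(baseline_log_rate)."""
        config = _flat_config(baseline_log_rate=math.log(5.0), dispersion=2.0)
        weather = generate_weather(config)
        counts = []
        for rep in range(40):  # ~6,000 nights total
            s = generate_baseline_series(config, weather, seed=100 + rep)
            counts.append(s.observed()["n_files"].to_numpy())
        counts = np.concatenate(counts)
        mu = 5.0
        sd = math.sqrt(mu + mu**2 / config.dispersion)
        assert abs(counts.mean() - mu) < 4 * sd / math.sqrt(counts.size)

    def test_poisson_limit_at_large_dispersion(self):
        """theta -> inf: variance approaches the mean."""
        config = _flat_config(baseline_log_rate=math.log(8.0), dispersion=1e9)
        weather = generate_weather(config)
        counts = np.concatenate(
            [
                generate_baseline_series(config, weather, seed=200 + rep)
                .observed()["n_files"]
                .to_numpy()
                for rep in range(40)
            ]
        )
        assert counts.var() / counts.mean() == pytest.approx(1.0, abs=0.1)

    def test_overdispersion_at_small_theta(self):
        config = _flat_config(baseline_log_rate=math.log(8.0), dispersion=1.0)
        weather = generate_weather(config)
        counts = np.concatenate(
            [
                generate_baseline_series(config, weather, seed=300 + rep)
                .observed()["n_files"]
                .to_numpy()
                for rep in range(20)
            ]
        )
        # variance/mean ~ 1 + mu/theta = 9 for mu=8, theta=1
        assert counts.var() / counts.mean() > 3.0

    def test_all_nights_observed_when_no_dropout(self):
        config = _flat_config(p_detector_off=0.0)
        weather = generate_weather(config)
        s = generate_baseline_series(config, weather, seed=1)
        assert s.nights["observed"].all()

    def test_dropout_rate(self):
        config = _flat_config(p_detector_off=0.3)
        weather = generate_weather(config)
        observed = np.concatenate(
            [
                generate_baseline_series(config, weather, seed=400 + rep)
                .nights["observed"]
                .to_numpy()
                for rep in range(30)
            ]
        )
        assert 1 - observed.mean() == pytest.approx(0.3, abs=0.03)


class TestSimulateSurveys:
    def test_degenerate_law_injects_nothing(self):
        config = _flat_config(true_beta0=-50.0, true_beta_df=0.0)
        weather = generate_weather(config)
        series = [generate_baseline_series(config, weather, seed=7)]
        _, _, truth = simulate_surveys(config, series, weather, seed=8)
        assert truth["response"].sum() == 0

    def test_response_frequency_matches_logistic_law(self):
        """Monte-Carlo response rate vs the closed-form inverse logit."""
        config = _flat_config()
        weather = generate_weather(config)
        series = [generate_baseline_series(config, weather, seed=7)]
        responses, p_true = [], []
        for rep in range(600):
            _, _, truth = simulate_surveys(config, series, weather, seed=900 + rep)
            responses.extend(truth["response"])
            p_true.extend(truth["p_true"])
        p_hat = np.mean(responses)
        p_bar = np.mean(p_true)
        se = math.sqrt(p_bar * (1 - p_bar) / len(responses))
        assert abs(p_hat - p_bar) < 4 * se

    def test_paper_truth_at_df700_cold_night(self):
        """DF=700 at -5.4 C disturbs in ~94% of replicates under the default law."""
        config = SyntheticConfig()
        b0, b1, b2 = config.truth_coefficients()
        p = expit(b0 + b1 * 700 + b2 * (-5.4))
        rng = np.random.default_rng(17)
        hits = rng.random(10_000) < p
        assert p == pytest.approx(0.94, abs=0.005)
        assert hits.mean() == pytest.approx(p, abs=0.02)

    def test_disturbed_nights_dominate(self):
        """Conditional on response, the survey-night count is stochastically larger."""
        config = _flat_config(
            baseline_log_rate=math.log(5.0), response_spike_mult=10.0,
            true_beta0=5.0,  # force response
        )
        weather = generate_weather(config)
        spiked, base = [], []
        for rep in range(80):
            series = [generate_baseline_series(config, weather, seed=rep)]
            surveys, modified, truth = simulate_surveys(
                config, series, weather, seed=5000 + rep
            )
            assert truth["response"].iloc[0] == 1
            date = surveys[0].survey_date
            night = modified[0].nights
            spiked.append(float(night.loc[night["date"] == date, "n_files"].iloc[0]))
            base.append(
                float(series[0].nights["n_files"].mean())
            )
        assert np.median(spiked) > 5 * np.median(base)

    def test_df_always_factors(self, small_bundle):
        for r in small_bundle.surveys:
            assert r.disturbance_factor == r.n_researchers * r.total_minutes


class TestGenerateDataset:
    def test_bundle_readable_and_valid(self, tmp_path, small_bundle):
        paths = small_bundle.write(tmp_path)
        series = read_activity_table(paths["activity"])
        assert len(series) == len(small_bundle.activity)

    def test_same_seed_identical_different_seed_not(self):
        config = SyntheticConfig(seed=21, n_caves=1, seasons=("2014/2015",))
        a = generate_dataset(config)
        b = generate_dataset(config)
        c = generate_dataset(SyntheticConfig(seed=22, n_caves=1,
                                             seasons=("2014/2015",)))
        ya = a.activity[0].observed()["n_files"].to_numpy()
        yb = b.activity[0].observed()["n_files"].to_numpy()
        yc = c.activity[0].observed()["n_files"].to_numpy()
        np.testing.assert_array_equal(ya, yb)
        assert not np.array_equal(ya[: yc.size], yc[: ya.size])

    def test_truth_recorded_per_survey(self, small_bundle):
        assert len(small_bundle.truth) == len(small_bundle.surveys)
        assert set(small_bundle.truth["response"]) <= {0, 1}
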