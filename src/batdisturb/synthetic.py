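"""Synthetic activity / survey / weather bundles with known ground truth.

The generator emulates the statistical structure of a winter acoustic
monitoring study at cave mouths:

* nightly call-file counts per cave-season-species drawn from a
  negative binomial (variance ``mu + mu^2/theta``) whose log mean is a
  baseline plus a smooth seasonal curve (activity lowest mid-winter)
  plus a per-degree temperature effect — so the Poisson fits of the
  analysis stage really are overdispersed unless ``theta`` is large;
* overnight weather with a seasonal temperature trough mid-winter and
  AR(1) night-to-night noise, non-negative wind and pressure ranges;
* occasional detector-off nights with no count;
* hibernacula surveys (one per cave-season by default) whose crew size
  and duration give a disturbance factor DF = researchers x minutes;
  each survey draws a latent response from the logistic disturbance law

      P(response) = inv-logit(b0 + b_DF * DF + b_T * T)

  and, on response, the count of the night following the survey is
  redrawn with its expected value multiplied by a spike factor.

Temperature enters both the activity law and the disturbance law, and
survey duration scales with cave length (as do bat counts), reproducing
the confounding that the screening stage must handle.  All latent draws
are recorded in a truth table so recovery can be verified.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from batdisturb.io import (
    NightlyActivitySeries,
    SurveyRecord,
    WeatherNight,
    season_bounds,
    write_activity_table,
    write_survey_table,
    write_weather_table,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticBundle",
    "generate_weather",
    "generate_baseline_series",
    "simulate_surveys",
    "generate_dataset",
]

#: published disturbance-law coefficients used as the default truth
DEFAULT_TRUTH = (-3.817, 0.013, 0.472)


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of a synthetic monitoring study.

    Defaults mirror the scale of the field study the pipeline was built
    for: nine caves, one survey per cave per monitored winter, crews of
    3-4 researchers spending tens of minutes to ~3 hours underground,
    mean overnight temperature -5.4 degC, and disturbance-law
    coefficients equal to the published fit.
    """

    n_caves: int = 9
    seasons: Sequence[str] = ("2012/2013", "2014/2015")
    baseline_log_rate: float = math.log(3.0)
    seasonal_amplitude: float = 1.0
    temp_effect: float = 0.08
    dispersion: float = 1.0
    p_detector_off: float = 0.05
    surveys_per_cave_season: int = 1
    researcher_range: tuple[int, int] = (3, 4)
    minutes_range: tuple[int, int] = (19, 175)
    response_spike_mult: float = 10.0
    true_beta0: float = DEFAULT_TRUTH[0]
    true_beta_df: float = DEFAULT_TRUTH[1]
    true_beta_temp: float = DEFAULT_TRUTH[2]
    mean_temp_c: float = -5.4
    temp_seasonal_amp: float = 6.0
    temp_ar: float = 0.7
    temp_sd: float = 3.0
    wind_mean_ms: float = 3.0
    species: Sequence[str] = ("COTO", "MYCI")
    affected_species: Sequence[str] = ("COTO",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion theta must be > 0")
        if not 0 <= self.p_detector_off < 1:
            raise ValueError("p_detector_off must be in [0, 1)")
        if self.response_spike_mult <= 1:
            raise ValueError("response_spike_mult must be > 1")

    def truth_coefficients(self) -> tuple[float, float, float]:
        return (self.true_beta0, self.true_beta_df, self.true_beta_temp)


def _season_nights(season: str) -> list[dt.date]:
    lo, hi = season_bounds(season)
    return [lo + dt.timedelta(days=i) for i in range((hi - lo).days + 1)]


def _season_frac(date: dt.date, season: str) -> float:
    lo, hi = season_bounds(season)
    return (date - lo).days / (hi - lo).days


def generate_weather(
    config: SyntheticConfig, seed: int | None = None
) -> list[WeatherNight]:
    """One weather record per night per configured season.

    Temperature follows a smooth seasonal curve — coldest mid-winter,
    averaging ``mean_temp_c`` over the season — plus AR(1) noise; wind
    speeds are gamma-distributed and pressure ranges non-negative.
    """
    if not config.seasons:
        raise ValueError("no seasons configured")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out: list[WeatherNight] = []
    for season in config.seasons:
        nights = _season_nights(season)
        if len(nights) < 2:
            raise ValueError(f"degenerate date range for season {season}")
        n = len(nights)
        u = np.array([_season_frac(d, season) for d in nights])
        seasonal = -config.temp_seasonal_amp * np.cos(2 * np.pi * (u - 0.5))
        seasonal -= seasonal.mean()  # exact zero mean over the window
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, config.temp_sd)
        innov_sd = config.temp_sd * math.sqrt(1.0 - config.temp_ar**2)
        for i in range(1, n):
            noise[i] = config.temp_ar * noise[i - 1] + rng.normal(0.0, innov_sd)
        temp = config.mean_temp_c + seasonal + noise
        wind = rng.gamma(4.0, config.wind_mean_ms / 4.0, size=n)
        pressure = rng.gamma(2.0, 2.0, size=n)
        for d, t, w, p in zip(nights, temp, wind, pressure):
            out.append(WeatherNight(d, float(t), float(p), float(w)))
    return out


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixing; Poisson limit as theta->inf."""
    lam = mu * rng.gamma(theta, 1.0 / theta, size=mu.shape)
    return rng.poisson(lam)


def generate_baseline_series(
    config: SyntheticConfig,
    weather: Sequence[WeatherNight],
    seed: int | None = None,
    cave_id: str = "S01",
    season: str | None = None,
    species: str = "COTO",
) -> NightlyActivitySeries:
    """Undisturbed nightly counts for one cave-season-species.

    log mean = baseline + seasonal smooth (dip mid-winter) +
    temp_effect x that night's mean temperature; counts are negative
    binomial with shape ``dispersion``; nights drop out as unobserved
    with probability ``p_detector_off``.
    """
    season = season or config.seasons[0]
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = season_bounds(season)
    temp_by_date = {w.night_date: w.mean_temp_c for w in weather}
    nights = _season_nights(season)
    missing = [d for d in nights if d not in temp_by_date]
    if missing:
        raise ValueError(f"weather does not cover {len(missing)} nights "
                         f"(first: {missing[0]})")
    u = np.array([_season_frac(d, season) for d in nights])
    seasonal = -config.seasonal_amplitude * np.cos(2 * np.pi * (u - 0.5))
    temps = np.array([temp_by_date[d] for d in nights])
    log_mu = config.baseline_log_rate + seasonal + config.temp_effect * temps
    mu = np.exp(log_mu)
    counts = _nb_counts(rng, mu, config.dispersion)
    observed = rng.random(len(nights)) >= config.p_detector_off
    frame = pd.DataFrame(
        {
            "date": nights,
            "n_files": np.where(observed, counts, np.nan),
            "observed": observed,
            "_mu": mu,  # latent expected rate, stripped before I/O
        }
    )
    return NightlyActivitySeries(cave_id, season, species, frame)


def simulate_surveys(
    config: SyntheticConfig,
    series: Sequence[NightlyActivitySeries],
    weather: Sequence[WeatherNight],
    seed: int | None = None,
    cave_lengths: dict[str, float] | None = None,
) -> tuple[list[SurveyRecord], list[NightlyActivitySeries], pd.DataFrame]:
    """Inject surveys and their latent disturbance responses.

    For each cave-season, survey dates are sampled in December-March;
    crew size and minutes come from the configured ranges (minutes also
    scale with cave length, reproducing the big-cave/long-survey
    confound); the latent response is Bernoulli with the logistic
    disturbance law evaluated at that survey's DF and night
    temperature.  On response, the count of the night labelled by the
    survey date is redrawn for each affected species with mean
    multiplied by ``response_spike_mult``.  Returns the survey records,
    the modified series and a truth table of every latent draw.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    temp_by_date = {w.night_date: w.mean_temp_c for w in weather}
    by_key = {s.key: s for s in series}
    cave_ids = sorted({s.cave_id for s in series})
    if cave_lengths is None:
        cave_lengths = {
            c: float(np.clip(rng.lognormal(math.log(150.0), 0.8), 20.0, 700.0))
            for c in cave_ids
        }
    lo_m, hi_m = config.minutes_range
    surveys: list[SurveyRecord] = []
    truth_rows = []
    new_series = {k: s for k, s in by_key.items()}
    b0, b_df, b_t = config.truth_coefficients()
    for cave in cave_ids:
        seasons_here = sorted({s.season_id for s in series if s.cave_id == cave})
        for season in seasons_here:
            ref = by_key[(cave, season, next(iter(config.species)))]
            eligible = [
                d for d in ref.nights["date"]
                if d.month in (12, 1, 2, 3) and d <= season_bounds(season)[1]
            ]
            if not eligible:
                raise ValueError(f"no December-March nights for {cave} {season}")
            picks = rng.choice(len(eligible), size=config.surveys_per_cave_season,
                               replace=False)
            for pick in np.atleast_1d(picks):
                date = eligible[int(pick)]
                if date not in temp_by_date:
                    raise ValueError(f"survey date {date} outside weather table")
                n_res = int(rng.integers(config.researcher_range[0],
                                         config.researcher_range[1] + 1))
                length = cave_lengths[cave]
                mins = int(np.clip(
                    round(lo_m + (hi_m - lo_m)
                          * (0.55 * (length / max(cave_lengths.values()))
                             + 0.45 * rng.random())),
                    lo_m, hi_m,
                ))
                df_value = float(n_res * mins)
                temp = temp_by_date[date]
                eta = b0 + b_df * df_value + b_t * temp
                p_true = 1.0 / (1.0 + math.exp(-eta))
                response = bool(rng.random() < p_true)
                n_coto = int(rng.poisson(0.6 * length))
                n_myci = int(rng.poisson(4.0))
                n_clusters = int(rng.poisson(1 + n_coto / 50.0))
                surveys.append(
                    SurveyRecord(
                        cave_id=cave,
                        cave_length_m=length,
                        survey_date=date,
                        n_coto=n_coto,
                        n_myci=n_myci,
                        n_researchers=n_res,
                        total_minutes=float(mins),
                        disturbance_factor=df_value,
                        n_clusters=n_clusters,
                        cluster_size=(n_coto / n_clusters) if n_clusters else 0.0,
                    )
                )
                truth_rows.append(
                    {
                        "cave": cave,
                        "season": season,
                        "date": date.isoformat(),
                        "disturbance_factor": df_value,
                        "mean_temp_c": temp,
                        "p_true": p_true,
                        "response": int(response),
                    }
                )
                if response:
                    for sp in config.affected_species:
                        key = (cave, season, sp)
                        if key in new_series:
                            new_series[key] = _spike_night(
                                new_series[key], date, config, rng
                            )
    truth = pd.DataFrame(truth_rows)
    return surveys, list(new_series.values()), truth


def _spike_night(
    s: NightlyActivitySeries, date: dt.date, config: SyntheticConfig,
    rng: np.random.Generator,
) -> NightlyActivitySeries:
    frame = s.nights.copy()
    mask = frame["date"] == date
    if not mask.any():
        raise ValueError(f"survey date {date} not in series {s.key}")
    if "_mu" in frame.columns:
        mu = frame.loc[mask, "_mu"].to_numpy()
    else:
        mu = np.maximum(frame.loc[mask, "n_files"].to_numpy(dtype=float), 1.0)
    spike = _nb_counts(rng, config.response_spike_mult * mu, config.dispersion)
    observed = frame.loc[mask, "observed"].to_numpy()
    frame.loc[mask, "n_files"] = np.where(observed, spike, np.nan)
    return NightlyActivitySeries(s.cave_id, s.season_id, s.species, frame)


@dataclass
class SyntheticBundle:
    """A complete generated dataset plus its ground truth."""

    config: SyntheticConfig
    activity: list[NightlyActivitySeries]
    surveys: list[SurveyRecord]
    weather: list[WeatherNight]
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the standard delimited tables plus the truth sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "activity": outdir / "activity.csv",
            "surveys": outdir / "surveys.csv",
            "weather": outdir / "weather.csv",
            "truth": outdir / "truth.csv",
        }
        clean = [
            NightlyActivitySeries(
                s.cave_id, s.season_id, s.species,
                s.nights[["date", "n_files", "observed"]].copy(),
            )
            for s in self.activity
        ]
        write_activity_table(clean, paths["activity"])
        write_survey_table(self.surveys, paths["surveys"])
        write_weather_table(self.weather, paths["weather"])
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def generate_dataset(config: SyntheticConfig) -> SyntheticBundle:
    """Generate a full bundle: weather, activity, surveys, latent truth.

    Deterministic given ``config.seed``; sub-streams are spawned per
    component so adding caves or seasons does not reshuffle unrelated
    draws.
    """
    root = np.random.SeedSequence(config.seed)
    weather_seed, series_seed, survey_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3)
    ]
    weather = generate_weather(config, weather_seed)
    series: list[NightlyActivitySeries] = []
    series_rng = np.random.SeedSequence(series_seed)
    cave_ids = [f"S{i + 1:02d}" for i in range(config.n_caves)]
    child_seeds = iter(series_rng.spawn(config.n_caves * len(config.seasons)
                                        * len(config.species)))
    for cave in cave_ids:
        for season in config.seasons:
            for sp in config.species:
                seed = int(next(child_seeds).generate_state(1)[0] % (2**31))
                series.append(
                    generate_baseline_series(
                        config, weather, seed, cave_id=cave, season=season,
                        species=sp,
                    )
                )
    surveys, series, truth = simulate_surveys(config, series, weather, survey_seed)
    return SyntheticBundle(
        config=config, activity=series, surveys=surveys, weather=weather,
        truth=truth,
    )
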