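"""Residual-exceedance classification of post-survey nights.

A night is *flagged* when its weighted working residual exceeds a
multiple (default 2) of the standard error of the model-fit envelope on
the same scale — one-sided, high side only, because the question is
whether bats flew out of the cave *more* than the seasonal model
predicts.  The envelope SE combines the dispersion of a single night
about the curve with the uncertainty of the fitted curve itself (see
:func:`batdisturb.gam.envelope_se`), so that under a correct model
roughly 2.3% of nights exceed it at the default multiplier.  The
night attributed to a survey is the night labelled by the survey date:
surveys end hours before dark, so the following night begins the same
calendar day.

Each survey then yields a binary outcome per species (1 = the matched
night was flagged) with the disturbance factor and overnight weather
attached; these outcomes are the response data of the logistic
disturbance model.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from batdisturb.gam import GamFit, envelope_se, working_residuals
from batdisturb.io import SurveyRecord, WeatherNight, season_label

logger = logging.getLogger(__name__)

DEFAULT_MULTIPLIER = 2.0


@dataclass
class ExceedanceCall:
    """Classification of a single night against the model envelope.

    ``status`` is ``"ok"`` when the night could be assessed and
    ``"unassessable"`` when it was unobserved or outside the fitted
    season (in which case ``flagged`` is ``None``, never 0).
    """

    cave_id: str | None
    season_id: str | None
    species: str | None
    night_date: dt.date
    residual: float | None
    se_fit: float | None
    threshold_multiplier: float
    flagged: bool | None
    status: str = "ok"


@dataclass
class SurveyOutcome:
    """Binary exceedance outcome of one survey for one species."""

    survey: SurveyRecord
    species: str
    outcome: int
    night_date: dt.date
    disturbance_factor: float
    mean_temp_c: float | None = None
    mean_wind_ms: float | None = None
    pressure_range_hpa: float | None = None


@dataclass
class OutcomeSet:
    """Survey outcomes plus the surveys dropped as unassessable."""

    outcomes: list[SurveyOutcome] = field(default_factory=list)
    dropped: list[tuple[SurveyRecord, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cave": o.survey.cave_id,
                    "date": o.survey.survey_date,
                    "species": o.species,
                    "outcome": o.outcome,
                    "disturbance_factor": o.disturbance_factor,
                    "mean_temp_c": o.mean_temp_c,
                    "mean_wind_ms": o.mean_wind_ms,
                    "pressure_range_hpa": o.pressure_range_hpa,
                }
                for o in self.outcomes
            ]
        )


def classify_night(
    fit: GamFit,
    night_date: dt.date,
    multiplier: float = DEFAULT_MULTIPLIER,
) -> ExceedanceCall:
    """Compare one night's weighted working residual to the fit envelope.

    The flag is one-sided: ``residual > multiplier * envelope_se``.
    Residual and envelope are both on the weighted working scale;
    because they carry the same ``sqrt(w_i)`` factor the classification
    is identical on the unweighted working scale.
    """
    cave = fit.series.cave_id if fit.series is not None else None
    season = fit.series.season_id if fit.series is not None else None
    species = fit.series.species if fit.series is not None else None
    idx = fit.night_index(night_date)
    if idx is None or fit.degenerate:
        status = "unassessable"
        reason = "degenerate fit" if fit.degenerate else "night not observed in fit"
        logger.warning("%s %s: %s", cave, night_date, reason)
        return ExceedanceCall(
            cave, season, species, night_date, None, None, multiplier, None, status
        )
    r, _ = working_residuals(fit)
    se = envelope_se(fit)
    flagged = bool(r[idx] > multiplier * se[idx])
    return ExceedanceCall(
        cave, season, species, night_date,
        float(r[idx]), float(se[idx]), multiplier, flagged,
    )


def flag_rate(fit: GamFit, multiplier: float = DEFAULT_MULTIPLIER) -> float:
    """Fraction of observed nights flagged — the null rate diagnostic."""
    r, _ = working_residuals(fit)
    return float(np.mean(r > multiplier * envelope_se(fit)))


def survey_outcomes(
    fits: Mapping[tuple[str, str, str], GamFit],
    surveys: Sequence[SurveyRecord],
    species: Iterable[str] = ("COTO", "MYCI"),
    weather: Sequence[WeatherNight] | None = None,
    multiplier: float = DEFAULT_MULTIPLIER,
) -> OutcomeSet:
    """Classify the night following every survey, for every species.

    ``fits`` maps ``(cave, season, species)`` to a fitted activity
    model.  A survey whose cave-season has no fit raises ``KeyError``
    naming the orphan survey; a survey whose matched night was a
    detector-off night is dropped with a logged warning and recorded in
    ``OutcomeSet.dropped``.  Weather covariates are joined by night
    date when a weather table is supplied.
    """
    weather_by_date = {w.night_date: w for w in (weather or [])}
    out = OutcomeSet()
    for survey in surveys:
        season = season_label(survey.survey_date)
        for sp in species:
            key = (survey.cave_id, season, sp)
            if key not in fits:
                raise KeyError(
                    f"survey {survey.cave_id} {survey.survey_date}: no fitted "
                    f"series for {key}"
                )
            call = classify_night(fits[key], survey.survey_date, multiplier)
            if call.status != "ok":
                logger.warning(
                    "dropping survey %s %s (%s): %s",
                    survey.cave_id, survey.survey_date, sp, call.status,
                )
                out.dropped.append((survey, f"{sp}: {call.status}"))
                continue
            w = weather_by_date.get(survey.survey_date)
            out.outcomes.append(
                SurveyOutcome(
                    survey=survey,
                    species=sp,
                    outcome=int(call.flagged),
                    night_date=survey.survey_date,
                    disturbance_factor=survey.disturbance_factor,
                    mean_temp_c=w.mean_temp_c if w else None,
                    mean_wind_ms=w.mean_wind_ms if w else None,
                    pressure_range_hpa=w.pressure_range_hpa if w else None,
                )
            )
    return out


def outcomes_from_annotations(
    surveys: Sequence[SurveyRecord],
    responses: Mapping[str, Iterable[tuple[str, str]]],
    weather: Sequence[WeatherNight] | None = None,
) -> OutcomeSet:
    """Build outcomes from externally known response annotations.

    ``responses`` maps species code to the ``(cave, iso-date)`` keys of
    responding surveys.  This is the path used when the classification
    is already known (e.g. the packaged survey table, whose footnotes
    record which surveys elicited a response) and the raw acoustic
    series are unavailable.
    """
    weather_by_date = {w.night_date: w for w in (weather or [])}
    out = OutcomeSet()
    for survey in surveys:
        for sp, keys in responses.items():
            w = weather_by_date.get(survey.survey_date)
            out.outcomes.append(
                SurveyOutcome(
                    survey=survey,
                    species=sp,
                    outcome=int(survey.key in set(keys)),
                    night_date=survey.survey_date,
                    disturbance_factor=survey.disturbance_factor,
                    mean_temp_c=w.mean_temp_c if w else None,
                    mean_wind_ms=w.mean_wind_ms if w else None,
                    pressure_range_hpa=w.pressure_range_hpa if w else None,
                )
            )
    return out
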