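"""End-to-end orchestration: read -> fit -> classify -> model -> predict.

A :class:`PipelineConfig` describes one run: where the three input
tables come from (files, a synthetic bundle generated on the fly, or
the packaged survey table with known outcomes), the GAM and exceedance
settings, and the logistic candidate terms.  :func:`run_pipeline`
executes the stages, writes every artifact as delimited text under the
output directory and returns a :class:`RunReport`.

The known-outcomes switch exists because nightly acoustic series are
often not archived alongside a published survey table: when the
per-survey responses are already recorded (as annotations), the GAM and
exceedance stages are bypassed and the modelling stage runs directly on
those outcomes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from batdisturb.disturbance import (
    SingleClassError,
    auc,
    model_selection,
    pearson_screen,
    probability_curve,
    term_significance,
)
from batdisturb.exceedance import (
    OutcomeSet,
    outcomes_from_annotations,
    survey_outcomes,
)
from batdisturb.gam import fit_summary_frame, select_family, working_residuals
from batdisturb.io import (
    read_activity_table,
    read_survey_table,
    read_weather_table,
    surveys_to_frame,
    validate_survey_table,
)
from batdisturb.synthetic import SyntheticConfig, generate_dataset
from batdisturb.table1 import table1_fixture

logger = logging.getLogger(__name__)

_version = "0.1.0"

SCREEN_CANDIDATES = ("cave_length_m", "n_coto", "n_clusters", "cluster_size")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending unit."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    activity_path: str | None = None
    surveys_path: str | None = None
    weather_path: str | None = None
    synthetic: SyntheticConfig | None = None
    use_table1_fixture: bool = False
    species: Sequence[str] = ("COTO", "MYCI")
    model_species: str = "COTO"
    gam_k: int = 10
    lambda_rule: str | float = "gcv"
    dispersion_threshold: float = 1.5
    multiplier: float = 2.0
    screening_alpha: float = 0.05
    candidate_terms: Sequence[str] = (
        "disturbance_factor",
        "mean_temp_c",
        "mean_wind_ms",
    )
    aic_variant: str = "aic"
    outdir: str = "batdisturb_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = raw["synthetic"]
            for key in ("seasons", "species", "affected_species"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            for key in ("researcher_range", "minutes_range"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            raw["synthetic"] = SyntheticConfig(**syn)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)  # hash the analysis, not where it lands
        payload.pop("log_level", None)
        if self.synthetic is not None:
            payload["synthetic"] = dataclasses.asdict(self.synthetic)
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything a run produced, plus warnings and provenance."""

    config_digest: str
    seed: int
    version: str
    fit_table: pd.DataFrame | None
    outcome_table: pd.DataFrame
    dropped: list
    screening_table: pd.DataFrame | None
    selection_table: pd.DataFrame
    top_model_terms: tuple[str, ...]
    top_model_coefficients: list[float]
    term_tests: dict[str, tuple[float, int, float]]
    auc: float | None
    curve: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.use_table1_fixture:
        fixture = table1_fixture()
        responses = {
            "COTO": fixture.coto_responses,
            "MYCI": fixture.myci_responses,
        }
        return None, fixture.surveys, None, responses
    if config.synthetic is not None:
        bundle = generate_dataset(config.synthetic)
        bundle.write(outdir / "synthetic")
        return bundle.activity, bundle.surveys, bundle.weather, None
    if not (config.activity_path and config.surveys_path):
        raise PipelineError(
            "input: need activity_path and surveys_path, a synthetic config, "
            "or use_table1_fixture"
        )
    activity = read_activity_table(config.activity_path)
    surveys = read_survey_table(config.surveys_path)
    weather = (
        read_weather_table(config.weather_path) if config.weather_path else None
    )
    return activity, surveys, weather, None


def fit_all_series(activity, config: PipelineConfig) -> tuple[dict, pd.DataFrame, list[str]]:
    """Stage 2: one penalized count smooth per (cave, season, species)."""
    fits = {}
    frames = []
    warn: list[str] = []
    for series in activity:
        if series.species not in config.species:
            continue
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fit = select_family(
                    series, k=config.gam_k,
                    threshold=config.dispersion_threshold,
                    lambda_rule=config.lambda_rule,
                )
            for c in caught:
                warn.append(f"{series.key}: {c.message}")
        except Exception as exc:  # noqa: BLE001 - stage error must name the unit
            raise PipelineError(f"gam: {series.key}: {exc}") from exc
        fits[series.key] = fit
        for msg in fit.messages:
            warn.append(f"{series.key}: {msg}")
        frame = fit_summary_frame(fit, config.multiplier)
        frame.insert(0, "cave", series.cave_id)
        frame.insert(1, "season", series.season_id)
        frame.insert(2, "species", series.species)
        frame["family"] = fit.family
        frame["dispersion"] = fit.dispersion
        frames.append(frame)
    fit_table = (
        pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    )
    return fits, fit_table, warn


def _model_stage(
    outcome_set: OutcomeSet,
    surveys,
    config: PipelineConfig,
) -> tuple:
    frame = outcome_set.to_frame()
    model_frame = frame[frame["species"] == config.model_species].copy()
    if model_frame.empty:
        raise PipelineError(
            f"model: no outcomes for species {config.model_species}"
        )
    survey_frame = surveys_to_frame(surveys)
    screen = None
    candidates = [
        c for c in SCREEN_CANDIDATES
        if c in survey_frame.columns and survey_frame[c].notna().any()
    ]
    if candidates:
        screen = pearson_screen(
            survey_frame, candidates, protected="disturbance_factor",
            alpha=config.screening_alpha,
        )
    terms = [
        t for t in config.candidate_terms
        if t in model_frame.columns and model_frame[t].notna().all()
    ]
    selection = model_selection(model_frame, terms, criterion=config.aic_variant)
    best = selection.best
    term_tests = {t: term_significance(best, t) for t in best.terms}
    try:
        auc_value = auc(best)
    except SingleClassError:
        auc_value = None
    curve = probability_curve(best)
    return model_frame, screen, selection, best, term_tests, auc_value, curve


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages and write artifacts to ``config.outdir``.

    Deterministic given the config (and its seed, in synthetic mode).
    Raises :class:`PipelineError` naming the stage and the offending
    cave-season on any stage failure.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warn: list[str] = []

    activity, surveys, weather, known_responses = _load_inputs(config, outdir)
    report = validate_survey_table(surveys)
    if not report.passed:
        raise PipelineError("input: survey table invalid: "
                            + "; ".join(report.messages))

    fit_table = None
    if known_responses is not None:
        outcome_set = outcomes_from_annotations(surveys, known_responses, weather)
    else:
        fits, fit_table, fit_warnings = fit_all_series(activity, config)
        warn.extend(fit_warnings)
        try:
            outcome_set = survey_outcomes(
                fits, surveys, species=config.species, weather=weather,
                multiplier=config.multiplier,
            )
        except KeyError as exc:
            raise PipelineError(f"exceedance: {exc}") from exc
        for survey, why in outcome_set.dropped:
            warn.append(
                f"dropped survey {survey.cave_id} {survey.survey_date}: {why}"
            )

    model_frame, screen, selection, best, term_tests, auc_value, curve = (
        _model_stage(outcome_set, surveys, config)
    )
    if best.separation_detected:
        warn.append("top model: separation detected")
    if not best.converged:
        warn.append("top model: did not converge")

    # ---- artifacts -------------------------------------------------------
    if fit_table is not None:
        fit_table.to_csv(outdir / "fits.csv", index=False)
    outcome_set.to_frame().to_csv(outdir / "outcomes.csv", index=False)
    if screen is not None:
        screen.table.to_csv(outdir / "screening.csv", index=False)
    sel_out = selection.table.drop(columns=["terms"])
    sel_out.to_csv(outdir / "model_selection.csv", index=False)
    curve.to_csv(outdir / "probability_curve.csv", index=False)
    digest = config.digest()
    header = {
        "package": "batdisturb",
        "version": _version,
        "config_digest": digest,
        "seed": config.seed,
        "top_model": list(best.terms),
        "coefficients": [float(b) for b in best.coefficients],
        "term_tests": {
            t: {"chi2": v[0], "df": v[1], "p": v[2]} for t, v in term_tests.items()
        },
        "auc": auc_value,
        "warnings": warn,
    }
    (outdir / "report.yaml").write_text(yaml.safe_dump(header, sort_keys=True))

    return RunReport(
        config_digest=digest,
        seed=config.seed,
        version=_version,
        fit_table=fit_table,
        outcome_table=outcome_set.to_frame(),
        dropped=getattr(outcome_set, "dropped", []),
        screening_table=screen.table if screen is not None else None,
        selection_table=selection.table,
        top_model_terms=best.terms,
        top_model_coefficients=[float(b) for b in best.coefficients],
        term_tests=term_tests,
        auc=auc_value,
        curve=curve,
        warnings=warn,
    )
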