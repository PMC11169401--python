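"""Reading, writing and validating the three delimited input tables.

The pipeline consumes three plain-text tables (comma-delimited by
default, tab accepted):

``activity``
    one row per detector night: ``cave, season, species, date, n_files,
    observed``.  ``season`` is a winter label of the form ``YYYY/YYYY``;
    ``date`` identifies the evening on which the night begins (ISO-8601);
    ``observed`` is true when the detector was operational.
``surveys``
    one row per hibernaculum survey: ``cave, cave_length_m, date,
    n_coto, n_myci, n_researchers, total_minutes`` and optionally
    ``n_clusters, cluster_size, disturbance_factor``.
``weather``
    one row per night: ``date, mean_temp_c, pressure_range_hpa,
    mean_wind_ms``.

Species codes follow the field convention: COTO for Townsend's
big-eared bat (*Corynorhinus townsendii*) and MYCI for western
small-footed myotis (*Myotis ciliolabrum*).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

SPECIES_CODES = ("COTO", "MYCI")

#: months that belong to a hibernation season (November-March)
SEASON_MONTHS = (11, 12, 1, 2, 3)
#: months in which hibernacula surveys take place (December-March)
SURVEY_MONTHS = (12, 1, 2, 3)

ACTIVITY_COLUMNS = ["cave", "season", "species", "date", "n_files", "observed"]
SURVEY_COLUMNS = [
    "cave",
    "cave_length_m",
    "date",
    "n_coto",
    "n_myci",
    "n_researchers",
    "total_minutes",
]
WEATHER_COLUMNS = ["date", "mean_temp_c", "pressure_range_hpa", "mean_wind_ms"]


class TableFormatError(ValueError):
    """Fatal problem with a table's structure (e.g. a missing column)."""


class RowValidationError(ValueError):
    """One or more rows failed validation; message lists line numbers."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "row validation failed:\n" + "\n".join(self.problems)
        )


def season_label(date: dt.date) -> str:
    """Winter label ``YYYY/YYYY`` for a night or survey date.

    November and December belong to the winter labelled by their own
    year; January-March belong to the winter that started the previous
    calendar year (e.g. 2014-12-22 -> ``2014/2015``).
    """
    if date.month >= 11:
        return f"{date.year}/{date.year + 1}"
    return f"{date.year - 1}/{date.year}"


def season_bounds(season: str) -> tuple[dt.date, dt.date]:
    """First and last possible night (Nov 1 - Mar 31) of a winter label."""
    y0, y1 = (int(p) for p in season.split("/"))
    if y1 != y0 + 1:
        raise ValueError(f"malformed season label {season!r}")
    return dt.date(y0, 11, 1), dt.date(y1, 3, 31)


@dataclass
class NightlyActivitySeries:
    """One cave-season's nightly acoustic call-file counts for one species.

    ``nights`` holds one row per night with columns ``date``
    (datetime.date), ``n_files`` (count, NaN when unobserved) and
    ``observed`` (bool).  Nights are strictly increasing in date and all
    fall within November-March of the labelled winter.
    """

    cave_id: str
    season_id: str
    species: str
    nights: pd.DataFrame

    def __post_init__(self) -> None:
        problems = list(self._validate())
        if problems:
            raise RowValidationError(problems)

    def _validate(self) -> Iterable[str]:
        tag = f"{self.cave_id}/{self.season_id}/{self.species}"
        if self.species not in SPECIES_CODES:
            yield f"{tag}: unknown species code {self.species!r}"
            return
        dates = list(self.nights["date"])
        if any(b <= a for a, b in zip(dates, dates[1:])):
            yield f"{tag}: night dates not strictly increasing"
        lo, hi = season_bounds(self.season_id)
        for d in dates:
            if not (lo <= d <= hi):
                yield f"{tag}: night {d} outside season {self.season_id}"
        for d, n, obs in self.nights[["date", "n_files", "observed"]].itertuples(
            index=False
        ):
            if obs:
                if pd.isna(n) or n < 0 or float(n) != int(n):
                    yield f"{tag}: night {d} has invalid count {n!r}"
            elif not pd.isna(n):
                yield f"{tag}: unobserved night {d} carries a count"

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.cave_id, self.season_id, self.species)

    def observed(self) -> pd.DataFrame:
        """Rows for operational detector nights only."""
        out = self.nights[self.nights["observed"]].copy()
        out["n_files"] = out["n_files"].astype(int)
        return out

    def has_night(self, date: dt.date) -> bool:
        return bool((self.nights["date"] == date).any())


@dataclass
class SurveyRecord:
    """One hibernaculum survey with its derived disturbance factor.

    The disturbance factor is the number of researchers multiplied by
    the total minutes the crew spent in the cave.
    """

    cave_id: str
    cave_length_m: float
    survey_date: dt.date
    n_coto: int
    n_myci: int
    n_researchers: int
    total_minutes: float
    disturbance_factor: float
    n_clusters: int | None = None
    cluster_size: float | None = None

    @property
    def season_id(self) -> str:
        return season_label(self.survey_date)

    @property
    def key(self) -> tuple[str, str]:
        return (self.cave_id, self.survey_date.isoformat())


@dataclass
class WeatherNight:
    """Overnight weather summary for one night.

    ``pressure_range_hpa`` is maximum minus minimum barometric pressure
    over the night; temperature and wind are overnight means.
    """

    night_date: dt.date
    mean_temp_c: float
    pressure_range_hpa: float
    mean_wind_ms: float

    def __post_init__(self) -> None:
        if self.pressure_range_hpa < 0:
            raise ValueError(f"{self.night_date}: negative pressure range")
        if self.mean_wind_ms < 0:
            raise ValueError(f"{self.night_date}: negative wind speed")


@dataclass
class ValidationReport:
    """Outcome of a report-only validation pass."""

    passed: bool
    messages: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# reading


def _read_delimited(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        frame = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError(f"{path}: empty file, no header") from exc
    if len(frame.columns) == 1 and sep == ",":
        # comma suffix but tab-delimited content
        frame = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")
    return frame


def _parse_date(value: object, line: int, problems: list[str]) -> dt.date | None:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError:
        problems.append(f"line {line}: bad ISO-8601 date {value!r}")
        return None


def read_activity_table(path: str | Path) -> list[NightlyActivitySeries]:
    """Read a nightly activity table into one series per (cave, season, species).

    Rows are grouped and sorted by night date.  Malformed rows raise a
    :class:`RowValidationError` listing 1-based file line numbers; a
    missing column raises :class:`TableFormatError`.
    """
    frame = _read_delimited(path, ACTIVITY_COLUMNS)
    problems: list[str] = []
    rows = []
    for idx, row in frame.iterrows():
        line = int(idx) + 2  # header is line 1
        date = _parse_date(row["date"], line, problems)
        observed = _parse_bool(row["observed"], line, problems)
        n_files = row["n_files"]
        if observed:
            if pd.isna(n_files) or float(n_files) < 0 or float(n_files) != int(n_files):
                problems.append(
                    f"line {line}: n_files must be a non-negative integer, got {n_files!r}"
                )
                continue
            n_files = int(n_files)
        else:
            n_files = math.nan
        if date is None or observed is None:
            continue
        rows.append(
            {
                "cave": str(row["cave"]),
                "season": str(row["season"]),
                "species": str(row["species"]),
                "date": date,
                "n_files": n_files,
                "observed": bool(observed),
            }
        )
    if problems:
        raise RowValidationError(problems)
    out: list[NightlyActivitySeries] = []
    clean = pd.DataFrame(rows, columns=["cave", "season", "species", "date", "n_files", "observed"])
    for (cave, season, species), grp in clean.groupby(
        ["cave", "season", "species"], sort=True
    ):
        nights = grp.sort_values("date")[["date", "n_files", "observed"]].reset_index(
            drop=True
        )
        out.append(NightlyActivitySeries(cave, season, species, nights))
    return out


def _parse_bool(value: object, line: int, problems: list[str]) -> bool | None:
    text = str(value).strip().lower()
    if text in {"true", "1", "yes", "t"}:
        return True
    if text in {"false", "0", "no", "f"}:
        return False
    problems.append(f"line {line}: bad boolean {value!r}")
    return None


def read_survey_table(path: str | Path) -> list[SurveyRecord]:
    """Read a survey table.  Missing optional fields read as absent."""
    frame = _read_delimited(path, SURVEY_COLUMNS)
    problems: list[str] = []
    records: list[SurveyRecord] = []
    for idx, row in frame.iterrows():
        line = int(idx) + 2
        date = _parse_date(row["date"], line, problems)
        if date is None:
            continue
        n_res = int(row["n_researchers"])
        minutes = float(row["total_minutes"])
        if "disturbance_factor" in frame.columns and not pd.isna(
            row.get("disturbance_factor")
        ):
            df_value = float(row["disturbance_factor"])
        else:
            df_value = n_res * minutes
        n_clusters = row.get("n_clusters")
        cluster_size = row.get("cluster_size")
        records.append(
            SurveyRecord(
                cave_id=str(row["cave"]),
                cave_length_m=float(row["cave_length_m"]),
                survey_date=date,
                n_coto=int(row["n_coto"]),
                n_myci=int(row["n_myci"]),
                n_researchers=n_res,
                total_minutes=minutes,
                disturbance_factor=df_value,
                n_clusters=None if pd.isna(n_clusters) else int(n_clusters),
                cluster_size=None if pd.isna(cluster_size) else float(cluster_size),
            )
        )
    if problems:
        raise RowValidationError(problems)
    return records


def read_weather_table(path: str | Path) -> list[WeatherNight]:
    frame = _read_delimited(path, WEATHER_COLUMNS)
    problems: list[str] = []
    nights: list[WeatherNight] = []
    for idx, row in frame.iterrows():
        line = int(idx) + 2
        date = _parse_date(row["date"], line, problems)
        if date is None:
            continue
        try:
            nights.append(
                WeatherNight(
                    night_date=date,
                    mean_temp_c=float(row["mean_temp_c"]),
                    pressure_range_hpa=float(row["pressure_range_hpa"]),
                    mean_wind_ms=float(row["mean_wind_ms"]),
                )
            )
        except ValueError as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise RowValidationError(problems)
    return nights


# ---------------------------------------------------------------------------
# writing (round-trip partners of the readers)


def write_activity_table(series: Iterable[NightlyActivitySeries], path: str | Path) -> None:
    frames = []
    for s in series:
        frame = s.nights.copy()
        frame.insert(0, "cave", s.cave_id)
        frame.insert(1, "season", s.season_id)
        frame.insert(2, "species", s.species)
        frames.append(frame)
    if frames:
        out = pd.concat(frames, ignore_index=True)
        out["n_files"] = out["n_files"].astype("Int64")
    else:
        out = pd.DataFrame(columns=ACTIVITY_COLUMNS)
    out.to_csv(path, index=False)


def write_survey_table(records: Iterable[SurveyRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "cave": r.cave_id,
                "cave_length_m": r.cave_length_m,
                "date": r.survey_date.isoformat(),
                "n_coto": r.n_coto,
                "n_myci": r.n_myci,
                "n_researchers": r.n_researchers,
                "total_minutes": r.total_minutes,
                "disturbance_factor": r.disturbance_factor,
                "n_clusters": r.n_clusters,
                "cluster_size": r.cluster_size,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "cave",
            "cave_length_m",
            "date",
            "n_coto",
            "n_myci",
            "n_researchers",
            "total_minutes",
            "disturbance_factor",
            "n_clusters",
            "cluster_size",
        ],
    ).to_csv(path, index=False)


def write_weather_table(nights: Iterable[WeatherNight], path: str | Path) -> None:
    rows = [
        {
            "date": w.night_date.isoformat(),
            "mean_temp_c": w.mean_temp_c,
            "pressure_range_hpa": w.pressure_range_hpa,
            "mean_wind_ms": w.mean_wind_ms,
        }
        for w in nights
    ]
    pd.DataFrame(rows, columns=WEATHER_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# validation


def validate_survey_table(records: Iterable[SurveyRecord]) -> ValidationReport:
    """Report-only consistency check of a survey table.

    Flags any record whose disturbance factor does not factor exactly as
    researchers x minutes, and any survey date outside December-March.
    """
    messages: list[str] = []
    for r in records:
        expected = r.n_researchers * r.total_minutes
        if r.disturbance_factor != expected:
            messages.append(
                f"{r.cave_id} {r.survey_date}: disturbance_factor "
                f"{r.disturbance_factor} != {r.n_researchers} researchers x "
                f"{r.total_minutes} min = {expected}"
            )
        if r.survey_date.month not in SURVEY_MONTHS:
            messages.append(
                f"{r.cave_id} {r.survey_date}: survey date outside December-March"
            )
        if r.n_researchers < 1:
            messages.append(f"{r.cave_id} {r.survey_date}: fewer than one researcher")
        if r.total_minutes <= 0:
            messages.append(f"{r.cave_id} {r.survey_date}: non-positive survey time")
    return ValidationReport(passed=not messages, messages=messages)


def surveys_to_frame(records: Iterable[SurveyRecord]) -> pd.DataFrame:
    """Survey records as a DataFrame (one row per survey)."""
    return pd.DataFrame(
        [
            {
                "cave": r.cave_id,
                "cave_length_m": r.cave_length_m,
                "date": r.survey_date,
                "season": r.season_id,
                "n_coto": r.n_coto,
                "n_myci": r.n_myci,
                "n_researchers": r.n_researchers,
                "total_minutes": r.total_minutes,
                "disturbance_factor": r.disturbance_factor,
                "n_clusters": r.n_clusters,
                "cluster_size": r.cluster_size,
            }
            for r in records
        ]
    )
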