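"""Built-in fixture: the published hibernacula-survey table.

Seventeen surveys of nine lava-tube caves in southeastern Idaho
(winters 2012/2013 through 2017/2018), with the number of Townsend's
big-eared bats (COTO) and western small-footed myotis (MYCI) counted,
crew size, time in cave, and the derived researcher disturbance factor
(researchers x minutes).  Response annotations mark the surveys after
which each species showed higher-than-expected cave-exiting activity
the following night.

The transcription is machine-checked: :func:`fixture_self_check`
recomputes the published summary statistics (group means, standard
deviations and ranges of the disturbance factor, mean bats counted,
crew sizes) and raises if any disagrees, so a transcription error
cannot pass silently.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from batdisturb.io import SurveyRecord, validate_survey_table

# cave, length_m, date, n_coto, n_myci, n_researchers, minutes,
# MYCI response, COTO response
_ROWS = [
    ("C22", 88, "2013-02-15", 112, 0, 4, 79, False, False),
    ("C22", 88, "2018-02-13", 66, 0, 4, 118, False, False),
    ("C14", 25, "2013-02-11", 3, 0, 3, 19, False, False),
    ("C14", 25, "2015-02-11", 2, 0, 3, 25, False, False),
    ("C19", 250, "2013-02-05", 23, 2, 3, 115, False, False),
    ("C19", 250, "2015-02-27", 25, 0, 3, 74, False, False),
    ("C36", 117, "2013-02-08", 5, 0, 3, 69, False, False),
    ("C40", 615, "2013-02-11", 391, 9, 3, 127, False, False),
    ("C40", 615, "2015-03-20", 443, 9, 4, 133, False, True),
    ("C40", 615, "2018-01-30", 373, 23, 4, 175, True, True),
    ("C41", 148, "2013-02-14", 1, 0, 3, 48, False, False),
    ("C41", 148, "2015-02-11", 2, 0, 3, 52, False, False),
    ("C46", 123, "2013-02-05", 3, 0, 3, 59, False, False),
    ("C46", 123, "2015-02-11", 3, 0, 3, 30, False, False),
    ("C47", 65, "2013-02-25", 25, 0, 3, 37, False, False),
    ("C54", 311, "2013-02-25", 130, 24, 3, 106, False, False),
    ("C54", 311, "2014-12-22", 127, 6, 4, 75, False, True),
]


@dataclass
class Table1Fixture:
    """Survey records plus per-species response annotations.

    ``coto_responses`` / ``myci_responses`` hold the ``(cave, date)``
    keys of surveys after which the species exited the cave the
    following night; they drive the known-outcomes path of the
    pipeline.
    """

    surveys: list[SurveyRecord]
    coto_responses: set[tuple[str, str]] = field(default_factory=set)
    myci_responses: set[tuple[str, str]] = field(default_factory=set)

    def response(self, record: SurveyRecord, species: str) -> int:
        annotated = self.coto_responses if species == "COTO" else self.myci_responses
        return int(record.key in annotated)

    def outcomes(self, species: str) -> list[int]:
        return [self.response(r, species) for r in self.surveys]


def table1_fixture() -> Table1Fixture:
    """The packaged survey table, self-checked against published aggregates."""
    surveys = []
    coto_resp: set[tuple[str, str]] = set()
    myci_resp: set[tuple[str, str]] = set()
    for cave, length, date, coto, myci, n_res, minutes, r_myci, r_coto in _ROWS:
        rec = SurveyRecord(
            cave_id=cave,
            cave_length_m=float(length),
            survey_date=dt.date.fromisoformat(date),
            n_coto=coto,
            n_myci=myci,
            n_researchers=n_res,
            total_minutes=float(minutes),
            disturbance_factor=float(n_res * minutes),
        )
        surveys.append(rec)
        if r_coto:
            coto_resp.add(rec.key)
        if r_myci:
            myci_resp.add(rec.key)
    fixture = Table1Fixture(surveys, coto_resp, myci_resp)
    fixture_self_check(fixture)
    return fixture


def fixture_self_check(fixture: Table1Fixture) -> None:
    """Validate the transcription against the published summary statistics.

    Raises ``AssertionError`` on the first aggregate that fails to
    reproduce at the printed rounding.
    """
    surveys = fixture.surveys
    assert len(surveys) == 17, "expected 17 surveys"
    assert len({r.cave_id for r in surveys}) == 9, "expected 9 distinct caves"
    report = validate_survey_table(surveys)
    assert report.passed, "; ".join(report.messages)

    df = np.array([r.disturbance_factor for r in surveys])
    responding = np.array([r.key in fixture.coto_responses for r in surveys])
    assert responding.sum() == 3, "expected 3 COTO-response surveys"
    assert len(fixture.myci_responses) == 1, "expected 1 MYCI-response survey"
    assert fixture.myci_responses <= fixture.coto_responses | fixture.myci_responses

    resp, nonresp = df[responding], df[~responding]
    assert round(resp.mean()) == 511
    assert round(resp.std(ddof=1), 1) == 200.9
    assert (resp.min(), resp.max()) == (300, 700)
    assert round(nonresp.mean()) == 219
    assert round(nonresp.std(ddof=1), 1) == 127.7
    assert (nonresp.min(), nonresp.max()) == (57, 472)

    coto = np.array([r.n_coto for r in surveys])
    myci = np.array([r.n_myci for r in surveys])
    assert round(coto.mean()) == 102
    assert round(coto.std(ddof=1), 1) == 150.7
    assert round(myci.mean()) == 4
    assert round(myci.std(ddof=1), 1) == 7.9

    researchers = np.array([r.n_researchers for r in surveys])
    assert (researchers.min(), researchers.max()) == (3, 4)
    assert round(researchers.mean()) == 3
    assert round(researchers.std(ddof=1), 1) == 0.5
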