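"""Weekly MET-minute phenotypes from raw exercise survey records.

Each reported exercise activity carries a MET value (energy cost as a
multiple of basal expenditure), a weekly frequency, and an average session
duration.  The weekly volume of an activity is

    METmin = MET * times_per_week * minutes_per_session

and a participant's total phenotype is the sum over their voluntary,
non-seasonal activities.  Every activity is classified on three binary
axes — team vs solitary, competitive vs non-competitive, externally vs
internally paced — yielding six class-specific MET-minute phenotypes that
partition the total on each axis.

Obligatory exercise (e.g. PE classes), transport-related activity (e.g.
commuter cycling), and purely seasonal exercise are excluded before
scoring.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

TEAM_LABELS = ("team", "solitary")
COMPETITION_LABELS = ("competitive", "non-competitive")
PACING_LABELS = ("internal", "external")

AGE_MIN, AGE_MAX = 16.0, 65.0
DEFAULT_GAP_YEARS = 10.0

TRAIT_COLUMNS = (
    "total_metmin", "team_metmin", "solitary_metmin",
    "competitive_metmin", "noncompetitive_metmin",
    "external_metmin", "internal_metmin",
)


class ActivityTableError(ValueError):
    """Raised when an activity classification table is malformed."""


@dataclass(frozen=True)
class ActivityDefinition:
    """One row of the activity classification table."""

    name: str
    met_value: float
    team_membership: str    # "team" | "solitary"
    competition: str        # "competitive" | "non-competitive"
    pacing: str             # "internal" | "external"

    def __post_init__(self):
        if self.met_value < 1.0:
            raise ActivityTableError(
                f"activity {self.name!r}: MET value {self.met_value} < 1 "
                "(a MET is a multiple of resting expenditure)"
            )
        for value, allowed, axis in (
            (self.team_membership, TEAM_LABELS, "team"),
            (self.competition, COMPETITION_LABELS, "competition"),
            (self.pacing, PACING_LABELS, "pacing"),
        ):
            if value not in allowed:
                raise ActivityTableError(
                    f"activity {self.name!r}: unknown {axis} label {value!r} "
                    f"(expected one of {allowed})"
                )


@dataclass
class ExerciseRecord:
    participant_id: str
    activity_name: str
    times_per_week: float
    minutes_per_session: float
    years_practiced: float = 0.0
    months_per_year: int = 12
    obligatory_flag: bool = False
    transport_flag: bool = False
    seasonal_flag: bool = False
    wave_id: Optional[str] = None
    age_at_survey: Optional[float] = None
    sex: Optional[str] = None

    def __post_init__(self):
        if self.times_per_week < 0 or self.minutes_per_session < 0:
            raise ValueError(
                f"record for {self.participant_id!r}/{self.activity_name!r}: "
                "frequency and duration must be non-negative"
            )

    @property
    def excluded(self) -> bool:
        return self.obligatory_flag or self.transport_flag or self.seasonal_flag


@dataclass
class PhenotypeVector:
    """Weekly MET-minute phenotypes for one participant (all >= 0).

    The two classes on each axis partition the total exactly:
    team + solitary = competitive + non-competitive =
    external + internal = total.
    """

    participant_id: str
    total_metmin: float = 0.0
    team_metmin: float = 0.0
    solitary_metmin: float = 0.0
    competitive_metmin: float = 0.0
    noncompetitive_metmin: float = 0.0
    external_metmin: float = 0.0
    internal_metmin: float = 0.0
    age_at_survey: Optional[float] = None
    sex: Optional[str] = None

    def as_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            **{c: getattr(self, c) for c in TRAIT_COLUMNS},
            "age_at_survey": self.age_at_survey,
            "sex": self.sex,
        }


# ---------------------------------------------------------------------------
# Activity table
# ---------------------------------------------------------------------------

def load_activity_table(path_or_buffer=None) -> dict[str, ActivityDefinition]:
    """Load an activity classification table (CSV: name,met,team,competition,pacing).

    Without an argument, loads the bundled table covering common survey
    activities.  Returns a dict keyed by activity name.
    """
    if path_or_buffer is None:
        with resources.files("exped.data").joinpath("activities.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path_or_buffer)
    required = {"name", "met", "team", "competition", "pacing"}
    missing = required - set(df.columns)
    if missing:
        raise ActivityTableError(f"activity table missing columns: {sorted(missing)}")
    table: dict[str, ActivityDefinition] = {}
    for i, row in df.iterrows():
        name = str(row["name"])
        if name in table:
            raise ActivityTableError(f"row {i + 2}: duplicate activity name {name!r}")
        try:
            table[name] = ActivityDefinition(
                name=name,
                met_value=float(row["met"]),
                team_membership=str(row["team"]),
                competition=str(row["competition"]),
                pacing=str(row["pacing"]),
            )
        except ActivityTableError as exc:
            raise ActivityTableError(f"row {i + 2}: {exc}") from exc
    return table


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def weekly_metmin(record: ExerciseRecord, activity: ActivityDefinition) -> float:
    """Weekly MET-minutes: MET value x weekly frequency x session minutes."""
    if record.activity_name != activity.name:
        raise ValueError(
            f"record activity {record.activity_name!r} does not match "
            f"definition {activity.name!r}"
        )
    return activity.met_value * record.times_per_week * record.minutes_per_session


def score_participant(
    records: Iterable[ExerciseRecord],
    table: Mapping[str, ActivityDefinition],
    strict: bool = False,
) -> PhenotypeVector:
    """Score one participant's records into a PhenotypeVector.

    Records with any exclusion flag contribute nothing.  Unknown
    activities are skipped with a warning, or raise in strict mode.
    A participant with no included records gets an all-zero vector
    (a non-exerciser).
    """
    records = list(records)
    if not records:
        raise ValueError("no records supplied")
    pid = records[0].participant_id
    unknown = sorted(
        {r.activity_name for r in records
         if not r.excluded and r.activity_name not in table}
    )
    if unknown:
        if strict:
            raise KeyError(f"unknown activities for {pid!r}: {unknown}")
        logger.warning("participant %s: skipping unknown activities %s", pid, unknown)

    vec = PhenotypeVector(participant_id=pid)
    for rec in records:
        if rec.participant_id != pid:
            raise ValueError("records from more than one participant")
        if rec.excluded or rec.activity_name not in table:
            continue
        act = table[rec.activity_name]
        mm = weekly_metmin(rec, act)
        vec.total_metmin += mm
        if act.team_membership == "team":
            vec.team_metmin += mm
        else:
            vec.solitary_metmin += mm
        if act.competition == "competitive":
            vec.competitive_metmin += mm
        else:
            vec.noncompetitive_metmin += mm
        if act.pacing == "external":
            vec.external_metmin += mm
        else:
            vec.internal_metmin += mm
        if vec.age_at_survey is None:
            vec.age_at_survey = rec.age_at_survey
        if vec.sex is None:
            vec.sex = rec.sex
    if vec.age_at_survey is None:
        vec.age_at_survey = records[0].age_at_survey
    if vec.sex is None:
        vec.sex = records[0].sex
    return vec


def score_survey(
    records_df: pd.DataFrame,
    table: Mapping[str, ActivityDefinition],
    strict: bool = False,
) -> pd.DataFrame:
    """Score a survey-record table (one row per participant x activity).

    Expects columns participant_id, activity_name, times_per_week,
    minutes_per_session and optionally the exclusion flags, wave_id,
    age_at_survey, sex.  Returns one phenotype row per participant.
    """
    rows = []
    for pid, grp in records_df.groupby("participant_id", sort=True):
        recs = [
            ExerciseRecord(
                participant_id=str(pid),
                activity_name=str(r.activity_name),
                times_per_week=float(r.times_per_week),
                minutes_per_session=float(r.minutes_per_session),
                obligatory_flag=bool(getattr(r, "obligatory_flag", False)),
                transport_flag=bool(getattr(r, "transport_flag", False)),
                seasonal_flag=bool(getattr(r, "seasonal_flag", False)),
                wave_id=getattr(r, "wave_id", None),
                age_at_survey=getattr(r, "age_at_survey", None),
                sex=getattr(r, "sex", None),
            )
            for r in grp.itertuples()
        ]
        rows.append(score_participant(recs, table, strict=strict).as_dict())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Wave selection
# ---------------------------------------------------------------------------

def select_wave(
    participation: pd.DataFrame,
    gap_years: float = DEFAULT_GAP_YEARS,
    age_min: float = AGE_MIN,
    age_max: float = AGE_MAX,
) -> dict[str, str]:
    """Select one survey wave per retained participant.

    ``participation`` has one row per (participant, wave) with columns
    ``participant_id``, ``family_id``, ``wave_id``, ``survey_year`` and
    ``age_at_survey``.  Rules:

    1. Waves at which a participant is outside [age_min, age_max] are
       discarded; participants with no eligible wave are dropped.
    2. Within a family, the modal wave (largest number of participating
       members; earliest survey year on ties) is chosen.
    3. Members absent from the modal wave use their survey closest in
       time; if that gap exceeds ``gap_years``, their last survey is used.
    4. Participants whose family retains no other member are dropped.
    """
    if participation.empty:
        return {}
    elig = participation[
        (participation["age_at_survey"] >= age_min)
        & (participation["age_at_survey"] <= age_max)
    ]
    selected: dict[str, str] = {}
    for fam, grp in elig.groupby("family_id"):
        counts = grp.groupby("wave_id").agg(
            n=("participant_id", "nunique"), year=("survey_year", "first")
        )
        if counts.empty:
            continue
        counts = counts.sort_values(["n", "year"], ascending=[False, True])
        modal_wave = counts.index[0]
        modal_year = counts.loc[modal_wave, "year"]
        fam_selected: dict[str, str] = {}
        for pid, pgrp in grp.groupby("participant_id"):
            waves = pgrp.set_index("wave_id")["survey_year"]
            if modal_wave in waves.index:
                fam_selected[str(pid)] = str(modal_wave)
                continue
            gaps = (waves - modal_year).abs()
            nearest = gaps.idxmin()
            if gaps.loc[nearest] > gap_years:
                fam_selected[str(pid)] = str(waves.idxmax())  # last survey
            else:
                fam_selected[str(pid)] = str(nearest)
        if len(fam_selected) >= 2:  # needs >=1 other participating member
            selected.update(fam_selected)
    return selected
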