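"""Tabular input/output and the study's calendar conventions.

The study design samples RFID feeder visits on weekends only: a season is an
ordered list of 13 (Saturday, Sunday) weekend pairs. Calendar time is encoded
as "experimental day", which preserves real elapsed time across the weekend-only
sampling: weekend ``k`` (1-based) maps to days ``7(k-1)+1`` and ``7(k-1)+2``,
so the second weekend is experimental days 8 and 9.

Visit timestamps are stored as real-valued seconds since the season start
(midnight of the first Saturday), snapped to the RFID detector's 1/3-s scan
resolution; calendar dates are carried alongside.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: RFID detectors scan for PIT tags every one-third of a second; two reads of
#: the same tag at the same feeder closer than this are one physical visit.
DETECTOR_RESOLUTION_S = 1.0 / 3.0

VISIT_COLUMNS = ("tag_id", "feeder_id", "datetime")
SEXES = frozenset({"M", "F", "U"})


class ValidationError(ValueError):
    """Raised when an input table violates its schema contract."""


@dataclass(frozen=True)
class SeasonCalendar:
    """One winter sampling season: an ordered list of weekend date pairs."""

    label: str
    weekends: tuple[tuple[dt.date, dt.date], ...]

    def __post_init__(self) -> None:
        prev_end: dt.date | None = None
        for sat, sun in self.weekends:
            if sun != sat + dt.timedelta(days=1):
                raise ValidationError(
                    f"weekend ({sat}, {sun}) is not a consecutive (Saturday, Sunday) pair"
                )
            if prev_end is not None and sat <= prev_end:
                raise ValidationError(f"weekends overlap or are out of order near {sat}")
            prev_end = sun

    @property
    def season_start(self) -> dt.datetime:
        """Midnight of the first sampling Saturday; origin for timestamps."""
        return dt.datetime.combine(self.weekends[0][0], dt.time.min)

    @property
    def first_date(self) -> dt.date:
        return self.weekends[0][0]

    @property
    def last_date(self) -> dt.date:
        return self.weekends[-1][1]

    def sampling_days(self) -> list[dt.date]:
        return [d for weekend in self.weekends for d in weekend]

    def contains(self, date: dt.date) -> bool:
        # Half-open membership: [first Saturday, day after last Sunday).
        return self.first_date <= date < self.last_date + dt.timedelta(days=1)


def make_calendar(label: str, first_saturday: dt.date, n_weekends: int = 13) -> SeasonCalendar:
    """Build a season of ``n_weekends`` consecutive weekends.

    ``first_saturday`` must actually be a Saturday (weekday 5).
    """
    if first_saturday.weekday() != 5:
        raise ValidationError(f"{first_saturday} is not a Saturday")
    weekends = tuple(
        (
            first_saturday + dt.timedelta(days=7 * k),
            first_saturday + dt.timedelta(days=7 * k + 1),
        )
        for k in range(n_weekends)
    )
    return SeasonCalendar(label=label, weekends=weekends)


def experimental_day(calendar: SeasonCalendar, date: dt.date) -> int:
    """Map a sampling date to its experimental day: 7*(k-1) + d.

    ``k`` is the 1-based weekend index and ``d`` is 1 for Saturday, 2 for
    Sunday, so consecutive weekends are (1, 2), (8, 9), (15, 16), ...
    """
    for k, (sat, sun) in enumerate(calendar.weekends, start=1):
        if date == sat:
            return 7 * (k - 1) + 1
        if date == sun:
            return 7 * (k - 1) + 2
    raise ValidationError(f"{date} is not a sampling day of season {calendar.label!r}")


def assign_season(date: dt.date, calendars: Sequence[SeasonCalendar]) -> str:
    """Label of the unique season whose span contains ``date``."""
    spans = sorted(calendars, key=lambda c: c.first_date)
    for a, b in zip(spans, spans[1:]):
        if b.first_date <= a.last_date:
            raise ValidationError(f"seasons {a.label!r} and {b.label!r} overlap")
    for cal in spans:
        if cal.contains(date):
            return cal.label
    raise ValidationError(f"{date} falls outside every season")


def snap_to_resolution(timestamp_s: float | np.ndarray) -> float | np.ndarray:
    """Snap a timestamp (s) onto the 1/3-s detector grid."""
    return np.round(np.asarray(timestamp_s) * 3.0) / 3.0


# ---------------------------------------------------------------------------
# Visit records


def read_visits(path: str | Path, calendar: SeasonCalendar) -> pd.DataFrame:
    """Read a visits CSV into the canonical visit table.

    Input columns: ``tag_id, feeder_id, datetime`` (ISO 8601). Output columns:
    ``tag_id, feeder_id, timestamp, date`` sorted by (feeder_id, timestamp),
    with timestamps in seconds since season start on the 1/3-s grid.

    Cleaning steps (counts logged and stashed in ``df.attrs``):

    * exact duplicates (same tag, feeder, timestamp) dropped;
    * detections of one tag at one feeder within 1/3 s merged to one visit;
    * detections on non-sampling days discarded (the design is weekend-only).
    """
    raw = pd.read_csv(path, dtype={"tag_id": str, "feeder_id": str})
    for col in VISIT_COLUMNS:
        if col not in raw.columns:
            raise ValidationError(f"visits file {path} is missing required column {col!r}")
    parsed = pd.to_datetime(raw["datetime"], format="ISO8601", errors="coerce")
    if parsed.isna().any():
        row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise ValidationError(
            f"visits file {path}: unparsable datetime {raw['datetime'].iloc[row]!r} "
            f"at data row {row + 1}"
        )
    if raw["tag_id"].isna().any() or (raw["tag_id"].astype(str).str.len() == 0).any():
        raise ValidationError(f"visits file {path}: empty tag_id")

    df = pd.DataFrame(
        {
            "tag_id": raw["tag_id"].astype(str),
            "feeder_id": raw["feeder_id"].astype(str),
            "timestamp": (parsed - calendar.season_start).dt.total_seconds().to_numpy(),
            "date": parsed.dt.date,
        }
    )

    sampling = set(calendar.sampling_days())
    off = ~df["date"].isin(sampling)
    n_offday = int(off.sum())
    if n_offday:
        logger.info("read_visits: discarded %d non-weekend detections", n_offday)
        df = df.loc[~off]

    n0 = len(df)
    df = df.drop_duplicates(subset=["tag_id", "feeder_id", "timestamp"])
    n_dup = n0 - len(df)
    if n_dup:
        logger.info("read_visits: dropped %d exact duplicate detections", n_dup)

    # Merge re-reads of one tag within the detector scan period (on the raw
    # time axis, before snapping widens sub-resolution gaps to a grid step).
    df = df.sort_values(["tag_id", "feeder_id", "timestamp"], kind="mergesort")
    gap = df.groupby(["tag_id", "feeder_id"])["timestamp"].diff()
    rescan = gap.notna() & (gap < DETECTOR_RESOLUTION_S - 1e-9)
    n_rescan = int(rescan.sum())
    if n_rescan:
        logger.info("read_visits: merged %d sub-resolution re-reads", n_rescan)
        df = df.loc[~rescan]

    df["timestamp"] = snap_to_resolution(df["timestamp"].to_numpy())
    collided = df.duplicated(subset=["tag_id", "feeder_id", "timestamp"])
    n_rescan += int(collided.sum())
    df = df.loc[~collided]

    df = df.sort_values(["feeder_id", "timestamp", "tag_id"], kind="mergesort").reset_index(
        drop=True
    )
    df.attrs.update(
        n_dropped_duplicates=n_dup, n_dropped_offday=n_offday, n_merged_rescans=n_rescan
    )
    return df


def write_visits(df: pd.DataFrame, path: str | Path, calendar: SeasonCalendar) -> None:
    """Write the canonical visit table back to the CSV interchange format."""
    out = pd.DataFrame(
        {
            "tag_id": df["tag_id"],
            "feeder_id": df["feeder_id"],
            "datetime": [
                (calendar.season_start + dt.timedelta(seconds=float(t))).isoformat(
                    timespec="microseconds"
                )
                for t in df["timestamp"]
            ],
        }
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Breeding, sightings, bird attributes


def read_breeding(path: str | Path) -> pd.DataFrame:
    """Breeding records: season_year, nest_id, male_id, female_id.

    An empty string marks an unidentified parent; at least one parent must be
    present and (season_year, nest_id) must be unique.
    """
    df = pd.read_csv(
        path, dtype={"nest_id": str, "male_id": str, "female_id": str}
    )
    for col in ("season_year", "nest_id", "male_id", "female_id"):
        if col not in df.columns:
            raise ValidationError(f"breeding file {path} is missing required column {col!r}")
    df["season_year"] = df["season_year"].astype(int)
    for col in ("male_id", "female_id"):
        df[col] = df[col].fillna("").astype(str)
    if ((df["male_id"] == "") & (df["female_id"] == "")).any():
        raise ValidationError(f"breeding file {path}: record with no identified parent")
    if df.duplicated(subset=["season_year", "nest_id"]).any():
        raise ValidationError(f"breeding file {path}: duplicate (season_year, nest_id)")
    return df


def read_sightings(path: str | Path) -> pd.DataFrame:
    """Sightings ("observed alive") table: bird_id, date."""
    df = pd.read_csv(path, dtype={"bird_id": str})
    for col in ("bird_id", "date"):
        if col not in df.columns:
            raise ValidationError(f"sightings file {path} is missing required column {col!r}")
    if df["bird_id"].isna().any() or (df["bird_id"].str.len() == 0).any():
        raise ValidationError(f"sightings file {path}: empty bird_id")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def read_birds(path: str | Path) -> pd.DataFrame:
    """Bird attribute table: bird_id, sex in {M, F, U}, cohort_year (optional)."""
    df = pd.read_csv(path, dtype={"bird_id": str, "sex": str})
    for col in ("bird_id", "sex", "cohort_year"):
        if col not in df.columns:
            raise ValidationError(f"birds file {path} is missing required column {col!r}")
    bad = set(df["sex"].unique()) - SEXES
    if bad:
        raise ValidationError(f"birds file {path}: invalid sex value(s) {sorted(bad)}")
    if df["bird_id"].duplicated().any():
        raise ValidationError(f"birds file {path}: duplicate bird_id")
    df["cohort_year"] = df["cohort_year"].astype("Int64")
    return df


# ---------------------------------------------------------------------------
# Calendar files


def read_calendar(path: str | Path) -> list[SeasonCalendar]:
    """Read a calendar.yaml: a list of seasons with weekend date pairs."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    calendars = []
    for season in payload["seasons"]:
        weekends = tuple(
            (_as_date(sat), _as_date(sun)) for sat, sun in season["weekends"]
        )
        calendars.append(SeasonCalendar(label=str(season["label"]), weekends=weekends))
    return calendars


def write_calendar(calendars: Iterable[SeasonCalendar], path: str | Path) -> None:
    payload = {
        "seasons": [
            {
                "label": cal.label,
                "weekends": [[sat.isoformat(), sun.isoformat()] for sat, sun in cal.weekends],
            }
            for cal in calendars
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def _as_date(value: str | dt.date) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


# ---------------------------------------------------------------------------
# Validation report


@dataclass
class ValidationReport:
    n_visits: int = 0
    n_birds_seen: int = 0
    n_breeding_records: int = 0
    warnings: list[str] = field(default_factory=list)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            f"visits: {self.n_visits}",
            f"birds seen at feeders: {self.n_birds_seen}",
            f"breeding records: {self.n_breeding_records}",
            f"warnings: {len(self.warnings)}",
        ]
        lines.extend(f"  - {w}" for w in self.warnings)
        return "\n".join(lines)


def validate_dataset(
    visits: pd.DataFrame,
    breeding: pd.DataFrame,
    birds: pd.DataFrame,
    sightings: pd.DataFrame | None = None,
) -> ValidationReport:
    """Cross-table consistency checks; returns a report with any warnings."""
    report = ValidationReport(
        n_visits=len(visits),
        n_birds_seen=visits["tag_id"].nunique(),
        n_breeding_records=len(breeding),
    )
    known = set(birds["bird_id"])
    seen = set(visits["tag_id"]) - known
    if seen:
        report.warnings.append(
            f"{len(seen)} tag(s) at feeders missing from birds table (sex treated as U)"
        )
    parents = set(breeding["male_id"]) | set(breeding["female_id"])
    parents.discard("")
    missing = parents - known
    if missing:
        report.warnings.append(
            f"{len(missing)} breeding parent(s) missing from birds table (sex treated as U)"
        )
    sex_map = dict(zip(birds["bird_id"], birds["sex"]))
    bad_m = [b for b in breeding["male_id"] if b and sex_map.get(b, "U") == "F"]
    bad_f = [b for b in breeding["female_id"] if b and sex_map.get(b, "U") == "M"]
    if bad_m or bad_f:
        report.warnings.append(
            f"{len(bad_m) + len(bad_f)} breeding record parent(s) with inconsistent sex"
        )
    if sightings is not None:
        stray = set(sightings["bird_id"]) - known
        if stray:
            report.warnings.append(f"{len(stray)} sighted bird(s) missing from birds table")
    return report
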