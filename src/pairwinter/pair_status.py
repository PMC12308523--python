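"""Classify breeding dyads by their fate across three linked seasons.

A candidate dyad is any male-female pair appearing in the breeding records of
spring t-1 or spring t+1 whose members were both detected at feeders during
the focal winter t. Each candidate receives exactly one status:

* ``faithful`` - bred together in both springs;
* ``divorcing`` - bred together at t-1 and then either both re-paired with
  other birds at t+1, or one re-paired while the other was unobserved at t+1
  but known to be alive later (so the split cannot be explained by death);
* ``new`` - bred together at t+1 after each member bred with someone else at
  t-1, or one member bred with someone else and the other was a juvenile;
* ``juvenile`` - both members born the previous year, breeding together at
  t+1 in their first breeding season;
* ``excluded_absent`` - either member never detected in the focal winter;
* ``excluded_unclear`` - any remaining partial or ambiguous history
  (e.g. a vanished partner never confirmed alive, or within-season polygyny).

A single bird can legitimately appear in two analysed pairs in one year: once
in a divorcing pair (with its old partner) and once in a new pair (with its
next one). Pair identity is the sorted concatenation of the two bird ids, so a
faithful pair keeps one pair_id across consecutive focal winters.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

STATUSES = (
    "faithful",
    "divorcing",
    "new",
    "juvenile",
    "excluded_unclear",
    "excluded_absent",
)
ANALYSED_STATUSES = STATUSES[:4]


@dataclass(frozen=True)
class PairRecord:
    pair_id: str
    male_id: str
    female_id: str
    focal_winter: str
    status: str


def pair_key(a: str, b: str) -> str:
    """Canonical pair id, identical for the same two birds in any year."""
    return "-".join(sorted((a, b)))


def _partner_maps(breeding: pd.DataFrame, year: int):
    """(bird -> set of partners, set of birds observed breeding) for one year."""
    partners: dict[str, set[str]] = {}
    observed: set[str] = set()
    sub = breeding[breeding["season_year"] == year]
    for male, female in zip(sub["male_id"], sub["female_id"]):
        for bird in (male, female):
            if bird:
                observed.add(bird)
        if male and female:
            partners.setdefault(male, set()).add(female)
            partners.setdefault(female, set()).add(male)
    return partners, observed


def classify_pairs(
    breeding_t_minus_1: pd.DataFrame,
    breeding_t_plus_1: pd.DataFrame,
    winter_presence: set,
    sightings: pd.DataFrame,
    birds: pd.DataFrame,
    *,
    focal_winter: str,
    year_t_minus_1: int,
    year_t_plus_1: int,
    spring_end_month_day: tuple[int, int] = (6, 30),
) -> list[PairRecord]:
    """Assign one status to every candidate dyad.

    ``winter_presence`` is the set of birds detected at feeders at least once
    in winter t (use :func:`winter_presence_from_visits`). "Known alive later"
    means any sighting strictly after the end of the t+1 breeding season
    (by convention, after 30 June of the t+1 year).
    """
    part1, obs1 = _partner_maps(breeding_t_minus_1, year_t_minus_1)
    part3, obs3 = _partner_maps(breeding_t_plus_1, year_t_plus_1)

    sex_map = dict(zip(birds["bird_id"], birds["sex"]))
    cohort = {
        b: int(c)
        for b, c in zip(birds["bird_id"], birds["cohort_year"])
        if pd.notna(c)
    }
    spring_end = dt.date(year_t_plus_1, *spring_end_month_day)
    alive_later = {
        b for b, d in zip(sightings["bird_id"], sightings["date"]) if d > spring_end
    }

    candidates: set[tuple[str, str]] = set()
    for partners in (part1, part3):
        for bird, mates in partners.items():
            for mate in mates:
                candidates.add(tuple(sorted((bird, mate))))

    missing = {b for ab in candidates for b in ab if b not in sex_map}
    if missing:
        logger.warning(
            "%d breeding bird(s) missing from birds table; sex treated as U",
            len(missing),
        )

    records = []
    for a, b in sorted(candidates):
        status = _classify_one(
            a, b, part1, part3, obs1, obs3, winter_presence, alive_later, cohort,
            year_t_minus_1,
        )
        male, female = _orient(a, b, sex_map)
        records.append(
            PairRecord(
                pair_id=pair_key(a, b),
                male_id=male,
                female_id=female,
                focal_winter=focal_winter,
                status=status,
            )
        )
    return records


def _orient(a: str, b: str, sex_map: dict) -> tuple[str, str]:
    """Order a dyad as (male, female); unknown sexes keep sorted order."""
    if sex_map.get(a) == "F" or sex_map.get(b) == "M":
        return b, a
    return a, b


def _classify_one(
    a: str,
    b: str,
    part1: dict,
    part3: dict,
    obs1: set,
    obs3: set,
    winter_presence: set,
    alive_later: set,
    cohort: dict,
    year_t_minus_1: int,
) -> str:
    # Rule 1: both members must have visited feeders in the focal winter.
    if a not in winter_presence or b not in winter_presence:
        return "excluded_absent"

    # Simultaneous polygyny makes the history ambiguous under one-partner rules.
    if any(len(part.get(bird, ())) > 1 for part in (part1, part3) for bird in (a, b)):
        return "excluded_unclear"

    together_t1 = b in part1.get(a, ())
    together_t3 = b in part3.get(a, ())

    def repaired_t3(bird: str, other: str) -> bool:
        mates = part3.get(bird, set())
        return bool(mates) and other not in mates

    def other_partner_t1(bird: str, other: str) -> bool:
        mates = part1.get(bird, set())
        return bool(mates) and other not in mates

    def juvenile(bird: str) -> bool:
        return cohort.get(bird) == year_t_minus_1 and bird not in obs1

    # Rule 2: faithful.
    if together_t1 and together_t3:
        return "faithful"

    # Rule 3: divorcing.
    if together_t1:
        if repaired_t3(a, b) and repaired_t3(b, a):
            return "divorcing"
        if repaired_t3(a, b) and b not in obs3 and b in alive_later:
            return "divorcing"
        if repaired_t3(b, a) and a not in obs3 and a in alive_later:
            return "divorcing"

    # Rules 4 & 5 require the dyad to have bred together at t+1.
    if together_t3:
        oa, ob = other_partner_t1(a, b), other_partner_t1(b, a)
        if (oa and ob) or (oa and juvenile(b)) or (ob and juvenile(a)):
            return "new"
        if juvenile(a) and juvenile(b):
            return "juvenile"

    return "excluded_unclear"


def winter_presence_from_visits(visits: pd.DataFrame) -> set:
    """Birds detected at least once in the focal winter's visit table."""
    return set(visits["tag_id"].unique())


def tabulate_statuses(pairs: list[PairRecord]) -> pd.DataFrame:
    """Counts of pairs by (focal_winter, status), with row/column totals.

    Analysed statuses and exclusion categories appear as separate columns;
    the layout mirrors a per-season status count table.
    """
    frame = pairs_to_frame(pairs)
    if frame.empty:
        table = pd.DataFrame(0, index=pd.Index([], name="focal_winter"), columns=STATUSES)
    else:
        table = (
            frame.pivot_table(
                index="focal_winter",
                columns="status",
                values="pair_id",
                aggfunc="count",
                fill_value=0,
            )
            .reindex(columns=STATUSES, fill_value=0)
        )
    table.columns.name = None
    table["total_analysed"] = table[list(ANALYSED_STATUSES)].sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    return table.astype(int)


def pairs_to_frame(pairs: list[PairRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs],
            "male_id": [p.male_id for p in pairs],
            "female_id": [p.female_id for p in pairs],
            "focal_winter": [p.focal_winter for p in pairs],
            "status": [p.status for p in pairs],
        }
    )
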