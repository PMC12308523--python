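"""Daily dyadic association indices over flocking events.

Two indices are computed per pair per experimental day:

* **Winter association (WA)** — the simple ratio index over the day's
  flocking events, ``WA = x / (m + f + x)``, where ``x`` counts events shared
  by the pair and ``m`` / ``f`` count events containing only the male / only
  the female. Events are pooled over all feeders for the day.

* **Visit adjacency (VAI)** — a finer-scale index computed only within the
  day's shared events: a visit is *adjacent* when it lands within 3 s after a
  visit by the partner at the same feeder, and
  ``VAI = (adj_m + adj_f) / (vx + vy)`` with ``vx`` / ``vy`` the members'
  total visit counts inside shared events. The window is closed at exactly
  3.0 s; a simultaneous read (0 s) is not a follow.

A day's row exists only if at least one member was detected that day; a day
with no shared events has WA = 0 and an undefined (NaN) VAI.

The *preferred social partner* of a focal bird on a day is its opposite-sex
associate with the highest WA that day. When the top associate's sex is
unknown, the highest-WA associate of known opposite sex is used instead. Ties
break by higher shared-event count, then lexicographic id.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .flock_detection import FlockEvent
from .records_io import SeasonCalendar, experimental_day

__all__ = [
    "winter_association",
    "adjacent_count",
    "visit_adjacency",
    "daily_dyad_table",
    "preferred_partner_daily",
    "preferred_partner_table",
    "preferred_model_table",
    "nonpair_comparison",
    "nonpair_comparison_table",
    "PreferredPartnerDay",
    "ADJACENCY_WINDOW_S",
]

ADJACENCY_WINDOW_S = 3.0


def winter_association(x: int, m: int, f: int) -> float:
    """Simple ratio index x/(m+f+x); NaN when the pair had no events at all."""
    if min(x, m, f) < 0:
        raise ValueError("event counts must be non-negative")
    total = x + m + f
    if total == 0:
        return float("nan")
    return x / total


def adjacent_count(follower_times: np.ndarray, leader_times: np.ndarray,
                   window_s: float = ADJACENCY_WINDOW_S) -> int:
    """Number of follower visits with a leader visit in [t - window, t).

    The window is closed at exactly ``window_s`` before the follower's visit
    and open at the visit itself (a simultaneous detection does not count).
    """
    if follower_times.size == 0 or leader_times.size == 0:
        return 0
    leader = np.sort(leader_times)
    idx = np.searchsorted(leader, follower_times, side="left")
    ok = idx > 0
    prev = leader[np.maximum(idx - 1, 0)]
    return int(np.sum(ok & (follower_times - prev <= window_s)))


def visit_adjacency(
    shared_events: Sequence[FlockEvent],
    male_id: str,
    female_id: str,
    window_s: float = ADJACENCY_WINDOW_S,
) -> tuple[int, int, int, int, float]:
    """Pool adjacency counts over a day's shared events.

    Returns ``(adj_m, adj_f, vx, vy, vai)`` where ``adj_m`` counts male
    visits within ``window_s`` after a female visit (and vice versa), and
    ``vx`` / ``vy`` are total male / female visits inside the shared events.
    ``vai`` is NaN when there are no shared events.
    """
    adj_m = adj_f = vx = vy = 0
    for event in shared_events:
        if male_id not in event.members or female_id not in event.members:
            raise ValueError(f"event {event.event_id} does not contain both pair members")
        mt = np.array([t for tag, t in event.visits if tag == male_id])
        ft = np.array([t for tag, t in event.visits if tag == female_id])
        adj_m += adjacent_count(mt, ft, window_s)
        adj_f += adjacent_count(ft, mt, window_s)
        vx += mt.size
        vy += ft.size
    vai = (adj_m + adj_f) / (vx + vy) if (vx + vy) > 0 else float("nan")
    return adj_m, adj_f, vx, vy, vai


# ---------------------------------------------------------------------------
# Per-day event indexing shared by the table builders


class _DayIndex:
    """Precomputed per-day structures: membership sets and visit times."""

    def __init__(self, events: Sequence[FlockEvent], calendar: SeasonCalendar):
        self.by_day: dict[int, list[FlockEvent]] = {}
        for e in events:
            day = experimental_day(calendar, e.date)
            self.by_day.setdefault(day, []).append(e)
        self.days = sorted(self.by_day)
        # bird -> set of event positions, per day
        self.membership: dict[int, dict[str, set[int]]] = {}
        self.visit_times: dict[int, list[dict[str, np.ndarray]]] = {}
        for day, evs in self.by_day.items():
            members: dict[str, set[int]] = {}
            times: list[dict[str, np.ndarray]] = []
            for i, e in enumerate(evs):
                per_bird: dict[str, list[float]] = {}
                for tag, t in e.visits:
                    per_bird.setdefault(tag, []).append(t)
                times.append({b: np.asarray(ts) for b, ts in per_bird.items()})
                for b in e.members:
                    members.setdefault(b, set()).add(i)
            self.membership[day] = members
            self.visit_times[day] = times


def daily_dyad_table(
    events: Sequence[FlockEvent],
    pairs: pd.DataFrame,
    calendar: SeasonCalendar,
    window_s: float = ADJACENCY_WINDOW_S,
) -> pd.DataFrame:
    """Per pair per experimental day: x, m, f, wa, adjacency counts, vai.

    ``pairs`` needs columns pair_id, male_id, female_id (a status column, if
    present, is carried through for modelling). Days where neither member was
    detected produce no row. ``mean_flock_size`` is the mean member count of
    that day's shared events (NaN when none were shared).
    """
    index = _DayIndex(events, calendar)
    carry_status = "status" in pairs.columns
    rows = []
    for pair in pairs.itertuples(index=False):
        male, female = pair.male_id, pair.female_id
        for day in index.days:
            members = index.membership[day]
            em = members.get(male, set())
            ef = members.get(female, set())
            if not em and not ef:
                continue  # pair absent: recorded as NA, not zero
            shared_idx = sorted(em & ef)
            x = len(shared_idx)
            m = len(em) - x
            f = len(ef) - x
            evs = index.by_day[day]
            times = index.visit_times[day]
            adj_m = adj_f = vx = vy = 0
            sizes = []
            for i in shared_idx:
                mt = times[i].get(male, np.empty(0))
                ft = times[i].get(female, np.empty(0))
                adj_m += adjacent_count(mt, ft, window_s)
                adj_f += adjacent_count(ft, mt, window_s)
                vx += mt.size
                vy += ft.size
                sizes.append(evs[i].size)
            row = {
                "pair_id": pair.pair_id,
                "experimental_day": day,
                "x": x,
                "m": m,
                "f": f,
                "wa": winter_association(x, m, f),
                "adj_m": adj_m,
                "adj_f": adj_f,
                "vx": vx,
                "vy": vy,
                "vai": (adj_m + adj_f) / (vx + vy) if (vx + vy) else float("nan"),
                "mean_flock_size": float(np.mean(sizes)) if sizes else float("nan"),
            }
            if carry_status:
                row["status"] = pair.status
            rows.append(row)
    columns = [
        "pair_id", "experimental_day", "x", "m", "f", "wa",
        "adj_m", "adj_f", "vx", "vy", "vai", "mean_flock_size",
    ] + (["status"] if carry_status else [])
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Preferred partner


@dataclass(frozen=True)
class PreferredPartnerDay:
    bird_id: str
    experimental_day: int
    preferred_id: str
    is_breeding_partner: int


def preferred_partner_daily(
    bird_id: str,
    day: int,
    wa_table: Mapping[str, tuple[float, int]],
    birds_sex: Mapping[str, str],
    breeding_partner: str,
) -> PreferredPartnerDay | None:
    """Pick the day's preferred partner for one focal bird.

    ``wa_table`` maps each same-day associate to ``(wa, shared_events)``.
    Associates whose sex is unknown or equal to the focal's are never
    eligible, which realises the fallback rule: if the top associate overall
    has unknown sex, the choice drops to the best known-opposite-sex one.
    Returns None when no opposite-sex associate exists that day.
    """
    focal_sex = birds_sex.get(bird_id, "U")
    if focal_sex not in ("M", "F"):
        return None
    opposite = "F" if focal_sex == "M" else "M"
    candidates = [
        (wa, x, assoc)
        for assoc, (wa, x) in wa_table.items()
        if assoc != bird_id and birds_sex.get(assoc, "U") == opposite
    ]
    if not candidates:
        return None
    # Ties: higher WA, then higher shared-event count, then lexicographic id.
    best = min(candidates, key=lambda c: (-c[0], -c[1], c[2]))
    return PreferredPartnerDay(
        bird_id=bird_id,
        experimental_day=day,
        preferred_id=best[2],
        is_breeding_partner=int(best[2] == breeding_partner),
    )


def _daily_wa_tables(index: _DayIndex, day: int) -> dict[str, dict[str, tuple[float, int]]]:
    """All nonzero dyadic WA values for one day, keyed by focal bird."""
    members = index.membership[day]
    birds = sorted(members)
    counts = {b: len(evs) for b, evs in members.items()}
    out: dict[str, dict[str, tuple[float, int]]] = {b: {} for b in birds}
    for i, a in enumerate(birds):
        ea = members[a]
        for b in birds[i + 1:]:
            x = len(ea & members[b])
            if x == 0:
                continue
            wa = x / (counts[a] + counts[b] - x)
            out[a][b] = (wa, x)
            out[b][a] = (wa, x)
    return out


def preferred_partner_table(
    events: Sequence[FlockEvent],
    birds: pd.DataFrame,
    partner_map: Mapping[str, str],
    calendar: SeasonCalendar,
) -> pd.DataFrame:
    """Daily preferred-partner series for every focal bird in ``partner_map``.

    ``partner_map`` maps focal bird id -> its focal breeding partner id.
    Only days on which the focal bird was detected and had at least one
    opposite-sex associate yield a row.
    """
    index = _DayIndex(events, calendar)
    sex = dict(zip(birds["bird_id"], birds["sex"]))
    rows = []
    for day in index.days:
        tables = _daily_wa_tables(index, day)
        for bird_id, partner in partner_map.items():
            wa_table = tables.get(bird_id)
            if not wa_table:
                continue
            rec = preferred_partner_daily(bird_id, day, wa_table, sex, partner)
            if rec is not None:
                rows.append(rec)
    return pd.DataFrame(
        {
            "bird_id": [r.bird_id for r in rows],
            "experimental_day": [r.experimental_day for r in rows],
            "preferred_id": [r.preferred_id for r in rows],
            "is_breeding_partner": [r.is_breeding_partner for r in rows],
        }
    )


def preferred_model_table(preferred: pd.DataFrame, pairs: pd.DataFrame,
                          birds: pd.DataFrame) -> pd.DataFrame:
    """Expand the preferred-partner series to one row per (pair member, day).

    Adds pair_id, status and sex so the series can be modelled at the
    individual level while permuting at the pair level. A bird belonging to
    two analysed pairs (divorcing + new) contributes one series per pair.
    """
    sex = dict(zip(birds["bird_id"], birds["sex"]))
    out = []
    for pair in pairs.itertuples(index=False):
        for bird, mate in ((pair.male_id, pair.female_id), (pair.female_id, pair.male_id)):
            sub = preferred[preferred["bird_id"] == bird]
            if sub.empty:
                continue
            frame = sub.copy()
            frame["is_breeding_partner"] = (frame["preferred_id"] == mate).astype(int)
            frame["pair_id"] = pair.pair_id
            frame["status"] = pair.status
            frame["sex"] = sex.get(bird, "U")
            out.append(frame)
    if not out:
        return pd.DataFrame(
            columns=["bird_id", "experimental_day", "preferred_id",
                     "is_breeding_partner", "pair_id", "status", "sex"]
        )
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Partner vs non-partner associates


def nonpair_comparison(
    partner_score: float, other_scores: Sequence[float]
) -> tuple[float, float] | None:
    """(partner score, mean over non-partner associates); None if no others."""
    others = [s for s in other_scores if not np.isnan(s)]
    if not others:
        return None
    return partner_score, float(np.mean(others))


def nonpair_comparison_table(
    events: Sequence[FlockEvent],
    pairs: pd.DataFrame,
    calendar: SeasonCalendar,
    window_s: float = ADJACENCY_WINDOW_S,
) -> pd.DataFrame:
    """Long-format per bird-day scores with a partner/non-partner indicator.

    For each focal pair member and day, emits the WA and VAI of the focal
    bird with its breeding partner (``is_partner=1``) and with each other
    same-day associate (``is_partner=0``). Days without the partner or
    without any other associate still emit whichever rows exist, so both the
    paired comparison and the model-ready long table can be built from this.
    """
    index = _DayIndex(events, calendar)
    focals = {}
    for pair in pairs.itertuples(index=False):
        focals[pair.male_id] = (pair.female_id, pair.pair_id)
        focals[pair.female_id] = (pair.male_id, pair.pair_id)
    rows = []
    for day in index.days:
        members = index.membership[day]
        times = index.visit_times[day]
        counts = {b: len(evs) for b, evs in members.items()}
        for bird, (partner, pair_id) in focals.items():
            eb = members.get(bird)
            if not eb:
                continue
            for assoc in sorted(members):
                if assoc == bird:
                    continue
                shared = eb & members[assoc]
                if not shared:
                    continue
                x = len(shared)
                wa = x / (counts[bird] + counts[assoc] - x)
                adj_a = adj_b = va = vb = 0
                for i in shared:
                    ta = times[i].get(bird, np.empty(0))
                    tb = times[i].get(assoc, np.empty(0))
                    adj_a += adjacent_count(ta, tb, window_s)
                    adj_b += adjacent_count(tb, ta, window_s)
                    va += ta.size
                    vb += tb.size
                vai = (adj_a + adj_b) / (va + vb) if (va + vb) else float("nan")
                rows.append(
                    (bird, pair_id, day, assoc, int(assoc == partner), wa, vai)
                )
    return pd.DataFrame(
        rows,
        columns=["bird_id", "pair_id", "experimental_day", "associate_id",
                 "is_partner", "wa", "vai"],
    )
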