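"""Seeded synthetic study datasets with known ground truth.

The generator emulates a Wytham-style winter study design: ~65 grid-spaced
feeders sampled on 13 weekends (Saturday/Sunday) of one focal winter, linked
to breeding records of the springs before (t-1) and after (t+1), an
"observed alive" sightings table, and a bird attribute table. Every pipeline
stage therefore has a truth to recover:

* **Pair histories** are constructed to satisfy exactly one classification
  rule each — faithful, divorcing (including the "partner unobserved at t+1
  but sighted later" subtype), new (including the juvenile-partner subtype)
  and juvenile — plus *decoys*: ambiguous histories (``excluded_unclear``)
  and pairs that never visit feeders (``excluded_absent``).

* **Visit streams** are built from bursty flocking events per feeder-day
  (Poisson event counts, Gaussian within-event visit times whose spread is
  far below inter-event gaps, 1/3-s detector resolution). Each pair joins an
  event *jointly* with probability
  ``invlogit(baseline + offset_status + slope_status * z(day) +
  quad_status * z(day)^2)``, otherwise members may join independently; within
  joint events, follower visits land within (0, 3] s of a partner visit with
  a status-specific probability. This encodes season-long, status-structured
  trends in both WA and VAI on the logit scale of joint event membership.

Status trajectory defaults mirror the qualitative winter dynamics the
pipeline is meant to detect: divorcing pairs associate least and decline over
the season, faithful pairs associate most and increase, newly forming pairs
follow an n-shaped rise, juvenile pairs a u-shaped one. Only the signs and
ordering of these effects are asserted anywhere; flock sizes and visit rates
are emergent and plausible rather than calibrated.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import records_io
from .records_io import SeasonCalendar, make_calendar, experimental_day, snap_to_resolution
from .pair_status import pair_key

__all__ = [
    "SimConfig",
    "Population",
    "simulate_population",
    "simulate_visits",
    "simulate_dataset",
    "write_dataset",
    "make_fixture",
    "FIXTURE_NAMES",
]

_STATUSES = ("faithful", "divorcing", "new", "juvenile")


@dataclass(frozen=True)
class SimConfig:
    """Study-design and effect-size parameters for the generator.

    Defaults encode the emulated design: 65 feeders, 13 weekends, one focal
    winter starting on the first December Saturday, and per-season pair
    counts in the proportions of the real study (faithful 26, divorcing 9,
    new 31, juvenile 30). Trajectory parameters are on the logit scale of
    per-event joint membership; slopes/quadratics apply to the z-scored
    experimental day.
    """

    n_feeders: int = 65
    n_weekends: int = 13
    first_saturday: dt.date = dt.date(2011, 12, 3)
    winter_label: str = "2011-12"
    year_t_minus_1: int = 2011
    year_t_plus_1: int = 2012
    n_pairs_per_status: Mapping[str, int] = field(
        default_factory=lambda: {"faithful": 26, "divorcing": 9, "new": 31, "juvenile": 30}
    )
    n_floaters: int = 20
    n_unclear_decoys: int = 6
    n_absent_decoys: int = 6
    baseline_wa_logit: float = -3.5
    status_offsets: Mapping[str, float] = field(
        default_factory=lambda: {
            "faithful": 0.0, "new": -0.54, "juvenile": -0.88, "divorcing": -1.31,
        }
    )
    status_slopes: Mapping[str, float] = field(
        default_factory=lambda: {
            "faithful": 0.24, "new": 0.14, "juvenile": 0.29, "divorcing": -0.26,
        }
    )
    status_quadratic: Mapping[str, float] = field(
        default_factory=lambda: {
            "faithful": 0.0, "new": -0.09, "juvenile": 0.09, "divorcing": 0.0,
        }
    )
    adjacency_prob: Mapping[str, float] = field(
        default_factory=lambda: {
            "faithful": 0.30, "new": 0.31, "juvenile": 0.31, "divorcing": 0.14,
        }
    )
    indep_join_prob: float = 0.02
    flock_rate_per_feeder_day: float = 3.0
    visits_per_member_mean: float = 2.0  # zero-truncated Poisson
    p_unknown_sex: float = 0.3
    p_missing_t_plus_1_but_alive: float = 0.3
    p_new_with_juvenile: float = 0.3
    day_start_s: float = 7 * 3600.0
    day_length_s: float = 10 * 3600.0
    within_event_sd_s: float = 40.0

    def __post_init__(self) -> None:
        for status in _STATUSES:
            if status not in self.n_pairs_per_status:
                raise ValueError(f"n_pairs_per_status missing {status!r}")
            if self.n_pairs_per_status[status] < 0:
                raise ValueError(f"negative pair count for {status!r}")
            for m in (self.status_offsets, self.status_slopes, self.status_quadratic):
                if not np.isfinite(m[status]):
                    raise ValueError(f"non-finite trajectory parameter for {status!r}")
            if not 0.0 <= self.adjacency_prob[status] <= 1.0:
                raise ValueError(f"adjacency_prob[{status!r}] outside [0, 1]")
        for name in ("indep_join_prob", "p_unknown_sex",
                     "p_missing_t_plus_1_but_alive", "p_new_with_juvenile"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if min(self.n_feeders, self.n_weekends) < 1:
            raise ValueError("n_feeders and n_weekends must be >= 1")
        if min(self.n_floaters, self.n_unclear_decoys, self.n_absent_decoys) < 0:
            raise ValueError("counts must be non-negative")
        if self.flock_rate_per_feeder_day <= 0 or self.visits_per_member_mean < 1:
            raise ValueError("flock rate must be positive; visits per member >= 1")
        if self.within_event_sd_s <= 0 or self.day_length_s <= 0:
            raise ValueError("time-scale parameters must be positive")

    def calendar(self) -> SeasonCalendar:
        return make_calendar(self.winter_label, self.first_saturday, self.n_weekends)


@dataclass
class Population:
    """Simulated birds, breeding records, sightings and their ground truth."""

    birds: pd.DataFrame
    breeding_t_minus_1: pd.DataFrame
    breeding_t_plus_1: pd.DataFrame
    sightings: pd.DataFrame
    ground_truth: dict
    config: SimConfig

    @property
    def present_birds(self) -> list[str]:
        return sorted(
            b for b, info in self.ground_truth["birds"].items() if info["present_winter"]
        )

    def analysed_pairs(self) -> pd.DataFrame:
        rows = [
            {
                "pair_id": pid,
                "male_id": info["male_id"],
                "female_id": info["female_id"],
                "status": info["status"],
            }
            for pid, info in sorted(self.ground_truth["pairs"].items())
            if not info["decoy"]
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Population construction


class _Builder:
    def __init__(self, config: SimConfig):
        self.config = config
        self.birds: list[dict] = []
        self.b1: list[dict] = []
        self.b3: list[dict] = []
        self.sightings: list[dict] = []
        self.pairs: dict[str, dict] = {}
        self.absent: set[str] = set()
        self._nest = {config.year_t_minus_1: 0, config.year_t_plus_1: 0}

    def bird(self, bird_id: str, sex: str, cohort: int | None, present: bool = True) -> str:
        self.birds.append({"bird_id": bird_id, "sex": sex, "cohort_year": cohort})
        if not present:
            self.absent.add(bird_id)
        return bird_id

    def nest(self, year: int, male: str, female: str) -> None:
        self._nest[year] += 1
        rows = self.b1 if year == self.config.year_t_minus_1 else self.b3
        rows.append(
            {
                "season_year": year,
                "nest_id": f"n{year}_{self._nest[year]:04d}",
                "male_id": male,
                "female_id": female,
            }
        )

    def pair(self, male: str, female: str, status: str, decoy: bool) -> None:
        cfg = self.config
        tracked = status in _STATUSES
        self.pairs[pair_key(male, female)] = {
            "male_id": male,
            "female_id": female,
            "status": status,
            "decoy": decoy,
            "baseline_logit": cfg.baseline_wa_logit
            + (cfg.status_offsets[status] if tracked else 0.0),
            "slope": cfg.status_slopes[status] if tracked else 0.0,
            "quadratic": cfg.status_quadratic[status] if tracked else 0.0,
            "adjacency_prob": cfg.adjacency_prob[status] if tracked else 0.2,
        }


def simulate_population(config: SimConfig, seed: int = 0) -> Population:
    """Emit birds, breeding records at t-1/t+1, sightings and ground truth.

    Every requested pair's history satisfies exactly its status's defining
    rules; decoy dyads with ambiguous or absent histories are added so the
    classifier's exclusion branches are exercised. Immigrant re-pairing
    partners and displaced former partners are winter-absent, so the extra
    dyads they create are ``excluded_absent`` (recorded in the ground truth).
    """
    rng = np.random.default_rng(seed)
    cfg = config
    bld = _Builder(cfg)
    y1, y3 = cfg.year_t_minus_1, cfg.year_t_plus_1
    adult_cohort = y1 - 2
    late = dt.date(y3, 9, 15)  # "observed alive" strictly after spring t+1

    for i in range(cfg.n_pairs_per_status["faithful"]):
        m = bld.bird(f"fa{i:03d}m", "M", adult_cohort)
        f = bld.bird(f"fa{i:03d}f", "F", adult_cohort)
        bld.nest(y1, m, f)
        bld.nest(y3, m, f)
        bld.pair(m, f, "faithful", decoy=False)

    for i in range(cfg.n_pairs_per_status["divorcing"]):
        m = bld.bird(f"dv{i:03d}m", "M", adult_cohort)
        f = bld.bird(f"dv{i:03d}f", "F", adult_cohort)
        bld.nest(y1, m, f)
        imf = bld.bird(f"im{i:03d}f", "F", adult_cohort, present=False)
        bld.nest(y3, m, imf)
        bld.pair(m, imf, "excluded_absent", decoy=True)
        if rng.random() < cfg.p_missing_t_plus_1_but_alive:
            # known-alive subtype: female unobserved at t+1, sighted later
            bld.sightings.append({"bird_id": f, "date": late})
        else:
            imm = bld.bird(f"im{i:03d}m", "M", adult_cohort, present=False)
            bld.nest(y3, imm, f)
            bld.pair(imm, f, "excluded_absent", decoy=True)
        bld.pair(m, f, "divorcing", decoy=False)

    for i in range(cfg.n_pairs_per_status["new"]):
        m = bld.bird(f"nw{i:03d}m", "M", adult_cohort)
        oxf = bld.bird(f"ox{i:03d}f", "F", adult_cohort, present=False)
        bld.nest(y1, m, oxf)
        bld.pair(m, oxf, "excluded_absent", decoy=True)
        if rng.random() < cfg.p_new_with_juvenile:
            f = bld.bird(f"nw{i:03d}f", "F", y1)  # juvenile partner subtype
        else:
            f = bld.bird(f"nw{i:03d}f", "F", adult_cohort)
            oxm = bld.bird(f"ox{i:03d}m", "M", adult_cohort, present=False)
            bld.nest(y1, oxm, f)
            bld.pair(oxm, f, "excluded_absent", decoy=True)
        bld.nest(y3, m, f)
        bld.pair(m, f, "new", decoy=False)

    for i in range(cfg.n_pairs_per_status["juvenile"]):
        m = bld.bird(f"jv{i:03d}m", "M", y1)
        f = bld.bird(f"jv{i:03d}f", "F", y1)
        bld.nest(y3, m, f)
        bld.pair(m, f, "juvenile", decoy=False)

    for i in range(cfg.n_unclear_decoys):
        # together at t-1; male re-pairs, female vanishes with no later sighting
        m = bld.bird(f"uc{i:03d}m", "M", adult_cohort)
        f = bld.bird(f"uc{i:03d}f", "F", adult_cohort)
        bld.nest(y1, m, f)
        imf = bld.bird(f"ui{i:03d}f", "F", adult_cohort, present=False)
        bld.nest(y3, m, imf)
        bld.pair(m, imf, "excluded_absent", decoy=True)
        bld.pair(m, f, "excluded_unclear", decoy=True)

    for i in range(cfg.n_absent_decoys):
        m = bld.bird(f"ab{i:03d}m", "M", adult_cohort, present=False)
        f = bld.bird(f"ab{i:03d}f", "F", adult_cohort, present=False)
        bld.nest(y1, m, f)
        bld.nest(y3, m, f)
        bld.pair(m, f, "excluded_absent", decoy=True)

    for i in range(cfg.n_floaters):
        u = rng.random()
        sex = "U" if u < cfg.p_unknown_sex else ("M" if i % 2 == 0 else "F")
        bld.bird(f"fl{i:03d}", sex, y1 - 1)

    birds = pd.DataFrame(bld.birds, columns=["bird_id", "sex", "cohort_year"])
    birds["cohort_year"] = birds["cohort_year"].astype("Int64")
    ground_truth = {
        "pairs": bld.pairs,
        "birds": {
            row["bird_id"]: {
                "sex": row["sex"],
                "cohort_year": row["cohort_year"],
                "present_winter": row["bird_id"] not in bld.absent,
            }
            for row in bld.birds
        },
        "winter_label": cfg.winter_label,
    }
    cols = ["season_year", "nest_id", "male_id", "female_id"]
    return Population(
        birds=birds,
        breeding_t_minus_1=pd.DataFrame(bld.b1, columns=cols),
        breeding_t_plus_1=pd.DataFrame(bld.b3, columns=cols),
        sightings=pd.DataFrame(bld.sightings, columns=["bird_id", "date"]),
        ground_truth=ground_truth,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Visit-stream simulation


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def draw_event_memberships(
    rng: np.random.Generator,
    n_events: int,
    p_joint: np.ndarray,
    n_birds: int,
    male_ix: np.ndarray,
    female_ix: np.ndarray,
    indep_join_prob: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one day's event memberships.

    Returns ``(joint, member)``: a (n_events x n_pairs) boolean matrix of
    joint pair attendance (each pair joins an event jointly with its own
    probability) and a (n_events x n_birds) boolean membership matrix in
    which non-joint birds attend independently and joint pairs' members are
    switched on.
    """
    joint = rng.random((n_events, p_joint.size)) < p_joint
    member = rng.random((n_events, n_birds)) < indep_join_prob
    rows = np.nonzero(joint)
    member[rows[0], male_ix[rows[1]]] = True
    member[rows[0], female_ix[rows[1]]] = True
    return joint, member


def simulate_visits(population: Population, seed: int = 1) -> pd.DataFrame:
    """Generate the focal winter's RFID visit table for a population.

    Returns the canonical visit table (tag_id, feeder_id, timestamp, date)
    with timestamps on the 1/3-s detector grid, weekend days only.
    """
    cfg = population.config
    calendar = cfg.calendar()
    rng = np.random.default_rng(seed)

    present = population.present_birds
    bird_ix = {b: i for i, b in enumerate(present)}
    n_birds = len(present)

    # Pairs whose members are both present attend events jointly.
    joint_pairs = [
        info
        for info in population.ground_truth["pairs"].values()
        if info["male_id"] in bird_ix and info["female_id"] in bird_ix
    ]
    pm = np.array([bird_ix[p["male_id"]] for p in joint_pairs], dtype=int)
    pf = np.array([bird_ix[p["female_id"]] for p in joint_pairs], dtype=int)
    base = np.array([p["baseline_logit"] for p in joint_pairs])
    slope = np.array([p["slope"] for p in joint_pairs])
    quad = np.array([p["quadratic"] for p in joint_pairs])
    adj_p = np.array([p["adjacency_prob"] for p in joint_pairs])

    days = calendar.sampling_days()
    exp_days = np.array([experimental_day(calendar, d) for d in days], dtype=float)
    zdays = (exp_days - exp_days.mean()) / (exp_days.std() or 1.0)

    tag_col: list[str] = []
    feeder_col: list[str] = []
    time_col: list[float] = []
    date_col: list[dt.date] = []
    feeder_names = [f"F{j:03d}" for j in range(cfg.n_feeders)]
    season_start = calendar.season_start

    vpm = cfg.visits_per_member_mean - 1.0
    follow_lo = records_io.DETECTOR_RESOLUTION_S

    for d_idx, date in enumerate(days):
        day_offset = (date - season_start.date()).days * 86400.0
        p_joint = _expit(base + slope * zdays[d_idx] + quad * zdays[d_idx] ** 2)
        n_events_by_feeder = rng.poisson(cfg.flock_rate_per_feeder_day, cfg.n_feeders)
        total_events = int(n_events_by_feeder.sum())
        if total_events == 0:
            continue
        event_feeder = np.repeat(np.arange(cfg.n_feeders), n_events_by_feeder)
        centres = cfg.day_start_s + rng.uniform(0.0, cfg.day_length_s, total_events)

        joint, member = draw_event_memberships(
            rng, total_events, p_joint, n_birds, pm, pf, cfg.indep_join_prob
        )

        for e in range(total_events):
            members = np.flatnonzero(member[e])
            if members.size == 0:
                continue
            feeder = feeder_names[event_feeder[e]]
            counts = 1 + rng.poisson(vpm, members.size)
            times = centres[e] + rng.normal(0.0, cfg.within_event_sd_s, int(counts.sum()))
            owners = np.repeat(members, counts)
            split = np.split(np.arange(owners.size), np.cumsum(counts))[:-1]
            per_bird = dict(zip(members.tolist(), split))

            tag_col.extend(present[b] for b in owners)
            feeder_col.extend([feeder] * owners.size)
            time_col.extend((day_offset + times).tolist())
            date_col.extend([date] * owners.size)

            for p in np.flatnonzero(joint[e]):
                for leader, follower in ((pm[p], pf[p]), (pf[p], pm[p])):
                    lead_times = times[per_bird[leader]]
                    emit = rng.random(lead_times.size) < adj_p[p] / 2.0
                    n_follow = int(emit.sum())
                    if n_follow == 0:
                        continue
                    ft = lead_times[emit] + rng.uniform(follow_lo, 3.0, n_follow)
                    tag_col.extend([present[follower]] * n_follow)
                    feeder_col.extend([feeder] * n_follow)
                    time_col.extend((day_offset + ft).tolist())
                    date_col.extend([date] * n_follow)

    visits = pd.DataFrame(
        {
            "tag_id": tag_col,
            "feeder_id": feeder_col,
            "timestamp": snap_to_resolution(np.array(time_col)),
            "date": date_col,
        }
    )
    visits = visits.drop_duplicates(subset=["tag_id", "feeder_id", "timestamp"])
    visits = visits.sort_values(
        ["feeder_id", "timestamp", "tag_id"], kind="mergesort"
    ).reset_index(drop=True)
    return visits


def simulate_dataset(
    config: SimConfig | None = None, seed: int = 0, outdir: str | Path | None = None
) -> tuple[Population, pd.DataFrame]:
    """Convenience wrapper: population + visits from one master seed."""
    config = config or SimConfig()
    ss = np.random.SeedSequence(seed)
    pop_seed, visit_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    population = simulate_population(config, seed=pop_seed)
    visits = simulate_visits(population, seed=visit_seed)
    if outdir is not None:
        write_dataset(population, visits, outdir)
    return population, visits


def write_dataset(population: Population, visits: pd.DataFrame, outdir: str | Path) -> None:
    """Write the five CSV inputs, the calendar and ground_truth.json.

    Output is byte-identical for identical seeds and configs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calendar = population.config.calendar()
    records_io.write_visits(visits, outdir / "visits.csv", calendar)
    population.birds.to_csv(outdir / "birds.csv", index=False)
    population.breeding_t_minus_1.to_csv(outdir / "breeding_t_minus_1.csv", index=False)
    population.breeding_t_plus_1.to_csv(outdir / "breeding_t_plus_1.csv", index=False)
    population.sightings.to_csv(outdir / "sightings.csv", index=False)
    records_io.write_calendar([calendar], outdir / "calendar.yaml")
    payload = dict(population.ground_truth)
    payload["config"] = {
        k: (v.isoformat() if isinstance(v, dt.date) else
            dict(v) if isinstance(v, Mapping) else v)
        for k, v in asdict(population.config).items()
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Direct daily-table simulation (no event machinery)


def simulate_daily_table(
    seed: int,
    n_pairs_per_status: Mapping[str, int],
    n_weekends: int = 13,
    mean_events_per_day: float = 12.0,
    baseline_logit: float = -0.3,
    offsets: Mapping[str, float] | None = None,
    slopes: Mapping[str, float] | None = None,
    quadratics: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Draw a WA-style daily table straight from the binomial model.

    Per pair-day the pair's event total ``n`` is 1 + Poisson and the shared
    count ``x`` is Binomial(n, invlogit(eta)) with
    ``eta = baseline + offset + slope * z(day) + quad * z(day)^2`` — so a
    logit-scale binomial fit recovers the stated parameters exactly (up to
    sampling error). Useful for calibration checks and null simulations where
    the visit-stream machinery is irrelevant.
    """
    rng = np.random.default_rng(seed)
    offsets = offsets or {}
    slopes = slopes or {}
    quadratics = quadratics or {}
    days = np.array([7 * k + d for k in range(n_weekends) for d in (1, 2)], dtype=float)
    z = (days - days.mean()) / days.std()
    rows = []
    for status in sorted(n_pairs_per_status):
        eta = (
            baseline_logit
            + offsets.get(status, 0.0)
            + slopes.get(status, 0.0) * z
            + quadratics.get(status, 0.0) * z**2
        )
        p = _expit(eta)
        for i in range(n_pairs_per_status[status]):
            n = 1 + rng.poisson(mean_events_per_day - 1.0, days.size)
            x = rng.binomial(n, p)
            m = rng.binomial(n - x, 0.5)
            for j, day in enumerate(days):
                rows.append(
                    {
                        "pair_id": f"{status[:2]}{i:04d}a-{status[:2]}{i:04d}b",
                        "status": status,
                        "experimental_day": int(day),
                        "x": int(x[j]),
                        "m": int(m[j]),
                        "f": int(n[j] - x[j] - m[j]),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Committed miniature fixtures


FIXTURE_NAMES = ("tiny_faithful", "separation_case", "two_burst_feeder", "truthtable_pairs")


def make_fixture(name: str):
    """Deterministic miniature datasets for unit and acceptance tests."""
    if name == "tiny_faithful":
        return _tiny_faithful()
    if name == "separation_case":
        return _separation_case()
    if name == "two_burst_feeder":
        return _two_burst_feeder()
    if name == "truthtable_pairs":
        return _truthtable_pairs()
    raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")


def _tiny_calendar() -> SeasonCalendar:
    return make_calendar("tiny", dt.date(2011, 12, 3), 2)


def _tiny_faithful():
    """One faithful pair over two days with hand-checkable x, m, f.

    Day 1: three events — shared, male-only, shared -> x=2, m=1, f=0, WA=2/3.
    Day 2: two events — shared, female-only -> x=1, m=0, f=1, WA=1/2.
    """
    from .flock_detection import FlockEvent

    cal = _tiny_calendar()
    d1, d2 = dt.date(2011, 12, 3), dt.date(2011, 12, 4)

    def ev(i, date, t0, members_visits):
        visits = tuple(sorted(members_visits, key=lambda v: v[1]))
        times = [t for _, t in visits]
        return FlockEvent(
            event_id=f"F000:{date.isoformat()}:{i:03d}", feeder_id="F000", date=date,
            start_time=min(times), end_time=max(times),
            members=frozenset(tag for tag, _ in visits), visits=visits,
        )

    events = [
        ev(0, d1, 1000, [("m1", 1000.0), ("f1", 1002.0), ("m1", 1010.0)]),
        ev(1, d1, 5000, [("m1", 5000.0), ("m1", 5004.0)]),
        ev(2, d1, 9000, [("f1", 9000.0), ("m1", 9002.5), ("f1", 9010.0)]),
        ev(3, d2, 87400, [("m1", 87400.0), ("f1", 87401.0)]),
        ev(4, d2, 90000, [("f1", 90000.0)]),
    ]
    pairs = pd.DataFrame(
        [{"pair_id": pair_key("m1", "f1"), "male_id": "m1", "female_id": "f1",
          "status": "faithful"}]
    )
    birds = pd.DataFrame(
        {"bird_id": ["m1", "f1"], "sex": ["M", "F"], "cohort_year": [2009, 2009]}
    )
    expected = pd.DataFrame(
        {
            "experimental_day": [1, 2],
            "x": [2, 1], "m": [1, 0], "f": [0, 1],
            "wa": [2 / 3, 1 / 2],
        }
    )
    return {"calendar": cal, "events": events, "pairs": pairs, "birds": birds,
            "expected_daily": expected}


def _separation_case() -> pd.DataFrame:
    """Preferred-partner table where the divorcing level is perfectly separated.

    No divorcing bird ever has its breeding partner as preferred social
    partner (all responses 0); the other statuses mix 0s and 1s with a mild
    upward trend, so the over-time model remains estimable.
    """
    rng = np.random.default_rng(20111203)
    rows = []
    days = [7 * k + d for k in range(13) for d in (1, 2)]
    plan = {"faithful": (8, 0.55), "new": (8, 0.35), "juvenile": (6, 0.30),
            "divorcing": (4, 0.0)}
    for status, (n_pairs, p_base) in plan.items():
        for i in range(n_pairs):
            pid = f"{status[:2]}{i:02d}a-{status[:2]}{i:02d}b"
            for member, sex in ((f"{status[:2]}{i:02d}a", "M"), (f"{status[:2]}{i:02d}b", "F")):
                for day in days:
                    if status == "divorcing":
                        y = 0
                    else:
                        p = min(0.95, p_base + 0.01 * day / 7)
                        y = int(rng.random() < p)
                    rows.append(
                        {"bird_id": member, "pair_id": pid, "status": status,
                         "sex": sex, "experimental_day": day,
                         "is_breeding_partner": y}
                    )
    table = pd.DataFrame(rows)
    # Guarantee mixed responses in the non-divorcing levels.
    for status in ("faithful", "new", "juvenile"):
        sub = table["status"] == status
        table.loc[table[sub].index[0], "is_breeding_partner"] = 0
        table.loc[table[sub].index[1], "is_breeding_partner"] = 1
    return table


def _two_burst_feeder() -> pd.DataFrame:
    """Two 20-visit bursts 600 s apart (within-burst spread ~10 s).

    Burst 1 members: {a, b, c}; burst 2 members: {c, d}. Exactly two events
    under both the mixture detector and a 60-s gap oracle.
    """
    rng = np.random.default_rng(42)
    date = dt.date(2011, 12, 3)
    t1 = np.sort(30000.0 + rng.normal(0.0, 10.0, 20))
    t2 = np.sort(30600.0 + rng.normal(0.0, 10.0, 20))
    tags1 = [["a", "b", "c"][i % 3] for i in range(20)]
    tags2 = [["c", "d"][i % 2] for i in range(20)]
    return pd.DataFrame(
        {
            "tag_id": tags1 + tags2,
            "feeder_id": "F000",
            "timestamp": snap_to_resolution(np.concatenate([t1, t2])),
            "date": [date] * 40,
        }
    )


def _truthtable_pairs():
    """Enumerated three-season histories with committed expected statuses.

    Loads the frozen truth table (one row per feasible combination of t-1
    state, t+1 state, later-alive flags and juvenile flags for a focal dyad
    A-B, both present in winter) and builds the corresponding record tables
    for each case. Returns a list of case dicts plus the expected frame.
    """
    from importlib import resources

    with resources.files("pairwinter.data").joinpath(
        "pair_status_truthtable.csv"
    ).open() as fh:
        expected = pd.read_csv(fh)

    y1, y3 = 2011, 2012
    cases = []
    for row in expected.itertuples(index=False):
        b1, b3, sight, birds = _truthtable_records(row, y1, y3)
        cases.append(
            {
                "case_id": row.case_id,
                "breeding_t_minus_1": b1,
                "breeding_t_plus_1": b3,
                "sightings": sight,
                "birds": birds,
                "winter_presence": {"A", "B"},
                "expected_status": row.expected_status,
            }
        )
    return {"cases": cases, "expected": expected}


def _truthtable_records(row, y1: int, y3: int):
    """Build breeding/sighting/bird tables for one truth-table case.

    A is male, B is female; C/D are A's and B's alternative partners, E/F
    fill the other sex at those nests. Alternative partners are winter-absent
    so they add only excluded_absent dyads.
    """
    b1, b3, sight = [], [], []
    juv_a = row.juv in ("A", "both")
    juv_b = row.juv in ("B", "both")

    def nest(rows, year, male, female):
        rows.append({"season_year": year, "nest_id": f"n{year}_{len(rows):02d}",
                     "male_id": male, "female_id": female})

    if row.t1 == "together":
        nest(b1, y1, "A", "B")
    elif row.t1 == "both_others":
        nest(b1, y1, "A", "C")
        nest(b1, y1, "D", "B")
    elif row.t1 == "A_other_B_none":
        nest(b1, y1, "A", "C")
    elif row.t1 == "B_other_A_none":
        nest(b1, y1, "D", "B")

    if row.t3 == "together":
        nest(b3, y3, "A", "B")
    elif row.t3 == "both_others":
        nest(b3, y3, "A", "C")
        nest(b3, y3, "D", "B")
    elif row.t3 == "A_other_B_none":
        nest(b3, y3, "A", "C")
    elif row.t3 == "B_other_A_none":
        nest(b3, y3, "D", "B")

    if row.a_alive_later:
        sight.append({"bird_id": "A", "date": dt.date(y3, 9, 1)})
    if row.b_alive_later:
        sight.append({"bird_id": "B", "date": dt.date(y3, 9, 1)})

    birds = pd.DataFrame(
        {
            "bird_id": ["A", "B", "C", "D"],
            "sex": ["M", "F", "F", "M"],
            "cohort_year": [y1 if juv_a else y1 - 2, y1 if juv_b else y1 - 2,
                            y1 - 2, y1 - 2],
        }
    )
    cols = ["season_year", "nest_id", "male_id", "female_id"]
    return (
        pd.DataFrame(b1, columns=cols),
        pd.DataFrame(b3, columns=cols),
        pd.DataFrame(sight, columns=["bird_id", "date"]),
        birds,
    )
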