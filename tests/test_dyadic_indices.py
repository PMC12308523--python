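"""Association indices against brute-force counting oracles."""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from pairwinter.dyadic_indices import (
    adjacent_count,
    daily_dyad_table,
    nonpair_comparison,
    nonpair_comparison_table,
    preferred_partner_daily,
    visit_adjacency,
    winter_association,
)
from pairwinter.flock_detection import FlockEvent
from pairwinter.records_io import make_calendar
from pairwinter.synthetic_data import make_fixture

CAL = make_calendar("w", dt.date(2011, 12, 3), 13)
DATE = dt.date(2011, 12, 3)


def event(i, visits, date=DATE, feeder="F0"):
    visits = tuple(sorted(visits, key=lambda v: v[1]))
    times = [t for _, t in visits]
    return FlockEvent(
        event_id=f"{feeder}:{date.isoformat()}:{i:03d}", feeder_id=feeder, date=date,
        start_time=min(times), end_time=max(times),
        members=frozenset(tag for tag, _ in visits), visits=visits,
    )


def brute_adjacency(follower, leader, w=3.0):
    """Naive double loop: a visit follows if a partner visit is in [t-w, t)."""
    return sum(1 for t in follower if any(0.0 < t - s <= w for s in leader))


class TestWinterAssociation:
    @pytest.mark.parametrize(
        "x,m,f,expected",
        [(0, 3, 2, 0.0), (5, 0, 0, 1.0), (3, 2, 1, 0.5), (1, 1, 2, 0.25)],
    )
    def test_simple_ratio_values(self, x, m, f, expected):
        assert winter_association(x, m, f) == expected

    def test_no_events_is_undefined(self):
        assert math.isnan(winter_association(0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            winter_association(-1, 0, 0)


class TestVisitAdjacency:
    def test_follow_within_window(self):
        ev = event(0, [("f1", 8.0), ("m1", 10.0)])
        adj_m, adj_f, vx, vy, vai = visit_adjacency([ev], "m1", "f1")
        assert (adj_m, adj_f, vx, vy) == (1, 0, 1, 1)
        assert vai == 0.5

    def test_window_closed_at_three_seconds(self):
        ev3 = event(0, [("f1", 10.0), ("m1", 13.0)])
        ev31 = event(0, [("f1", 10.0), ("m1", 13.1)])
        assert visit_adjacency([ev3], "m1", "f1")[0] == 1
        assert visit_adjacency([ev31], "m1", "f1")[0] == 0

    def test_simultaneous_visit_not_a_follow(self):
        ev = event(0, [("f1", 10.0), ("m1", 10.0)])
        adj_m, adj_f, *_ = visit_adjacency([ev], "m1", "f1")
        assert adj_m == adj_f == 0

    def test_vai_direct_value(self):
        # 3 adjacent follows out of 20 visits -> VAI = 0.15
        mv = [("m1", 100.0 + 10 * i) for i in range(10)]
        fv = [("f1", 101.0), ("f1", 111.0), ("f1", 121.0)] + [
            ("f1", 400.0 + 10 * i) for i in range(7)
        ]
        ev = event(0, mv + fv)
        adj_m, adj_f, vx, vy, vai = visit_adjacency([ev], "m1", "f1")
        assert adj_m + adj_f == 3 and vx + vy == 20
        assert vai == pytest.approx(0.15)

    def test_one_leader_can_license_multiple_followers(self):
        ev = event(0, [("f1", 10.0), ("m1", 11.0), ("m1", 12.0)])
        assert visit_adjacency([ev], "m1", "f1")[0] == 2

    def test_requires_both_members(self):
        ev = event(0, [("m1", 10.0)])
        with pytest.raises(ValueError):
            visit_adjacency([ev], "m1", "f1")


class TestBruteForceOracles:
    def test_adjacent_count_matches_naive_loop(self):
        rng = np.random.default_rng(21)
        for _ in range(300):
            follower = np.round(rng.uniform(0, 60, rng.integers(0, 12)) * 3) / 3
            leader = np.round(rng.uniform(0, 60, rng.integers(0, 12)) * 3) / 3
            assert adjacent_count(follower, leader) == brute_adjacency(follower, leader)

    def test_daily_counts_match_naive_recount(self):
        rng = np.random.default_rng(22)
        birds = list("mnfg")
        for _ in range(50):
            events = []
            for i in range(int(rng.integers(1, 8))):
                k = int(rng.integers(1, 5))
                who = rng.choice(birds, k, replace=False)
                t0 = rng.uniform(0, 30000)
                visits = [
                    (b, float(np.round((t0 + rng.uniform(0, 60)) * 3) / 3))
                    for b in who
                    for _ in range(int(rng.integers(1, 4)))
                ]
                events.append(event(i, visits))
            pairs = pd.DataFrame(
                [{"pair_id": "m-f", "male_id": "m", "female_id": "f"}]
            )
            table = daily_dyad_table(events, pairs, CAL)
            x = sum(1 for e in events if {"m", "f"} <= e.members)
            m = sum(1 for e in events if "m" in e.members and "f" not in e.members)
            f = sum(1 for e in events if "f" in e.members and "m" not in e.members)
            if x + m + f == 0:
                assert table.empty
                continue
            row = table.iloc[0]
            assert (row.x, row.m, row.f) == (x, m, f)
            assert row.wa == winter_association(x, m, f)
            shared = [e for e in events if {"m", "f"} <= e.members]
            adj_m = sum(
                brute_adjacency(
                    [t for b, t in e.visits if b == "m"],
                    [t for b, t in e.visits if b == "f"],
                )
                for e in shared
            )
            assert row.adj_m == adj_m


class TestDailyTable:
    def test_tiny_fixture_hand_checked(self):
        fx = make_fixture("tiny_faithful")
        table = daily_dyad_table(fx["events"], fx["pairs"], fx["calendar"])
        merged = table.merge(fx["expected_daily"], on="experimental_day",
                             suffixes=("", "_exp"))
        assert (merged["x"] == merged["x_exp"]).all()
        assert (merged["m"] == merged["m_exp"]).all()
        assert (merged["f"] == merged["f_exp"]).all()
        assert np.allclose(merged["wa"], merged["wa_exp"])

    def test_day_with_neither_member_absent_not_zero(self):
        events = [event(0, [("m", 1.0), ("f", 2.0)]),
                  event(1, [("g", 90000.0)], date=dt.date(2011, 12, 4))]
        pairs = pd.DataFrame([{"pair_id": "f-m", "male_id": "m", "female_id": "f"}])
        table = daily_dyad_table(events, pairs, CAL)
        assert list(table["experimental_day"]) == [1]  # no row for day 2

    def test_wa_symmetric_in_member_order(self):
        events = [event(0, [("m", 1.0), ("f", 2.0)]), event(1, [("m", 700.0)])]
        fwd = pd.DataFrame([{"pair_id": "p", "male_id": "m", "female_id": "f"}])
        rev = pd.DataFrame([{"pair_id": "p", "male_id": "f", "female_id": "m"}])
        assert (
            daily_dyad_table(events, fwd, CAL)["wa"].iloc[0]
            == daily_dyad_table(events, rev, CAL)["wa"].iloc[0]
        )

    def test_vai_defined_only_with_shared_events(self):
        events = [event(0, [("m", 1.0)]), event(1, [("f", 700.0)])]
        pairs = pd.DataFrame([{"pair_id": "f-m", "male_id": "m", "female_id": "f"}])
        row = daily_dyad_table(events, pairs, CAL).iloc[0]
        assert row.x == 0 and math.isnan(row.vai) and math.isnan(row.mean_flock_size)


SEX = {"a": "M", "b": "F", "c": "F", "u": "U", "m2": "M"}


class TestPreferredPartner:
    def test_highest_opposite_sex_associate(self):
        rec = preferred_partner_daily(
            "a", 1, {"b": (0.6, 3), "c": (0.4, 2)}, SEX, breeding_partner="b"
        )
        assert rec.preferred_id == "b" and rec.is_breeding_partner == 1

    def test_unknown_sex_top_associate_falls_back(self):
        rec = preferred_partner_daily(
            "a", 1, {"u": (0.7, 4), "b": (0.5, 2)}, SEX, breeding_partner="b"
        )
        assert rec.preferred_id == "b" and rec.is_breeding_partner == 1

    def test_same_sex_associate_never_preferred(self):
        rec = preferred_partner_daily(
            "a", 1, {"m2": (0.9, 5), "c": (0.2, 1)}, SEX, breeding_partner="b"
        )
        assert rec.preferred_id == "c" and rec.is_breeding_partner == 0

    def test_tie_breaks_on_shared_events_then_id(self):
        rec = preferred_partner_daily(
            "a", 1, {"b": (0.5, 2), "c": (0.5, 3)}, SEX, breeding_partner="b"
        )
        assert rec.preferred_id == "c"
        rec = preferred_partner_daily(
            "a", 1, {"b": (0.5, 2), "c": (0.5, 2)}, SEX, breeding_partner="b"
        )
        assert rec.preferred_id == "b"  # lexicographic

    def test_no_opposite_sex_associate_absent(self):
        assert (
            preferred_partner_daily("a", 1, {"m2": (0.9, 5)}, SEX, "b") is None
        )

    def test_preference_is_not_symmetric(self):
        """A's top associate is B while B's is C, on one constructed day."""
        events = [
            event(0, [("a", 0.0), ("b", 10.0)]),
            event(1, [("b", 700.0), ("c", 710.0)]),
            event(2, [("b", 1400.0), ("c", 1410.0)]),
            event(3, [("a", 2100.0), ("b", 2110.0), ("c", 2120.0)]),
        ]
        sex = {"a": "F", "b": "M", "c": "F"}
        # WA(a,b) = 2/4, WA(b,c) = 3/4, WA(a,c) = 1/4
        rec_a = preferred_partner_daily(
            "a", 1, {"b": (0.5, 2), "c": (0.25, 1)}, sex, "b"
        )
        rec_b = preferred_partner_daily(
            "b", 1, {"a": (0.5, 2), "c": (0.75, 3)}, sex, "a"
        )
        assert rec_a.preferred_id == "b" and rec_b.preferred_id == "c"


class TestNonpairComparison:
    def test_partner_and_mean_of_others(self):
        assert nonpair_comparison(0.8, [0.2, 0.4]) == (0.8, pytest.approx(0.3))

    def test_only_partner_present_absent(self):
        assert nonpair_comparison(0.8, []) is None

    def test_table_matches_naive_loop(self):
        rng = np.random.default_rng(30)
        birds = list("mfgh")
        events = []
        for i in range(10):
            who = rng.choice(birds, int(rng.integers(2, 5)), replace=False)
            t0 = float(rng.uniform(0, 30000))
            events.append(
                event(i, [(b, t0 + float(rng.uniform(0, 40))) for b in who])
            )
        pairs = pd.DataFrame([{"pair_id": "f-m", "male_id": "m", "female_id": "f"}])
        table = nonpair_comparison_table(events, pairs, CAL)
        # naive WA of focal m with each associate
        mem = {b: {e.event_id for e in events if b in e.members} for b in birds}
        for row in table[table["bird_id"] == "m"].itertuples():
            x = len(mem["m"] & mem[row.associate_id])
            wa = x / (len(mem["m"]) + len(mem[row.associate_id]) - x)
            assert row.wa == pytest.approx(wa)
            assert row.is_partner == (row.associate_id == "f")


class TestIdentityShuffleInvariance:
    def test_wa_distribution_stable_under_within_day_relabelling(self):
        """Shuffling member identities within a day's events leaves the
        across-dyad WA distribution unchanged in expectation."""
        rng = np.random.default_rng(31)
        birds = [f"b{i}" for i in range(12)]
        events = []
        for i in range(40):
            who = rng.choice(birds, int(rng.integers(2, 6)), replace=False)
            t0 = float(rng.uniform(0, 30000))
            events.append(event(i, [(b, t0 + float(rng.uniform(0, 40))) for b in who]))

        def mean_wa(evs):
            mem = {b: {e.event_id for e in evs if b in e.members} for b in birds}
            vals = []
            for i, a in enumerate(birds):
                for b in birds[i + 1:]:
                    tot = len(mem[a]) + len(mem[b])
                    if tot:
                        x = len(mem[a] & mem[b])
                        vals.append(x / (tot - x))
            return np.mean(vals)

        base = mean_wa(events)
        perms = []
        for _ in range(60):
            shuffled = []
            for i, e in enumerate(events):
                who = rng.choice(birds, len(e.members), replace=False)
                times = sorted(t for _, t in e.visits)[: len(who)]
                shuffled.append(event(i, list(zip(who, times))))
            perms.append(mean_wa(shuffled))
        # the fixture's memberships are exchangeable, so the observed mean WA
        # is one draw from the same ensemble as the shuffled means
        assert abs(base - np.mean(perms)) <= 3 * np.std(perms, ddof=1)
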