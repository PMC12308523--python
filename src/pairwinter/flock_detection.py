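"""Segment feeder-day visit streams into flocking (gathering) events.

Great tits forage in loose fission-fusion flocks; a feeder's RFID detections
arrive in bursts as flocks pass through. Under the gambit of the group, every
individual detected in the same burst is treated as associating, so the unit
of co-occurrence is the "flocking event": a temporal cluster of visits at one
feeder on one day.

Events are recovered by fitting a one-dimensional Gaussian mixture over visit
timestamps for each feeder-day, choosing the number of components 1..K by an
information criterion (BIC by default), assigning each visit to its
maximum-responsibility component, and merging components whose assigned visit
ranges interleave. A simple inter-visit gap threshold (``gap_oracle_events``)
serves as an independent reference partition for well-separated streams.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FlockEvent",
    "EventDetectionConfig",
    "detect_events",
    "detect_all_events",
    "gap_oracle_events",
    "events_to_gbi",
    "events_to_frame",
    "gbi_long",
]


@dataclass(frozen=True)
class FlockEvent:
    """A contiguous cluster of visits at one feeder treated as one group."""

    event_id: str
    feeder_id: str
    date: dt.date
    start_time: float
    end_time: float
    members: frozenset
    visits: tuple  # ordered (tag_id, timestamp) pairs

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class EventDetectionConfig:
    max_components: int = 15
    component_selection: str = "BIC"  # or "AICc"
    min_event_size: int = 1  # in visits; smaller events merge into a neighbour
    fallback_gap_s: float = 600.0  # gap segmentation when EM fails
    #: gaps this long cannot lie inside one gathering event; the stream is
    #: pre-segmented at them and the mixture fitted within each segment,
    #: which leaves the partition unchanged but keeps EM cheap.
    presplit_gap_s: float = 1800.0

    def __post_init__(self) -> None:
        if self.max_components < 1:
            raise ValueError("max_components must be >= 1")
        if self.fallback_gap_s <= 0 or self.presplit_gap_s <= 0:
            raise ValueError("gap thresholds must be positive")
        if self.component_selection not in ("BIC", "AICc"):
            raise ValueError("component_selection must be 'BIC' or 'AICc'")


# ---------------------------------------------------------------------------
# 1-D Gaussian mixture EM

# Variance floor (s^2). A gathering event spans tens of seconds, so no
# mixture component may collapse below a 5-s SD; without this floor, EM puts
# near-singular spikes on ties/followers and BIC oversplits small streams.
_MIN_VAR = 25.0


def _em_1d_kernel(x, k, max_iter, tol, min_var):  # pragma: no cover - jitted
    """EM core: sorted 1-D data, k components, quantile-spaced means init.

    Returns (loglik, labels, ok); ok=False flags a degenerate fit. Written
    with explicit loops so numba can compile it; the numpy path wraps it
    unchanged.
    """
    n = x.size
    mu = np.empty(k)
    for j in range(k):
        mu[j] = x[int((j + 0.5) / k * n)]
    v0 = x.var() / (k * k)
    if v0 < min_var:
        v0 = min_var
    var = np.full(k, v0)
    w = np.full(k, 1.0 / k)
    r = np.empty((n, k))
    ll = -np.inf
    ll_old = -np.inf
    for _ in range(max_iter):
        ll = 0.0
        for i in range(n):
            mmax = -1e300
            for j in range(k):
                lp = -0.5 * ((x[i] - mu[j]) ** 2 / var[j] + np.log(2.0 * np.pi * var[j])) \
                    + np.log(w[j])
                r[i, j] = lp
                if lp > mmax:
                    mmax = lp
            s = 0.0
            for j in range(k):
                r[i, j] = np.exp(r[i, j] - mmax)
                s += r[i, j]
            ll += np.log(s) + mmax
            for j in range(k):
                r[i, j] /= s
        if not np.isfinite(ll):
            return ll, np.zeros(n, np.int64), False
        for j in range(k):
            nk = 0.0
            m1 = 0.0
            for i in range(n):
                nk += r[i, j]
                m1 += r[i, j] * x[i]
            if nk < 1e-10:
                return ll, np.zeros(n, np.int64), False
            w[j] = nk / n
            mu[j] = m1 / nk
            v = 0.0
            for i in range(n):
                v += r[i, j] * (x[i] - mu[j]) ** 2
            var[j] = v / nk + min_var
        if ll - ll_old < tol * (abs(ll_old) + 1.0):
            break
        ll_old = ll
    labels = np.empty(n, np.int64)
    for i in range(n):
        best = 0
        for j in range(1, k):
            if r[i, j] > r[i, best]:
                best = j
        labels[i] = best
    return ll, labels, True


try:  # numba speeds the sweep ~50x; the pure-python kernel is the fallback
    from numba import njit

    _em_1d_jit = njit(cache=True)(_em_1d_kernel)
except ImportError:  # pragma: no cover
    _em_1d_jit = _em_1d_kernel


def _em_1d(x: np.ndarray, k: int, max_iter: int = 150, tol: float = 1e-6):
    """Fit a k-component 1-D mixture; None when the fit degenerates."""
    ll, labels, ok = _em_1d_jit(x, k, max_iter, tol, _MIN_VAR)
    return (ll, labels) if ok else None


def _criterion(loglik: float, k: int, n: int, which: str) -> float:
    n_params = 3 * k - 1  # k means, k variances, k-1 free weights
    if which == "BIC":
        return -2.0 * loglik + n_params * np.log(n)
    aic = -2.0 * loglik + 2.0 * n_params
    if n - n_params - 1 > 0:
        aic += 2.0 * n_params * (n_params + 1) / (n - n_params - 1)
    return aic


def _fit_mixture_labels(x: np.ndarray, config: EventDetectionConfig, rng) -> np.ndarray | None:
    """Select the component count and return per-visit component labels."""
    n = x.size
    # a component needs a few visits to be a credible event
    k_max = max(1, min(config.max_components, len(np.unique(x)), n // 3))
    best = None
    best_score = np.inf
    worse_streak = 0
    for k in range(1, k_max + 1):
        fit = _em_1d(x, k)
        if fit is None and k > 1:
            # one jittered restart before giving up on this k
            fit = _em_1d(x + rng.normal(0.0, 1e-3, size=n), k)
        if fit is None:
            continue
        ll, labels = fit
        score = _criterion(ll, k, n, config.component_selection)
        if score < best_score:
            best_score = score
            best = labels
            worse_streak = 0
        else:
            worse_streak += 1
            if worse_streak >= 3:
                break  # criterion has turned; larger k only overfits
    return best


# ---------------------------------------------------------------------------
# Public API


def _as_stream(visits: pd.DataFrame) -> tuple[str, dt.date, np.ndarray, np.ndarray]:
    feeders = visits["feeder_id"].unique()
    dates = visits["date"].unique()
    if len(feeders) != 1 or len(dates) != 1:
        raise ValueError("detect_events expects visits from a single feeder-day")
    order = np.argsort(visits["timestamp"].to_numpy(), kind="stable")
    t = visits["timestamp"].to_numpy()[order]
    tags = visits["tag_id"].to_numpy()[order]
    return str(feeders[0]), dates[0], t, tags


def _build_events(
    feeder: str, date: dt.date, t: np.ndarray, tags: np.ndarray, labels: np.ndarray,
    min_event_size: int,
) -> list[FlockEvent]:
    """Turn per-visit component labels into disjoint, ordered events."""
    # Components ordered by their earliest assigned visit; merge any whose
    # assigned time ranges overlap (mixture tails can interleave).
    groups = {}
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        groups[lab] = (t[idx[0]], t[idx[-1]], idx)
    spans = sorted(groups.values(), key=lambda g: (g[0], g[1]))
    merged: list[list] = []
    for lo, hi, idx in spans:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
            merged[-1][2] = np.concatenate([merged[-1][2], idx])
        else:
            merged.append([lo, hi, idx])

    # Fold events smaller than min_event_size into the nearest neighbour so
    # the partition property (every visit in exactly one event) is preserved.
    while min_event_size > 1 and len(merged) > 1:
        sizes = [len(g[2]) for g in merged]
        i = int(np.argmin(sizes))
        if sizes[i] >= min_event_size:
            break
        if i == 0:
            j = 1
        elif i == len(merged) - 1:
            j = i - 1
        else:
            j = i - 1 if merged[i][0] - merged[i - 1][1] <= merged[i + 1][0] - merged[i][1] else i + 1
        lo, hi = min(merged[i][0], merged[j][0]), max(merged[i][1], merged[j][1])
        merged[j] = [lo, hi, np.concatenate([merged[j][2], merged[i][2]])]
        del merged[i]

    events = []
    for i, (lo, hi, idx) in enumerate(sorted(merged, key=lambda g: g[0])):
        idx = np.sort(idx)
        events.append(
            FlockEvent(
                event_id=f"{feeder}:{date.isoformat()}:{i:03d}",
                feeder_id=feeder,
                date=date,
                start_time=float(lo),
                end_time=float(hi),
                members=frozenset(tags[idx]),
                visits=tuple(zip(tags[idx], t[idx].tolist())),
            )
        )
    return events


def detect_events(
    visits: pd.DataFrame,
    config: EventDetectionConfig | None = None,
    seed: int = 0,
) -> list[FlockEvent]:
    """Partition one feeder-day's visits into flocking events.

    Deterministic given ``seed`` (used only for jittered EM restarts on
    degenerate streams). A single visit yields one singleton event; if EM
    fails entirely, segmentation falls back to a ``fallback_gap_s`` gap rule.
    """
    config = config or EventDetectionConfig()
    feeder, date, t, tags = _as_stream(visits)
    if t.size == 1 or np.ptp(t) == 0.0:
        labels = np.zeros(t.size, dtype=int)
    else:
        rng = np.random.default_rng(seed)
        # Pre-segment at gaps no single gathering event could span, then fit
        # the mixture within each segment; the partition is unchanged but EM
        # stays cheap on long multi-event days.
        labels = np.empty(t.size, dtype=int)
        offset = 0
        bounds = np.flatnonzero(np.diff(t) > config.presplit_gap_s) + 1
        for seg in np.split(np.arange(t.size), bounds):
            ts = t[seg]
            if ts.size == 1 or np.ptp(ts) == 0.0:
                seg_labels = np.zeros(ts.size, dtype=int)
            else:
                seg_labels = _fit_mixture_labels(ts, config, rng)
                if seg_labels is None:
                    seg_labels = _gap_labels(ts, config.fallback_gap_s)
            labels[seg] = seg_labels + offset
            offset += int(seg_labels.max()) + 1
    return _build_events(feeder, date, t, tags, labels, config.min_event_size)


def _gap_labels(t: np.ndarray, gap_s: float) -> np.ndarray:
    return np.concatenate([[0], np.cumsum(np.diff(t) > gap_s)])


def gap_oracle_events(visits: pd.DataFrame, gap_s: float) -> list[FlockEvent]:
    """Reference partition: split wherever the inter-visit interval exceeds gap_s."""
    feeder, date, t, tags = _as_stream(visits)
    return _build_events(feeder, date, t, tags, _gap_labels(t, gap_s), 1)


def detect_all_events(
    visits: pd.DataFrame,
    config: EventDetectionConfig | None = None,
    seed: int = 0,
) -> list[FlockEvent]:
    """Run event detection over every feeder-day in a season's visit table."""
    config = config or EventDetectionConfig()
    events: list[FlockEvent] = []
    # Stable iteration order (feeder, then date) keeps event ids reproducible.
    for (feeder, date), group in visits.groupby(["feeder_id", "date"], sort=True):
        events.extend(detect_events(group, config, seed=seed))
    return events


# ---------------------------------------------------------------------------
# Group-by-individual structure and tabular output


def events_to_gbi(events: Sequence[FlockEvent]) -> pd.DataFrame:
    """Binary group-by-individual incidence: rows = events, columns = birds."""
    if not events:
        return pd.DataFrame()
    birds = sorted(set().union(*(e.members for e in events)))
    col = {b: j for j, b in enumerate(birds)}
    mat = np.zeros((len(events), len(birds)), dtype=np.int8)
    for i, e in enumerate(events):
        for b in e.members:
            mat[i, col[b]] = 1
    return pd.DataFrame(mat, index=[e.event_id for e in events], columns=birds)


def events_to_frame(events: Sequence[FlockEvent]) -> pd.DataFrame:
    """Summary table: event_id, feeder_id, date, start/end, n_visits, n_members."""
    return pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "feeder_id": [e.feeder_id for e in events],
            "date": [e.date for e in events],
            "start_time": [e.start_time for e in events],
            "end_time": [e.end_time for e in events],
            "n_visits": [e.n_visits for e in events],
            "n_members": [e.size for e in events],
        }
    )


def gbi_long(events: Sequence[FlockEvent]) -> pd.DataFrame:
    """Long-format incidence (event_id, bird_id), one row per membership."""
    rows = [(e.event_id, b) for e in events for b in sorted(e.members)]
    return pd.DataFrame(rows, columns=["event_id", "bird_id"])
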