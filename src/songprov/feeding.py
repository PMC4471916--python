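"""RFID nest-visit logs -> visits -> session feeding rates -> per-male medians.

Antenna registrations (1-second resolution) are collapsed into visits by
merging consecutive registrations of a male separated by less than
``min_gap`` seconds.  Per day, a morning feeding rate spans from the first
visit of the day until 10:00 and an evening rate from 18:00 until the last
visit; each male's feeding effort is the median of all his session rates.
A one-way fixed-effects ANOVA quantifies between- versus within-male
variability of session rates.
"""

from __future__ import annotations

import math
import statistics
import warnings
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats as sps

from .errors import FormatError, StatisticsError

EVENT_KINDS = ("arrival", "departure")

DEFAULT_MIN_GAP = 60.0
DEFAULT_MORNING_END = time(10, 0)
DEFAULT_EVENING_START = time(18, 0)


@dataclass(frozen=True)
class AntennaEvent:
    male_id: str
    timestamp: datetime
    kind: str


@dataclass(frozen=True)
class Visit:
    male_id: str
    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"visit of {self.male_id!r} ends before it starts"
            )


@dataclass(frozen=True)
class SessionRate:
    male_id: str
    date: date
    session: str  # "morning" | "evening"
    window_start: datetime
    window_end: datetime
    visit_count: int
    rate: float  # visits per hour


@dataclass(frozen=True)
class FeedingSummary:
    male_id: str
    median_rate: float
    n_sessions: int


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    ss_between: float
    ss_within: float


def parse_rfid_log(path: str | Path) -> list[AntennaEvent]:
    """Parse a delimited RFID log (male_id, timestamp, kind).

    Duplicate identical rows are dropped; events are sorted per male by
    timestamp.  An unparseable timestamp raises :class:`FormatError` with
    the offending line number (1-based, header = line 1).
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in ("male_id", "timestamp", "kind") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    parsed = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = parsed.isna()
    if bad.any():
        line_no = int(bad.idxmax()) + 2  # +1 header, +1 to 1-based
        raise FormatError(
            f"{path}: unparseable timestamp {df['timestamp'][bad.idxmax()]!r} "
            f"at line {line_no}"
        )
    unknown = ~df["kind"].isin(EVENT_KINDS)
    if unknown.any():
        raise FormatError(
            f"{path}: unknown event kind {df['kind'][unknown.idxmax()]!r} "
            f"(expected one of {EVENT_KINDS})"
        )
    df = df.assign(timestamp=parsed.dt.floor("s")).drop_duplicates()
    df = df.sort_values(["male_id", "timestamp", "kind"], kind="stable")
    return [
        AntennaEvent(male_id=str(r.male_id), timestamp=r.timestamp.to_pydatetime(), kind=str(r.kind))
        for r in df.itertuples()
    ]


def events_to_visits(
    events: Iterable[AntennaEvent], min_gap: float = DEFAULT_MIN_GAP
) -> list[Visit]:
    """Collapse antenna registrations into visits.

    Consecutive registrations of one male less than ``min_gap`` seconds
    apart are merged into a single visit spanning first to last
    registration; a gap of ``min_gap`` or more starts a new visit.  An
    isolated registration yields a zero-duration visit.
    """
    by_male: dict[str, list[datetime]] = {}
    for ev in events:
        by_male.setdefault(ev.male_id, []).append(ev.timestamp)
    visits: list[Visit] = []
    for male_id in sorted(by_male):
        stamps = sorted(by_male[male_id])
        start = prev = stamps[0]
        for t in stamps[1:]:
            if (t - prev).total_seconds() >= min_gap:
                visits.append(Visit(male_id=male_id, start=start, end=prev))
                start = t
            prev = t
        visits.append(Visit(male_id=male_id, start=start, end=prev))
    return visits


def _window_rate(
    male_id: str,
    day: date,
    session: str,
    window_start: datetime,
    window_end: datetime,
    count: int,
) -> SessionRate | None:
    hours = (window_end - window_start).total_seconds() / 3600.0
    if hours <= 0 or count == 0:
        return None
    return SessionRate(
        male_id=male_id,
        date=day,
        session=session,
        window_start=window_start,
        window_end=window_end,
        visit_count=count,
        rate=count / hours,
    )


def session_rates(
    visits: Iterable[Visit],
    morning_end: time = DEFAULT_MORNING_END,
    evening_start: time = DEFAULT_EVENING_START,
) -> list[SessionRate]:
    """Morning and evening feeding rates per male per day.

    A visit belongs to a window by its start time.  Morning window =
    [first visit start that day, ``morning_end``); evening window =
    [``evening_start``, last visit start that day].  Days with a
    zero-duration window or no qualifying visits yield no SessionRate.
    """
    by_male_day: dict[tuple[str, date], list[Visit]] = {}
    for v in visits:
        by_male_day.setdefault((v.male_id, v.start.date()), []).append(v)
    out: list[SessionRate] = []
    for (male_id, day) in sorted(by_male_day):
        day_visits = sorted(by_male_day[(male_id, day)], key=lambda v: v.start)
        m_end = datetime.combine(day, morning_end)
        e_start = datetime.combine(day, evening_start)

        morning = [v for v in day_visits if v.start < m_end]
        if morning:
            w_start = morning[0].start
            sr = _window_rate(male_id, day, "morning", w_start, m_end, len(morning))
            if sr is not None:
                out.append(sr)

        evening = [v for v in day_visits if v.start >= e_start]
        if evening:
            w_end = evening[-1].start
            sr = _window_rate(male_id, day, "evening", e_start, w_end, len(evening))
            if sr is not None:
                out.append(sr)
    return out


def summarize_male(rates: Sequence[SessionRate | float], male_id: str | None = None) -> FeedingSummary:
    """Median session rate of one male (midpoint convention for even counts)."""
    if len(rates) == 0:
        raise StatisticsError("cannot summarise a male with no session rates")
    if isinstance(rates[0], SessionRate):
        ids = {r.male_id for r in rates}  # type: ignore[union-attr]
        if len(ids) > 1:
            raise StatisticsError(f"rates span multiple males: {sorted(ids)}")
        male_id = rates[0].male_id  # type: ignore[union-attr]
        values = [r.rate for r in rates]  # type: ignore[union-attr]
    else:
        values = [float(r) for r in rates]  # type: ignore[arg-type]
        if male_id is None:
            raise StatisticsError("male_id required for raw rate values")
    return FeedingSummary(
        male_id=male_id, median_rate=statistics.median(values), n_sessions=len(values)
    )


def group_rates(rates: Iterable[SessionRate]) -> dict[str, list[float]]:
    grouped: dict[str, list[float]] = {}
    for r in rates:
        grouped.setdefault(r.male_id, []).append(r.rate)
    return grouped


def feeding_anova(rates_by_male: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA of session rates grouped by male.

    Computed from sums of squares: SS_between over group means vs grand
    mean, SS_within over deviations from group means; F on
    (n_males - 1, n_sessions - n_males) df; p from the F distribution.
    A zero within-group SS is reported as p -> 0 with a warning.
    """
    groups = [[float(v) for v in vals] for vals in rates_by_male.values()]
    k = len(groups)
    if k < 2:
        raise StatisticsError("ANOVA needs >= 2 males")
    if not any(len(g) >= 2 for g in groups):
        raise StatisticsError("ANOVA needs >= 2 sessions for at least one male")
    n_total = sum(len(g) for g in groups)
    grand = sum(sum(g) for g in groups) / n_total
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(
        sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups
    )
    df_between = k - 1
    df_within = n_total - k
    if df_within <= 0:
        raise StatisticsError("no within-group degrees of freedom")
    if ss_within == 0:
        warnings.warn(
            "within-male sum of squares is zero; F is unbounded, p -> 0",
            stacklevel=2,
        )
        f = math.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f = (ss_between / df_between) / (ss_within / df_within)
        p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(
        f_statistic=f,
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        ss_between=ss_between,
        ss_within=ss_within,
    )


def rates_to_frame(rates: Iterable[SessionRate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "male_id": r.male_id,
                "date": r.date.isoformat(),
                "session": r.session,
                "window_start": r.window_start.isoformat(),
                "window_end": r.window_end.isoformat(),
                "visit_count": r.visit_count,
                "rate": r.rate,
            }
            for r in rates
        ]
    )
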