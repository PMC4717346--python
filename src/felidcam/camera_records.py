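"""Photo-record ingestion and detection-history construction.

Camera-trap studies of carnivores record time-stamped photographs at fixed
sites.  Before any occupancy or activity analysis the raw photographs are
reduced to *independent detection events* (photographs of the same species at
the same site are collapsed unless separated by more than a fixed interval,
or attributable to distinct marked individuals), and the events are binned
into *sampling occasions* to form a sites x occasions detection history with
an aligned effort matrix recording how many days each camera operated.

Conventions
-----------
* A daily occasion runs from the day boundary (noon by default) of one
  calendar day to the day boundary of the next, matching the crepuscular /
  nocturnal activity of the focal felids so that a single night is never
  split across two occasions.
* A cell of the detection matrix is *missing* (NaN), not 0, wherever the
  camera was inoperative for the whole occasion (effort = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhotoRecord",
    "DetectionEvent",
    "Deployment",
    "SurveyDesign",
    "DetectionHistory",
    "RowError",
    "SchemaError",
    "read_photo_records",
    "read_deployments",
    "filter_independent",
    "assign_daily_occasions",
    "pool_occasions",
    "naive_occupancy",
    "event_count_by_site",
]


class SchemaError(ValueError):
    """A required column is absent from an input table."""


@dataclass(frozen=True)
class RowError:
    """A malformed input row, reported with its 1-based line number."""

    line: int
    message: str


@dataclass(frozen=True, order=True)
class PhotoRecord:
    timestamp: datetime
    site_id: str
    species: str
    individual_id: str | None = None
    is_dependent_young: bool = False


@dataclass(frozen=True, order=True)
class DetectionEvent:
    """An independent photographic event after the >1 h filtering rule."""

    timestamp: datetime
    site_id: str
    species: str
    individual_id: str | None = None


@dataclass(frozen=True)
class Deployment:
    site_id: str
    start: datetime
    end: datetime
    inactive_intervals: tuple[tuple[datetime, datetime], ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"deployment start must precede end for {self.site_id}")
        prev_end = None
        for lo, hi in self.inactive_intervals:
            if lo >= hi:
                raise ValueError("inactive interval must have positive length")
            if lo < self.start or hi > self.end:
                raise ValueError("inactive interval outside deployment window")
            if prev_end is not None and lo < prev_end:
                raise ValueError("inactive intervals must be disjoint and sorted")
            prev_end = hi

    def active_during(self, lo: datetime, hi: datetime) -> bool:
        """True if the camera operated for any part of [lo, hi)."""
        if hi <= self.start or lo >= self.end:
            return False
        # Clip to deployment, then subtract inactive intervals.
        lo = max(lo, self.start)
        hi = min(hi, self.end)
        for ilo, ihi in self.inactive_intervals:
            if ilo <= lo and hi <= ihi:
                return False
            # Partial overlap still leaves some active time within [lo, hi).
        return True


@dataclass(frozen=True)
class SurveyDesign:
    """Occasion layout for one study area.

    ``n_daily_occasions`` equals the inclusive calendar-day span of the
    survey window; pooling (optional) groups ``pooling_length`` consecutive
    days per occasion and drops the trailing remainder days.
    """

    survey_start_date: date
    survey_end_date: date
    day_boundary: time = time(12, 0)
    pooling_length: int | None = None

    def __post_init__(self) -> None:
        if self.survey_end_date < self.survey_start_date:
            raise ValueError("survey_end_date precedes survey_start_date")
        if self.pooling_length is not None and self.pooling_length < 1:
            raise ValueError("pooling_length must be >= 1")

    @property
    def n_daily_occasions(self) -> int:
        return (self.survey_end_date - self.survey_start_date).days + 1

    @property
    def n_pooled_occasions(self) -> int | None:
        if self.pooling_length is None:
            return None
        return self.n_daily_occasions // self.pooling_length

    def occasion_bounds(self, d: int) -> tuple[datetime, datetime]:
        """Half-open [start, end) datetime bounds of daily occasion ``d`` (1-based)."""
        day = self.survey_start_date + timedelta(days=d - 1)
        lo = datetime.combine(day, self.day_boundary)
        return lo, lo + timedelta(days=1)


@dataclass
class DetectionHistory:
    """Sites x occasions detection matrix with aligned effort.

    ``Y`` holds 1.0 (detected), 0.0 (not detected) or NaN (missing: the
    camera was inoperative).  ``effort`` holds operating days per cell and is
    0 exactly where ``Y`` is missing.
    """

    sites: list[str]
    Y: np.ndarray
    effort: np.ndarray
    occasion_length_days: int = 1

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.effort = np.asarray(self.effort, dtype=float)
        if self.Y.shape != self.effort.shape:
            raise ValueError("Y and effort dimensions disagree")
        if self.Y.shape[0] != len(self.sites):
            raise ValueError("row count does not match number of sites")
        if np.any((self.effort == 0) & ~np.isnan(self.Y)):
            raise ValueError("Y must be missing wherever effort = 0")
        if np.any((self.effort > 0) & np.isnan(self.Y)):
            raise ValueError("Y must be observed wherever effort > 0")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_occasions(self) -> int:
        return self.Y.shape[1]

    @property
    def is_daily(self) -> bool:
        return self.occasion_length_days == 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.Y, index=pd.Index(self.sites, name="site_id"),
            columns=[f"occ{j + 1}" for j in range(self.n_occasions)],
        )
        return df

    def effort_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.effort, index=pd.Index(self.sites, name="site_id"),
            columns=[f"occ{j + 1}" for j in range(self.n_occasions)],
        )


# ---------------------------------------------------------------------------
# Input parsing


_REQUIRED_PHOTO_COLUMNS = ("site_id", "species", "timestamp")


def read_photo_records(
    path: str | Path,
    *,
    drop_dependent_young: bool = True,
    collect_errors: bool = False,
) -> list[PhotoRecord] | tuple[list[PhotoRecord], list[RowError]]:
    """Parse a photo-record CSV into time-sorted :class:`PhotoRecord` objects.

    The CSV must provide ``site_id``, ``species`` and ISO-8601 ``timestamp``
    columns; ``individual_id`` and ``dependent_young`` (0/1) are optional.
    Malformed rows are collected as :class:`RowError` (returned when
    ``collect_errors`` is true, otherwise surfaced as a warning) without
    aborting the parse.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_PHOTO_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"photo-record CSV missing required columns: {missing}")

    records: list[PhotoRecord] = []
    errors: list[RowError] = []
    has_indiv = "individual_id" in df.columns
    has_young = "dependent_young" in df.columns
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header line
        ts = pd.to_datetime(getattr(row, "timestamp"), errors="coerce")
        if pd.isna(ts):
            errors.append(RowError(line, f"unparseable timestamp {row.timestamp!r}"))
            continue
        indiv = getattr(row, "individual_id", "") if has_indiv else ""
        young_raw = getattr(row, "dependent_young", "") if has_young else ""
        young = str(young_raw).strip() in {"1", "true", "True"}
        if young and drop_dependent_young:
            continue
        records.append(
            PhotoRecord(
                timestamp=ts.to_pydatetime(),
                site_id=str(row.site_id),
                species=str(row.species),
                individual_id=(str(indiv) or None),
                is_dependent_young=young,
            )
        )
    records.sort()
    if collect_errors:
        return records, errors
    for err in errors:
        warnings.warn(f"line {err.line}: {err.message}", stacklevel=2)
    return records


def read_deployments(path: str | Path) -> list[Deployment]:
    """Parse a deployment CSV (site_id, start, end[, inactive_start, inactive_end]).

    Multiple rows per site are allowed: the first supplies the window and
    additional rows with inactive_start/inactive_end supply failure intervals.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("site_id", "start", "end"):
        if col not in df.columns:
            raise SchemaError(f"deployment CSV missing required column: {col}")
    windows: dict[str, tuple[datetime, datetime]] = {}
    inactive: dict[str, list[tuple[datetime, datetime]]] = {}
    for row in df.itertuples(index=False):
        sid = str(row.site_id)
        start, end = getattr(row, "start", ""), getattr(row, "end", "")
        if start and end:
            windows[sid] = (
                pd.to_datetime(start).to_pydatetime(),
                pd.to_datetime(end).to_pydatetime(),
            )
        ilo = getattr(row, "inactive_start", "")
        ihi = getattr(row, "inactive_end", "")
        if ilo and ihi:
            inactive.setdefault(sid, []).append(
                (pd.to_datetime(ilo).to_pydatetime(), pd.to_datetime(ihi).to_pydatetime())
            )
    return [
        Deployment(sid, lo, hi, tuple(sorted(inactive.get(sid, []))))
        for sid, (lo, hi) in sorted(windows.items())
    ]


# ---------------------------------------------------------------------------
# Independence filtering


def filter_independent(
    records: Sequence[PhotoRecord],
    window_minutes: float = 60.0,
) -> list[DetectionEvent]:
    """Collapse photographs into independent detection events.

    Within each (site, species) stream a photograph starts a new event iff it
    is strictly more than ``window_minutes`` after the most recent *retained*
    event, or it carries an ``individual_id`` different from that event's
    (distinguishable marked animals photographed close together count
    separately).  Records flagged as dependent young are ignored.

    Assessing the gap against the last retained event (rather than the last
    raw photograph) keeps a burst of sub-hour photographs from extending the
    suppression window indefinitely; the rule is therefore idempotent.
    """
    if window_minutes < 0:
        raise ValueError("window_minutes must be non-negative")
    window = timedelta(minutes=window_minutes)

    streams: dict[tuple[str, str], list[PhotoRecord]] = {}
    for rec in sorted(records):
        if rec.is_dependent_young:
            continue
        streams.setdefault((rec.site_id, rec.species), []).append(rec)

    events: list[DetectionEvent] = []
    for (site, species), recs in streams.items():
        last: PhotoRecord | None = None
        for rec in recs:
            if last is None:
                keep = True
            elif rec.timestamp - last.timestamp > window:
                keep = True
            else:
                keep = (
                    rec.individual_id is not None
                    and last.individual_id is not None
                    and rec.individual_id != last.individual_id
                )
            if keep:
                events.append(
                    DetectionEvent(rec.timestamp, site, species, rec.individual_id)
                )
                last = rec
    events.sort()
    return events


# ---------------------------------------------------------------------------
# Detection histories


def assign_daily_occasions(
    events: Iterable[DetectionEvent],
    design: SurveyDesign,
    deployments: Sequence[Deployment],
    *,
    sites: Sequence[str] | None = None,
    species: str | None = None,
) -> DetectionHistory:
    """Bin events into one occasion per calendar day of the survey window.

    Occasion ``d`` covers ``[day_d at day_boundary, day_{d+1} at
    day_boundary)``.  Daily effort is 1 when the camera was active for any
    part of the interval, else 0 (and the cell is missing).  Events outside
    the survey window are excluded with a warning.
    """
    dep_by_site = {d.site_id: d for d in deployments}
    if sites is None:
        sites = sorted(dep_by_site)
    sites = list(sites)
    t = design.n_daily_occasions
    site_index = {s: i for i, s in enumerate(sites)}

    effort = np.zeros((len(sites), t))
    for s, i in site_index.items():
        dep = dep_by_site.get(s)
        if dep is None:
            continue
        for d in range(1, t + 1):
            lo, hi = design.occasion_bounds(d)
            effort[i, d - 1] = 1.0 if dep.active_during(lo, hi) else 0.0

    Y = np.where(effort > 0, 0.0, np.nan)
    window_lo, _ = design.occasion_bounds(1)
    _, window_hi = design.occasion_bounds(t)
    n_excluded = 0
    for ev in events:
        if species is not None and ev.species != species:
            continue
        if ev.site_id not in site_index:
            continue
        if not (window_lo <= ev.timestamp < window_hi):
            n_excluded += 1
            continue
        d = (ev.timestamp - window_lo) // timedelta(days=1)  # 0-based occasion
        i = site_index[ev.site_id]
        if effort[i, d] > 0:
            Y[i, d] = 1.0
    if n_excluded:
        warnings.warn(
            f"{n_excluded} event(s) outside the survey window were excluded",
            stacklevel=2,
        )
    return DetectionHistory(sites, Y, effort, occasion_length_days=1)


def pool_occasions(daily: DetectionHistory, L: int) -> DetectionHistory:
    """Pool a daily history into occasions of ``L`` consecutive days.

    The pooled cell is the max over constituent days with data (a detection
    on any day marks the pooled occasion), pooled effort is the sum of daily
    effort, and trailing remainder days are dropped.  A pool whose days are
    all missing stays missing.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    t = daily.n_occasions
    if L > t:
        raise ValueError(f"pooling length {L} exceeds {t} daily occasions")
    T = t // L
    Y = np.full((daily.n_sites, T), np.nan)
    effort = np.zeros((daily.n_sites, T))
    for j in range(T):
        block_Y = daily.Y[:, j * L : (j + 1) * L]
        block_E = daily.effort[:, j * L : (j + 1) * L]
        effort[:, j] = np.nansum(block_E, axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            pooled = np.nanmax(block_Y, axis=1)
        Y[:, j] = np.where(effort[:, j] > 0, pooled, np.nan)
    return DetectionHistory(
        daily.sites, Y, effort, occasion_length_days=L * daily.occasion_length_days
    )


# ---------------------------------------------------------------------------
# Summaries


def naive_occupancy(
    history: DetectionHistory, site_subset: Sequence[str] | None = None
) -> float:
    """Fraction of sites with at least one detection (no detection correction)."""
    if site_subset is None:
        site_subset = history.sites
    site_subset = list(site_subset)
    if not site_subset:
        raise ValueError("site subset must be non-empty")
    idx = [history.sites.index(s) for s in site_subset]
    detected = np.nansum(history.Y[idx], axis=1) > 0
    return float(detected.sum()) / len(idx)


def event_count_by_site(
    events: Iterable[DetectionEvent],
    species: str,
    sites: Sequence[str],
) -> pd.Series:
    """Independent photographic events per site for one species.

    This is the "photograph count" site covariate (e.g. *puma count*): the
    total number of independent events for the dominant species at each
    camera over the survey.
    """
    counts = pd.Series(0, index=pd.Index(list(sites), name="site_id"), dtype=int)
    for ev in events:
        if ev.species == species and ev.site_id in counts.index:
            counts[ev.site_id] += 1
    return counts
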