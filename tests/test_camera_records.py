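"""Detection-event filtering and detection-history construction."""

from datetime import date, datetime, time, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from felidcam import camera_records as cr
from felidcam.synthetic_data import write_fixture

from conftest import make_history


def rec(ts, site="s1", species="bobcat", indiv=None):
    return cr.PhotoRecord(datetime.fromisoformat(ts), site, species, indiv)


# ---------------------------------------------------------------------------
# CSV parsing


def test_read_photo_records_well_formed(tmp_path):
    p = tmp_path / "photos.csv"
    p.write_text(
        "site_id,species,timestamp\n"
        "s2,puma,2010-10-02T08:00:00\n"
        "s1,bobcat,2010-10-01T06:30:00\n"
        "s1,puma,2010-10-03T22:15:00\n"
    )
    records = cr.read_photo_records(p)
    assert len(records) == 3
    assert [r.timestamp for r in records] == sorted(r.timestamp for r in records)


def test_read_photo_records_collects_row_errors(tmp_path):
    p = tmp_path / "photos.csv"
    p.write_text(
        "site_id,species,timestamp\n"
        "s1,bobcat,2010-10-01T06:30:00\n"
        "s1,bobcat,2010-13-01T08:00\n"  # month 13
    )
    records, errors = cr.read_photo_records(p, collect_errors=True)
    assert len(records) == 1
    assert len(errors) == 1 and errors[0].line == 3


def test_read_photo_records_missing_column(tmp_path):
    p = tmp_path / "photos.csv"
    p.write_text("site_id,timestamp\ns1,2010-10-01T06:30:00\n")
    with pytest.raises(cr.SchemaError):
        cr.read_photo_records(p)


def test_fixture_round_trip(survey, tmp_path):
    """write_fixture output rereads into identical records."""
    import pandas as pd

    dep_df = pd.DataFrame(
        {
            "site_id": [d.site_id for d in survey.deployments],
            "start": [d.start for d in survey.deployments],
            "end": [d.end for d in survey.deployments],
        }
    )
    paths = write_fixture(survey.photos, dep_df, survey.landscape, tmp_path)
    records = cr.read_photo_records(paths["photos"])
    assert len(records) == len(survey.photos)
    orig = survey.photos.sort_values(["timestamp", "site_id", "species"])
    got = sorted(records)
    assert [r.timestamp for r in got] == list(pd.to_datetime(orig["timestamp"]))
    # same seed -> byte-identical files; different seed -> different
    again = write_fixture(survey.photos, dep_df, survey.landscape, tmp_path / "b")
    assert paths["photos"].read_bytes() == again["photos"].read_bytes()


# ---------------------------------------------------------------------------
# Independence filtering


@pytest.mark.parametrize(
    "timestamps, expected_kept",
    [
        # 10:30 is within 1 h of retained 10:00; 11:30 is 90 min after 10:00
        (["2010-10-01T10:00", "2010-10-01T10:30", "2010-10-01T11:30"], [0, 2]),
        (["2010-10-01T10:00"], [0]),
        # exactly 60 min apart reads "> 1 h" strictly: not independent
        (["2010-10-01T10:00", "2010-10-01T11:00"], [0]),
        (["2010-10-01T10:00", "2010-10-01T11:00:01"], [0, 1]),
    ],
)
def test_filter_independent_window_rule(timestamps, expected_kept):
    records = [rec(t) for t in timestamps]
    events = cr.filter_independent(records)
    assert [e.timestamp for e in events] == [records[i].timestamp for i in expected_kept]


def test_marked_individuals_count_separately():
    records = [rec("2010-10-01T10:00", indiv="B01"), rec("2010-10-01T10:20", indiv="B02")]
    assert len(cr.filter_independent(records)) == 2
    # same individual within the window collapses
    records = [rec("2010-10-01T10:00", indiv="B01"), rec("2010-10-01T10:20", indiv="B01")]
    assert len(cr.filter_independent(records)) == 1


def test_dependent_young_excluded():
    records = [
        cr.PhotoRecord(datetime(2010, 10, 1, 10), "s1", "bobcat", None, True),
        rec("2010-10-01T14:00"),
    ]
    assert len(cr.filter_independent(records)) == 1


def test_negative_window_rejected():
    with pytest.raises(ValueError):
        cr.filter_independent([rec("2010-10-01T10:00")], window_minutes=-5)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    offsets=st.lists(st.integers(min_value=0, max_value=5000), min_size=1, max_size=40)
)
def test_filter_independent_idempotent(offsets):
    """Filtering twice equals filtering once, for arbitrary photo streams."""
    base = datetime(2010, 10, 1)
    records = [rec((base + timedelta(minutes=m)).isoformat()) for m in sorted(offsets)]
    once = cr.filter_independent(records)
    as_records = [
        cr.PhotoRecord(e.timestamp, e.site_id, e.species, e.individual_id) for e in once
    ]
    twice = cr.filter_independent(as_records)
    assert twice == once


# ---------------------------------------------------------------------------
# Occasions


def test_daily_occasion_count_fr_window(fr_design):
    assert fr_design.n_daily_occasions == 92


def test_noon_boundary_assignment(fr_design):
    dep = [cr.Deployment("s1", datetime(2010, 10, 1, 12), datetime(2011, 1, 1, 12))]
    morning = cr.DetectionEvent(datetime(2010, 10, 2, 11, 0), "s1", "bobcat")
    afternoon = cr.DetectionEvent(datetime(2010, 10, 2, 13, 0), "s1", "bobcat")
    hist = cr.assign_daily_occasions([morning, afternoon], fr_design, dep)
    assert hist.Y[0, 0] == 1  # 11:00 belongs to occasion 1 (noon Oct 1 - noon Oct 2)
    assert hist.Y[0, 1] == 1  # 13:00 opens occasion 2
    assert np.nansum(hist.Y) == 2


def test_no_events_all_zero(fr_design):
    dep = [cr.Deployment("s1", datetime(2010, 10, 1, 12), datetime(2011, 1, 1, 12))]
    hist = cr.assign_daily_occasions([], fr_design, dep)
    assert hist.n_occasions == 92
    assert np.nansum(hist.Y) == 0 and np.all(hist.effort == 1)


def test_event_outside_window_warns(fr_design):
    dep = [cr.Deployment("s1", datetime(2010, 10, 1, 12), datetime(2011, 1, 1, 12))]
    stray = cr.DetectionEvent(datetime(2010, 9, 1, 13), "s1", "bobcat")
    with pytest.warns(UserWarning, match="outside the survey window"):
        hist = cr.assign_daily_occasions([stray], fr_design, dep)
    assert np.nansum(hist.Y) == 0


def test_effort_zero_is_missing(fr_design):
    dep = [
        cr.Deployment(
            "s1",
            datetime(2010, 10, 1, 12),
            datetime(2011, 1, 1, 12),
            ((datetime(2010, 10, 5, 12), datetime(2010, 10, 7, 12)),),
        )
    ]
    hist = cr.assign_daily_occasions([], fr_design, dep)
    assert np.isnan(hist.Y[0, 4]) and np.isnan(hist.Y[0, 5])
    assert hist.effort[0, 4] == 0 and hist.effort[0, 6] == 1


# ---------------------------------------------------------------------------
# Pooling


@pytest.mark.parametrize("t, L, expected_T, dropped", [(113, 22, 5, 3), (92, 18, 5, 2)])
def test_pooling_occasion_counts(t, L, expected_T, dropped):
    daily = make_history(np.zeros((2, t)))
    pooled = cr.pool_occasions(daily, L)
    assert pooled.n_occasions == expected_T
    assert pooled.effort.sum() == 2 * (t - dropped)


def test_pooling_max_and_missing_propagation():
    Y = np.array([[np.nan, 1.0, 0.0, np.nan, np.nan, np.nan]])
    daily = make_history(Y)
    pooled = cr.pool_occasions(daily, 3)
    assert pooled.Y[0, 0] == 1.0 and pooled.effort[0, 0] == 2
    assert np.isnan(pooled.Y[0, 1]) and pooled.effort[0, 1] == 0


def test_pooling_never_creates_detections(survey):
    pooled = cr.pool_occasions(survey.daily_b, 18)
    daily_counts = np.nansum(survey.daily_b.Y, axis=1)
    pooled_counts = np.nansum(pooled.Y, axis=1)
    assert np.all(pooled_counts <= daily_counts)
    assert np.all(pooled.effort.sum(axis=1) <= survey.daily_b.effort.sum(axis=1))


def test_pooling_length_validation(tiny_history):
    with pytest.raises(ValueError):
        cr.pool_occasions(tiny_history, 4)
    with pytest.raises(ValueError):
        cr.pool_occasions(tiny_history, 0)


# ---------------------------------------------------------------------------
# Summaries


def test_naive_occupancy_values():
    # 38 detected sites of 40 (as in the rural study area's bobcat data)
    Y = np.zeros((40, 4))
    Y[:38, 0] = 1
    hist = make_history(Y)
    assert cr.naive_occupancy(hist) == pytest.approx(0.95)
    assert cr.naive_occupancy(make_history(np.zeros((5, 3)))) == 0.0
    assert cr.naive_occupancy(make_history(np.ones((5, 3)))) == 1.0
    with pytest.raises(ValueError):
        cr.naive_occupancy(hist, [])


def test_event_counts_match_simulation_truth(survey):
    counts = cr.event_count_by_site(
        survey.events, "puma", list(survey.landscape.sites.index)
    )
    assert dict(counts) == survey.truth["event_counts"]["puma"]
    # plausible photographic rates for the dominant species: a handful per site
    assert counts.min() == 0 and counts.max() <= 12


def test_event_counts_absent_species(survey):
    counts = cr.event_count_by_site(survey.events, "lynx", list(survey.landscape.sites.index))
    assert (counts == 0).all()
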