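"""Daily metric extraction: thresholds, oracles, invariants."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermotrack.config import DayBoundary, SeasonWindow
from thermotrack.metrics import (
    activity_metrics,
    assemble_daily,
    daily_temp_params,
    haversine_km,
    hourly_displacements,
    label_season,
    microclimate_metrics,
    normalize_activity,
    travel_metrics,
)
from thermotrack.streams import GpsTrack, LoggerStream, make_stream

DAY = dt.date(2013, 10, 1)


def _temp_stream(values, start=None, step_min=10, animal="A1"):
    start = start or dt.datetime.combine(DAY, dt.time())
    idx = pd.date_range(start, periods=len(values), freq=f"{step_min}min")
    return LoggerStream(animal, "body_temperature", step_min, pd.Series(values, index=idx))


def _hourly_stream(values, kind, start=None, animal="A1"):
    start = start or dt.datetime.combine(DAY, dt.time())
    idx = pd.date_range(start, periods=len(values), freq="h")
    return LoggerStream(animal, kind, 60, pd.Series(np.asarray(values, float), index=idx))


# ---------------------------------------------------------------------------
# Body temperature


def test_constant_day_gives_zero_amplitude(boundary):
    out = daily_temp_params(_temp_stream([38.0] * 144), boundary)
    row = out.iloc[0]
    assert (row.t_min, row.t_max, row.t_amplitude) == (38.0, 38.0, 0.0)
    assert row.complete


def test_cosine_day_recovers_closed_form_amplitude(boundary):
    # T(t) = 38.54 + 1.1 cos(2pi (t - 18h)/24h): amplitude 2.2 with extremes
    # at 18:00 and 06:00, both on the 10-min grid
    h = np.arange(144) / 6.0
    temps = 38.54 + 1.1 * np.cos(2 * np.pi * (h - 18.0) / 24.0)
    out = daily_temp_params(_temp_stream(temps), boundary)
    assert out.iloc[0].t_amplitude == pytest.approx(2.2, abs=1e-9)
    assert out.iloc[0].t_max == pytest.approx(39.64, abs=1e-9)


def test_sparse_day_is_flagged_incomplete(boundary):
    out = daily_temp_params(_temp_stream([38.0] * 100), boundary)  # 100/144 < 0.8
    assert not out.iloc[0].complete


def test_daily_extrema_match_brute_force_scan(boundary):
    rng = np.random.default_rng(5)
    vals = 38.5 + rng.normal(0, 0.8, 3 * 144)
    stream = _temp_stream(vals)
    out = daily_temp_params(stream, boundary)
    for i, (_, row) in enumerate(out.iterrows()):
        day = vals[i * 144 : (i + 1) * 144]
        assert row.t_min == day.min() and row.t_max == day.max()
        assert row.t_amplitude == day.max() - day.min()


def test_empty_stream_yields_empty_result(boundary):
    empty = LoggerStream("A1", "body_temperature", 10, pd.Series(dtype=float, index=pd.DatetimeIndex([])))
    assert daily_temp_params(empty, boundary).empty


def test_unsorted_timestamps_are_rejected():
    idx = pd.DatetimeIndex([dt.datetime(2013, 10, 1, 0, 10), dt.datetime(2013, 10, 1, 0, 0)])
    with pytest.raises(ValueError, match="sorted"):
        LoggerStream("A1", "body_temperature", 10, pd.Series([38.0, 38.1], index=idx))


def test_order_invariance_after_sorting(boundary):
    rng = np.random.default_rng(11)
    vals = 38.5 + rng.normal(0, 0.5, 144)
    idx = pd.date_range(dt.datetime.combine(DAY, dt.time()), periods=144, freq="10min")
    perm = rng.permutation(144)
    shuffled = make_stream("A1", "body_temperature", idx[perm], vals[perm], 10)
    ordered = _temp_stream(vals)
    pd.testing.assert_frame_equal(daily_temp_params(shuffled, boundary), daily_temp_params(ordered, boundary))


# ---------------------------------------------------------------------------
# Microclimate


def test_identical_globes_give_no_cool_use(boundary):
    ref = _hourly_stream(30 + np.arange(24, dtype=float) % 12, "reference_globe")
    collar = _hourly_stream(30 + np.arange(24, dtype=float) % 12, "collar_globe")
    out = microclimate_metrics(collar, ref, boundary)
    assert out.iloc[0].cool_hours == 0 and out.iloc[0].cumulative_cool_use == 0.0


def test_cool_hours_respect_strict_half_degree_rule(boundary):
    # collar 2.0 °C cooler for 5 daylight hours, 0.3 °C cooler otherwise:
    # only the 5 deep hours count, giving 10 °C·h of cumulative use
    ref_vals = np.full(24, 35.0)
    collar_vals = ref_vals - 0.3
    collar_vals[9:14] = ref_vals[9:14] - 2.0  # 09:00–13:00, all daylight in October
    ref = _hourly_stream(ref_vals, "reference_globe")
    collar = _hourly_stream(collar_vals, "collar_globe")
    out = microclimate_metrics(collar, ref, boundary)
    assert out.iloc[0].cool_hours == 5
    assert out.iloc[0].cumulative_cool_use == pytest.approx(10.0)


def test_exactly_half_degree_cooler_does_not_count(boundary):
    ref = _hourly_stream(np.full(24, 35.0), "reference_globe")
    collar = _hourly_stream(np.full(24, 34.5), "collar_globe")
    out = microclimate_metrics(collar, ref, boundary)
    assert out.iloc[0].cool_hours == 0 and out.iloc[0].cumulative_cool_use == 0.0


def test_cool_threshold_flip_at_hundredth_of_degree(boundary):
    ref_vals = np.full(24, 35.0)
    for delta, expect in ((-0.50, 0), (-0.51, 1)):
        collar_vals = ref_vals.copy()
        collar_vals[12] += delta
        out = microclimate_metrics(
            _hourly_stream(collar_vals, "collar_globe"), _hourly_stream(ref_vals, "reference_globe"), boundary
        )
        assert out.iloc[0].cool_hours == expect


def test_hours_missing_either_globe_are_dropped(boundary):
    ref = _hourly_stream(np.full(24, 35.0), "reference_globe")
    collar_vals = np.full(24, 33.0)
    idx = pd.date_range(dt.datetime.combine(DAY, dt.time()), periods=24, freq="h")
    collar = LoggerStream("A1", "collar_globe", 60, pd.Series(collar_vals, index=idx).drop(idx[12]))
    out = microclimate_metrics(collar, ref, boundary)
    assert out.iloc[0].n_records == 23


def test_no_overlap_yields_empty_result(boundary):
    ref = _hourly_stream(np.full(24, 35.0), "reference_globe")
    collar = _hourly_stream(np.full(24, 33.0), "collar_globe", start=dt.datetime(2014, 3, 1))
    assert microclimate_metrics(collar, ref, boundary).empty


def test_cumulative_use_monotone_in_cooling_depth(boundary):
    ref_vals = np.full(24, 35.0)
    collar_vals = ref_vals - 0.0
    collar_vals[10:14] = ref_vals[10:14] - 2.0
    base = microclimate_metrics(
        _hourly_stream(collar_vals, "collar_globe"), _hourly_stream(ref_vals, "reference_globe"), boundary
    )
    deeper = collar_vals.copy()
    deeper[11] -= 1.5
    more = microclimate_metrics(
        _hourly_stream(deeper, "collar_globe"), _hourly_stream(ref_vals, "reference_globe"), boundary
    )
    assert more.iloc[0].cumulative_cool_use == pytest.approx(base.iloc[0].cumulative_cool_use + 1.5)


# ---------------------------------------------------------------------------
# Travel


def _track(points, start=None, animal="A1"):
    start = start or dt.datetime.combine(DAY, dt.time())
    idx = pd.date_range(start, periods=len(points), freq="h")
    lat, lon = zip(*points)
    return GpsTrack(animal, pd.DataFrame({"lat": lat, "lon": lon}, index=idx))


def test_stationary_animal_has_zero_travel_hours(boundary):
    out = travel_metrics(_track([(-24.35, 20.62)] * 24), boundary)
    assert out.iloc[0].travel_hours == 0


def test_pure_latitude_offset_matches_haversine_oracle(boundary):
    # 0.0145° of latitude on a 6371.0088 km sphere is ~1.612 km: a travel hour
    d = haversine_km(-24.35, 20.62, -24.3355, 20.62)
    assert d == pytest.approx(0.0145 * np.pi * 6371.0088 / 180.0, rel=1e-9)
    assert d == pytest.approx(1.612, abs=0.002)
    out = travel_metrics(_track([(-24.35, 20.62), (-24.3355, 20.62)] + [(-24.3355, 20.62)] * 5), boundary)
    assert out.iloc[0].travel_hours == 1


def test_exactly_threshold_displacement_is_not_travel(boundary):
    # the strict > 1.6 km rule: displacements at (or a hair under) the
    # threshold never count, a hair over always does
    km_per_deg = np.pi * 6371.0088 / 180.0
    dlat_at = 1.6 * (1 - 1e-9) / km_per_deg
    dlat_above = 1.6 * (1 + 1e-9) / km_per_deg
    base = (-24.35, 20.62)
    at = travel_metrics(_track([base, (base[0] + dlat_at, base[1])] * 3), boundary)
    above = travel_metrics(_track([base, (base[0] + dlat_above, base[1])] * 3), boundary)
    assert at.iloc[0].travel_hours == 0
    assert above.iloc[0].travel_hours == 5


def test_gapped_fixes_break_the_hour_pair(boundary):
    idx = pd.DatetimeIndex(
        [dt.datetime(2013, 10, 1, 0), dt.datetime(2013, 10, 1, 2), dt.datetime(2013, 10, 1, 3)]
    )
    track = GpsTrack("A1", pd.DataFrame({"lat": [-24.35, -24.30, -24.25], "lon": [20.62] * 3}, index=idx))
    disp = hourly_displacements(track)
    assert len(disp) == 1  # the 2 h gap pair is dropped


def test_single_fix_day_yields_no_rows(boundary):
    track = GpsTrack("A1", pd.DataFrame({"lat": [-24.35], "lon": [20.62]},
                                        index=pd.DatetimeIndex([dt.datetime(2013, 10, 1, 8)])))
    assert travel_metrics(track, boundary).empty


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    lat=st.floats(-60, 60),
    lon=st.floats(-179, 179),
    dlat=st.floats(-0.5, 0.5),
    dlon=st.floats(-0.5, 0.5),
)
def test_haversine_is_symmetric_and_nonnegative(lat, lon, dlat, dlon):
    d1 = haversine_km(lat, lon, lat + dlat, lon + dlon)
    d2 = haversine_km(lat + dlat, lon + dlon, lat, lon)
    assert d1 == pytest.approx(d2, rel=1e-12)
    assert d1 >= 0.0


# ---------------------------------------------------------------------------
# Activity


def _activity(values, start=None):
    start = start or dt.datetime.combine(DAY, dt.time())
    idx = pd.date_range(start, periods=len(values), freq="5min")
    return LoggerStream("A1", "activity", 5, pd.Series(np.asarray(values, float), index=idx))


def test_all_heat_window_activity_gives_proportion_one(boundary):
    vals = np.zeros(288)
    vals[120:192] = 3.0  # 10:00–16:00
    out = activity_metrics(_activity(vals), boundary)
    assert out.iloc[0].heat_activity_proportion == pytest.approx(1.0)


def test_uniform_activity_gives_quarter_heat_proportion(boundary):
    out = activity_metrics(_activity(np.full(288, 5.0)), boundary)
    assert out.iloc[0].heat_activity_proportion == pytest.approx(6.0 / 24.0)


def test_study_maximum_record_normalizes_to_one(boundary):
    vals = np.full(288, 2.0)
    vals[100] = 40.0
    rel = normalize_activity(_activity(vals))
    assert rel.data.max() == pytest.approx(1.0)
    assert rel.data.iloc[0] == pytest.approx(2.0 / 40.0)


def test_normalization_is_idempotent(boundary):
    vals = np.linspace(1.0, 30.0, 288)
    once = normalize_activity(_activity(vals))
    twice = normalize_activity(once)
    pd.testing.assert_series_equal(once.data, twice.data)


def test_all_zero_logger_is_rejected():
    with pytest.raises(ValueError, match="normalization undefined"):
        normalize_activity(_activity(np.zeros(288)))


# ---------------------------------------------------------------------------
# Assembly


def test_season_labels_and_window_exclusion(short_windows):
    assert label_season(dt.date(2013, 9, 15), short_windows) == "drought"
    assert label_season(dt.date(2014, 9, 15), short_windows) == "non-drought"
    assert label_season(dt.date(2014, 1, 15), short_windows) == "outside"


def test_assemble_daily_excludes_out_of_window_days(boundary, short_windows):
    idx_in = dt.datetime(2013, 9, 10)
    idx_out = dt.datetime(2014, 1, 15)
    streams = {}
    for day0 in (idx_in, idx_out):
        vals = 38.5 + 0.3 * np.sin(np.arange(144) / 10)
        s = _temp_stream(vals, start=day0)
        streams.setdefault("A1", []).append(s.data)
    merged = LoggerStream("A1", "body_temperature", 10, pd.concat(streams["A1"]))
    empty_ref = LoggerStream("R", "reference_globe", 60, pd.Series(dtype=float, index=pd.DatetimeIndex([])))
    daily = assemble_daily(
        {"A1": merged}, {}, {}, empty_ref, {}, {"A1": "gemsbok"}, boundary, short_windows
    )
    assert list(daily["date"]) == [dt.date(2013, 9, 10)]
    assert list(daily["season"]) == ["drought"]


def test_missing_species_label_is_an_error(boundary, short_windows):
    s = _temp_stream([38.0] * 144)
    empty_ref = LoggerStream("R", "reference_globe", 60, pd.Series(dtype=float, index=pd.DatetimeIndex([])))
    with pytest.raises(ValueError, match="species"):
        assemble_daily({"A1": s}, {}, {}, empty_ref, {}, {}, boundary, short_windows)
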