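"""Synthetic study generator: determinism, planted-truth consistency, envelope."""

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
import pytest

from thermotrack.config import SeasonWindow, VarianceComponents, default_config
from thermotrack.models import ModelSpec, fit_mixed
from thermotrack.simulate import (
    planted_recovery_table,
    simulate_daily_responses,
    simulate_reference_globe,
    simulate_study,
)

METRICS = [
    "t_min", "t_max", "t_amplitude", "cool_hours", "cumulative_cool_use",
    "travel_hours", "total_activity_24h", "heat_activity_proportion",
]


def test_invalid_configs_are_rejected():
    with pytest.raises(ValueError, match="disjoint"):
        default_config(
            season_windows=(
                SeasonWindow("drought", dt.date(2013, 9, 1), dt.date(2013, 11, 30)),
                SeasonWindow("non-drought", dt.date(2013, 11, 1), dt.date(2014, 1, 31)),
            )
        )
    with pytest.raises(ValueError, match="28 days"):
        default_config(
            season_windows=(
                SeasonWindow("drought", dt.date(2013, 9, 1), dt.date(2013, 9, 10)),
                SeasonWindow("non-drought", dt.date(2014, 9, 1), dt.date(2014, 11, 30)),
            )
        )
    with pytest.raises(ValueError, match=">= 0"):
        VarianceComponents(-0.1, 0.0, 0.0)


def test_same_seed_reproduces_dataset_bit_for_bit(small_config):
    d1, t1 = simulate_study(small_config)
    d2, t2 = simulate_study(small_config)
    for aid in d1.species:
        pd.testing.assert_series_equal(d1.body_temps[aid].data, d2.body_temps[aid].data)
        pd.testing.assert_series_equal(d1.activities[aid].data, d2.activities[aid].data)
        pd.testing.assert_series_equal(d1.collar_globes[aid].data, d2.collar_globes[aid].data)
        pd.testing.assert_frame_equal(d1.tracks[aid].data, d2.tracks[aid].data)
    pd.testing.assert_series_equal(d1.reference_globe.data, d2.reference_globe.data)
    pd.testing.assert_frame_equal(d1.weather, d2.weather)
    pd.testing.assert_frame_equal(t1.daily, t2.daily)
    pd.testing.assert_frame_equal(t1.animal_effects, t2.animal_effects)


def test_different_seed_changes_dataset(small_config):
    d1, _ = simulate_study(small_config)
    d2, _ = simulate_study(dataclasses.replace(small_config, rng_seed=7))
    aid = next(iter(d1.species))
    assert not d1.body_temps[aid].data.equals(d2.body_temps[aid].data)


def test_streams_have_increasing_timestamps_on_their_cadence(small_config):
    ds, _ = simulate_study(small_config)
    for aid in ds.species:
        for stream, step in ((ds.body_temps[aid], 10), (ds.activities[aid], 5),
                             (ds.collar_globes[aid], 60)):
            idx = stream.data.index
            assert idx.is_monotonic_increasing and not idx.has_duplicates
            gaps = np.diff(idx.asi8) // (60 * 10**9)
            within = gaps[gaps < 24 * 60]  # ignore the between-season break
            assert (within % step == 0).all()


def test_collar_and_reference_share_the_hourly_grid(small_config):
    ds, _ = simulate_study(small_config)
    ref_idx = ds.reference_globe.data.index
    for aid in ds.species:
        assert ds.collar_globes[aid].data.index.isin(ref_idx).all()


def test_zero_noise_metrics_equal_planted_cell_means(small_config):
    """With all noise off, the rendered streams reproduce the planted daily
    truth exactly; in particular the gemsbok-drought amplitude is the
    planted 2.2 °C intercept on every single day."""
    ds, truth = simulate_study(small_config.zero_noise())
    daily = ds.daily_metrics()
    merged = daily.merge(truth.daily, on=["animal_id", "date"], suffixes=("", "_t"))
    for col in METRICS:
        assert np.allclose(merged[col], merged[col + "_t"], atol=1e-9), col
    gd = merged[(merged.species == "gemsbok") & (merged.season == "drought")]
    assert np.allclose(gd["t_amplitude"], 2.2, atol=1e-12)
    assert np.allclose(gd["t_min"], 37.64, atol=1e-12)


def test_default_noise_metrics_track_planted_truth(small_config):
    """With default noise the stream-derived metrics stay close to the
    planted daily values (dropout and sensor noise are the only gaps)."""
    ds, truth = simulate_study(small_config)
    daily = ds.daily_metrics()
    merged = daily.merge(truth.daily, on=["animal_id", "date"], suffixes=("", "_t"))
    assert (merged["t_amplitude"] - merged["t_amplitude_t"]).abs().mean() < 0.02
    assert (merged["heat_activity_proportion"] - merged["heat_activity_proportion_t"]).abs().mean() < 0.01
    # travel hours: dropout can only lose hour pairs, never invent them
    assert (merged["travel_hours"] <= merged["travel_hours_t"]).all()


def test_cool_hours_never_exceed_daylight(small_config):
    ds, truth = simulate_study(small_config)
    daily = ds.daily_metrics()
    assert (daily["cool_hours"] <= 14).all()
    assert (daily["cumulative_cool_use"] >= 0.5 * daily["cool_hours"] - 1e-9).all()


def test_reference_globe_envelope_matches_seasonal_targets():
    """91-day drought season: mean daily max within 1 °C of 40.2, mean
    daily min within 1 °C of 10.6 (the configured drought envelope)."""
    cfg = default_config(rng_seed=60309)
    ref = simulate_reference_globe(cfg, "drought")
    grp = ref.data.groupby(ref.data.index.date)
    assert grp.max().mean() == pytest.approx(40.2, abs=1.0)
    assert grp.min().mean() == pytest.approx(10.6, abs=1.0)


def test_zero_noise_reference_globe_repeats_daily_extremes(small_config):
    ref = simulate_reference_globe(small_config.zero_noise(), "drought")
    daily_max = ref.data.groupby(ref.data.index.date).max()
    assert daily_max.nunique() == 1


def test_amplitude_cell_mean_matches_linear_predictor_over_replicates():
    """Monte-Carlo: wildebeest-drought daily amplitude averages to
    intercept + species effect (2.2 + 1.0) within two standard errors."""
    vals = []
    for rep in range(20):
        cfg = default_config(rng_seed=8800 + rep, n_gemsbok=2, n_wildebeest=2)
        daily, _ = simulate_daily_responses(cfg, responses=["t_amplitude"])
        cell = daily[(daily.species == "wildebeest") & (daily.season == "drought")]
        vals.append(cell["t_amplitude"].mean())
    vals = np.asarray(vals)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - 3.2) < 2 * se + 1e-9


def test_recovery_table_reports_bias_and_coverage(small_config):
    daily, truth = simulate_daily_responses(small_config)
    fit = fit_mixed(ModelSpec.for_response("t_amplitude", variance_by_cell=False), daily)
    report = planted_recovery_table(truth, [fit])
    assert set(report["term"]) == {"intercept", "season", "species", "interaction"}
    assert np.allclose(report["bias"], report["estimate"] - report["planted"])
    assert report["covered"].dtype == bool


def test_recovery_table_empty_fits_give_empty_report(small_config):
    _, truth = simulate_daily_responses(small_config)
    report = planted_recovery_table(truth, [])
    assert report.empty


def test_zero_noise_recovery_bias_is_zero(small_config):
    daily, truth = simulate_daily_responses(small_config.zero_noise())
    fit = fit_mixed(ModelSpec.for_response("t_amplitude", variance_by_cell=False), daily)
    report = planted_recovery_table(truth, [fit])
    assert report["bias"].abs().max() < 1e-6
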