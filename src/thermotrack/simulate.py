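"""Synthetic multi-sensor bio-logger studies with planted ground truth.

The generator works in two stages:

1. **Daily truth** — for every response a daily GLMM draw
   ``g(value_ij) = x_ij'beta + a_i + d_j (+ eps_ij)`` with the planted
   fixed effects, a per-animal intercept, a daily deviate shared by all
   animals, and (for Gaussian responses) residual noise.  Counts
   (travel hours, cool hours) are Poisson draws around the planted rate.
2. **Stream rendering** — raw sensor streams are synthesized so that the
   pipeline's derived daily metrics reproduce the daily truth: a
   two-harmonic cosinor (24 h + 12 h) body-temperature day with AR(1)
   texture, affinely pinned to the day's planted min/max; a crepuscular
   activity profile rescaled so the daily total and heat-window share
   are exact; collar-globe shade bouts whose depth sums to the planted
   cumulative cool use over exactly the planted number of daylight
   hours; and a correlated random walk whose per-hour displacements
   exceed 1.6 km in exactly the planted travel hours.

With all noise off, every derived daily metric equals its planted cell
mean; with defaults, small known distortions remain (collar sensor
noise can tip borderline hours past the 0.5 °C threshold, and record
dropout thins sums) — see the package methods note.

Everything is driven by a single integer seed: identical
(config, seed) pairs reproduce datasets bit for bit.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import SimulationConfig, SeasonWindow, PlantedCoefficients, RESPONSES
from .metrics import assemble_daily
from .solar import daylight_window
from .streams import GpsTrack, LoggerStream

__all__ = [
    "PlantedTruth",
    "StudyDataset",
    "simulate_daily_responses",
    "simulate_reference_globe",
    "simulate_weather",
    "simulate_rainfall",
    "simulate_ndvi",
    "simulate_study",
    "planted_recovery_table",
]

# responses realized directly from a planted daily GLMM (t_max is derived)
_DIRECT_RESPONSES = [
    "t_min",
    "t_amplitude",
    "cool_hours",
    "cumulative_cool_use",
    "travel_hours",
    "total_activity_24h",
    "heat_activity_proportion",
]

_MIN_AMPLITUDE = 0.15  # °C floor keeps a renderable rhythm
_MIN_HOUR_DEPTH = 0.6  # °C; every planted cool hour clears the 0.5 °C threshold
_EXCURSION_KM = (1.8, 6.0)  # excursion step lengths, safely above 1.6 km
_ROUTINE_STEP_MEAN_KM = 0.35
_ROUTINE_STEP_CAP_KM = 1.45  # safely below 1.6 km


@dataclass
class PlantedTruth:
    """Exact effect sizes and random effects behind a realized dataset."""

    config: SimulationConfig
    seed: int
    coefficients: Mapping[str, PlantedCoefficients]
    animal_effects: pd.DataFrame  # animal_id x response (model scale)
    date_effects: pd.DataFrame  # date x response (model scale)
    daily: pd.DataFrame  # realized daily response values per animal-day


@dataclass
class StudyDataset:
    """A complete synthetic study: all sensor streams plus context tables."""

    species: dict[str, str]
    body_temps: dict[str, LoggerStream]
    activities: dict[str, LoggerStream]
    collar_globes: dict[str, LoggerStream]
    reference_globe: LoggerStream
    tracks: dict[str, GpsTrack]
    weather: pd.DataFrame  # hourly: timestamp, drybulb_c, wind_ms, solar_wm2
    rainfall: pd.DataFrame  # daily: date, rain_mm
    ndvi: pd.DataFrame  # 16-day composites: start_date, end_date, ndvi
    config: SimulationConfig

    def daily_metrics(self) -> pd.DataFrame:
        """Run the metrics stage over the rendered streams."""
        return assemble_daily(
            self.body_temps,
            self.activities,
            self.collar_globes,
            self.reference_globe,
            self.tracks,
            self.species,
            self.config.boundary,
            self.config.season_windows,
            self.config.latitude,
            self.config.longitude,
        )


def _study_dates(config: SimulationConfig) -> list[tuple[dt.date, str]]:
    out = []
    for w in sorted(config.season_windows, key=lambda w: w.start):
        out += [(d, w.label) for d in w.dates()]
    return out


# ---------------------------------------------------------------------------
# Stage 1: daily truth


def simulate_daily_responses(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    responses: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Draw the daily-level GLMM truth for each response.

    Returns a tidy animal-day table (with ``complete_*`` flags set, so it
    feeds straight into the model stage) and the planted truth.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(1)[0])
    responses = list(responses) if responses is not None else list(_DIRECT_RESPONSES)
    for r in responses:
        if r not in config.planted_coefficients:
            raise KeyError(f"no planted coefficients for response {r!r}")

    roster = config.animals()
    dates = _study_dates(config)
    n_a, n_d = len(roster), len(dates)
    animal_ids = [a for a, _ in roster]
    date_list = [d for d, _ in dates]

    a_eff = {}
    d_eff = {}
    cells = {}
    season_vec = np.array([1.0 if lab == "non-drought" else 0.0 for _, lab in dates])
    species_vec = np.array([1.0 if sp == "wildebeest" else 0.0 for _, sp in roster])

    base = pd.DataFrame(
        {
            "animal_id": np.repeat(animal_ids, n_d),
            "species": np.repeat([sp for _, sp in roster], n_d),
            "date": np.tile(date_list, n_a),
            "season": np.tile([lab for _, lab in dates], n_a),
        }
    )

    for resp in _DIRECT_RESPONSES:  # fixed draw order keeps seeds comparable
        if resp not in responses:
            continue
        coefs = config.planted_coefficients[resp]
        vc = config.variance_components[resp]
        b0, bs, bp, bi = coefs.linear()
        a = rng.normal(0.0, vc.animal_sd, n_a) if vc.animal_sd > 0 else np.zeros(n_a)
        d = rng.normal(0.0, vc.date_sd, n_d) if vc.date_sd > 0 else np.zeros(n_d)
        a_eff[resp], d_eff[resp] = a, d

        lp = (
            b0
            + bs * season_vec[None, :]
            + bp * species_vec[:, None]
            + bi * (season_vec[None, :] * species_vec[:, None])
            + a[:, None]
            + d[None, :]
        )
        if vc.residual_sd > 0:
            lp = lp + rng.normal(0.0, vc.residual_sd, lp.shape)

        if resp in ("cool_hours", "travel_hours"):
            lam = np.exp(lp)
            cap = 12 if resp == "cool_hours" else 22
            if config.is_zero_noise:
                # fully deterministic request: the rounded expectation
                vals = np.minimum(np.round(lam), cap).astype(float)
            else:
                vals = np.minimum(rng.poisson(lam), cap).astype(float)
        elif resp == "total_activity_24h":
            vals = np.exp(lp)
        elif resp == "heat_activity_proportion":
            vals = np.clip(lp, 0.005, 0.95)
        elif resp == "t_amplitude":
            vals = np.maximum(lp, _MIN_AMPLITUDE)
        else:
            vals = lp
        cells[resp] = vals.ravel()

    daily = base.copy()
    for resp in responses:
        daily[resp] = cells[resp]
    if "t_min" in responses and "t_amplitude" in responses:
        daily["t_max"] = daily["t_min"] + daily["t_amplitude"]
    if "cool_hours" in responses and "cumulative_cool_use" in responses:
        k = daily["cool_hours"].to_numpy()
        c = daily["cumulative_cool_use"].to_numpy()
        c = np.where(k > 0, np.clip(c, _MIN_HOUR_DEPTH * k, 12.0 * k), 0.0)
        daily["cumulative_cool_use"] = c
    for flag in ("complete_temp", "complete_microclimate", "complete_travel", "complete_activity"):
        daily[flag] = True

    truth = PlantedTruth(
        config=config,
        seed=config.rng_seed,
        coefficients=dict(config.planted_coefficients),
        animal_effects=pd.DataFrame(a_eff, index=pd.Index(animal_ids, name="animal_id")),
        date_effects=pd.DataFrame(d_eff, index=pd.Index(date_list, name="date")),
        daily=daily,
    )
    return daily, truth


# ---------------------------------------------------------------------------
# Environment streams


def _diurnal_profile(tmins: np.ndarray, tmaxs: np.ndarray, peak_hour: int, trough_hour: int) -> np.ndarray:
    """Hourly temperatures (days x 24): trough at trough_hour, peak at peak_hour.

    Rises as a half-cosine trough→peak, then decays toward the next day's
    trough, so the daily hourly maximum/minimum equal the inputs exactly.
    """
    n = len(tmins)
    hours = np.arange(24)
    out = np.empty((n, 24))
    rise = (hours >= trough_hour) & (hours <= peak_hour)
    span_up = peak_hour - trough_hour
    span_down = 24 - span_up
    next_min = np.append(tmins[1:], tmins[-1])
    prev_max = np.insert(tmaxs[:-1], 0, tmaxs[0])
    for j, h in enumerate(hours):
        if rise[j]:
            f = 0.5 * (1.0 - np.cos(np.pi * (h - trough_hour) / span_up))
            out[:, j] = tmins + (tmaxs - tmins) * f
        elif h > peak_hour:
            f = 0.5 * (1.0 + np.cos(np.pi * (h - peak_hour) / span_down))
            out[:, j] = next_min + (tmaxs - next_min) * f
        else:  # pre-dawn: decaying from yesterday's peak to today's trough
            f = 0.5 * (1.0 + np.cos(np.pi * (h + 24 - peak_hour) / span_down))
            out[:, j] = tmins + (prev_max - tmins) * f
    return out


def _window_hours(window: SeasonWindow) -> pd.DatetimeIndex:
    return pd.date_range(
        dt.datetime.combine(window.start, dt.time()),
        dt.datetime.combine(window.end, dt.time(23)),
        freq="h",
    )


def simulate_reference_globe(
    config: SimulationConfig,
    window: SeasonWindow | str | None = None,
    rng: np.random.Generator | None = None,
) -> LoggerStream:
    """Hourly full-sun reference miniglobe series over one or both seasons.

    Daily extremes are drawn around the configured seasonal envelope
    (trough 06:00, peak 15:00), so seasonal means of the daily maxima and
    minima match the configured targets.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(2)[1])
    if window is None:
        windows = sorted(config.season_windows, key=lambda w: w.start)
    else:
        if isinstance(window, str):
            window = config.window[window]
        windows = [window]

    pieces = []
    for w in windows:
        globe, _weather = config.environment[w.label]
        n = w.n_days
        tmax = rng.normal(globe.daily_max_mean, globe.daily_max_sd, n)
        tmin = rng.normal(globe.daily_min_mean, globe.daily_min_sd, n)
        tmax = np.maximum(tmax, tmin + 2.0)
        vals = _diurnal_profile(tmin, tmax, peak_hour=15, trough_hour=6).ravel()
        pieces.append(pd.Series(vals, index=_window_hours(w)))
    return LoggerStream("REFERENCE", "reference_globe", 60, pd.concat(pieces))


def simulate_weather(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Hourly weather-station table (dry bulb °C, wind m/s, solar W/m²)."""
    pieces = []
    for w in sorted(config.season_windows, key=lambda w: w.start):
        _globe, wx = config.environment[w.label]
        n = w.n_days
        tmax = rng.normal(wx.drybulb_max_mean, wx.drybulb_max_sd, n)
        tmin = rng.normal(wx.drybulb_min_mean, wx.drybulb_min_sd, n)
        tmax = np.maximum(tmax, tmin + 2.0)
        temp = _diurnal_profile(tmin, tmax, peak_hour=15, trough_hour=5).ravel()

        hours = np.arange(24)
        shape = np.where((hours >= 6) & (hours <= 18), np.sin(np.pi * (hours - 6) / 12.0), 0.0)
        shape_mean = shape.mean()
        s_day = np.maximum(rng.normal(wx.solar_mean, wx.solar_sd, n), 0.0)
        solar = (s_day[:, None] * shape[None, :] / shape_mean).ravel()

        w_day = np.maximum(rng.normal(wx.wind_mean, wx.wind_sd, n), 0.05)
        wind = np.maximum(rng.normal(w_day[:, None], 0.3, (n, 24)), 0.05).ravel()

        idx = _window_hours(w)
        pieces.append(
            pd.DataFrame({"timestamp": idx, "drybulb_c": temp, "wind_ms": wind, "solar_wm2": solar})
        )
    return pd.concat(pieces, ignore_index=True)


def simulate_rainfall(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Daily rainfall with the configured per-season total and rainy-day count."""
    pieces = []
    for w in sorted(config.season_windows, key=lambda w: w.start):
        _globe, wx = config.environment[w.label]
        days = w.dates()
        amounts = np.zeros(len(days))
        k = min(wx.rainy_days, len(days))
        if k > 0 and wx.rain_total_mm > 0:
            which = rng.choice(len(days), size=k, replace=False)
            base = 0.2  # every rainy day clears the 0.1 mm detection rule
            extra = max(wx.rain_total_mm - base * k, 0.0)
            split = rng.gamma(1.0, 1.0, k)
            amounts[which] = base + extra * split / split.sum()
        pieces.append(pd.DataFrame({"date": days, "rain_mm": amounts}))
    return pd.concat(pieces, ignore_index=True)


def simulate_ndvi(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """16-day NDVI composites per season: per-season constant plus noise."""
    rows = []
    for w in sorted(config.season_windows, key=lambda w: w.start):
        _globe, wx = config.environment[w.label]
        start = w.start
        while start <= w.end:
            rows.append(
                {
                    "start_date": start,
                    "end_date": min(start + dt.timedelta(days=15), w.end),
                    "ndvi": rng.normal(wx.ndvi_mean, wx.ndvi_sd),
                }
            )
            start += dt.timedelta(days=16)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stream rendering


def _render_body_temp(
    tmin: np.ndarray, amp: np.ndarray, index: pd.DatetimeIndex, config: SimulationConfig, rng
) -> pd.Series:
    """10-min body temperature: cosinor days pinned to exact (min, max).

    The base curve is a two-harmonic cosinor with trough 06:00 and peak
    18:00 (|12 h term| < amplitude/8, so the grid extremes stay at those
    times); AR(1) texture is added and each day affinely mapped back to
    the planted extremes.
    """
    n_days = len(tmin)
    h = np.arange(144) / 6.0  # hours at 10-min steps
    phi1 = np.cos(2.0 * np.pi * (h - 18.0) / 24.0)
    phi2 = np.cos(4.0 * np.pi * (h - 18.0) / 24.0)
    a1 = amp[:, None] / 2.0
    a2 = amp[:, None] / 10.0
    base = (tmin[:, None] + a1 - a2) + a1 * phi1[None, :] + a2 * phi2[None, :]

    if config.bodytemp_texture_sd > 0:
        rho = config.bodytemp_ar1_rho
        innov = rng.normal(0.0, config.bodytemp_texture_sd * math.sqrt(1 - rho**2), (n_days, 144))
        tex = lfilter([1.0], [1.0, -rho], innov, axis=1)
        x = base + tex
        span = x.max(axis=1) - x.min(axis=1)
        alpha = np.where(span > 0, amp / np.where(span > 0, span, 1.0), 1.0)
        vals = tmin[:, None] + alpha[:, None] * (x - x.min(axis=1)[:, None])
    else:
        vals = base
    return pd.Series(vals.ravel(), index=index)


_ACT_SLOT_HOURS = np.arange(288) / 12.0


def _activity_template() -> np.ndarray:
    """Crepuscular 5-min weight curve: dawn/dusk peaks, quiet midday/night."""
    h = _ACT_SLOT_HOURS
    return (
        0.15
        + np.exp(-0.5 * ((h - 6.5) / 1.3) ** 2)
        + np.exp(-0.5 * ((h - 18.5) / 1.3) ** 2)
        + 0.10 * np.exp(-0.5 * ((h - 13.0) / 2.5) ** 2)
    )


def _render_activity_day(total, heat_prop, jitter_cv, rng) -> np.ndarray:
    """One day of relative 5-min counts with exact total and heat share."""
    w = _activity_template()
    if jitter_cv > 0:
        w = w * rng.gamma(1.0 / jitter_cv**2, jitter_cv**2, 288)
    in_heat = (_ACT_SLOT_HOURS >= 10.0) & (_ACT_SLOT_HOURS < 16.0)
    out = np.empty(288)
    out[in_heat] = total * heat_prop * w[in_heat] / w[in_heat].sum()
    out[~in_heat] = total * (1.0 - heat_prop) * w[~in_heat] / w[~in_heat].sum()
    return out


def _render_collar_day(
    ref_day: pd.Series,
    k: int,
    cum_use: float,
    date: dt.date,
    config: SimulationConfig,
    rng,
) -> pd.Series:
    """Collar miniglobe for one day: shade bout carved out of the reference."""
    collar = ref_day.copy()
    hours = ref_day.index.hour.to_numpy()
    rise, sset = daylight_window(date, config.latitude, config.longitude,
                                 config.boundary.utc_offset_hours)
    mids = ref_day.index + pd.Timedelta(minutes=30)
    daylight = (mids > rise) & (mids < sset)
    dl_hours = hours[daylight]

    noise_mask = np.ones(len(collar), dtype=bool)
    k = int(min(k, len(dl_hours)))
    if k > 0:
        mid_pos = int(np.searchsorted(dl_hours, 13))
        start = mid_pos - k // 2 + int(np.round(rng.normal(0.0, 1.0)))
        start = int(np.clip(start, 0, len(dl_hours) - k))
        shade_hours = dl_hours[start : start + k]
        split = rng.gamma(1.0, 1.0, k)
        depths = _MIN_HOUR_DEPTH + max(cum_use - _MIN_HOUR_DEPTH * k, 0.0) * split / split.sum()
        sel = np.isin(hours, shade_hours)
        collar.iloc[np.flatnonzero(sel)] -= depths
        noise_mask &= ~sel
    if config.globe_sensor_sd > 0:
        collar.iloc[np.flatnonzero(noise_mask)] += rng.normal(
            0.0, config.globe_sensor_sd, int(noise_mask.sum())
        )
    return collar


_KM_PER_DEG = math.pi * 6371.0088 / 180.0


def _render_track(
    travel_hours_by_day: pd.Series, config: SimulationConfig, rng
) -> pd.DataFrame:
    """Correlated random walk with planted excursion (>1.6 km) hours.

    Routine steps are capped below the travel threshold and excursion
    steps floored above it, so the per-day count of >1.6 km hourly
    displacements equals the planted truth exactly.
    """
    dates = list(travel_hours_by_day.index)
    lat = config.latitude + rng.uniform(-0.3, 0.3)
    lon = config.longitude + rng.uniform(-0.3, 0.3)
    bearing = rng.uniform(0.0, 2.0 * math.pi)

    ts, lats, lons = [], [], []
    window_ends = {w.end for w in config.season_windows}
    for day_i, date in enumerate(dates):
        h_needed = int(travel_hours_by_day.iloc[day_i])
        last_hour = 22 if date in window_ends else 23
        hour_pool = np.arange(0, min(last_hour, 23))
        h_needed = min(h_needed, len(hour_pool))
        excursions = set(rng.choice(hour_pool, size=h_needed, replace=False).tolist())
        for hour in range(24):
            ts.append(dt.datetime.combine(date, dt.time(hour)))
            lats.append(lat)
            lons.append(lon)
            # step to the next fix (the displacement credited to this hour)
            if hour in excursions:
                step = rng.uniform(*_EXCURSION_KM)
            else:
                step = min(rng.gamma(2.0, _ROUTINE_STEP_MEAN_KM / 2.0), _ROUTINE_STEP_CAP_KM)
            home_km = math.hypot(
                (lat - config.latitude) * _KM_PER_DEG,
                (lon - config.longitude) * _KM_PER_DEG * math.cos(math.radians(lat)),
            )
            if home_km > 60.0:  # drift back toward the study core
                bearing = math.atan2(
                    -(lon - config.longitude) * math.cos(math.radians(lat)),
                    -(lat - config.latitude),
                ) + rng.normal(0.0, 0.3)
            else:
                bearing += rng.normal(0.0, 0.7)
            dlat = step * math.cos(bearing) / _KM_PER_DEG
            lat_mid = lat + dlat / 2.0
            dlon = step * math.sin(bearing) / (_KM_PER_DEG * math.cos(math.radians(lat_mid)))
            lat += dlat
            lon += dlon
    return pd.DataFrame({"lat": lats, "lon": lons}, index=pd.DatetimeIndex(ts))


def _apply_dropout(index_len: int, rate: float, rng, keep: np.ndarray | None = None) -> np.ndarray:
    mask = rng.random(index_len) >= rate
    if keep is not None:
        mask |= keep
    return mask


def simulate_study(config: SimulationConfig) -> tuple[StudyDataset, PlantedTruth]:
    """Generate a full synthetic study: daily truth plus all sensor streams."""
    ss = np.random.SeedSequence(config.rng_seed).spawn(8)
    rng_daily = np.random.default_rng(ss[0])
    rng_globe = np.random.default_rng(ss[1])
    rng_wx = np.random.default_rng(ss[2])
    rng_body = np.random.default_rng(ss[3])
    rng_act = np.random.default_rng(ss[4])
    rng_collar = np.random.default_rng(ss[5])
    rng_gps = np.random.default_rng(ss[6])
    rng_drop = np.random.default_rng(ss[7])

    daily, truth = simulate_daily_responses(config, rng_daily)
    reference = simulate_reference_globe(config, rng=rng_globe)
    weather = simulate_weather(config, rng_wx)
    rainfall = simulate_rainfall(config, rng_wx)
    ndvi = simulate_ndvi(config, rng_wx)

    windows = sorted(config.season_windows, key=lambda w: w.start)
    species = dict(config.animals())
    all_dates = [d for w in windows for d in w.dates()]
    ref_by_day = {d: reference.data[reference.data.index.date == d] for d in all_dates}

    body_temps, activities, collar_globes, tracks = {}, {}, {}, {}
    for aid in species:
        rows = daily[daily["animal_id"] == aid].set_index("date")

        # --- body temperature (10-min)
        pieces = []
        for w in windows:
            idx = pd.date_range(
                dt.datetime.combine(w.start, dt.time()),
                dt.datetime.combine(w.end, dt.time(23, 50)),
                freq="10min",
            )
            sub = rows.loc[list(w.dates())]
            pieces.append(
                _render_body_temp(
                    sub["t_min"].to_numpy(), sub["t_amplitude"].to_numpy(), idx, config, rng_body
                )
            )
        bt = pd.concat(pieces)
        bt = bt[_apply_dropout(len(bt), config.dropout_rate, rng_drop)]
        body_temps[aid] = LoggerStream(aid, "body_temperature", 10, bt)

        # --- activity (5-min), with a full-scale handling spike in a 3-day
        # lead-in before the first season so per-logger normalization is exact
        scale = rng_act.uniform(400.0, 1000.0)
        jitter_cv = config.activity_jitter_cv
        lead_start = windows[0].start - dt.timedelta(days=3)
        lead_days = [lead_start + dt.timedelta(days=i) for i in range(3)]
        slots, vals = [], []
        for d in lead_days:
            idx = pd.date_range(dt.datetime.combine(d, dt.time()), periods=288, freq="5min")
            day = scale * _render_activity_day(1.5, 0.2, jitter_cv, rng_act)
            slots.append(idx)
            vals.append(day)
        vals[0][0] = scale  # the handling/deployment full-scale event
        for w in windows:
            for d in w.dates():
                idx = pd.date_range(dt.datetime.combine(d, dt.time()), periods=288, freq="5min")
                day = scale * _render_activity_day(
                    float(rows.at[d, "total_activity_24h"]),
                    float(rows.at[d, "heat_activity_proportion"]),
                    jitter_cv,
                    rng_act,
                )
                slots.append(idx)
                vals.append(day)
        act = pd.Series(np.concatenate(vals), index=slots[0].append(slots[1:]))
        keep = np.zeros(len(act), dtype=bool)
        keep[0] = True  # never drop the normalization spike
        act = act[_apply_dropout(len(act), config.dropout_rate, rng_drop, keep)]
        activities[aid] = LoggerStream(aid, "activity", 5, act)

        # --- collar miniglobe (hourly)
        days = []
        for d in all_dates:
            days.append(
                _render_collar_day(
                    ref_by_day[d],
                    int(rows.at[d, "cool_hours"]),
                    float(rows.at[d, "cumulative_cool_use"]),
                    d,
                    config,
                    rng_collar,
                )
            )
        cg = pd.concat(days)
        cg = cg[_apply_dropout(len(cg), config.dropout_rate, rng_drop)]
        collar_globes[aid] = LoggerStream(aid, "collar_globe", 60, cg)

        # --- GPS track (hourly)
        th = rows["travel_hours"]
        fixes = _render_track(th, config, rng_gps)
        fixes = fixes[_apply_dropout(len(fixes), config.dropout_rate, rng_drop)]
        tracks[aid] = GpsTrack(aid, fixes)

    dataset = StudyDataset(
        species=species,
        body_temps=body_temps,
        activities=activities,
        collar_globes=collar_globes,
        reference_globe=reference,
        tracks=tracks,
        weather=weather,
        rainfall=rainfall,
        ndvi=ndvi,
        config=config,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# Recovery harness


def planted_recovery_table(truth: PlantedTruth, fits) -> pd.DataFrame:
    """Per-coefficient recovery report: bias and 95% CI coverage of the truth.

    ``fits`` is a list of :class:`~thermotrack.models.MixedModelFit`
    objects produced from data generated under ``truth``; an empty list
    yields an empty report.
    """
    rows = []
    for fit in fits:
        resp = fit.spec.response
        if resp not in truth.coefficients:
            raise KeyError(f"fit response {resp!r} has no planted truth")
        planted = truth.coefficients[resp]
        for _, row in fit.coefficients.iterrows():
            pv = getattr(planted, row["term"])
            rows.append(
                {
                    "response": resp,
                    "model": fit.spec.fixed,
                    "term": row["term"],
                    "planted": pv,
                    "estimate": row["estimate"],
                    "bias": row["estimate"] - pv,
                    "ci_low": row["ci_low"],
                    "ci_high": row["ci_high"],
                    "covered": bool(row["ci_low"] <= pv <= row["ci_high"]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["response", "model", "term", "planted", "estimate", "bias", "ci_low", "ci_high", "covered"],
    )
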