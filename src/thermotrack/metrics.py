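"""Per-animal-per-day analysis variables from raw sensor streams.

Implements the derived metrics of the drought-response analysis:

* daily minimum, maximum and amplitude (max − min) of the 24 h body
  temperature rhythm (10-min implant records);
* cool-microclimate hours — daylight hours in which the collar miniglobe
  reads *more than* 0.5 °C below the full-sun reference miniglobe — and
  cumulative cool-microclimate use, the daily sum of the cooling depth
  (reference − collar, °C·h) over those hours;
* travel hours — hours in which consecutive GPS fixes are more than
  1.6 km apart (great-circle distance);
* total 24 h activity (sum of per-logger-normalized 5-min counts) and
  the proportion of activity falling in the 10:00–16:00 heat window.

Thresholds are strict inequalities (> 1.6 km, more than 0.5 °C cooler).
Days run local midnight-to-midnight at fixed UTC+2; a day yields a
sensor's metrics only if at least the configured fraction of that
sensor's expected records is present.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import DayBoundary, SeasonWindow
from .solar import STUDY_LAT, STUDY_LON, daylight_window
from .streams import EXPECTED_RECORDS_PER_DAY, GpsTrack, LoggerStream

__all__ = [
    "COOL_DELTA_THRESHOLD_C",
    "TRAVEL_DISTANCE_THRESHOLD_KM",
    "EARTH_RADIUS_KM",
    "HEAT_WINDOW",
    "haversine_km",
    "daily_temp_params",
    "microclimate_metrics",
    "travel_metrics",
    "activity_metrics",
    "normalize_activity",
    "assemble_daily",
]

COOL_DELTA_THRESHOLD_C = 0.5  # collar must be MORE than this much cooler
TRAVEL_DISTANCE_THRESHOLD_KM = 1.6  # strict: displacement must exceed this
MAX_FIX_GAP_MINUTES = 75  # displacement only between fixes at most this far apart
EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius
HEAT_WINDOW = (10, 16)  # [10:00, 16:00) local


def _require_sorted(index: pd.DatetimeIndex, what: str) -> None:
    if len(index) > 1 and not index.is_monotonic_increasing:
        raise ValueError(f"{what}: timestamps must be sorted; sort the stream first")


def haversine_km(lat1, lon1, lat2, lon2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance between WGS84 points, in km (vectorized)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# Body temperature


def daily_temp_params(body_temp: LoggerStream, boundary: DayBoundary) -> pd.DataFrame:
    """Daily (t_min, t_max, t_amplitude) of the body-temperature rhythm.

    Returns a frame indexed by civil date with columns ``t_min``, ``t_max``,
    ``t_amplitude``, ``n_records`` and ``complete``.  Incomplete days (fewer
    than ``boundary.completeness`` of the 144 expected 10-min records) keep
    their values but are flagged for downstream exclusion.
    """
    s = body_temp.data
    if s.empty:
        return pd.DataFrame(columns=["t_min", "t_max", "t_amplitude", "n_records", "complete"])
    _require_sorted(s.index, "body temperature")

    expected = EXPECTED_RECORDS_PER_DAY["body_temperature"]
    by_day = s.groupby(s.index.date)
    out = pd.DataFrame(
        {
            "t_min": by_day.min(),
            "t_max": by_day.max(),
            "n_records": by_day.size(),
        }
    )
    out["t_amplitude"] = out["t_max"] - out["t_min"]
    out["complete"] = out["n_records"] >= boundary.completeness * expected
    out.index = pd.Index(out.index, name="date")
    return out[["t_min", "t_max", "t_amplitude", "n_records", "complete"]]


# ---------------------------------------------------------------------------
# Microclimate


def hourly_deltas(
    collar: LoggerStream,
    reference: LoggerStream,
    latitude: float = STUDY_LAT,
    longitude: float = STUDY_LON,
    utc_offset_hours: float = 2.0,
) -> pd.DataFrame:
    """Hour-by-hour collar-vs-reference comparison.

    Joins the two hourly globes on exact timestamps (hours missing either
    reading are dropped, not imputed) and classifies each hour: an hour
    stamped at its start is *daylight* if its midpoint falls between
    sunrise and sunset, and *cool* if additionally the collar reads more
    than 0.5 °C below the reference.
    """
    joined = pd.concat(
        {"collar": collar.data, "reference": reference.data}, axis=1, join="inner"
    ).dropna()
    if joined.empty:
        return pd.DataFrame(columns=["collar", "reference", "delta", "is_daylight", "is_cool"])

    joined["delta"] = joined["collar"] - joined["reference"]
    mids = joined.index + pd.Timedelta(minutes=30)
    daylight = np.empty(len(joined), dtype=bool)
    for date, sel in pd.Series(mids, index=joined.index).groupby(joined.index.date):
        rise, sset = daylight_window(date, latitude, longitude, utc_offset_hours)
        daylight[joined.index.get_indexer(sel.index)] = (sel > rise) & (sel < sset)
    joined["is_daylight"] = daylight
    joined["is_cool"] = joined["is_daylight"] & (joined["delta"] < -COOL_DELTA_THRESHOLD_C)
    return joined


def microclimate_metrics(
    collar: LoggerStream,
    reference: LoggerStream,
    boundary: DayBoundary,
    latitude: float = STUDY_LAT,
    longitude: float = STUDY_LON,
) -> pd.DataFrame:
    """Daily (cool_hours, cumulative_cool_use) from the two miniglobes.

    ``cool_hours`` counts cool daylight hours; ``cumulative_cool_use`` sums
    the cooling depth (reference − collar, positive °C·h) over those hours.
    """
    deltas = hourly_deltas(collar, reference, latitude, longitude, boundary.utc_offset_hours)
    if deltas.empty:
        return pd.DataFrame(columns=["cool_hours", "cumulative_cool_use", "n_records", "complete"])

    grp = deltas.groupby(deltas.index.date)
    depth = (-deltas["delta"]).where(deltas["is_cool"], 0.0)
    out = pd.DataFrame(
        {
            "cool_hours": grp["is_cool"].sum().astype(int),
            "cumulative_cool_use": depth.groupby(deltas.index.date).sum(),
            "n_records": grp.size(),
        }
    )
    expected = EXPECTED_RECORDS_PER_DAY["collar_globe"]
    out["complete"] = out["n_records"] >= boundary.completeness * expected
    out.index = pd.Index(out.index, name="date")
    return out


# ---------------------------------------------------------------------------
# Movement


def hourly_displacements(track: GpsTrack) -> pd.Series:
    """Great-circle displacement (km) between consecutive fixes.

    Indexed by the timestamp of the earlier fix of each pair; pairs more
    than 75 min apart are dropped (a missed fix breaks the hour).
    """
    df = track.data
    if len(df) < 2:
        return pd.Series(dtype=float)
    _require_sorted(df.index, "GPS track")
    gaps = df.index.to_series().diff().dt.total_seconds().iloc[1:] / 60.0
    d = haversine_km(
        df["lat"].values[:-1], df["lon"].values[:-1], df["lat"].values[1:], df["lon"].values[1:]
    )
    disp = pd.Series(d, index=df.index[:-1])
    return disp[(gaps <= MAX_FIX_GAP_MINUTES).values]


def travel_metrics(track: GpsTrack, boundary: DayBoundary) -> pd.DataFrame:
    """Daily travel hours: count of hours with displacement strictly > 1.6 km."""
    disp = hourly_displacements(track)
    if disp.empty:
        return pd.DataFrame(columns=["travel_hours", "n_records", "complete"])
    grp = disp.groupby(disp.index.date)
    out = pd.DataFrame(
        {
            "travel_hours": grp.apply(lambda x: int((x > TRAVEL_DISTANCE_THRESHOLD_KM).sum())),
            "n_records": grp.size(),
        }
    )
    # 24 fixes/day -> at most 24 within-day pairs; require the usual fraction
    out["complete"] = out["n_records"] >= boundary.completeness * 23
    out.index = pd.Index(out.index, name="date")
    return out


# ---------------------------------------------------------------------------
# Activity


def normalize_activity(activity: LoggerStream) -> LoggerStream:
    """Scale counts relative to the logger's maximum over its entire record.

    Normalization happens once per logger across the whole study period
    (before any daily aggregation), so re-normalizing is the identity.
    An all-zero logger has no defined scale and raises ``ValueError``.
    """
    peak = activity.data.max()
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError(f"activity logger {activity.animal_id}: all-zero record, normalization undefined")
    return LoggerStream(activity.animal_id, activity.kind, activity.cadence_minutes, activity.data / peak)


def activity_metrics(
    activity: LoggerStream,
    boundary: DayBoundary,
    heat_window: tuple[int, int] = HEAT_WINDOW,
) -> pd.DataFrame:
    """Daily total 24 h activity and heat-of-day proportion.

    Counts are first normalized per logger; the daily total is the sum of
    relative counts and the heat proportion the share falling in
    [``heat_window[0]``:00, ``heat_window[1]``:00).
    """
    rel = normalize_activity(activity).data
    _require_sorted(rel.index, "activity")
    in_heat = (rel.index.hour >= heat_window[0]) & (rel.index.hour < heat_window[1])

    grp = rel.groupby(rel.index.date)
    total = grp.sum()
    heat = rel.where(in_heat, 0.0).groupby(rel.index.date).sum()
    out = pd.DataFrame({"total_activity_24h": total, "n_records": grp.size()})
    with np.errstate(invalid="ignore", divide="ignore"):
        out["heat_activity_proportion"] = np.where(total > 0, heat / total, np.nan)
    expected = EXPECTED_RECORDS_PER_DAY["activity"]
    out["complete"] = (out["n_records"] >= boundary.completeness * expected) & (total > 0)
    out.index = pd.Index(out.index, name="date")
    return out[["total_activity_24h", "heat_activity_proportion", "n_records", "complete"]]


# ---------------------------------------------------------------------------
# Assembly


def label_season(date: dt.date, windows: Iterable[SeasonWindow]) -> str:
    for w in windows:
        if w.contains(date):
            return w.label
    return "outside"


METRIC_COLUMNS = [
    "t_min",
    "t_max",
    "t_amplitude",
    "cool_hours",
    "cumulative_cool_use",
    "travel_hours",
    "total_activity_24h",
    "heat_activity_proportion",
]


def assemble_daily(
    body_temps: Mapping[str, LoggerStream],
    activities: Mapping[str, LoggerStream],
    collar_globes: Mapping[str, LoggerStream],
    reference_globe: LoggerStream,
    tracks: Mapping[str, GpsTrack],
    species: Mapping[str, str],
    boundary: DayBoundary,
    season_windows: Iterable[SeasonWindow],
    latitude: float = STUDY_LAT,
    longitude: float = STUDY_LON,
) -> pd.DataFrame:
    """Tidy table of daily metrics: one row per animal-day inside a season window.

    Animals missing a sensor simply have NaN for that sensor's metrics.
    Each metric family carries a ``complete_*`` flag; days outside both
    season windows are excluded.
    """
    windows = list(season_windows)
    animal_ids = sorted(set(body_temps) | set(activities) | set(collar_globes) | set(tracks))
    for aid in animal_ids:
        if aid not in species:
            raise ValueError(f"animal {aid} has no species label")

    frames = []
    for aid in animal_ids:
        parts = []
        if aid in body_temps:
            t = daily_temp_params(body_temps[aid], boundary)
            parts.append(
                t[["t_min", "t_max", "t_amplitude"]].assign(complete_temp=t["complete"])
            )
        if aid in collar_globes:
            m = microclimate_metrics(collar_globes[aid], reference_globe, boundary, latitude, longitude)
            parts.append(
                m[["cool_hours", "cumulative_cool_use"]].assign(complete_microclimate=m["complete"])
            )
        if aid in tracks:
            tr = travel_metrics(tracks[aid], boundary)
            parts.append(tr[["travel_hours"]].assign(complete_travel=tr["complete"]))
        if aid in activities:
            a = activity_metrics(activities[aid], boundary)
            parts.append(
                a[["total_activity_24h", "heat_activity_proportion"]].assign(
                    complete_activity=a["complete"]
                )
            )
        if not parts:
            continue
        row = pd.concat(parts, axis=1)
        row.insert(0, "animal_id", aid)
        row.insert(1, "species", species[aid])
        frames.append(row.reset_index(names="date"))

    if not frames:
        return pd.DataFrame(columns=["animal_id", "species", "date", "season", *METRIC_COLUMNS])

    daily = pd.concat(frames, ignore_index=True)
    daily["date"] = pd.to_datetime(daily["date"]).dt.date
    daily["season"] = [label_season(d, windows) for d in daily["date"]]
    daily = daily[daily["season"] != "outside"].reset_index(drop=True)

    for col in METRIC_COLUMNS:
        if col not in daily.columns:
            daily[col] = np.nan
    for col in ("complete_temp", "complete_microclimate", "complete_travel", "complete_activity"):
        if col not in daily.columns:
            daily[col] = False
        else:
            daily[col] = daily[col].notna() & daily[col].astype("boolean").fillna(False).astype(bool)

    lead = ["animal_id", "species", "date", "season"]
    flags = ["complete_temp", "complete_microclimate", "complete_travel", "complete_activity"]
    return daily[lead + METRIC_COLUMNS + flags]
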