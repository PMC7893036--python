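"""Delimited-text I/O for sensor streams, tracks and context tables.

One file per sensor per animal; timestamps ISO-8601 with an explicit
+02:00 offset (the study clock); coordinates WGS84 decimal degrees.
A ``data_dictionary.md`` describing every file is written alongside.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import pandas as pd

from .streams import GpsTrack, LoggerStream

__all__ = ["write_dataset", "read_dataset", "read_daily_metrics", "write_daily_metrics"]

_TZ = "+02:00"

_DATA_DICTIONARY = """\
# Data dictionary

All timestamps are ISO-8601 local time with an explicit +02:00 offset
(study clock, no DST). Coordinates are WGS84 decimal degrees
(south/west negative).

| file | columns | cadence | units |
|---|---|---|---|
| roster.csv | animal_id, species | — | species: gemsbok or wildebeest |
| bodytemp_<animal>.csv | animal_id, timestamp, temp_c | 10 min | °C (implanted logger) |
| activity_<animal>.csv | animal_id, timestamp, counts | 5 min | per-logger arbitrary counts |
| collarglobe_<animal>.csv | animal_id, timestamp, temp_c | 1 h | °C (collar miniglobe) |
| gps_<animal>.csv | animal_id, timestamp, lat, lon | 1 h | decimal degrees |
| reference_globe.csv | timestamp, temp_c | 1 h | °C (full-sun reference miniglobe) |
| weather.csv | timestamp, drybulb_c, wind_ms, solar_wm2 | 1 h | °C, m s⁻¹, W m⁻² |
| rainfall.csv | date, rain_mm | 1 day | mm |
| ndvi.csv | start_date, end_date, ndvi | 16 day | unitless composite |
"""


def _fmt_ts(index: pd.DatetimeIndex) -> pd.Index:
    return index.strftime("%Y-%m-%dT%H:%M:%S") + _TZ


def _parse_ts(col: pd.Series) -> pd.DatetimeIndex:
    ts = pd.to_datetime(col, utc=True) + pd.Timedelta(hours=2)
    return pd.DatetimeIndex(ts.dt.tz_localize(None))


def write_dataset(dataset, out_dir) -> Path:
    """Write a StudyDataset as the delimited-text layout the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(sorted(dataset.species.items()), columns=["animal_id", "species"]).to_csv(
        out / "roster.csv", index=False
    )

    def stream_frame(s: LoggerStream, value_col: str) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal_id": s.animal_id, "timestamp": _fmt_ts(s.data.index), value_col: s.data.values}
        )

    for aid, s in sorted(dataset.body_temps.items()):
        stream_frame(s, "temp_c").to_csv(out / f"bodytemp_{aid}.csv", index=False, float_format="%.4f")
    for aid, s in sorted(dataset.activities.items()):
        stream_frame(s, "counts").to_csv(out / f"activity_{aid}.csv", index=False, float_format="%.4f")
    for aid, s in sorted(dataset.collar_globes.items()):
        stream_frame(s, "temp_c").to_csv(out / f"collarglobe_{aid}.csv", index=False, float_format="%.4f")
    for aid, t in sorted(dataset.tracks.items()):
        pd.DataFrame(
            {
                "animal_id": aid,
                "timestamp": _fmt_ts(t.data.index),
                "lat": t.data["lat"].values,
                "lon": t.data["lon"].values,
            }
        ).to_csv(out / f"gps_{aid}.csv", index=False, float_format="%.6f")

    ref = dataset.reference_globe
    pd.DataFrame({"timestamp": _fmt_ts(ref.data.index), "temp_c": ref.data.values}).to_csv(
        out / "reference_globe.csv", index=False, float_format="%.4f"
    )

    wx = dataset.weather.copy()
    wx["timestamp"] = _fmt_ts(pd.DatetimeIndex(wx["timestamp"]))
    wx.to_csv(out / "weather.csv", index=False, float_format="%.4f")
    dataset.rainfall.to_csv(out / "rainfall.csv", index=False, float_format="%.4f")
    dataset.ndvi.to_csv(out / "ndvi.csv", index=False, float_format="%.4f")
    (out / "data_dictionary.md").write_text(_DATA_DICTIONARY)
    return out


def read_dataset(in_dir, config=None):
    """Read a dataset directory back into a StudyDataset.

    ``config`` supplies the analysis conventions (season windows, day
    boundary, site coordinates); defaults are used when omitted.
    """
    from .config import default_config
    from .simulate import StudyDataset

    src = Path(in_dir)
    if config is None:
        config = default_config()

    roster = pd.read_csv(src / "roster.csv")
    species = dict(zip(roster["animal_id"], roster["species"]))

    def read_stream(path: Path, kind: str, cadence: int, value_col: str) -> LoggerStream:
        df = pd.read_csv(path)
        s = pd.Series(df[value_col].values, index=_parse_ts(df["timestamp"])).sort_index()
        return LoggerStream(str(df["animal_id"].iloc[0]), kind, cadence, s)

    body_temps, activities, collar_globes, tracks = {}, {}, {}, {}
    for path in sorted(src.glob("bodytemp_*.csv")):
        s = read_stream(path, "body_temperature", 10, "temp_c")
        body_temps[s.animal_id] = s
    for path in sorted(src.glob("activity_*.csv")):
        s = read_stream(path, "activity", 5, "counts")
        activities[s.animal_id] = s
    for path in sorted(src.glob("collarglobe_*.csv")):
        s = read_stream(path, "collar_globe", 60, "temp_c")
        collar_globes[s.animal_id] = s
    for path in sorted(src.glob("gps_*.csv")):
        df = pd.read_csv(path)
        idx = _parse_ts(df["timestamp"])
        tr = GpsTrack(str(df["animal_id"].iloc[0]), pd.DataFrame({"lat": df["lat"].values, "lon": df["lon"].values}, index=idx).sort_index())
        tracks[tr.animal_id] = tr

    ref_df = pd.read_csv(src / "reference_globe.csv")
    reference = LoggerStream(
        "REFERENCE", "reference_globe", 60,
        pd.Series(ref_df["temp_c"].values, index=_parse_ts(ref_df["timestamp"])).sort_index(),
    )

    weather = pd.read_csv(src / "weather.csv")
    weather["timestamp"] = _parse_ts(weather["timestamp"])
    rainfall = pd.read_csv(src / "rainfall.csv")
    rainfall["date"] = pd.to_datetime(rainfall["date"]).dt.date
    ndvi = pd.read_csv(src / "ndvi.csv")
    for c in ("start_date", "end_date"):
        ndvi[c] = pd.to_datetime(ndvi[c]).dt.date

    return StudyDataset(
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


def write_daily_metrics(daily: pd.DataFrame, path) -> None:
    daily.to_csv(path, index=False, float_format="%.6f")


def read_daily_metrics(path) -> pd.DataFrame:
    daily = pd.read_csv(path)
    daily["date"] = pd.to_datetime(daily["date"]).dt.date
    for col in daily.columns:
        if col.startswith("complete_"):
            daily[col] = daily[col].astype(bool)
    return daily
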