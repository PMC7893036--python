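"""In-memory containers for logger streams and GPS tracks.

Timestamps are naive local datetimes on the study clock (fixed UTC+2);
the I/O layer attaches/strips the explicit ``+02:00`` offset when
reading or writing delimited text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LoggerStream", "GpsTrack", "EXPECTED_RECORDS_PER_DAY"]

#: expected records per civil day at each sensor cadence
EXPECTED_RECORDS_PER_DAY = {
    "body_temperature": 144,  # 10-min
    "activity": 288,  # 5-min
    "collar_globe": 24,  # hourly
    "reference_globe": 24,  # hourly
}


def _check_monotone(index: pd.DatetimeIndex, what: str) -> None:
    if len(index) > 1 and not index.is_monotonic_increasing:
        raise ValueError(f"{what}: timestamps must be sorted increasing")
    if index.has_duplicates:
        raise ValueError(f"{what}: duplicate timestamps")


@dataclass
class LoggerStream:
    """A timestamped univariate sensor series for one logger."""

    animal_id: str
    kind: str  # body_temperature | activity | collar_globe | reference_globe
    cadence_minutes: int
    data: pd.Series  # DatetimeIndex -> float

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise TypeError("LoggerStream.data must be indexed by timestamps")
        _check_monotone(self.data.index, f"{self.kind} stream of {self.animal_id}")
        self.data = self.data.astype(float)

    def __len__(self) -> int:
        return len(self.data)

    def sorted(self) -> "LoggerStream":
        return LoggerStream(self.animal_id, self.kind, self.cadence_minutes, self.data.sort_index())


@dataclass
class GpsTrack:
    """Hourly GPS fixes (WGS84 decimal degrees) for one animal."""

    animal_id: str
    data: pd.DataFrame = field(repr=False)  # DatetimeIndex -> [lat, lon]

    def __post_init__(self) -> None:
        missing = {"lat", "lon"} - set(self.data.columns)
        if missing:
            raise ValueError(f"GpsTrack missing columns {sorted(missing)}")
        _check_monotone(self.data.index, f"GPS track of {self.animal_id}")

    def __len__(self) -> int:
        return len(self.data)


def make_stream(animal_id: str, kind: str, timestamps, values, cadence_minutes: int) -> LoggerStream:
    """Build a stream from raw (possibly unsorted) records."""
    s = pd.Series(np.asarray(values, dtype=float), index=pd.DatetimeIndex(timestamps))
    return LoggerStream(animal_id, kind, cadence_minutes, s.sort_index())
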