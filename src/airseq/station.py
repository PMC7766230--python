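"""The hourly multichannel station record shared by every stage of the pipeline.

A :class:`StationSeries` holds one roadside (or urban background) monitoring
station's hourly record: six pollutant channels and six meteorological
channels on a strictly contiguous hourly time axis.  Missing observations are
represented as ``NaN``; the boolean missing mask is derived, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

#: Pollutant channels, concentration units: µg/m³ except CO (mg/m³).
POLLUTANTS = ["pm25", "pm10", "co", "no2", "o3", "so2"]

#: Meteorological channels ("wind" is carried as speed + direction).
METEOROLOGY = ["temp", "rh", "pressure", "wind_speed", "wind_dir", "precip"]

CHANNELS = POLLUTANTS + METEOROLOGY

HOURS_PER_DAY = 24


@dataclass
class StationSeries:
    """Hourly pollutant + meteorology record for one station.

    Parameters
    ----------
    station_id:
        Free-form station label.
    data:
        DataFrame indexed by a timezone-naive hourly ``DatetimeIndex``
        (contiguous, strictly increasing, 1-hour step) with exactly the
        columns in :data:`CHANNELS`.  ``NaN`` marks a missing cell.
    """

    station_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = [c for c in CHANNELS if c not in df.columns]
        if missing_cols:
            raise FormatError(f"missing channels: {missing_cols}")
        if not isinstance(df.index, pd.DatetimeIndex):
            raise FormatError("index must be a DatetimeIndex")
        if len(df) == 0:
            raise FormatError("empty series")
        diffs = np.diff(df.index.asi8)
        if len(diffs) and not (diffs == 3_600_000_000_000).all():
            bad = int(np.flatnonzero(diffs != 3_600_000_000_000)[0]) + 1
            raise FormatError(
                f"timestamps must be contiguous hourly; violation at row {bad} "
                f"({df.index[bad]})"
            )
        self.data = df[CHANNELS].astype(float)

    # ------------------------------------------------------------------
    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def pollutants(self) -> pd.DataFrame:
        return self.data[POLLUTANTS]

    @property
    def meteorology(self) -> pd.DataFrame:
        return self.data[METEOROLOGY]

    @property
    def missing_mask(self) -> pd.DataFrame:
        """True where a cell is missing."""
        return self.data.isna()

    @property
    def n_hours(self) -> int:
        return len(self.data)

    @property
    def n_days(self) -> int:
        return len(self.data) // HOURS_PER_DAY

    def is_day_aligned(self) -> bool:
        """True when the record starts at hour 0 and spans whole days."""
        return (
            self.timestamps[0].hour == 0 and self.n_hours % HOURS_PER_DAY == 0
        )

    def channel(self, name: str) -> pd.Series:
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}")
        return self.data[name]

    def slice_days(self, start_day: int, n_days: int) -> "StationSeries":
        """Day-aligned sub-series covering ``n_days`` days from ``start_day``."""
        if not self.is_day_aligned():
            raise ValueError("series is not day-aligned")
        lo = start_day * HOURS_PER_DAY
        hi = lo + n_days * HOURS_PER_DAY
        return StationSeries(self.station_id, self.data.iloc[lo:hi].copy())

    def equals(self, other: "StationSeries") -> bool:
        return (
            self.station_id == other.station_id
            and self.data.index.equals(other.data.index)
            and np.array_equal(
                self.data.to_numpy(), other.data.to_numpy(), equal_nan=True
            )
        )
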