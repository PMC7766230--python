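"""Station CSV I/O, gap imputation, chronological splitting, and scaling.

CSV contract
------------
Header ``timestamp,pm25,pm10,co,no2,o3,so2,temp,rh,pressure,wind_speed,wind_dir,precip``,
one row per hour, timestamps as timezone-naive local ISO 8601
(``YYYY-MM-DD HH:00``), empty string for a missing cell, UTF-8,
comma-separated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, NotFittedError
from .station import CHANNELS, HOURS_PER_DAY, StationSeries

CSV_COLUMNS = ["timestamp"] + CHANNELS


# ----------------------------------------------------------------------
# CSV read / write
# ----------------------------------------------------------------------
def write_station_csv(series: StationSeries, path) -> None:
    """Write a station record to the CSV contract (lossless round trip)."""
    df = series.data.copy()
    df.insert(0, "timestamp", df.index.strftime("%Y-%m-%d %H:%M"))
    # shortest-repr floats (pandas default) round-trip binary64 exactly
    df.to_csv(path, index=False, na_rep="")


def read_station_csv(path, station_id: str | None = None) -> StationSeries:
    """Read a station CSV, masking empty cells as missing.

    Raises
    ------
    FormatError
        On a malformed header, duplicated or non-monotone or non-hourly
        timestamps, or unparseable cells — always naming the offending row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc

    if list(df.columns) != CSV_COLUMNS:
        raise FormatError(
            f"{path}: malformed header {list(df.columns)!r}; expected {CSV_COLUMNS!r}"
        )

    try:
        ts = pd.to_datetime(df["timestamp"], format="%Y-%m-%d %H:%M")
    except Exception:
        ts = pd.to_datetime(df["timestamp"], errors="coerce")
        bad = int(ts.isna().idxmax())
        raise FormatError(f"{path}: unparseable timestamp at data row {bad + 1}")

    dup = ts.duplicated()
    if dup.any():
        row = int(dup.idxmax())
        raise FormatError(
            f"{path}: duplicated timestamp {ts.iloc[row]} at data row {row + 1}"
        )
    steps = ts.diff().dropna()
    non_hourly = steps != pd.Timedelta(hours=1)
    if non_hourly.any():
        row = int(non_hourly.idxmax())
        raise FormatError(
            f"{path}: non-hourly step before {ts.iloc[row]} at data row {row + 1}"
        )

    values = {}
    for col in CHANNELS:
        raw = df[col].str.strip()
        # Python's float() is correctly rounded (pandas' fast parser is not),
        # which keeps the write/read cycle bit-exact
        out = np.empty(len(raw))
        for row, cell in enumerate(raw):
            if cell == "":
                out[row] = np.nan
                continue
            try:
                out[row] = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: unparseable value {cell!r} in column {col!r} "
                    f"at data row {row + 1}"
                ) from None
        values[col] = out

    out = pd.DataFrame(values, index=pd.DatetimeIndex(ts))
    return StationSeries(station_id or path.stem, out)


# ----------------------------------------------------------------------
# Imputation
# ----------------------------------------------------------------------
def impute_missing(series: StationSeries, max_gap_hours: int) -> StationSeries:
    """Linearly interpolate interior gaps of length <= ``max_gap_hours``.

    Longer gaps, and gaps touching either end of the record (no anchor on
    one side), remain masked.  Observed values are never altered.
    """
    if max_gap_hours < 0:
        raise ValueError("max_gap_hours must be >= 0")
    df = series.data.copy()
    if max_gap_hours == 0:
        return StationSeries(series.station_id, df)
    for col in df.columns:
        x = df[col].to_numpy(copy=True)
        isna = np.isnan(x)
        if not isna.any():
            continue
        # run-length encode the NaN runs
        change = np.flatnonzero(np.diff(isna.astype(int)))
        starts = np.r_[0, change + 1]
        ends = np.r_[change, len(x) - 1]
        for s, e in zip(starts, ends):
            if not isna[s]:
                continue
            length = e - s + 1
            if length > max_gap_hours or s == 0 or e == len(x) - 1:
                continue
            lo, hi = x[s - 1], x[e + 1]
            t = np.arange(1, length + 1) / (length + 1)
            x[s : e + 1] = lo + t * (hi - lo)
        df[col] = x
    return StationSeries(series.station_id, df)


# ----------------------------------------------------------------------
# Splitting
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SplitSpec:
    """Chronological day-aligned train/validation/test fractions."""

    train_fraction: float = 0.70
    val_fraction: float = 0.15
    test_fraction: float = 0.15

    def __post_init__(self) -> None:
        fracs = (self.train_fraction, self.val_fraction, self.test_fraction)
        if any(f <= 0 for f in fracs):
            raise ValueError("all split fractions must be > 0")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def split_series(series: StationSeries, spec: SplitSpec = SplitSpec()):
    """Partition into contiguous, chronological, day-aligned train/val/test.

    The series must span at least 30 whole days.  The partition is exhaustive
    (concatenating the three pieces reproduces the input) and each boundary is
    placed at midnight.
    """
    if not series.is_day_aligned():
        raise ValueError("series must start at hour 0 and span whole days")
    n_days = series.n_days
    if n_days < 30:
        raise ValueError(f"series spans {n_days} days; >= 30 required")
    n_train = int(round(spec.train_fraction * n_days))
    n_val = int(round(spec.val_fraction * n_days))
    n_train = max(1, min(n_train, n_days - 2))
    n_val = max(1, min(n_val, n_days - n_train - 1))
    n_test = n_days - n_train - n_val
    train = series.slice_days(0, n_train)
    val = series.slice_days(n_train, n_val)
    test = series.slice_days(n_train + n_val, n_test)
    return train, val, test


# ----------------------------------------------------------------------
# Scaling
# ----------------------------------------------------------------------
@dataclass
class Scaler:
    """Per-feature affine scaler, fitted on the training split only.

    ``minmax`` maps the training range to [0, 1]; ``zscore`` standardizes.
    Either way ``inverse(transform(x)) == x`` to 1e-9 for finite x.  Constant
    features get unit scale so the transform stays invertible.
    """

    method: str = "minmax"
    offset_: dict = field(default_factory=dict, repr=False)
    scale_: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.method not in ("minmax", "zscore"):
            raise ValueError(f"unknown scaler method {self.method!r}")

    @property
    def is_fitted(self) -> bool:
        return bool(self.scale_)

    def fit(self, frame: pd.DataFrame) -> "Scaler":
        self.offset_.clear()
        self.scale_.clear()
        for col in frame.columns:
            x = frame[col].to_numpy(dtype=float)
            x = x[np.isfinite(x)]
            if len(x) == 0:
                offset, scale = 0.0, 1.0
            elif self.method == "minmax":
                offset = float(x.min())
                scale = float(x.max() - x.min()) or 1.0
            else:
                offset = float(x.mean())
                scale = float(x.std()) or 1.0
            self.offset_[col] = offset
            self.scale_[col] = scale
        return self

    def _check(self, cols) -> None:
        if not self.is_fitted:
            raise NotFittedError("scaler used before fit()")
        unknown = [c for c in cols if c not in self.scale_]
        if unknown:
            raise KeyError(f"scaler was not fitted on columns {unknown}")

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        self._check(frame.columns)
        out = frame.copy()
        for col in frame.columns:
            out[col] = (frame[col] - self.offset_[col]) / self.scale_[col]
        return out

    def inverse_transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        self._check(frame.columns)
        out = frame.copy()
        for col in frame.columns:
            out[col] = frame[col] * self.scale_[col] + self.offset_[col]
        return out

    def transform_values(self, values: np.ndarray, column: str) -> np.ndarray:
        self._check([column])
        return (np.asarray(values, dtype=float) - self.offset_[column]) / self.scale_[column]

    def inverse_values(self, values: np.ndarray, column: str) -> np.ndarray:
        self._check([column])
        return np.asarray(values, dtype=float) * self.scale_[column] + self.offset_[column]

    def to_dict(self) -> dict:
        return {"method": self.method, "offset": dict(self.offset_), "scale": dict(self.scale_)}

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        s = cls(method=d["method"])
        s.offset_.update(d["offset"])
        s.scale_.update(d["scale"])
        return s
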