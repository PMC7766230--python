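"""Assembly of day-aligned 24-step training windows.

A forecast example for day ``T`` stacks, hour for hour, three lagged daily
sequences into a 24×F input matrix: the air-quality channels of day T−1, the
meteorology of day T−1, and — the distinguishing input of the
periodicity-aware model — the target pollutant of day T−7 (same weekday one
week earlier).  The target is the 24 hourly values of the pollutant on day T.
Any window touching an unresolved gap in a referenced day is dropped whole,
so samples never contain missing entries.

A causality note: taking the forecast day's own pollutant record as an input
would leak the answer, so the air-quality block defaults to day T−1.  Setting
``aq_day_offset = 0`` reproduces the leaky literal variant and exists only
for reproduction studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np

from .errors import NotFittedError
from .io_station import Scaler
from .station import HOURS_PER_DAY, METEOROLOGY, POLLUTANTS, StationSeries

FEATURE_SETS = ("target_only", "pol", "meo", "all")

#: Air-quality channels per feature set.  The base set carries both headline
#: pollutants; "pol" widens it to all six channels.
_AQ_CHANNELS = {
    "target_only": ["pm25", "co"],
    "pol": POLLUTANTS,
    "meo": ["pm25", "co"],
    "all": POLLUTANTS,
}


@dataclass(frozen=True)
class WindowSpec:
    """Shape of one forecasting example.

    ``input_length`` and ``output_length`` are both fixed at 24 hours; day
    offsets are negative (history only) unless leakage is explicitly allowed.
    """

    target_pollutant: str = "pm25"
    feature_set: str = "all"
    include_weekly_channel: bool = True
    aq_day_offset: int = -1
    meo_day_offset: int = -1
    weekly_day_offset: int = -7
    allow_leakage: bool = False
    input_length: int = HOURS_PER_DAY
    output_length: int = HOURS_PER_DAY
    #: require the week-ago day to be in range and gap-free even when the
    #: weekly channel is excluded from the features.  Model-comparison
    #: protocols set this so every variant trains and is scored on exactly
    #: the same forecast days; it never changes x or y.
    require_weekly_history: bool = False

    def __post_init__(self) -> None:
        if self.target_pollutant not in ("pm25", "co"):
            raise ValueError("target_pollutant must be 'pm25' or 'co'")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
        if self.input_length != HOURS_PER_DAY or self.output_length != HOURS_PER_DAY:
            raise ValueError("input_length and output_length are fixed at 24")
        offsets = (self.aq_day_offset, self.meo_day_offset, self.weekly_day_offset)
        if not self.allow_leakage and any(o >= 0 for o in offsets):
            raise ValueError(
                "non-negative day offsets leak the forecast day; "
                "set allow_leakage=True to override"
            )

    def feature_columns(self) -> list:
        """Ordered (channel, day_offset) pairs defining the columns of x."""
        cols = [(c, self.aq_day_offset) for c in _AQ_CHANNELS[self.feature_set]]
        if self.feature_set in ("meo", "all"):
            cols += [(c, self.meo_day_offset) for c in METEOROLOGY]
        if self.include_weekly_channel:
            cols.append((self.target_pollutant, self.weekly_day_offset))
        return cols

    @property
    def n_features(self) -> int:
        return len(self.feature_columns())

    def feature_names(self) -> list:
        return [f"{c}[T{o:+d}]" for c, o in self.feature_columns()]


@dataclass
class SampleWindow:
    """One training example: 24×F scaled inputs and 24 scaled targets."""

    x: np.ndarray  # (24, F)
    y: np.ndarray  # (24,)
    target_date: object  # datetime.date of the forecast day T
    feature_names: List[str] = field(default_factory=list)


def build_samples(
    series: StationSeries, spec: WindowSpec, scaler: Scaler
) -> List[SampleWindow]:
    """Build every gap-free forecasting example from a day-aligned series.

    One candidate per day T with all referenced offset days in range; the
    candidate survives only if day T's target column and every referenced
    (channel, offset-day) block are free of missing values.  All features and
    targets are scaled with the supplied (train-fitted) scaler.
    """
    if not scaler.is_fitted:
        raise NotFittedError("scaler must be fitted before building samples")
    if not series.is_day_aligned():
        raise ValueError("series must be day-aligned (start at hour 0, whole days)")
    n_days = series.n_days
    if n_days < 8:
        raise ValueError(f"series spans {n_days} days; >= 8 required")

    cols = spec.feature_columns()
    names = spec.feature_names()
    offsets = [o for _, o in cols]
    guard_weekly = spec.require_weekly_history and not spec.include_weekly_channel
    if guard_weekly:
        offsets.append(spec.weekly_day_offset)
    min_offset = min(offsets)

    # per-channel (n_days, 24) scaled value tables
    needed = sorted({c for c, _ in cols} | {spec.target_pollutant})
    tables = {
        c: scaler.transform_values(
            series.channel(c).to_numpy(), c
        ).reshape(n_days, HOURS_PER_DAY)
        for c in needed
    }
    dates = series.timestamps[::HOURS_PER_DAY].date

    samples: List[SampleWindow] = []
    first_day = max(0, -min_offset)
    target_tab = tables[spec.target_pollutant]
    for d in range(first_day, n_days):
        y = target_tab[d]
        if not np.isfinite(y).all():
            continue
        rows = [tables[c][d + o] for c, o in cols]
        x = np.stack(rows, axis=1)
        if not np.isfinite(x).all():
            continue
        if guard_weekly and not np.isfinite(
            target_tab[d + spec.weekly_day_offset]
        ).all():
            continue
        samples.append(SampleWindow(x=x, y=y.copy(), target_date=dates[d], feature_names=names))
    return samples
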