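"""Autocorrelation diagnostics and diurnal/weekly profile extraction.

The autocorrelation function used throughout is the classical biased
estimator with a single global mean,

    c_k = (1/T) * sum_{t=1..T-k} (y_t - ybar) (y_{t+k} - ybar),   r_k = c_k / c_0,

whose values are bounded by 1 in magnitude (Cauchy–Schwarz).  A white-noise
95% confidence band of ±1.96/√T accompanies every result; a candidate lag
whose coefficient clears the band is reported as a detected period.  Hourly
pollutant series from traffic-adjacent monitors typically clear the band at
lag 24 (rush-hour cycle); daily means clear it at lag 7 (weekly cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, DegenerateSeriesError
from .station import HOURS_PER_DAY, StationSeries


@dataclass
class ACFResult:
    """Autocorrelation coefficients r_0..r_K with a white-noise band."""

    lags: np.ndarray
    r: np.ndarray
    T: int
    confidence_bound: float
    detected_period: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "lags": self.lags.tolist(),
            "r": self.r.tolist(),
            "T": self.T,
            "confidence_bound": self.confidence_bound,
            "detected_period": self.detected_period,
        }


@dataclass
class DiurnalProfile:
    """24 hour-of-day means of a pollutant, non-missing values only."""

    pollutant: str
    means: np.ndarray  # length 24
    counts: np.ndarray  # length 24

    def argmax_hours(self, n_peaks: int = 2) -> list:
        """Hours of the ``n_peaks`` largest local maxima (circular)."""
        m = self.means
        peaks = [
            h
            for h in range(HOURS_PER_DAY)
            if m[h] >= m[(h - 1) % HOURS_PER_DAY] and m[h] >= m[(h + 1) % HOURS_PER_DAY]
        ]
        peaks.sort(key=lambda h: -m[h])
        return sorted(peaks[:n_peaks])


@dataclass
class WeeklyProfile:
    """7 day-of-week means of the daily averages, Monday first."""

    pollutant: str
    means: np.ndarray  # length 7
    counts: np.ndarray  # length 7


# ----------------------------------------------------------------------
def acf(values, max_lag: int) -> ACFResult:
    """Autocorrelation r_k for k = 0..max_lag (biased 1/T estimator).

    Missing values are removed listwise (the non-missing subsequence is
    concatenated) before computing; imputing would bias the coefficients.

    Raises
    ------
    DegenerateSeriesError
        If the series is constant (zero variance).
    ValueError
        If fewer than ``max_lag + 2`` non-missing values remain.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    y = np.asarray(values, dtype=float).ravel()
    y = y[np.isfinite(y)]
    T = len(y)
    if T < max_lag + 2:
        raise ValueError(f"need >= {max_lag + 2} non-missing values, got {T}")
    d = y - y.mean()
    c0 = float(d @ d) / T
    if c0 == 0:
        raise DegenerateSeriesError("constant series: autocorrelation undefined")
    # full autocovariance via FFT-free correlation; K+1 dot products is fine
    r = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        r[k] = (d[: T - k] @ d[k:]) / T / c0
    return ACFResult(
        lags=np.arange(max_lag + 1),
        r=r,
        T=T,
        confidence_bound=1.96 / np.sqrt(T),
    )


def detect_period(acf_result: ACFResult, candidate_lags: Sequence[int]) -> Optional[int]:
    """Candidate lag with the largest r_k, if it clears the confidence band.

    Returns ``None`` when no candidate's coefficient exceeds 1.96/√T.
    """
    computed = set(int(k) for k in acf_result.lags)
    for k in candidate_lags:
        if k < 2:
            raise ValueError("candidate lags must be >= 2")
        if k not in computed:
            raise ValueError(f"candidate lag {k} outside computed lags")
    best = max(candidate_lags, key=lambda k: acf_result.r[int(k)])
    if acf_result.r[int(best)] > acf_result.confidence_bound:
        return int(best)
    return None


# ----------------------------------------------------------------------
def daily_means(series: StationSeries, pollutant: str) -> pd.Series:
    """Mean over the non-missing hours of each calendar day.

    Days with no observation at all come back as NaN (kept, so day-of-week
    bookkeeping stays calendar-true).
    """
    ch = series.channel(pollutant)
    return ch.groupby(ch.index.date).mean()


def diurnal_profile(series: StationSeries, pollutant: str) -> DiurnalProfile:
    """Hour-of-day means over all non-missing observations."""
    ch = series.channel(pollutant)
    grouped = ch.groupby(ch.index.hour)
    means = np.full(HOURS_PER_DAY, np.nan)
    counts = np.zeros(HOURS_PER_DAY, dtype=int)
    counts_obs = grouped.count()
    means_obs = grouped.mean()
    for h in means_obs.index:
        means[h] = means_obs[h]
        counts[h] = counts_obs[h]
    empty = np.flatnonzero(counts == 0)
    if len(empty):
        raise CoverageError(f"no observations at hour(s) {empty.tolist()}")
    return DiurnalProfile(pollutant, means, counts)


def weekly_profile(series: StationSeries, pollutant: str) -> WeeklyProfile:
    """Day-of-week means of the daily averages (Monday first)."""
    daily = daily_means(series, pollutant).dropna()
    if daily.empty:
        raise CoverageError("no observed days")
    dow = pd.DatetimeIndex(daily.index).dayofweek
    means = np.full(7, np.nan)
    counts = np.zeros(7, dtype=int)
    for d in range(7):
        sel = daily[dow == d]
        counts[d] = len(sel)
        if len(sel):
            means[d] = sel.mean()
    empty = np.flatnonzero(counts == 0)
    if len(empty):
        raise CoverageError(f"no observations on day-of-week {empty.tolist()}")
    return WeeklyProfile(pollutant, means, counts)
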