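"""Forecast evaluation: RMSE, NMSE, Pearson r, and comparison protocols.

Metrics follow the conventions usual in air-quality model evaluation:

    RMSE = sqrt( (1/n) Σ (O_i − P_i)² )            (concentration units)
    NMSE = mean((P_i − O_i)²) / (P̄ · Ō)            (dimensionless, scale-free)
    r    = Pearson product-moment correlation       (dimensionless)

with O the observations and P the predictions.  All metrics are pooled over
every forecast hour of the evaluation period (not averaged per day); a
per-horizon breakdown (1..24 h ahead) is available separately.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateSeriesError, TrainingError
from .io_station import Scaler, SplitSpec, split_series
from .models import TrainConfig, build_variant, evaluate_loss, predict, train
from .station import StationSeries
from .windowing import FEATURE_SETS, WindowSpec, build_samples


def _check_pair(O, P, min_len=1):
    O = np.asarray(O, dtype=float).ravel()
    P = np.asarray(P, dtype=float).ravel()
    if len(O) != len(P):
        raise ValueError(f"length mismatch: {len(O)} observations vs {len(P)} predictions")
    if len(O) < min_len:
        raise ValueError(f"need at least {min_len} pairs")
    if not (np.isfinite(O).all() and np.isfinite(P).all()):
        raise ValueError("non-finite values in metric inputs")
    return O, P


def rmse(O, P) -> float:
    """Root mean square error."""
    O, P = _check_pair(O, P)
    return float(np.sqrt(np.mean((O - P) ** 2)))


def nmse(O, P) -> float:
    """Mean squared error normalized by the product of the two means."""
    O, P = _check_pair(O, P)
    denom = O.mean() * P.mean()
    if denom <= 0:
        raise DegenerateSeriesError(
            "NMSE undefined: product of means must be positive"
        )
    return float(np.mean((P - O) ** 2) / denom)


def pearson_r(O, P) -> float:
    """Pearson product-moment correlation coefficient."""
    O, P = _check_pair(O, P, min_len=2)
    dO = O - O.mean()
    dP = P - P.mean()
    denom = np.sqrt((dO**2).sum() * (dP**2).sum())
    if denom == 0:
        raise DegenerateSeriesError("correlation undefined on a constant vector")
    return float((dO @ dP) / denom)


@dataclass
class MetricsReport:
    """The three pooled metrics over n (observation, prediction) pairs."""

    rmse: float
    nmse: float
    pearson_r: float
    n: int
    pooling: str = "pooled-hours"

    @classmethod
    def from_pairs(cls, O, P) -> "MetricsReport":
        O = np.asarray(O, dtype=float).ravel()
        return cls(rmse=rmse(O, P), nmse=nmse(O, P), pearson_r=pearson_r(O, P), n=len(O))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def horizon_breakdown(O_days: np.ndarray, P_days: np.ndarray) -> pd.DataFrame:
    """Per-lead-hour RMSE over (n_days, 24) observation/prediction arrays."""
    O_days = np.asarray(O_days, dtype=float)
    P_days = np.asarray(P_days, dtype=float)
    if O_days.shape != P_days.shape or O_days.ndim != 2:
        raise ValueError("expected matching (n_days, horizon) arrays")
    rows = [
        {"horizon_h": h + 1, "rmse": rmse(O_days[:, h], P_days[:, h])}
        for h in range(O_days.shape[1])
    ]
    return pd.DataFrame(rows)


# ======================================================================
# protocols
# ======================================================================
@dataclass
class ComparisonTable:
    """Long-format results table: one row per (station, target, model, seed).

    ``failed`` rows carry NaN metrics and the error message, so a requested
    cell is never silently absent.
    """

    frame: pd.DataFrame

    COLUMNS = ["station", "target", "model", "seed", "rmse", "nmse", "r", "n", "error"]

    def median(self) -> pd.DataFrame:
        """Median metrics over seeds per (station, target, model) cell."""
        ok = self.frame[self.frame["error"].isna()]
        return (
            ok.groupby(["station", "target", "model"], sort=False)[["rmse", "nmse", "r"]]
            .median()
            .reset_index()
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ComparisonTable":
        frame = pd.read_csv(path)
        return cls(frame[cls.COLUMNS])


def run_experiment(
    series: StationSeries,
    target: str,
    variant: str,
    cfg: TrainConfig,
    window_spec: Optional[WindowSpec] = None,
    split_spec: SplitSpec = SplitSpec(),
    hidden_size: int = 64,
    scaler_method: str = "minmax",
    seed: int = 0,
) -> tuple:
    """Train one variant once and evaluate on the chronological test split.

    Returns (MetricsReport, trained model, loss history).  The scaler is
    fitted on the training split only; metrics are computed on unscaled
    concentrations pooled over all test-day hours.
    """
    base = window_spec or WindowSpec(target_pollutant=target)
    if base.target_pollutant != target:
        base = dataclasses.replace(base, target_pollutant=target)
    # score every variant on the same forecast days (see WindowSpec)
    base = dataclasses.replace(base, require_weekly_history=True)
    train_s, val_s, test_s = split_series(series, split_spec)
    scaler = Scaler(scaler_method).fit(train_s.data)
    model = build_variant(variant, base, hidden_size=hidden_size, seed=seed)
    spec = model.window_spec

    def _windows(part):
        # splits shorter than the 8-day minimum history yield no windows
        return build_samples(part, spec, scaler) if part.n_days >= 8 else []

    train_w = _windows(train_s)
    val_w = _windows(val_s)
    test_w = _windows(test_s)
    if not test_w:
        raise ValueError("no gap-free test windows")

    history = train(model, train_w, dataclasses.replace(cfg, seed=seed),
                    val_samples=val_w or None)
    obs, pred = [], []
    for w in test_w:
        pred.append(predict(model, w, scaler))
        obs.append(scaler.inverse_values(w.y, target))
    O = np.concatenate(obs)
    P = np.concatenate(pred)
    return MetricsReport.from_pairs(O, P), model, history


def compare_models(
    series: StationSeries,
    targets: Sequence[str] = ("pm25", "co"),
    variants: Sequence[str] = ("seq2seq_weekly", "seq2seq", "bilstm", "lstm"),
    cfg: TrainConfig = TrainConfig(),
    n_seeds: int = 5,
    window_spec: Optional[WindowSpec] = None,
    split_spec: SplitSpec = SplitSpec(),
    hidden_size: int = 64,
) -> ComparisonTable:
    """Model-comparison protocol: every variant, per target, over seeds.

    Per-seed metrics are recorded row by row; a training failure is recorded
    in the row's ``error`` column and the table is still returned.
    """
    if not variants:
        raise ValueError("variants must be non-empty")
    rows = []
    for target in targets:
        for variant in variants:
            for seed in range(n_seeds):
                row = {"station": series.station_id, "target": target,
                       "model": variant, "seed": seed,
                       "rmse": np.nan, "nmse": np.nan, "r": np.nan,
                       "n": 0, "error": None}
                try:
                    report, _, _ = run_experiment(
                        series, target, variant, cfg, window_spec=window_spec,
                        split_spec=split_spec, hidden_size=hidden_size, seed=seed,
                    )
                    row.update(rmse=report.rmse, nmse=report.nmse,
                               r=report.pearson_r, n=report.n)
                except (TrainingError, ValueError) as exc:
                    row["error"] = str(exc)
                rows.append(row)
    return ComparisonTable(pd.DataFrame(rows, columns=ComparisonTable.COLUMNS))


def ablation(
    series: StationSeries,
    target: str = "pm25",
    feature_sets: Sequence[str] = FEATURE_SETS,
    cfg: TrainConfig = TrainConfig(),
    n_seeds: int = 5,
    split_spec: SplitSpec = SplitSpec(),
    hidden_size: int = 64,
) -> ComparisonTable:
    """Input-ablation protocol with the proposed variant fixed.

    Varies the feature set (base pollutant pair, + other pollutants,
    + meteorology, all) and reports per-seed metrics; the ``model`` column
    carries the feature-set name.
    """
    rows = []
    for fs in feature_sets:
        if fs not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {fs!r}")
        spec = WindowSpec(target_pollutant=target, feature_set=fs)
        for seed in range(n_seeds):
            row = {"station": series.station_id, "target": target,
                   "model": fs, "seed": seed,
                   "rmse": np.nan, "nmse": np.nan, "r": np.nan, "n": 0, "error": None}
            try:
                report, _, _ = run_experiment(
                    series, target, "seq2seq_weekly", cfg, window_spec=spec,
                    split_spec=split_spec, hidden_size=hidden_size, seed=seed,
                )
                row.update(rmse=report.rmse, nmse=report.nmse,
                           r=report.pearson_r, n=report.n)
            except (TrainingError, ValueError) as exc:
                row["error"] = str(exc)
            rows.append(row)
    return ComparisonTable(pd.DataFrame(rows, columns=ComparisonTable.COLUMNS))
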