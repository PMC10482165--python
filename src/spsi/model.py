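"""Trait modelling: stratified partitioning, simple linear regression,
and calibration/validation accuracy metrics.

The modelling convention is deliberately plain: the trait (panicle number
per unit area, x10^4/ha) is regressed on one index at a time by ordinary
least squares.  Model skill is reported as

* calibration R^2 - the squared Pearson correlation on the fitting set;
* validation R_V^2 = 1 - SSE / SST about the 1:1 line (Eq. form
  ``1 - sum (y - yhat)^2 / sum (y - ybar)^2``), clamped at 0 when negative
  (a negative value only says the predictor is worse than the mean);
* RMSE = sqrt(mean squared error), in trait units;
* RRMSE = RMSE / ybar * 100, in percent.

``ybar`` is the mean of the measured trait over the samples being
evaluated (the validation set), configurable to the calibration mean.

The module exposes both plain functions (:func:`partition`,
:func:`fit_slr`, :func:`evaluate`) and a statsmodels-style model object
(:class:`TraitSLR` whose ``fit()`` returns :class:`TraitSLRResults` with a
``summary()`` table).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats

__all__ = [
    "PlotRecord",
    "SLRModel",
    "ModelMetrics",
    "records_to_frame",
    "partition",
    "fit_slr",
    "evaluate",
    "r2_matrix",
    "TraitSLR",
    "TraitSLRResults",
]


@dataclass(frozen=True)
class PlotRecord:
    """One plot's identifiers, index values and measured trait."""

    plot_id: str
    dataset_label: str
    date: str
    index_values: Mapping[str, float]
    pnpa: float

    def __post_init__(self) -> None:
        if not (self.pnpa > 0):
            raise ValueError(f"plot {self.plot_id}: trait must be positive")


@dataclass(frozen=True)
class SLRModel:
    """A fitted simple linear regression of trait on one index."""

    slope: float
    intercept: float
    r2_cal: float
    index_name: str = ""
    n_cal: int = 0
    stderr: float = float("nan")
    pvalue: float = float("nan")

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class ModelMetrics:
    """Validation metrics: R_V^2 (clamped >= 0), RMSE, RRMSE (%), n."""

    r2_v: float
    rmse: float
    rrmse: float
    n_val: int
    r2_v_raw: float = float("nan")


def records_to_frame(records: Sequence[PlotRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"plot_id": r.plot_id, "dataset_label": r.dataset_label,
               "date": r.date, "pnpa": r.pnpa}
        row.update(r.index_values)
        rows.append(row)
    return pd.DataFrame(rows)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(list(records))


def partition(records, fraction: float = 2.0 / 3.0, seed: int = 0,
              label_col: str = "dataset_label",
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random split into calibration and validation sets.

    Within each dataset label, ``round-half-up(fraction * n)`` records go to
    calibration and the rest to validation; the draw is deterministic given
    ``seed``.  The two sets are disjoint and their union is the input.
    """
    df = _as_frame(records)
    if df.empty:
        raise ValueError("no records to partition")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    cal_parts, val_parts = [], []
    for label in sorted(df[label_col].unique()):
        stratum = df[df[label_col] == label]
        n = len(stratum)
        if n < 3:
            raise ValueError(f"stratum {label!r} has fewer than 3 records")
        n_cal = int(math.floor(fraction * n + 0.5))
        order = rng.permutation(n)
        cal_parts.append(stratum.iloc[order[:n_cal]])
        val_parts.append(stratum.iloc[order[n_cal:]])
    return (pd.concat(cal_parts).reset_index(drop=True),
            pd.concat(val_parts).reset_index(drop=True))


def fit_slr(x, y, index_name: str = "") -> SLRModel:
    """Ordinary least squares y = a*x + b with calibration R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("fit_slr needs at least 3 finite pairs")
    if np.ptp(x) == 0:
        raise ValueError("fit_slr: predictor is constant")
    res = scipy_stats.linregress(x, y)
    return SLRModel(float(res.slope), float(res.intercept),
                    float(res.rvalue) ** 2, index_name, int(x.size),
                    float(res.stderr), float(res.pvalue))


def evaluate(model: SLRModel, x, y, center: str = "validation") -> ModelMetrics:
    """Apply a fitted model to held-out pairs and score it.

    ``center`` chooses the ybar used in R_V^2 and RRMSE: the mean measured
    trait of the evaluated samples (default) or of the calibration samples
    (pass ``center=ybar_value`` as a float for that).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if y.size == 0:
        raise ValueError("evaluate: no finite validation pairs")
    yhat = model.predict(x)
    sse = float(((y - yhat) ** 2).sum())
    ybar = float(y.mean()) if center == "validation" else float(center)
    sst = float(((y - ybar) ** 2).sum())
    if sst == 0:
        r2_raw = float("nan")
        r2_v = float("nan")
    else:
        r2_raw = 1.0 - sse / sst
        r2_v = max(0.0, r2_raw)
    rmse = math.sqrt(sse / y.size)
    rrmse = rmse / ybar * 100.0
    return ModelMetrics(r2_v, rmse, rrmse, int(y.size), r2_raw)


def r2_matrix(records, indices: Sequence[str],
              group_cols: Sequence[str] = ("dataset_label",),
              trait: str = "pnpa", floor: float = 0.0) -> pd.DataFrame:
    """Calibration R^2 of trait ~ index for every (index, group) cell.

    Cells with fewer than 3 finite pairs or a constant predictor are NaN;
    values below ``floor`` are floored (display convention for heatmaps).
    """
    df = _as_frame(records)
    rows = []
    for key, grp in df.groupby(list(group_cols)):
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(group_cols, key))
        for index in indices:
            x = grp[index].to_numpy(dtype=float)
            y = grp[trait].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.ptp(x[ok]) == 0:
                rec[index] = float("nan")
            else:
                r = float(np.corrcoef(x[ok], y[ok])[0, 1])
                rec[index] = max(floor, r * r)
        rows.append(rec)
    return pd.DataFrame(rows).set_index(list(group_cols))


# ---------------------------------------------------------------------------
# statsmodels-style front end
# ---------------------------------------------------------------------------

class TraitSLR:
    """Simple linear regression model of a trait on one index.

    Examples
    --------
    >>> model = TraitSLR.from_dataframe(df, index="SPSI")
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, x, y, index_name: str = "index",
                 trait_name: str = "pnpa"):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.index_name = index_name
        self.trait_name = trait_name

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, index: str,
                       trait: str = "pnpa") -> "TraitSLR":
        return cls(df[index], df[trait], index, trait)

    def fit(self) -> "TraitSLRResults":
        return TraitSLRResults(self, fit_slr(self.x, self.y, self.index_name))


@dataclass
class TraitSLRResults:
    """Results wrapper carrying the fitted coefficients and diagnostics."""

    model: TraitSLR
    params: SLRModel
    metrics: ModelMetrics | None = field(default=None)

    @property
    def slope(self) -> float:
        return self.params.slope

    @property
    def intercept(self) -> float:
        return self.params.intercept

    @property
    def rsquared(self) -> float:
        return self.params.r2_cal

    @property
    def nobs(self) -> int:
        return self.params.n_cal

    def predict(self, x) -> np.ndarray:
        return self.params.predict(x)

    def evaluate(self, x, y, center: str = "validation") -> ModelMetrics:
        self.metrics = evaluate(self.params, x, y, center)
        return self.metrics

    def equation(self) -> str:
        sign = "+" if self.intercept >= 0 else "-"
        return (f"{self.model.trait_name} = {self.slope:.2f} * "
                f"{self.model.index_name} {sign} {abs(self.intercept):.2f}")

    def summary(self) -> str:
        lines = [
            "Simple linear regression",
            "========================",
            f"trait:      {self.model.trait_name}",
            f"index:      {self.model.index_name}",
            f"n (cal):    {self.nobs}",
            f"equation:   {self.equation()}",
            f"R2 (cal):   {self.rsquared:.3f}",
            f"slope se:   {self.params.stderr:.3f}",
            f"p (slope):  {self.params.pvalue:.3g}",
        ]
        if self.metrics is not None:
            lines += [
                f"R2_V:       {self.metrics.r2_v:.3f}",
                f"RMSE:       {self.metrics.rmse:.2f}",
                f"RRMSE (%):  {self.metrics.rrmse:.2f}",
                f"n (val):    {self.metrics.n_val}",
            ]
        return "\n".join(lines)
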