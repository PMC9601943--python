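"""Regression performance metrics, descriptive statistics, correlations.

The metric set is RMSE, MSE, MAE and the coefficient of determination
R^2 = 1 - SS_res/SS_tot.  Descriptive statistics follow the usual
statistical-software conventions: sample (n-1) standard deviation,
bias-corrected Fisher skewness and excess kurtosis.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MetricSet",
    "DescriptiveStats",
    "compute_metrics",
    "describe",
    "correlations",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (report-table convention)."""
    if x is None or not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricSet:
    mse: float
    rmse: float
    mae: float
    r2: float | None  # None when the actuals have zero variance
    n: int

    @property
    def r2_defined(self) -> bool:
        return self.r2 is not None

    def as_dict(self) -> dict[str, float | None]:
        return {"MSE": self.mse, "RMSE": self.rmse, "MAE": self.mae,
                "R2": self.r2, "N": self.n}


def compute_metrics(actuals, estimates) -> MetricSet:
    """RMSE/MSE/MAE and R^2 of estimates against actuals.

    R^2 = 1 - sum((x_a - x_e)^2) / sum((x_a - mean(x_a))^2); when the
    actuals are constant the ratio is undefined and ``r2`` is None.
    """
    a = np.asarray(actuals, dtype=float)
    e = np.asarray(estimates, dtype=float)
    if a.shape != e.shape:
        raise ValueError("actuals and estimates must have the same length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    resid = a - e
    mse = float(np.mean(resid ** 2))
    rmse = float(np.sqrt(mse))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = None if ss_tot == 0.0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return MetricSet(mse=mse, rmse=rmse, mae=mae, r2=r2, n=n)


@dataclass(frozen=True)
class DescriptiveStats:
    n: int
    mean: float
    se_mean: float
    stdev: float
    variance: float
    coefvar: float | None  # percent; None when the mean is zero
    minimum: float
    median: float
    maximum: float
    skewness: float | None  # None when n < 4 or zero variance
    kurtosis: float | None  # bias-corrected excess kurtosis

    def rounded(self) -> dict[str, float | None]:
        """Report-table form: 3 decimals, coefficient of variation 2."""
        r3 = lambda v: None if v is None else round_half_up(v, 3)
        return {
            "N": self.n,
            "Mean": r3(self.mean), "SE Mean": r3(self.se_mean),
            "StDev": r3(self.stdev), "Variance": r3(self.variance),
            "CoefVar": None if self.coefvar is None else round_half_up(self.coefvar, 2),
            "Minimum": r3(self.minimum), "Median": r3(self.median),
            "Maximum": r3(self.maximum),
            "Skewness": r3(self.skewness), "Kurtosis": r3(self.kurtosis),
        }


def describe(values) -> DescriptiveStats:
    """Column summary in the style of standard statistical software."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    mean = float(x.mean())
    stdev = float(x.std(ddof=1))
    variance = stdev ** 2
    se = stdev / np.sqrt(n)
    coefvar = None if mean == 0 else 100.0 * stdev / mean
    if n >= 4 and stdev > 0:
        skew = float(sps.skew(x, bias=False))
        kurt = float(sps.kurtosis(x, bias=False))
    elif stdev == 0:
        skew = 0.0 if n >= 4 else None
        kurt = None
    else:
        skew = kurt = None
    return DescriptiveStats(
        n=n, mean=mean, se_mean=float(se), stdev=stdev, variance=variance,
        coefvar=0.0 if (mean != 0 and stdev == 0) else coefvar,
        minimum=float(x.min()), median=float(np.median(x)), maximum=float(x.max()),
        skewness=skew, kurtosis=kurt,
    )


def correlations(
    data: pd.DataFrame,
    features: tuple[str, ...] = ("pn", "nn", "bn", "cn", "tn"),
    outputs: tuple[str, ...] = ("pnt", "wt"),
) -> pd.DataFrame:
    """Pearson correlation of each input feature with each output column.

    Returns a frame indexed by feature with one ``R<output>`` column per
    output; a constant column on either side yields NaN for that pair.
    """
    if len(data) < 3:
        raise ValueError("need at least 3 rows")
    out = {}
    for y in outputs:
        yv = data[y].to_numpy(dtype=float)
        col = []
        for f in features:
            xv = data[f].to_numpy(dtype=float)
            mask = ~(np.isnan(xv) | np.isnan(yv))
            if xv[mask].std() == 0 or yv[mask].std() == 0:
                col.append(np.nan)
            else:
                col.append(float(sps.pearsonr(xv[mask], yv[mask])[0]))
        out[f"R{y}"] = col
    return pd.DataFrame(out, index=list(features))
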