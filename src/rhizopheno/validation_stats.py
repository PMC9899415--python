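"""Validation of automated traits against manual annotation.

Automated (CNN-derived) and manually annotated traits both carry
measurement error of similar magnitude, so ordinary least squares —
which assumes an error-free x — attenuates the slope. The appropriate
model-II estimator here is the standardized major axis (often called
reduced major axis): slope = sign(r) * sd(y)/sd(x), which is symmetric
in x and y (swapping the variables inverts the slope). Bias diagnostics
regress the normalized CNN-minus-manual difference on candidate
confounders (time, soil moisture, the manual value itself) and test for
linear trends. A helper correlates a daily trait series against sparse
destructive measurements (e.g. harvested root mass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class ValidationError(ValueError):
    """Raised for degenerate validation inputs."""


@dataclass(frozen=True)
class RMAFit:
    """Standardized-major-axis (model II) regression result."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    trait_name: str = ""

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def rma_fit(manual: np.ndarray, cnn: np.ndarray, trait_name: str = "") -> RMAFit:
    """Fit y (automated) on x (manual) by standardized major axis.

    slope = sign(r) * sd(y) / sd(x); intercept passes through the
    centroid; r_squared is the squared Pearson correlation (identical to
    the SMA determination coefficient).
    """
    x = np.asarray(manual, dtype=float)
    y = np.asarray(cnn, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("manual and cnn must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValidationError(f"need at least 3 pairs for regression, got {n}")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValidationError("degenerate fit: zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    return RMAFit(slope=float(slope), intercept=intercept,
                  r_squared=r * r, n=n, trait_name=trait_name)


def _norm01(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    rng = v.max() - v.min()
    if rng == 0:
        raise ValidationError("cannot normalize a constant vector")
    return (v - v.min()) / rng


def bias_trends(manual: np.ndarray, cnn: np.ndarray,
                covariates: pd.DataFrame) -> pd.DataFrame:
    """Linear trend of the normalized CNN-minus-manual difference per covariate.

    Both trait vectors are scaled 0–1 before differencing so traits on
    different scales are comparable. For each covariate column the
    output row carries the OLS slope of (difference vs covariate), its
    two-sided p-value, and n. Two magnitude diagnostics are appended:
    the trend of the absolute difference against the manual value
    (errors are expected to grow with how much root is in the image) and
    the mean relative difference (cnn - manual)/manual with zero-manual
    pairs excluded (their count reported in ``n_excluded``).
    """
    x = _norm01(manual)
    y = _norm01(cnn)
    diff = y - x
    rows = []
    for name in covariates.columns:
        cov = pd.to_numeric(covariates[name], errors="coerce").to_numpy(dtype=float)
        ok = ~np.isnan(cov) & ~np.isnan(diff)
        if ok.sum() < 3:
            raise ValidationError(f"covariate {name!r}: fewer than 3 usable pairs")
        if np.ptp(cov[ok]) == 0:
            raise ValidationError(f"covariate {name!r} is constant; trend undefined")
        fit = stats.linregress(cov[ok], diff[ok])
        rows.append({"covariate": name, "slope": fit.slope,
                     "p_value": fit.pvalue, "n": int(ok.sum()),
                     "n_excluded": 0, "kind": "difference_trend"})
    # absolute error vs manual magnitude
    fit = stats.linregress(x, np.abs(diff))
    rows.append({"covariate": "manual_value", "slope": fit.slope,
                 "p_value": fit.pvalue, "n": len(x),
                 "n_excluded": 0, "kind": "absolute_difference_trend"})
    manual_arr = np.asarray(manual, dtype=float)
    cnn_arr = np.asarray(cnn, dtype=float)
    nz = manual_arr != 0
    rel = (cnn_arr[nz] - manual_arr[nz]) / manual_arr[nz]
    rows.append({"covariate": "manual_value", "slope": float(rel.mean()) if nz.any() else np.nan,
                 "p_value": np.nan, "n": int(nz.sum()),
                 "n_excluded": int((~nz).sum()), "kind": "mean_relative_difference"})
    return pd.DataFrame(rows)


def series_correlation(daily: pd.DataFrame, points: pd.DataFrame,
                       normalize: bool = True) -> tuple[float, int]:
    """Pearson r between a daily series and a sparse point series.

    ``daily`` is a date-indexed series frame (column ``value``);
    ``points`` has columns ``date`` and ``value`` (e.g. destructive root
    mass on harvest days). Each point is matched to the daily value of
    the same calendar day; unmatched points are dropped. Both sides are
    scaled 0–1 over the matched subset before correlating (the scales
    are physically incommensurate). Returns (r, n_matched).
    """
    for col in ("date", "value"):
        if col not in points.columns:
            raise ValidationError(f"points missing column {col!r}")
    dates = pd.to_datetime(points["date"]).dt.normalize()
    daily_vals = daily["value"]
    matched_a, matched_b = [], []
    for d, v in zip(dates, points["value"]):
        if d in daily_vals.index:
            a = daily_vals.loc[d]
            if not np.isnan(a) and not np.isnan(v):
                matched_a.append(float(a))
                matched_b.append(float(v))
    if len(matched_a) < 3:
        raise ValidationError(
            f"only {len(matched_a)} matched pairs; need at least 3")
    a = np.asarray(matched_a)
    b = np.asarray(matched_b)
    if normalize:
        a = _norm01(a)
        b = _norm01(b)
    r = float(np.corrcoef(a, b)[0, 1])
    return r, len(a)


def export_covariate_table(series: dict[str, pd.DataFrame],
                           covariates: pd.DataFrame | None = None,
                           normalize: bool = True) -> pd.DataFrame:
    """Align daily trait series and covariates into one tidy date-indexed table.

    ``series`` maps column names to daily frames (column ``value``);
    ``covariates`` is an optional date-indexed frame joined as-is. With
    ``normalize`` each trait column is scaled 0–1 over its own extent.
    The result (one row per day on the union of dates) is what a
    downstream smooth-regression model of, e.g., soil CO2 efflux would
    consume; no such model is fitted here.
    """
    if not series:
        raise ValidationError("no series to export")
    cols = {}
    for name, frame in series.items():
        v = frame["value"]
        if normalize:
            rng = v.max() - v.min()
            if rng == 0:
                raise ValidationError(f"series {name!r} is constant")
            v = (v - v.min()) / rng
        cols[name] = v
    out = pd.DataFrame(cols)
    if covariates is not None:
        out = out.join(covariates, how="left")
    out.index.name = "date"
    return out.sort_index()


def ols_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Plain OLS slope and intercept of y on x (for model-comparison use)."""
    fit = stats.linregress(np.asarray(x, float), np.asarray(y, float))
    return float(fit.slope), float(fit.intercept)
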