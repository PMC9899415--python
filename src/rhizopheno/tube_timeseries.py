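"""Per-image trait records to interpretable daily time series.

The steps mirror how repeat minirhizotron imagery is condensed for
phenology: keep only the rotational positions the installation mode
trusts, drop poorly illuminated frames, pool everything within a
calendar day to one mean (so sub-daily sampling cannot bias the
series), linearly interpolate the occasional missing day, apply a
3-day centred rolling mean in common with above-ground phenology
practice, and express growth as the OLS slope of the smoothed series
over a sliding 5-day window. Series can finally be scaled 0–1 for
cross-trait comparison.

Record tables are pandas DataFrames with at least the columns
``instrument, cycle_time, long_idx, rot_idx, n_rot`` plus one column
per trait; daily series are DataFrames indexed by normalized
``DatetimeIndex`` with columns ``value, n_images, gapfilled, smoothed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_RECORD_COLUMNS = ("instrument", "cycle_time", "long_idx", "rot_idx", "n_rot")


class SeriesError(ValueError):
    """Raised for invalid series-engine inputs or configuration."""


@dataclass(frozen=True)
class SeriesConfig:
    """Series-engine settings.

    installation selects which rotational positions are trusted:
    ``horizontal`` tubes keep the 3/8 of positions centred on the tube
    top; ``angled`` (conventional) tubes keep the sides, excluding the
    quarter of positions centred on top and on bottom. Smoothing window
    defaults to 3 days, slope window to 5 days (4–7 give similar
    slopes). Gapfilling defaults off — it belongs to field deployments
    with missing cycles, not to complete greenhouse series.
    """

    installation: str = "angled"
    smooth_window_days: int = 3
    slope_window_days: int = 5
    gapfill: bool = False
    qc_brightness_min: float | None = None

    def __post_init__(self) -> None:
        if self.installation not in ("horizontal", "angled"):
            raise SeriesError(f"unknown installation mode: {self.installation!r}")
        if self.smooth_window_days < 1:
            raise SeriesError("smooth_window_days must be >= 1")
        if self.slope_window_days < 2:
            raise SeriesError("slope_window_days must be >= 2")


def _check_records(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise SeriesError(f"record table missing columns: {missing}")


def rotational_keep_set(installation: str, n_rot: int) -> set[int]:
    """Rotational indices kept under an installation mode.

    Index 0 is the tube top, increasing clockwise viewed from the tube
    entry; index n_rot/2 is the bottom. Horizontal mode keeps the three
    positions centred on top ({n_rot-1, 0, 1}); angled mode drops the
    ceil(n_rot/4) positions centred on top and the same number centred
    on bottom, keeping the sides. For the default n_rot = 8 these give
    3 and 4 survivors respectively.
    """
    if n_rot < 2:
        raise SeriesError("n_rot must be >= 2")
    if installation == "horizontal":
        return {(-1) % n_rot, 0, 1 % n_rot}
    if installation == "angled":
        k = -(-n_rot // 4)  # ceil
        drop = set()
        for centre in (0, n_rot // 2):
            for off in range(-(k // 2), k - k // 2):
                drop.add((centre + off) % n_rot)
        return set(range(n_rot)) - drop
    raise SeriesError(f"unknown installation mode: {installation!r}")


def select_positions(records: pd.DataFrame, installation: str) -> pd.DataFrame:
    """Filter records to the rotational positions trusted for the mode."""
    _check_records(records)
    if records.empty:
        return records.copy()
    n_rots = records["n_rot"].unique()
    if len(n_rots) != 1:
        raise SeriesError(f"records mix n_rot values: {sorted(n_rots)}")
    keep = rotational_keep_set(installation, int(n_rots[0]))
    return records[records["rot_idx"].isin(keep)].copy()


def qc_illumination(records: pd.DataFrame, threshold: float | None) -> pd.DataFrame:
    """Fail QC for frames whose mean brightness is below threshold.

    Frames with no recorded brightness pass by default. A sampling cycle
    whose frames all fail simply leaves that day with fewer (possibly
    zero) contributing images — i.e. a gap for gapfilling.
    """
    _check_records(records)
    out = records.copy()
    if "qc_pass" not in out.columns:
        out["qc_pass"] = True
    if threshold is None or out.empty:
        return out
    if "mean_brightness" in out.columns:
        bright = pd.to_numeric(out["mean_brightness"], errors="coerce")
        out.loc[bright < threshold, "qc_pass"] = False
    return out


def daily_aggregate(records: pd.DataFrame, trait: str) -> pd.DataFrame:
    """One value per calendar day: the mean over all QC-passing images.

    All images of a day are pooled directly (not averaged per cycle
    first), so twice-daily sampling contributes every frame equally.
    Days with no valid images are absent from the output.
    """
    _check_records(records)
    if trait not in records.columns:
        raise SeriesError(f"trait column {trait!r} not in records")
    if records.empty:
        return _empty_series()
    recs = records
    if "qc_pass" in recs.columns:
        recs = recs[recs["qc_pass"].astype(bool)]
    if recs.empty:
        return _empty_series()
    day = pd.to_datetime(recs["cycle_time"]).dt.normalize()
    grouped = recs.groupby(day)[trait].agg(["mean", "count"])
    out = pd.DataFrame(
        {
            "value": grouped["mean"],
            "n_images": grouped["count"].astype(int),
            "gapfilled": False,
            "smoothed": False,
        }
    )
    out.index.name = "date"
    return out.sort_index()


def _empty_series() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "value": pd.Series(dtype=float),
            "n_images": pd.Series(dtype=int),
            "gapfilled": pd.Series(dtype=bool),
            "smoothed": pd.Series(dtype=bool),
        },
        index=pd.DatetimeIndex([], name="date"),
    )


def gapfill_linear(series: pd.DataFrame) -> pd.DataFrame:
    """Fill interior missing days by linear interpolation.

    Only days strictly between the first and last observation are
    filled (no extrapolation). Observed values are never altered.
    Filled points carry ``gapfilled=True`` and ``n_images=0``.
    """
    if len(series) < 2:
        raise SeriesError("gapfill requires at least 2 observed points")
    s = series.sort_index()
    full = pd.date_range(s.index.min(), s.index.max(), freq="D")
    out = s.reindex(full)
    out.index.name = "date"
    missing = out["value"].isna()
    out["value"] = out["value"].interpolate(method="time", limit_area="inside")
    filled = missing & out["value"].notna()
    out.loc[filled, "gapfilled"] = True
    out.loc[filled, "n_images"] = 0
    out.loc[filled, "smoothed"] = False
    out = out[out["value"].notna()]
    out["n_images"] = out["n_images"].astype(int)
    out["gapfilled"] = out["gapfilled"].astype(bool)
    out["smoothed"] = out["smoothed"].astype(bool)
    return out


def rolling_smooth(series: pd.DataFrame, window_days: int = 3) -> pd.DataFrame:
    """Centred rolling mean over ``window_days``; edges use the partial window."""
    if window_days < 1:
        raise SeriesError("window_days must be >= 1")
    out = series.sort_index().copy()
    if out.empty:
        return out
    out["value"] = (
        out["value"].rolling(window=window_days, center=True, min_periods=1).mean()
    )
    out["smoothed"] = True
    return out


def growth_rate(series: pd.DataFrame, window_days: int = 5) -> pd.Series:
    """Per-day OLS slope of value vs day over a centred sliding window.

    Units are trait units per day. Windows truncated at the series edges
    use whatever points are available; fewer than 2 points yields NaN.
    Day spacing is taken from the calendar, so slopes remain correct
    across unfilled gaps.
    """
    if window_days < 2:
        raise SeriesError("window_days must be >= 2")
    s = series.sort_index()
    days = (s.index - s.index.min()) / pd.Timedelta(days=1)
    t = days.to_numpy(dtype=float)
    y = s["value"].to_numpy(dtype=float)
    # centred span of window_days consecutive days; for even windows the
    # extra day sits on the trailing (earlier) side
    lo = -(window_days // 2)
    hi = (window_days - 1) // 2
    slopes = np.full(len(s), np.nan)
    for i, ti in enumerate(t):
        in_win = (t - ti >= lo - 1e-9) & (t - ti <= hi + 1e-9)
        tw, yw = t[in_win], y[in_win]
        ok = ~np.isnan(yw)
        if ok.sum() >= 2 and np.ptp(tw[ok]) > 0:
            slopes[i] = np.polyfit(tw[ok], yw[ok], 1)[0]
    return pd.Series(slopes, index=s.index, name="slope")


def normalize01(series: pd.DataFrame) -> pd.DataFrame:
    """Scale values to [0, 1] over the full series extent."""
    out = series.sort_index().copy()
    vmin = out["value"].min()
    vmax = out["value"].max()
    if not np.isfinite(vmin) or not np.isfinite(vmax) or vmax == vmin:
        raise SeriesError("normalize01 undefined: series range is zero or empty")
    out["value"] = (out["value"] - vmin) / (vmax - vmin)
    return out
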