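"""Canopy greenness (green chromatic coordinate) from repeat RGB imagery.

GCC = G / (R + G + B), computed from the mean digital number per channel
over a fixed region of interest — the standard PhenoCam greenness index.
Computing the ratio of channel means (rather than the mean of per-pixel
ratios) follows PhenoCam practice and suppresses scene-illumination
scaling: multiplying all channels by a constant leaves GCC unchanged.
Daily values keep only images inside a midday local-time window, average
per day, then apply a centred 3-day rolling mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import time

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath

from rhizopheno.tube_timeseries import rolling_smooth


class GCCError(ValueError):
    """Raised for invalid ROI or degenerate (all-black) scenes."""


@dataclass(frozen=True)
class ROI:
    """Closed polygon region of interest in pixel coordinates.

    Vertices are (x, y) with x rightward, y downward, 0-based. A pixel
    belongs to the ROI when its centre falls inside the polygon.
    """

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise GCCError("ROI needs at least 3 vertices")
        if abs(self.signed_area()) <= 0:
            raise GCCError("ROI polygon has zero area")

    def signed_area(self) -> float:
        v = np.asarray(self.vertices, dtype=float)
        x, y = v[:, 0], v[:, 1]
        return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    def pixel_mask(self, height: int, width: int) -> np.ndarray:
        """Boolean raster of pixels whose centres lie inside the polygon."""
        v = np.asarray(self.vertices, dtype=float)
        if (v[:, 0].min() < -0.5 or v[:, 1].min() < -0.5
                or v[:, 0].max() > width - 0.5 or v[:, 1].max() > height - 0.5):
            raise GCCError("ROI vertices fall outside the image bounds")
        path = MplPath(v)
        xs, ys = np.meshgrid(np.arange(width), np.arange(height))
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        return path.contains_points(pts).reshape(height, width)

    @classmethod
    def from_file(cls, path) -> "ROI":
        """Read a vertex list from a text/CSV file with `x,y` per line."""
        verts = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.lower().startswith("x"):
                    continue
                x, y = line.replace("\t", ",").split(",")[:2]
                verts.append((float(x), float(y)))
        return cls(vertices=tuple(verts))


def gcc_of_image(image: np.ndarray, roi: ROI,
                 per_pixel: bool = False) -> dict:
    """GCC of one RGB frame over an ROI.

    Returns a dict with ``mean_r, mean_g, mean_b, gcc, n_pixels``. By
    default gcc is computed from the channel means; ``per_pixel=True``
    instead averages the per-pixel G/(R+G+B) ratio (zero-sum pixels
    excluded), exposed for comparison only.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise GCCError(f"expected an RGB image, got shape {image.shape}")
    h, w = image.shape[:2]
    mask = roi.pixel_mask(h, w)
    if not mask.any():
        raise GCCError("ROI contains no pixel centres")
    px = image[mask][:, :3].astype(float)
    mean_r, mean_g, mean_b = px.mean(axis=0)
    denom = mean_r + mean_g + mean_b
    if denom <= 0:
        raise GCCError("undefined GCC: ROI channel sums are zero (all-black ROI)")
    if per_pixel:
        sums = px.sum(axis=1)
        ok = sums > 0
        if not ok.any():
            raise GCCError("undefined GCC: every ROI pixel is black")
        gcc = float((px[ok, 1] / sums[ok]).mean())
    else:
        gcc = float(mean_g / denom)
    return {
        "mean_r": float(mean_r),
        "mean_g": float(mean_g),
        "mean_b": float(mean_b),
        "gcc": gcc,
        "n_pixels": int(mask.sum()),
    }


def daily_gcc(records: pd.DataFrame,
              window_start: time = time(12, 0),
              window_end: time = time(13, 0),
              smooth_days: int = 3) -> pd.DataFrame:
    """Daily GCC series from timestamped per-image records.

    Keeps records whose local timestamp falls inside
    ``[window_start, window_end]`` (midday, when illumination is most
    stable), averages per calendar day, then applies a centred
    ``smooth_days`` rolling mean. ``records`` needs columns
    ``timestamp`` and ``gcc``.
    """
    for col in ("timestamp", "gcc"):
        if col not in records.columns:
            raise GCCError(f"records missing column {col!r}")
    if records.empty:
        return _empty()
    ts = pd.to_datetime(records["timestamp"])
    tod = ts.dt.time
    in_window = (tod >= window_start) & (tod <= window_end)
    kept = records[in_window]
    if kept.empty:
        return _empty()
    day = pd.to_datetime(kept["timestamp"]).dt.normalize()
    grouped = kept.groupby(day)["gcc"].agg(["mean", "count"])
    series = pd.DataFrame(
        {
            "value": grouped["mean"],
            "n_images": grouped["count"].astype(int),
            "gapfilled": False,
            "smoothed": False,
        }
    )
    series.index.name = "date"
    return rolling_smooth(series.sort_index(), window_days=smooth_days)


def _empty() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "value": pd.Series(dtype=float),
            "n_images": pd.Series(dtype=int),
            "gapfilled": pd.Series(dtype=bool),
            "smoothed": pd.Series(dtype=bool),
        },
        index=pd.DatetimeIndex([], name="date"),
    )
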