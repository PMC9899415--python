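import numpy as np
import pandas as pd
import pytest

from rhizopheno.mask_traits import BinaryMask, PixelGeometry


@pytest.fixture
def geometry():
    return PixelGeometry(pixel_size_mm=0.025, width_px=800, height_px=600)


@pytest.fixture
def empty_mask(geometry):
    return BinaryMask(grid=np.zeros((600, 800), bool), geometry=geometry)


def mask_with_blobs(geometry, blobs):
    """Mask with axis-aligned rectangular blobs: (row, col, h, w) tuples."""
    grid = np.zeros((geometry.height_px, geometry.width_px), bool)
    for r, c, h, w in blobs:
        grid[r:r + h, c:c + w] = True
    return BinaryMask(grid=grid, geometry=geometry)


def daily_frame(values, start="2021-03-01", n_images=1):
    idx = pd.date_range(start, periods=len(values), freq="D", name="date")
    vals = np.asarray(values, dtype=float)
    return pd.DataFrame(
        {"value": vals, "n_images": n_images, "gapfilled": False, "smoothed": False},
        index=idx,
    )


def cycle_records(day_values, start="2021-03-01", rot_idx=0, n_rot=8):
    """One record per (day, value) pair at noon of each day."""
    rows = []
    start = pd.Timestamp(start)
    for d, vals in enumerate(day_values):
        if np.isscalar(vals):
            vals = [vals]
        for i, v in enumerate(vals):
            rows.append({
                "instrument": "T0",
                "cycle_time": start + pd.Timedelta(days=d, hours=10 + i),
                "long_idx": 0,
                "rot_idx": rot_idx,
                "n_rot": n_rot,
                "value": float(v),
                "qc_pass": True,
            })
    return pd.DataFrame(rows, columns=["instrument", "cycle_time", "long_idx",
                                       "rot_idx", "n_rot", "value", "qc_pass"])
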