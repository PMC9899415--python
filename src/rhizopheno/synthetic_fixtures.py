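"""Synthetic fixtures with analytic ground truth.

Three generators emulate the statistical structure of a minirhizotron
deployment so the whole pipeline can be exercised without field data:

* root *phantoms* — binary masks containing smooth curvilinear strokes
  of known centreline length and drawn pixel area, plus sub-threshold
  speckle noise that the area filter must remove. Speckles are placed so
  they never touch a root or each other, which makes the post-filter
  sRSA exactly 100 * drawn_root_area / frame_area.
* logistic *growth series* — trait trajectories S(t) = K / (1 + exp(-r(t-t0)))
  observed per sampling cycle with multiplicative noise, optional
  transient watering-event artefacts, and randomly missing cycles.
* constant-channel *canopy scenes* — RGB rasters with known analytic GCC.

All randomness flows through one ``numpy.random.Generator`` derived from
an explicit seed; no global RNG state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate
from skimage import draw as skdraw
from skimage import morphology

from rhizopheno.mask_traits import BinaryMask, PixelGeometry


class GenerationError(RuntimeError):
    """Raised when a requested scene cannot be constructed."""


@dataclass(frozen=True)
class PhantomParams:
    """Phantom-scene parameters.

    Frames default to 800 x 600 px at 25 um per pixel, a scale at which
    the default 0.5 mm^2 noise threshold equals 800 px. Root widths are
    odd (strokes are a 1-px polyline dilated by a disk) and at least
    3 px so thinning is meaningful; every root component is guaranteed
    to exceed the noise threshold and every speckle to sit strictly
    below it.
    """

    n_roots: int = 3
    width_px: int = 7
    n_control_points: int = 8
    step_px: float = 60.0
    n_speckles: int = 20
    speckle_area_range_px: tuple[int, int] = (4, 60)
    width_px_image: int = 800
    height_px_image: int = 600
    pixel_size_mm: float = 0.025
    min_area_mm2: float = 0.5

    def __post_init__(self) -> None:
        if self.n_roots < 0 or self.n_speckles < 0:
            raise GenerationError("counts must be non-negative")
        if self.n_roots and (self.width_px < 3 or self.width_px % 2 == 0):
            raise GenerationError("root width must be an odd integer >= 3")
        lo, hi = self.speckle_area_range_px
        thresh = self.min_area_mm2 / self.pixel_size_mm ** 2
        if hi >= thresh:
            raise GenerationError(
                f"speckle areas up to {hi} px reach the noise threshold ({thresh:.0f} px)")

    @property
    def geometry(self) -> PixelGeometry:
        return PixelGeometry(pixel_size_mm=self.pixel_size_mm,
                             width_px=self.width_px_image,
                             height_px=self.height_px_image)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth for one phantom scene."""

    seed: int
    n_roots: int
    roots: tuple[dict, ...]  # per root: control_points, width_px, arc_length_mm
    total_true_length_mm: float
    total_drawn_area_px: int
    n_noise_speckles: int
    speckle_area_range_px: tuple[int, int]

    def expected_srsa(self, geometry: PixelGeometry) -> float:
        """Analytic post-filter sRSA: speckles removed, every root kept."""
        return 100.0 * self.total_drawn_area_px / (geometry.width_px * geometry.height_px)


def _random_polyline(rng: np.random.Generator, p: PhantomParams) -> np.ndarray:
    """Smooth random polyline (spline through a persistent random walk)."""
    margin = p.width_px + 4
    h, w = p.height_px_image, p.width_px_image
    pos = np.array([rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)])
    heading = rng.uniform(0, 2 * math.pi)
    pts = [pos.copy()]
    for _ in range(p.n_control_points - 1):
        heading += rng.normal(0, 0.45)
        step = np.array([math.sin(heading), math.cos(heading)]) * p.step_px
        nxt = pos + step
        # reflect off frame margins so roots stay drawable
        for ax, lim in ((0, h), (1, w)):
            if nxt[ax] < margin or nxt[ax] > lim - margin:
                step[ax] = -step[ax]
                heading = math.atan2(step[1], step[0]) if ax == 0 else heading
                nxt = pos + step
        nxt = np.clip(nxt, margin, [h - margin, w - margin])
        pos = nxt
        pts.append(pos.copy())
    ctrl = np.asarray(pts)
    # cubic spline through control points, densely sampled (~2 samples/px)
    tck, _ = interpolate.splprep([ctrl[:, 0], ctrl[:, 1]], s=0,
                                 k=min(3, len(ctrl) - 1))
    n_dense = int(p.step_px * p.n_control_points * 2)
    rr, cc = interpolate.splev(np.linspace(0, 1, n_dense), tck)
    # spline may overshoot the control-point margin; clamp so the dilated
    # stroke stays inside the frame (truth length uses the clamped path)
    rr = np.clip(rr, p.width_px, h - 1 - p.width_px)
    cc = np.clip(cc, p.width_px, w - 1 - p.width_px)
    return np.column_stack([rr, cc])


def _draw_stroke(grid: np.ndarray, path: np.ndarray, width_px: int) -> None:
    """Rasterize a polyline as a constant-width stroke (round caps/joins)."""
    line = np.zeros_like(grid)
    ipts = np.round(path).astype(int)
    for (r0, c0), (r1, c1) in zip(ipts[:-1], ipts[1:]):
        rr, cc = skdraw.line(r0, c0, r1, c1)
        line[rr, cc] = True
    radius = (width_px - 1) // 2
    if radius > 0:
        line = morphology.dilation(line, morphology.disk(radius))
    grid |= line


def _arc_length_mm(path: np.ndarray, pixel_size_mm: float) -> float:
    seg = np.diff(path, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum() * pixel_size_mm)


def _place_speckles(grid: np.ndarray, rng: np.random.Generator,
                    p: PhantomParams) -> int:
    """Add isolated sub-threshold speckles; returns the number placed.

    Each speckle is a filled rectangle whose padded bounding box is
    checked against everything already drawn, so speckles never touch a
    root or another speckle under 8-connectivity.
    """
    h, w = grid.shape
    placed = 0
    lo, hi = p.speckle_area_range_px
    attempts = 0
    while placed < p.n_speckles and attempts < p.n_speckles * 200:
        attempts += 1
        area = int(rng.integers(lo, hi + 1))
        sh = int(rng.integers(1, int(math.sqrt(area)) + 1))
        sw = max(1, area // sh)
        r = int(rng.integers(1, h - sh - 1))
        c = int(rng.integers(1, w - sw - 1))
        if grid[r - 1:r + sh + 1, c - 1:c + sw + 1].any():
            continue
        grid[r:r + sh, c:c + sw] = True
        placed += 1
    if placed < p.n_speckles:
        raise GenerationError(
            f"could only place {placed}/{p.n_speckles} speckles without contact")
    return placed


def make_phantom(params: PhantomParams | None = None,
                 seed: int = 0) -> tuple[BinaryMask, PhantomTruth]:
    """Generate a root phantom mask and its ground truth.

    Deterministic per (params, seed). Raises :class:`GenerationError`
    if a root component ends up below the noise threshold (it would be
    filtered as noise, breaking the truth table).
    """
    p = params or PhantomParams()
    rng = np.random.default_rng(seed)
    grid = np.zeros((p.height_px_image, p.width_px_image), dtype=bool)
    roots = []
    for _ in range(p.n_roots):
        path = _random_polyline(rng, p)
        _draw_stroke(grid, path, p.width_px)
        roots.append({
            "control_points": path[:: max(1, len(path) // p.n_control_points)].tolist(),
            "width_px": p.width_px,
            "arc_length_mm": _arc_length_mm(path, p.pixel_size_mm),
        })
    drawn_area = int(grid.sum())
    thresh_px = p.min_area_mm2 / p.pixel_size_mm ** 2
    if p.n_roots:
        from skimage import measure
        lbl = measure.label(grid, connectivity=2)
        areas = np.bincount(lbl.ravel())[1:]
        if (areas < thresh_px).any():
            raise GenerationError(
                "a root component fell below the noise threshold; "
                "increase width or length")
    n_speckles = _place_speckles(grid, rng, p) if p.n_speckles else 0
    truth = PhantomTruth(
        seed=seed,
        n_roots=p.n_roots,
        roots=tuple(roots),
        total_true_length_mm=float(sum(r["arc_length_mm"] for r in roots)),
        total_drawn_area_px=drawn_area,
        n_noise_speckles=n_speckles,
        speckle_area_range_px=p.speckle_area_range_px,
    )
    return BinaryMask(grid=grid, geometry=p.geometry), truth


def make_bar_phantom(length_px: int = 400, width_px: int = 8,
                     pixel_size_mm: float = 0.025,
                     image_shape: tuple[int, int] = (600, 800),
                     n_speckles: int = 0, seed: int = 0,
                     speckle_area_range_px: tuple[int, int] = (4, 60),
                     ) -> tuple[BinaryMask, PhantomTruth]:
    """Axis-aligned bar phantom with exact area/length truth.

    The bar is a ``width_px x length_px`` rectangle centred in the
    frame: drawn area = length * width exactly, true length =
    length_px * pixel_size_mm.
    """
    h, w = image_shape
    if length_px > w - 4 or width_px > h - 4:
        raise GenerationError("bar does not fit the frame")
    grid = np.zeros((h, w), dtype=bool)
    r0 = h // 2 - width_px // 2
    c0 = (w - length_px) // 2
    grid[r0:r0 + width_px, c0:c0 + length_px] = True
    if n_speckles:
        p = PhantomParams(n_roots=0, n_speckles=n_speckles,
                          width_px_image=w, height_px_image=h,
                          pixel_size_mm=pixel_size_mm,
                          speckle_area_range_px=speckle_area_range_px)
        _place_speckles(grid, np.random.default_rng(seed), p)
    truth = PhantomTruth(
        seed=seed, n_roots=1,
        roots=({"control_points": [[r0 + width_px / 2, c0],
                                   [r0 + width_px / 2, c0 + length_px]],
                "width_px": width_px,
                "arc_length_mm": length_px * pixel_size_mm},),
        total_true_length_mm=length_px * pixel_size_mm,
        total_drawn_area_px=length_px * width_px,
        n_noise_speckles=n_speckles,
        speckle_area_range_px=speckle_area_range_px,
    )
    geom = PixelGeometry(pixel_size_mm=pixel_size_mm, width_px=w, height_px=h)
    return BinaryMask(grid=grid, geometry=geom), truth


def make_diagonal_phantom(n_px: int = 1000, pixel_size_mm: float = 0.025,
                          margin: int = 10) -> tuple[BinaryMask, PhantomTruth]:
    """One-pixel 45-degree chain; Euclidean truth length is n * sqrt(2) * px.

    The uncorrected pixel-count length of this chain is n * px, i.e.
    1/sqrt(2) of the Euclidean truth — the documented behaviour of
    diagonal-step counting.
    """
    side = n_px + 2 * margin
    grid = np.zeros((side, side), dtype=bool)
    idx = np.arange(n_px) + margin
    grid[idx, idx] = True
    truth = PhantomTruth(
        seed=0, n_roots=1,
        roots=({"control_points": [[margin, margin],
                                   [margin + n_px - 1, margin + n_px - 1]],
                "width_px": 1,
                "arc_length_mm": n_px * math.sqrt(2.0) * pixel_size_mm},),
        total_true_length_mm=n_px * math.sqrt(2.0) * pixel_size_mm,
        total_drawn_area_px=n_px,
        n_noise_speckles=0,
        speckle_area_range_px=(0, 0),
    )
    geom = PixelGeometry(pixel_size_mm=pixel_size_mm, width_px=side, height_px=side)
    return BinaryMask(grid=grid, geometry=geom), truth


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth-trajectory parameters.

    K is the trait asymptote (default 4.0, a realistic late-season sRSA
    percentage), r the logistic rate per day, t0 the inflection day.
    Observation noise is multiplicative with sd ``obs_noise_sd`` (5%
    default, matching the relative scatter of repeat segmentations).
    Watering-event artefacts are additive transients on ``event_days``
    that decay linearly over 2 days; the paperless magnitude default of
    0 keeps the clean trajectory unless events are requested. Cycles are
    sampled ``cycles_per_day`` times daily and dropped independently
    with ``missing_cycle_prob``.
    """

    K: float = 4.0
    r: float = 0.2
    t0: float = 30.0
    duration_days: int = 60
    obs_noise_sd: float = 0.05
    event_days: tuple[float, ...] = ()
    event_magnitude: float = 0.0
    event_decay_days: float = 2.0
    missing_cycle_prob: float = 0.0
    cycles_per_day: int = 2
    start_date: str = "2021-03-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K <= 0 or self.r <= 0:
            raise GenerationError("K and r must be > 0")
        if not 0 <= self.missing_cycle_prob < 1:
            raise GenerationError("missing_cycle_prob must be in [0, 1)")

    def truth(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.K / (1.0 + np.exp(-self.r * (t - self.t0)))


def make_growth_series(gp: GrowthParams | None = None,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a logistic trait trajectory and its noisy per-cycle record.

    Returns ``(truth, records)``: ``truth`` is a date-indexed daily frame
    with the noiseless trait value; ``records`` has one row per surviving
    sampling cycle with columns ``instrument, cycle_time, long_idx,
    rot_idx, n_rot, value, qc_pass`` ready for
    :func:`rhizopheno.tube_timeseries.daily_aggregate`.
    """
    gp = gp or GrowthParams()
    rng = np.random.default_rng(gp.seed)
    days = np.arange(gp.duration_days + 1)
    start = pd.Timestamp(gp.start_date)
    truth = pd.DataFrame(
        {"value": gp.truth(days)},
        index=pd.DatetimeIndex([start + pd.Timedelta(days=int(d)) for d in days],
                               name="date"),
    )
    cycle_hours = np.linspace(6, 18, gp.cycles_per_day) if gp.cycles_per_day > 1 else [12.0]
    rows = []
    for d in days:
        for hour in cycle_hours:
            if rng.random() < gp.missing_cycle_prob:
                continue
            t = float(d) + hour / 24.0
            value = float(gp.truth(t)) * (1.0 + rng.normal(0.0, gp.obs_noise_sd))
            for ed in gp.event_days:
                dt = t - ed
                if 0 <= dt <= gp.event_decay_days:
                    value += gp.event_magnitude * (1.0 - dt / gp.event_decay_days)
            rows.append({
                "instrument": "SIM0",
                "cycle_time": start + pd.Timedelta(days=int(d))
                + pd.Timedelta(hours=float(hour)),
                "long_idx": 0,
                "rot_idx": 0,
                "n_rot": 8,
                "value": max(value, 0.0),
                "qc_pass": True,
            })
    records = pd.DataFrame(rows, columns=["instrument", "cycle_time", "long_idx",
                                          "rot_idx", "n_rot", "value", "qc_pass"])
    return truth, records


def make_canopy(shape: tuple[int, int] = (100, 100),
                channel_means: tuple[float, float, float] = (80.0, 120.0, 60.0),
                noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Constant-channel RGB scene with analytic GCC = g / (r + g + b).

    Optional zero-mean Gaussian per-pixel noise of the stated sd is
    added independently per channel (values floored at 0). Returned as
    float64 so noise is not quantized; round and cast for file output.
    """
    h, w = shape
    img = np.empty((h, w, 3), dtype=float)
    for ch, mean in enumerate(channel_means):
        img[..., ch] = mean
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, noise_sd, size=img.shape)
        np.clip(img, 0.0, None, out=img)
    return img
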