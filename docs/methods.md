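# Methods

## Trait extraction from binary masks

A frame is a boolean raster tied to a `PixelGeometry` (pixel side length in
mm; frame dimensions). Defaults are 0.025 mm px⁻¹ and 2292 × 1944 px
(~1000 dpi root-window imaging). Where a published physical field of view
disagrees with pixel size × pixel count, the pixel size is treated as
authoritative; both are configurable.

**Noise filter.** Connected components of the foreground with physical
area strictly below `min_area_mm2` (default 0.5 mm², i.e. exactly 800 px at
25 µm pixels) are removed; a component exactly at the threshold is kept.
The comparison is `area_px · pixel_size² ≥ threshold` in exact floating
arithmetic — no integer rounding of the pixel threshold. Connectivity
defaults to 8 because fine roots trace thin diagonal paths that
4-connectivity fragments into sub-threshold pieces; it is configurable.
Filtering runs **before** skeletonization so speckle cannot seed skeleton
segments.

**sRSA.** 100 · foreground px / frame px, on the filtered mask.

**Skeleton and length.** The filtered foreground is thinned with the
Zhang–Suen algorithm (`skimage.morphology.skeletonize, method="zhang"`),
pinned so lengths are reproducible; alternative thinning schemes move
skeleton pixel counts by roughly 1–3%. Length is skeleton pixel count ×
pixel size, with **no** √2 weighting of diagonal steps and no branch
pruning: a 45° chain therefore reads 1/√2 ≈ 0.707 of its Euclidean length,
and curved-root phantoms recover 0.83–0.92 of true centreline length
(end-of-stroke erosion plus diagonal undercounting). An optional corrected
estimator weights each orthogonal 8-neighbour link 1 and each diagonal link
√2 (isolated pixels count 1); it is off by default and labelled a deviation
from the plain pixel-count definition. RLD = length / imaged area; the
identity RLD · area = length holds exactly.

Masks are read from PNG/JPEG with any nonzero value as foreground.

## Daily series engine

Rotational positions are indexed 0 at the tube top, increasing clockwise
viewed from the tube entry; a full cycle is `long_count × n_rot` images
(14 × 8 = 112 by default; n_rot is configurable). *Horizontal* installs
trust the tube top: keep {n_rot−1, 0, 1} (3/8 of a cycle, 42 of 112
images). *Angled* (conventional) installs trust the sides: drop the
⌈n_rot/4⌉ positions centred on the top and on the bottom, with the
even-count centring convention `{c − k//2, …, c + (k−1)//2} mod n_rot`,
so for n_rot = 8 the drop set is {7, 0} ∪ {3, 4} and the side positions
{1, 2, 5, 6} survive (56 of 112).

Illumination QC fails frames whose mean grey value is below a configurable
threshold (no default — the appropriate digital-number cutoff is
instrument-specific); frames without brightness pass. A day whose frames
all fail simply becomes a gap.

Daily aggregation pools **all** of a day's valid images into one arithmetic
mean (not a mean of per-cycle means), so twice-daily sampling weights every
frame equally and sub-daily artefacts cannot bias the series. Gapfilling
(linear interpolation in time, interior days only, no extrapolation) is a
config switch, default **off**: it belongs to field deployments with
occasional missing cycles; complete greenhouse series are analysed
unfilled. Observed values are never altered; filled points are flagged with
`n_images = 0`.

Smoothing is a centred 3-day rolling mean, edges using the available
partial window. Growth rate is the OLS slope of the smoothed series over a
centred 5-day window (4–7 give similar slope series); the window is a span
of exactly `w` consecutive calendar days, even windows placing the extra
day on the trailing side, truncated windows at the series edges needing at
least 2 points. Slopes are computed against calendar-day offsets, so they
remain correct across unfilled gaps. Normalization is (x−min)/(max−min)
over the full series extent and is refused for constant series; growth
rates of a normalized series equal raw rates divided by the range.

## Canopy greenness

GCC = Ḡ/(R̄+Ḡ+B̄) from the mean digital number per channel over ROI
pixels (pixels whose centres fall inside the ROI polygon), not the mean of
per-pixel ratios — the standard PhenoCam convention (the per-pixel variant
exists behind a flag). Channel means make GCC exactly invariant to scaling
all channels by a positive constant, the property that motivates its use as
an illumination-robust greenness index. 8- and 16-bit inputs are used
as-is; no gamma handling, no fish-eye distortion correction. Daily values
keep images in a local midday window (12:00–13:00 inclusive by default,
when artificial light and watering are excluded), average per day, and
apply the same 3-day centred mean as the root series.

## Validation statistics

"Reduced major axis" is implemented as the **standardized major axis**
(geometric-mean) estimator, the common meaning of the term:
slope = sign(r)·sd(y)/sd(x) through the centroid, r² the squared Pearson
correlation (identical to the SMA determination coefficient). The SMA slope
is symmetric (swapping x and y inverts it) and, unlike OLS, carries no
attenuation bias under symmetric error in both variables — verified by
simulation (mean bias < 2% at n = 100 where OLS attenuates by ~10% at
noise sd 0.1 on a unit-range latent variable). Degenerate inputs (n < 3,
zero variance) are rejected.

Bias diagnostics scale both trait vectors 0–1, difference them, and fit
OLS trends (two-sided t-test p-values via `scipy.stats.linregress`) against
each covariate; no multiple-testing correction is applied across
covariates. Two magnitude diagnostics are appended: the trend of the
absolute difference against the manual value, and the mean relative
difference (cnn−manual)/manual with zero-manual pairs excluded and
counted. Zero-manual pairs are retained for the RMA fit itself (they anchor
the intercept). Series-vs-biomass correlation joins sparse points to daily
values on the same calendar day, scales both matched sides 0–1, and
requires ≥ 3 matches.

## Synthetic fixtures

**Phantoms** draw each root as a cubic spline through a persistent random
walk, rasterized as a 1-px polyline dilated by a disk (odd widths ≥ 3 px,
default 7), with the spline clamped to the frame margin; the truth table
records the analytic centreline arc length (mm) and the drawn pixel area
counted from the root-only raster. Speckles are small rectangles with areas
drawn from 4–60 px — strictly below the 800-px noise threshold — placed
only where a 1-px-padded bounding box is empty, so no speckle ever touches
a root or another speckle under 8-connectivity. Post-filter sRSA therefore
equals the drawn-root fraction exactly, for every seed. Generation fails
loudly if a root component would fall below the noise threshold.
Axis-aligned bar and 45°-diagonal constructors provide exact length/area
oracles. Phantoms do not model root tapering (no diameter traits are
extracted), soil texture, or CNN segmentation errors beyond speckle.

**Growth series** follow S(t) = K/(1+exp(−r(t−t0))) with defaults K = 4
(a realistic late-season sRSA percentage), r = 0.2 day⁻¹, t0 = 30 d over a
60-day trial sampled 2 cycles/day. Observations are S(t)·(1+ε),
ε ~ N(0, 0.05) — 5% multiplicative noise, the upper end of the relative
scatter repeat segmentation shows. Optional watering-event artefacts are
additive transients decaying linearly over 2 days (off by default; no
quantitative magnitude is established for them, so any value is
illustrative), and cycles can be dropped independently with a configurable
probability (default 0).

At these defaults the day of maximum 5-day slope localizes the inflection
with a **mean** absolute error of ~1.6 days over 20 seeds, but individual
seeds can miss by 3–6 days: the logistic derivative's curvature at its
peak (K r³/8 ≈ 0.004 trait units day⁻³) is smaller than the noise sd of
the smoothed slope (~0.013), so single-seed argmax localization to ±2 days
is not statistically achievable at 5% noise — the package asserts the
across-seed mean instead. Likewise slope series for 4–7-day windows agree
with mean pairwise r > 0.95 across seeds, while a single seed's 4-vs-7-day
pair can dip just below. Passing these checks shows the engine recovers
logistic phenology under the stated noise; it says nothing about
segmentation quality on real imagery, root-diameter effects, or
depth-stratified dynamics, none of which the generator models.

**Canopy scenes** are constant-channel RGB rasters (float64, optional
seeded Gaussian pixel noise) with analytic GCC = g/(r+g+b).

## Orchestration

Images are bound to keys by a manifest CSV (`instrument, cycle_utc,
long_idx, rot_idx, file`; duplicates and dangling paths rejected with
offenders named) or the filename convention
`INSTR_YYYYmmddTHHMM_Lxx_Ryy.png` — an artifact convention, since
instrument log formats are deployment-specific. The pipeline writes
per-image traits CSV, a tidy daily CSV and a JSON run log (config hash,
stage counts satisfying images_in = kept + dropped-by-selection +
dropped-by-qc); reruns with the same config are byte-identical.
Configuration round-trips through YAML. Exit codes: 0 ok, 1 usage, 2 data
error.

The test battery and the acceptance script use desk-scale problem sizes —
800 × 600 px phantoms (50-µm pixels for the tiny simulated deployments, so
the 0.5 mm² threshold stays meaningful at 200 px), 20–30 phantom seeds,
20 growth seeds, 500-replicate calibration studies — chosen to exercise
every code path at full fidelity while keeping a complete run fast on one
CPU.

## Known limitations

- Length is a skeleton pixel count: systematically low on diagonal or
  curved roots (bounded below by 1/√2), by design faithful to the simple
  high-throughput definition rather than to Euclidean geometry.
- No per-root tracking, diameters, branching angles, depth profiles or
  sub-daily dynamics.
- The GAM-ready covariate export is a tidy CSV; the efflux model itself is
  out of scope.
- Illumination QC is a plain brightness threshold; it will not catch
  partially lit or blurred frames.
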