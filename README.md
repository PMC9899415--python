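# rhizopheno

Post-processing for automated minirhizotron root imaging: turn the binary
segmentation masks a CNN (e.g. RootPainter) produces into per-image root
traits and quality-controlled daily root-phenology time series, pair the
below-ground series with PhenoCam-style canopy greenness, and validate the
automated traits against manual annotation with model-II regression.

It is written for people who run repeat root imaging — greenhouse mesocosms
or field tubes sampled daily or sub-daily — and need interpretable daily
series and growth rates out of tens of thousands of segmented frames.

## What it computes

For each binary mask (geometry: 25 µm px⁻¹, 2292 × 1944 px by default,
both configurable):

- **noise filter** — connected foreground components with area < 0.5 mm²
  are treated as segmentation speckle and removed (8-connectivity default);
- **sRSA** (segmented root surface area) — surviving foreground pixels as a
  percentage of the frame;
- **root length** — the foreground is thinned to a one-pixel skeleton
  (Zhang–Suen) and length is the skeleton pixel count × pixel size. Diagonal
  steps are deliberately counted as one pixel (no √2 correction) and
  branches are not pruned; a corrected estimator exists behind a flag;
- **RLD** (root length density) = root length / imaged area (mm mm⁻²).

Per-image traits become daily series by: keeping the trusted rotational
positions (horizontal tubes: the 3/8 of positions centred on the tube top;
angled tubes: the sides, excluding the top and bottom quarters), dropping
poorly illuminated frames, pooling all of a day's valid images into one
mean, linearly interpolating interior missing days (field deployments),
applying a centred 3-day rolling mean, and taking the OLS slope of the
smoothed series over a sliding 5-day window as the **growth rate**. Series
can be scaled 0–1 for cross-trait comparison.

Canopy greenness uses the **green chromatic coordinate**,
GCC = Ḡ/(R̄+Ḡ+B̄) from mean digital numbers over a fixed ROI, midday
images only, 3-day averaged — invariant to scene-illumination scaling.

Validation uses **reduced (standardized) major axis regression** of
automated (y) on manual (x) traits — slope = sign(r)·sd(y)/sd(x) — which,
unlike OLS, does not attenuate when both variables carry comparable error,
plus linear-trend diagnostics of the normalized CNN−manual difference
against confounders (time, soil moisture, root abundance) and Pearson
correlation of trait series against destructive biomass points.

A synthetic-fixture module generates root phantoms (curvilinear strokes
with analytic length/area truth plus sub-threshold speckles), logistic
growth trajectories with noisy per-cycle observations, and constant-channel
canopy scenes, so the whole pipeline is testable without instrument data.

## Worked example

Simulate a small deployment (96 masks: 6 days × 2 longitudinal × 8
rotational positions) and run the pipeline on it:

```sh
$ rhizopheno simulate --out-dir demo --n-days 6 --n-long 2 --seed 7
wrote 96 masks + manifest + truth under demo
$ rhizopheno extract --config demo/config.yaml
INFO rhizopheno: pipeline complete: {'images_in': 96,
 'images_dropped_by_selection': 48, 'images_dropped_by_qc': 0,
 'images_kept': 48, 'days_observed': 6, 'days_gapfilled': 0}
traits: demo/out/traits.csv
daily:  demo/out/daily_rld_mm_per_mm2.csv
$ head -3 demo/out/daily_rld_mm_per_mm2.csv
date,value_raw,value_gapfilled,value_smoothed,slope,value_norm,n_images,flags
2021-03-01,0.02847916667,0.02847916667,0.02729166667,0.009302083333,0,8,observed
2021-03-02,0.02610416667,0.02610416667,0.03688194444,0.01220972222,0.1749319146,8,observed
```

Half the 96 images are dropped by rotational selection (angled default
keeps the 4 side positions of 8). Each daily row carries the raw daily mean
RLD (mm mm⁻²), the gapfilled and 3-day-smoothed values, the 5-day slope
(mm mm⁻² day⁻¹ — the root "growth rate"), the 0–1 normalized series, the
number of contributing images, and a provenance flag. The simulated root
count ramps up over the 6 days, which is why value and slope rise.

Other subcommands: `rhizopheno series` (daily series from an existing
traits CSV), `rhizopheno gcc` (canopy greenness from an image directory +
ROI vertex file), `rhizopheno validate` (RMA fit + bias trends from paired
manual/CNN CSVs).

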