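# resiligrid

Pixel-wise vegetation **resistance** and **resilience** to multi-year dry
periods, from gridded NDVI time series and station precipitation records —
with gradient binning, model-selected curve fits, and a synthetic-scene
generator for end-to-end verification.

Semi-arid grasslands can face not just single drought years but dry
*periods* lasting a decade. For ecologists and remote-sensing analysts
asking *which ecosystems along a precipitation gradient buffer such
periods, and which recover*, this package turns raw inputs (a yearly NDVI
raster stack, a station CSV, optionally a land-cover mask) into per-pixel
stability metrics and fitted precipitation-gradient profiles.

## The metrics

With the year axis split into normal / dry / recovery periods and period
means taken per pixel (P precipitation, N NDVI):

```
rain reduction  = (P_normal − P_dry) / P_normal
NDVI reduction  = (N_normal − N_dry) / N_normal
resistance      = rain reduction / NDVI reduction
resilience      = N_post / N_normal
```

Resistance > 1 means greenness declined proportionally less than rainfall;
resilience ≈ 1 means full post-drought recovery. Pixels with NDVI
reduction < 1% or without any rain reduction are excluded (screening out
human-managed or unaffected land), valid pixels are binned by mean annual
precipitation (50 mm bins), and each binned profile is fitted with a
line — or, when the line is not significant, the best of exponential /
quadratic / cubic by R².

## Worked example

Generate a synthetic scene with known ground truth and run the full
pipeline on it:

```python
import numpy as np
from resiligrid import (TruthConfig, generate_scene, regional_anomaly,
                        partition_years, period_stats, compute_pixel_metrics,
                        bin_by_map, fit_candidates, select_fit, peak_of_fit)

scene = generate_scene(TruthConfig(seed=1))          # 100x100 px, 32 years
anom = regional_anomaly(scene.precip_cube)
part = partition_years(anom, mode="auto")            # detect the dry run
stats = period_stats(scene.precip_cube, part)
print(len(part.dry_years), round(stats.regional["deficit_pct"], 1))

pm = compute_pixel_metrics(scene.precip_cube, scene.ndvi_cube, part)
profile = bin_by_map(pm.to_dataframe(), "resilience")
fit = select_fit(fit_candidates(profile, seed=1))
peak = peak_of_fit(fit, (profile.bin_mid.min(), profile.bin_mid.max()))
print(fit.family, round(fit.r2, 3), round(peak.map_mm, 1))
```

prints

```
13 11.5
cubic 0.994 251.1
```

i.e. the automatic partition finds the injected 13-year dry period with a
regional precipitation deficit of 11.5% of the long-term mean, and the
selected curve for binned resilience along the MAP gradient peaks at
251 mm — within half a bin of the 250 mm truth the generator imposed.

The same stages are available from the shell, each runnable standalone on
the previous stage's files:

```bash
resiligrid simulate --out scene/ --seed 1
resiligrid periods  --precip scene/precip.nc --out periods/
resiligrid metrics  --precip scene/precip.nc --ndvi scene/ndvi.nc \
                    --partition periods/periods.json --out metrics/
resiligrid gradient --pixels metrics/metrics.csv --out gradient/
resiligrid run-all  --config config.yaml       # everything from one YAML
```

Real data enter the same way: NetCDF (CF-style `year` coordinate) or
per-year GeoTIFF stacks for rasters, a `station_id, lon, lat, year,
precip_mm` CSV for stations (interpolated to the grid with a thin-plate
smoothing spline, GCV-chosen penalty), and an optional 0/1 GeoTIFF mask.

See `docs/methods.md` for the model, parameter defaults, the synthetic
generator's design, and known limitations.

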