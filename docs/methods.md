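# Methods

## The analysis

`resiligrid` quantifies how semi-arid vegetation withstands and recovers
from a *multi-year* dry period, per pixel of a gridded NDVI record, and how
those responses organize along a mean-annual-precipitation (MAP) gradient.

The year axis is split into three contiguous blocks — a **normal** period,
a **dry** period (consecutive below-average years), and a **recovery**
period after it. With period means per pixel (P = annual precipitation,
N = annual NDVI):

```
rain reduction  = (P_normal − P_dry) / P_normal
NDVI reduction  = (N_normal − N_dry) / N_normal
resistance      = rain reduction / NDVI reduction
resilience      = N_post / N_normal          (default; N_dry optional)
```

Resistance normalizes the vegetation response by the local severity of the
precipitation anomaly, so sites that dried by different amounts remain
comparable; values above 1 mean NDVI declined proportionally less than
rainfall. Resilience compares post-drought greenness with the pre-drought
baseline (full recovery ≈ 1). The printed-ratio form and the "relative to
the dry period" form of resilience disagree in parts of the literature;
both are computed and stored per pixel (`resilience_normal`,
`resilience_dry`), with the normal-period denominator as the default, so
the choice is auditable.

Pixels are excluded from gradient analysis when

* the NDVI reduction is below 1% (`min_ndvi_reduction = 0.01`) — a screen
  against pixels whose greenness barely responded, e.g. irrigated or
  otherwise human-managed land (at the cost of also dropping genuinely
  ultra-resistant sites, which cannot be separated without land-use data);
* there was no rain reduction at all (`rain_reduction ≤ 0`) — the analysis
  concerns responses *to* drying;
* any required period mean is missing, or the normal-period NDVI is ≤ 0
  (bare ground).

One exclusion reason is recorded per pixel with precedence
`nodata > no_rain_reduction > ndvi_reduction_below_min`, so tallies over
reasons are well defined even when a pixel fails several screens.

## Periods

Regional anomalies are yearly spatial means (uniform weights by default,
cos-latitude optional) minus the whole-series mean of those yearly means;
by construction they sum to zero. The default pipeline takes the period
split as explicit year ranges from the user. An automatic mode exists: the
dry period is the longest maximal run of ≥ `min_run` (default 5)
consecutive negative-anomaly years that does not touch the series start
(ties broken toward the more negative run mean); everything before it is
normal, everything after is recovery. The per-period reference means used
by the reduction ratios are the *normal-period* means, while anomalies are
relative to the *whole-series* mean — the two baselines serve different
purposes and are deliberately not conflated.

## Station interpolation

Station annual precipitation totals are interpolated to the analysis grid
with a 2-D thin-plate smoothing spline per year (kernel `r² log r` plus an
affine null space), treating lon/lat degrees as planar coordinates —
adequate at the regional scales targeted here. The penalty `λ` multiplies
the kernel diagonal as `n·λ`; `λ = 0` interpolates stations exactly and
reproduces affine surfaces exactly, `λ → ∞` tends to the least-squares
plane. The default `smoothing="gcv"` minimizes
`GCV(λ) = n‖(I−A)y‖² / tr(I−A)²` over a fixed grid of 45 penalties
(10⁻⁸…10³), taking the smallest penalty among minima; the influence matrix
`A` is formed explicitly, which is cheap at typical station counts
(~50). The spline is solved from the standard augmented linear system
rather than delegated to a library interpolator because GCV needs `A`;
`scipy`'s thin-plate RBF serves as an independent cross-check in the test
suite. Negative evaluations are clamped to 0 mm. Interpolation operates on
annual totals directly (one surface per year); a daily mode is out of
scope. An optional extra covariate column (e.g. elevation) can be appended
to the affine part but is off by default.

## Gradient profiles and model selection

Valid pixels are grouped into MAP bins of fixed width (default 50 mm),
anchored at multiples of the width from 0 mm, half-open `[lo, lo+width)`;
each bin contributes the unweighted mean (and sd) of the response. Bins
with fewer than `n_min = 10` pixels are dropped. Fits use the bin means
against bin midpoints (a raw-pixel mode is available but not default).

Candidate curves: a straight line first; if its slope is significant
(p ≤ 0.05, the t-test, equivalent to the overall F-test in simple
regression) the line is selected. Otherwise exponential `a·e^{bx}`
(nonlinear least squares, log-linear initialization), quadratic and cubic
are fitted and the highest `R² = 1 − SSE/SST` wins. The linear candidate
participates in that comparison, which only matters for exact ties since
the polynomials nest it; ties within 10⁻⁹ go to the model with fewer
parameters (so exact quadratic data selects the quadratic, not the equally
exact cubic). Significance is not gated for the nonlinear candidates. A
non-converging exponential is dropped with a logged warning.

95% bands for the fitted mean are analytic for the polynomial families
(OLS prediction-mean intervals) and a seeded parametric bootstrap (1,000
resamples of Gaussian residuals, refit each time) for the exponential.

The peak of a quadratic/cubic fit over a MAP interval comes from the
closed-form roots of the derivative clipped to the interval; a maximum
attained only at an endpoint is flagged as a boundary peak.

A subset analysis restricts to pixels with a similar degree of drying
(rain reduction in the closed interval [5%, 10%] by default) before
binning, removing the severity gradient as a confounder. On small scenes
this subset can retain fewer than the 5 bins a fit needs; the pipeline
then records the profile without a fit and warns, rather than aborting.

## The synthetic generator

The generator exists to verify the estimators, not to model vegetation. A
scene comprises:

* **MAP surface** — linear west-to-east gradient spanning 40–500 mm plus a
  smooth unit-variance texture scaled by `map_noise_sd = 15` mm, affinely
  rescaled into the range (rescaling rather than clipping: a clipped
  surface would carry point masses at the range ends, which a smooth field
  must not have).
* **Year structure** — 17 normal + 13 dry + 2 recovery years starting
  1982. Regionally, normal years run +4.9% and dry years −11.5% relative
  to the long-term mean; the recovery surplus (≈ +33%) is derived so the
  whole-series anomalies balance to zero. A shared interannual jitter
  (`noise_sd_year = 0.02`) keeps single years from flipping sign relative
  to the injected deficit, which is what makes exact automatic
  dry-period detection a fair target.
* **Per-pixel deficit** — the dry-year deficit deepens with MAP
  (`deficit_map_slope = 0.5` per relative MAP departure from mid-range)
  and carries a smooth spatial heterogeneity multiplier
  (`deficit_spatial_sd = 0.3`), then is normalized so the
  precipitation-weighted regional deficit equals the configured 11.5%.
  The heterogeneity is what populates the 5–10% rain-reduction subset
  across the MAP range, as in observed data.
* **Truth functions** — resistance rising affinely from 1 (dry end) to 6
  (wet end); resilience quadratic in MAP with vertex at 250 mm and values
  in [0.7, 1.1]. These are test fixtures, not ecological claims.
* **NDVI cube** — built by inverting the metric definitions on a
  saturating background `N(MAP) = 0.8·MAP/(200+MAP)`: dry years are
  depressed by `rain_reduction/resistance_true`, recovery years are
  `resilience_true · N` (normal-denominator convention; a dry-denominator
  generation mode exists). Multiplicative noise (`noise_sd_ndvi = 0.05`
  per pixel-year) is applied last; out-of-range cells are clipped into
  [0, 1] with a logged count.
* **Stations** — 51 sites at random pixel centers sampling the
  precipitation field with independent 3% observation noise.

At zero noise the pipeline recovers the truth fields to ~10⁻¹³ (floating
point only), which pins every algebraic step. With the default noise the
scene is a parameter-recovery surface: resilience (a plain ratio of period
means) recovers well, and the binned resilience profile relocates the
250 mm peak to within half a bin. Resistance is harsher: its denominator —
the NDVI reduction — is small (≈ 0.03) at the wet end while its sampling
sd under 5%-per-year noise is ≈ 0.018, so per-pixel resistance estimates
are noisy and heavy-tailed exactly where true resistance is largest, and
the 1% validity screen truncates that tail asymmetrically. Two visible
consequences, both measured by the acceptance tests: the per-pixel
estimate–truth Pearson correlation plateaus near 0.55–0.6, and the
wet-most bin's mean resistance occasionally dips below its neighbor. These
are properties of the ratio estimator at this noise level, not of the
implementation (the zero-noise inversion is exact); real-data analyses
face the same limitation where NDVI responses are weak.

What the generator does **not** emulate: phenology and sub-annual
composite structure, snow contamination, spatial autocorrelation of noise,
land-use change, or any vegetation dynamics — so passing tests validate
the estimators and plumbing, not ecological realism.

## Numerical and I/O choices

* Grids are regular lon/lat (WGS84), pixel-center registered, row 0
  north; missing cells are NaN in memory and the declared fill value on
  disk. NetCDF I/O goes through `xarray` (NETCDF3 via the scipy engine);
  GeoTIFF stacks carry minimal georeferencing tags
  (ModelPixelScale/ModelTiepoint/GeoKeyDirectory/GDAL_NODATA) written and
  read with `tifffile`. Rasters are written in float64 so a write/read
  round trip is bit-exact.
* Annual aggregation of sub-annual composites requires a minimum coverage
  fraction of 0.8 per pixel-year (below it, the year is missing).
  Calendar-year windows throughout; a growing-season window would be a
  different (configurable) aggregation, not a different method.
* Resampling is bilinear by default (nearest available); any missing
  contributor poisons the bilinear output cell, and target cells outside
  the source pixel-center hull are missing.
* The MAP axis of the gradient uses each pixel's all-years mean
  precipitation by default (`map_window="all"`, switchable to the normal
  period). This estimated axis, rather than an error-free covariate, is
  itself a (small) noise source in the bin assignment.
* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence.spawn`, so scenes are bit-reproducible and
  every stochastic test is seeded.
* Default problem sizes: 100×100 pixels × 32 years for scene-level
  checks, 30×30 for the 100-realization period-detection study — small
  enough to generate in well under a second each while leaving every bin
  with hundreds of pixels.

## Known limitations

* Resistance estimation degrades where NDVI reductions approach the 1%
  validity threshold (see above); interpreting per-pixel resistance at
  the wet end of the gradient requires either more years or sub-annual
  averaging to beat the noise down.
* The period partition assigns whole calendar years; a dry period that
  starts or ends mid-year is beyond the design.
* No spatial autocorrelation correction in the gradient fits: bins are
  treated as independent observations, as in the analysis this package
  operationalizes.
* Thin-plate interpolation in lon/lat degrees ignores meridional
  convergence; at continental scales, project first.
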