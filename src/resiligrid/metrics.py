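"""Per-pixel drought resistance and resilience from period-mean rasters.

Definitions (all per pixel, period means over the partition):

* rain reduction      = (P_normal - P_dry) / P_normal
* NDVI reduction      = (NDVI_normal - NDVI_dry) / NDVI_normal
* resistance          = rain reduction / NDVI reduction
* resilience          = NDVI_post / NDVI_normal   (default denominator;
  NDVI_dry available as an alternative and always reported alongside)

Higher resistance means the vegetation signal declined proportionally less
than rainfall did; higher resilience means a fuller post-dry-period
recovery.  Pixels are excluded from gradient analysis when the NDVI
reduction is below a minimum (default 1%, screening out pixels whose NDVI
barely responded — e.g. human-managed land) or when there was no rain
reduction at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grids import GridCube, GridSpec
from .periods import PeriodPartition

__all__ = [
    "MetricsConfig",
    "PixelMetrics",
    "rain_reduction",
    "ndvi_reduction",
    "resistance",
    "resilience",
    "compute_pixel_metrics",
    "REASON_CODES",
]

# exclusion-reason codes stored in the int8 reason grid
REASON_CODES = {
    "none": 0,
    "ndvi_reduction_below_min": 1,
    "no_rain_reduction": 2,
    "nodata": 3,
}
REASON_NAMES = {v: k for k, v in REASON_CODES.items()}


def rain_reduction(p_normal, p_dry):
    """Fractional precipitation reduction, dry period vs normal period.

    May be negative (a wetter dry period); downstream filtering, not this
    function, removes such pixels.  ``p_normal <= 0`` is a hard error.
    """
    p_normal = np.asarray(p_normal, dtype=float)
    p_dry = np.asarray(p_dry, dtype=float)
    if np.any(p_normal[np.isfinite(p_normal)] <= 0):
        raise ValueError("rain_reduction requires p_normal > 0")
    out = (p_normal - p_dry) / p_normal
    return float(out) if out.ndim == 0 else out


def ndvi_reduction(n_normal, n_dry):
    """Fractional NDVI reduction; NaN where ``n_normal <= 0`` (bare or
    sparse vegetation is flagged as missing, not an error)."""
    n_normal = np.asarray(n_normal, dtype=float)
    n_dry = np.asarray(n_dry, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n_normal > 0, (n_normal - n_dry) / n_normal, np.nan)
    return float(out) if out.ndim == 0 else out


def resistance(rain_red, ndvi_red):
    """Rain reduction divided by NDVI reduction.

    Contract: only meaningful on pixels that passed the validity filter
    (positive rain reduction, NDVI reduction at or above the minimum);
    calling it with non-positive inputs is a contract violation.
    """
    rain_red = np.asarray(rain_red, dtype=float)
    ndvi_red = np.asarray(ndvi_red, dtype=float)
    if np.any(rain_red[np.isfinite(rain_red)] <= 0) or np.any(
        ndvi_red[np.isfinite(ndvi_red)] <= 0
    ):
        raise ValueError(
            "resistance called on a filtered-out pixel "
            "(requires rain_red > 0 and ndvi_red > 0)"
        )
    out = rain_red / ndvi_red
    return float(out) if out.ndim == 0 else out


def resilience(n_post, n_normal, n_dry, denominator: str = "normal"):
    """Recovery-period NDVI relative to a reference period.

    ``denominator="normal"`` (default) compares the recovery mean to the
    pre-drought mean; ``"dry"`` compares it to the dry-period mean.  A
    non-positive denominator yields NaN (pixel flagged missing).
    """
    n_post = np.asarray(n_post, dtype=float)
    n_normal = np.asarray(n_normal, dtype=float)
    n_dry = np.asarray(n_dry, dtype=float)
    if denominator == "normal":
        denom = n_normal
    elif denominator == "dry":
        denom = n_dry
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, n_post / denom, np.nan)
    return float(out) if out.ndim == 0 else out


@dataclass
class MetricsConfig:
    """Tunables for :func:`compute_pixel_metrics`.

    ``min_ndvi_reduction``: validity threshold on the NDVI-reduction
    fraction (default 0.01, i.e. 1%).  ``resilience_denominator``:
    ``"normal"`` or ``"dry"``.  ``map_window``: which years define each
    pixel's mean annual precipitation for the gradient axis — ``"all"``
    (default) or ``"normal"``.
    """

    min_ndvi_reduction: float = 0.01
    resilience_denominator: str = "normal"
    map_window: str = "all"


@dataclass
class PixelMetrics:
    """Per-pixel period means, reductions, stability ratios and validity."""

    grid: GridSpec
    map_mm: np.ndarray
    p_normal: np.ndarray
    p_dry: np.ndarray
    n_normal: np.ndarray
    n_dry: np.ndarray
    n_post: np.ndarray
    rain_reduction: np.ndarray
    ndvi_reduction: np.ndarray
    resistance: np.ndarray
    resilience: np.ndarray
    resilience_normal: np.ndarray
    resilience_dry: np.ndarray
    valid: np.ndarray
    exclusion_reason: np.ndarray  # int8, see REASON_CODES
    config: MetricsConfig

    def reason_counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.exclusion_reason == code))
            for name, code in REASON_CODES.items()
        }

    def to_dataframe(self) -> pd.DataFrame:
        """One row per pixel with coordinates and all metric fields."""
        lon, lat = self.grid.lonlat_grids()
        rows, cols = np.indices(self.grid.shape)
        df = pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "lon": lon.ravel(),
                "lat": lat.ravel(),
                "map_mm": self.map_mm.ravel(),
                "p_normal": self.p_normal.ravel(),
                "p_dry": self.p_dry.ravel(),
                "ndvi_normal": self.n_normal.ravel(),
                "ndvi_dry": self.n_dry.ravel(),
                "ndvi_post": self.n_post.ravel(),
                "rain_reduction": self.rain_reduction.ravel(),
                "ndvi_reduction": self.ndvi_reduction.ravel(),
                "resistance": self.resistance.ravel(),
                "resilience": self.resilience.ravel(),
                "resilience_normal": self.resilience_normal.ravel(),
                "resilience_dry": self.resilience_dry.ravel(),
                "valid": self.valid.ravel(),
                "exclusion_reason": [
                    REASON_NAMES[c] for c in self.exclusion_reason.ravel()
                ],
            }
        )
        return df

    def to_dataset(self) -> xr.Dataset:
        coords = {"lat": self.grid.lats, "lon": self.grid.lons}
        data = {
            name: (("lat", "lon"), getattr(self, name).astype(np.float64))
            for name in (
                "map_mm", "p_normal", "p_dry", "n_normal", "n_dry", "n_post",
                "rain_reduction", "ndvi_reduction", "resistance",
                "resilience", "resilience_normal", "resilience_dry",
            )
        }
        data["valid"] = (("lat", "lon"), self.valid.astype(np.int8))
        data["exclusion_reason"] = (
            ("lat", "lon"), self.exclusion_reason.astype(np.int8)
        )
        ds = xr.Dataset(data, coords=coords)
        ds.attrs["exclusion_codes"] = str(REASON_CODES)
        return ds

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_dataset().to_netcdf(path, engine="scipy")
        return path


def compute_pixel_metrics(precip: GridCube, ndvi: GridCube,
                          part: PeriodPartition,
                          config: MetricsConfig | None = None) -> PixelMetrics:
    """Evaluate reductions, resistance and resilience per pixel.

    The cubes must share a grid and cover all partition years.  The four
    ratio fields are element-wise identical to applying the scalar
    operations to the period means.  The validity filter excludes pixels
    with ``ndvi_reduction < min_ndvi_reduction``, with ``rain_reduction
    <= 0``, and pixels where any required period mean is missing or the
    normal-period NDVI is non-positive (non-vegetated).
    """
    config = config or MetricsConfig()
    if not precip.grid.approx_equals(ndvi.grid):
        raise ValueError("precipitation and NDVI cubes are not co-registered")

    p_normal = precip.period_mean(part.normal_years)
    p_dry = precip.period_mean(part.dry_years)
    n_normal = ndvi.period_mean(part.normal_years)
    n_dry = ndvi.period_mean(part.dry_years)
    if part.recovery_years:
        n_post = ndvi.period_mean(part.recovery_years)
    else:
        n_post = np.full(ndvi.grid.shape, np.nan)

    if config.map_window == "all":
        map_mm = precip.period_mean(precip.years)
    elif config.map_window == "normal":
        map_mm = p_normal
    else:
        raise ValueError(f"unknown map_window {config.map_window!r}")

    with np.errstate(invalid="ignore", divide="ignore"):
        rain_red = np.where(p_normal > 0, (p_normal - p_dry) / p_normal, np.nan)
        ndvi_red = np.where(n_normal > 0, (n_normal - n_dry) / n_normal, np.nan)
        res_norm = np.where(n_normal > 0, n_post / n_normal, np.nan)
        res_dry = np.where(n_dry > 0, n_post / n_dry, np.nan)

    nodata = (
        ~np.isfinite(p_normal) | ~np.isfinite(p_dry)
        | ~np.isfinite(n_normal) | ~np.isfinite(n_dry)
        | (p_normal <= 0) | (n_normal <= 0)
    )
    valid = (
        ~nodata
        & (rain_red > 0)
        & (ndvi_red >= config.min_ndvi_reduction)
    )
    reason = np.zeros(precip.grid.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        below_min = ~nodata & (ndvi_red < config.min_ndvi_reduction)
        no_rain = ~nodata & (rain_red <= 0)
    reason[below_min] = REASON_CODES["ndvi_reduction_below_min"]
    reason[no_rain] = REASON_CODES["no_rain_reduction"]  # takes precedence
    reason[nodata] = REASON_CODES["nodata"]

    with np.errstate(invalid="ignore", divide="ignore"):
        resist = np.where(valid, rain_red / ndvi_red, np.nan)
    resil = res_norm if config.resilience_denominator == "normal" else res_dry
    if config.resilience_denominator not in {"normal", "dry"}:
        raise ValueError(
            f"unknown resilience denominator {config.resilience_denominator!r}"
        )

    return PixelMetrics(
        grid=precip.grid,
        map_mm=map_mm,
        p_normal=p_normal, p_dry=p_dry,
        n_normal=n_normal, n_dry=n_dry, n_post=n_post,
        rain_reduction=rain_red, ndvi_reduction=ndvi_red,
        resistance=resist,
        resilience=resil,
        resilience_normal=res_norm, resilience_dry=res_dry,
        valid=valid, exclusion_reason=reason,
        config=config,
    )
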