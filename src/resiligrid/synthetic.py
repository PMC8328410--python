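"""Synthetic scenes with known resistance/resilience ground truth.

The generator emulates the statistical structure of a temperate-steppe
study region: a smooth west-to-east mean-annual-precipitation (MAP)
gradient (default 40-500 mm), a 32-year record split into 17 normal years
(regionally ~4.9% above the whole-series average), a 13-year dry period
(~11.5% below average) and 2 wetter recovery years, a station network
sampling the precipitation field, and an NDVI cube constructed by
*inverting* the resistance/resilience definitions so that the pipeline's
estimators have exact known truth:

* normal-year NDVI   = N(MAP) * (1 + noise)
* dry-year NDVI      = N(MAP) * (1 - rain_reduction / resistance_true) * (1 + noise)
* recovery-year NDVI = resilience_true * N(MAP) * (1 + noise)

with ``N(MAP) = Nmax * MAP / (h + MAP)`` a saturating background NDVI.
At zero noise the pipeline recovers the truth fields exactly; with noise
the scene is a parameter-recovery test surface.  This is deliberately an
estimator-verification construction, not a vegetation process model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import GridCube, GridSpec, write_cube
from .periods import PeriodPartition
from .tps import StationTable

logger = logging.getLogger(__name__)

__all__ = [
    "TruthConfig",
    "SyntheticScene",
    "default_grid",
    "generate_map_surface",
    "generate_station_records",
    "generate_ndvi_cube",
    "generate_scene",
]


def default_grid(nrows: int = 100, ncols: int = 100,
                 resolution: float = 0.083) -> GridSpec:
    """A study-region-like grid: 0.083 deg pixels, NW corner (40N, 105E)."""
    return GridSpec(lon0=105.0, lat0=48.0, dlon=resolution, dlat=resolution,
                    nrows=nrows, ncols=ncols)


@dataclass
class TruthConfig:
    """Ground-truth parameters for a synthetic scene.

    Year structure and regional precipitation effects default to the
    study conditions: 17 normal + 13 dry + 2 recovery years, a dry-period
    deficit of 11.5% of the long-term mean that deepens with MAP, and a
    normal-period surplus of 4.9%.  The recovery surplus is derived so the
    whole-series anomalies balance to zero.  Truth functions default to a
    resistance rising linearly from 1 (dry end) to 6 (wet end) and a
    resilience peaking at 250 mm with values in [0.7, 1.1].
    """

    n_years_normal: int = 17
    n_years_dry: int = 13
    n_years_recovery: int = 2
    start_year: int = 1982
    map_range: tuple[float, float] = (40.0, 500.0)
    map_noise_sd: float = 15.0       # mm, smooth spatial texture on the gradient
    dry_deficit: float = 0.115       # regional dry-period deficit (fraction)
    normal_surplus: float = 0.049    # regional normal-period surplus (fraction)
    deficit_map_slope: float = 0.5   # deficit scaling per relative MAP departure
    deficit_spatial_sd: float = 0.3  # smooth per-pixel deficit heterogeneity
    resistance_fn: Callable[[np.ndarray], np.ndarray] | None = None
    resilience_fn: Callable[[np.ndarray], np.ndarray] | None = None
    resilience_peak_mm: float = 250.0
    ndvi_max: float = 0.8
    ndvi_half_sat: float = 200.0     # mm, half-saturation of background NDVI
    noise_sd_precip: float = 0.03    # per pixel-year multiplicative
    noise_sd_ndvi: float = 0.05      # per pixel-year multiplicative
    noise_sd_year: float = 0.02      # shared interannual jitter
    n_stations: int = 51
    recovery_denominator: str = "normal"  # NDVI reference used when imposing resilience
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_years_normal, self.n_years_dry, self.n_years_recovery) < 1:
            raise ValueError("all period lengths must be >= 1")
        if not 0 < self.dry_deficit < 1:
            raise ValueError("dry_deficit must be in (0, 1)")
        if self.map_range[0] <= 0 or self.map_range[1] <= self.map_range[0]:
            raise ValueError("invalid map_range")
        if self.n_stations < 4:
            raise ValueError("need at least 4 stations")
        if self.recovery_denominator not in {"normal", "dry"}:
            raise ValueError("recovery_denominator must be 'normal' or 'dry'")

    @property
    def n_years(self) -> int:
        return self.n_years_normal + self.n_years_dry + self.n_years_recovery

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))

    @property
    def recovery_surplus(self) -> float:
        """Regional recovery-year surplus closing the anomaly budget."""
        return (
            self.n_years_dry * self.dry_deficit
            - self.n_years_normal * self.normal_surplus
        ) / self.n_years_recovery

    def partition(self) -> PeriodPartition:
        years = self.years
        a, b = self.n_years_normal, self.n_years_normal + self.n_years_dry
        return PeriodPartition(years[:a], years[a:b], years[b:])

    def noiseless(self) -> "TruthConfig":
        """Copy with all stochastic perturbations off (truth structure kept)."""
        return replace(
            self, noise_sd_precip=0.0, noise_sd_ndvi=0.0, noise_sd_year=0.0
        )

    def true_resistance(self, map_mm: np.ndarray) -> np.ndarray:
        if self.resistance_fn is not None:
            return np.asarray(self.resistance_fn(map_mm), dtype=float)
        lo, hi = self.map_range
        return 1.0 + 5.0 * (np.asarray(map_mm, dtype=float) - lo) / (hi - lo)

    def true_resilience(self, map_mm: np.ndarray) -> np.ndarray:
        if self.resilience_fn is not None:
            return np.asarray(self.resilience_fn(map_mm), dtype=float)
        peak = self.resilience_peak_mm
        return 1.1 - 0.4 * ((np.asarray(map_mm, dtype=float) - peak) / peak) ** 2

    def background_ndvi(self, map_mm: np.ndarray) -> np.ndarray:
        m = np.asarray(map_mm, dtype=float)
        return self.ndvi_max * m / (self.ndvi_half_sat + m)


@dataclass
class SyntheticScene:
    """A generated scene bundling inputs and per-pixel ground truth."""

    config: TruthConfig
    grid: GridSpec
    map_true: np.ndarray
    resistance_true: np.ndarray
    resilience_true: np.ndarray
    rain_reduction_true: np.ndarray
    deficit_true: np.ndarray
    year_factors: np.ndarray  # (n_years, nrows, ncols) noise-free multipliers
    stations: StationTable
    precip_cube: GridCube
    ndvi_cube: GridCube
    partition_true: PeriodPartition
    n_ndvi_clipped: int = 0

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write station CSV, cubes, truth rasters and a truth manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "stations": str(self.stations.write_csv(outdir / "stations.csv")),
            "precip": str(write_cube(self.precip_cube, outdir / "precip.nc", "precip")),
            "ndvi": str(write_cube(self.ndvi_cube, outdir / "ndvi.nc", "ndvi")),
        }
        truth = GridCube(
            np.stack([self.map_true, self.resistance_true,
                      self.resilience_true, self.rain_reduction_true]),
            # year axis reused as a band axis for the truth stack
            list(range(1, 5)), self.grid,
        )
        ds = truth.to_dataset("truth").rename({"year": "band"})
        ds["band"] = ["map_mm", "resistance", "resilience", "rain_reduction"]
        ds.to_netcdf(outdir / "truth.nc", engine="scipy")
        paths["truth"] = str(outdir / "truth.nc")
        manifest = {
            "seed": self.config.seed,
            "years": self.partition_true.to_dict(),
            "map_range": list(self.config.map_range),
            "dry_deficit": self.config.dry_deficit,
            "normal_surplus": self.config.normal_surplus,
            "recovery_surplus": self.config.recovery_surplus,
            "noise_sd_precip": self.config.noise_sd_precip,
            "noise_sd_ndvi": self.config.noise_sd_ndvi,
            "noise_sd_year": self.config.noise_sd_year,
            "n_ndvi_clipped": self.n_ndvi_clipped,
        }
        (outdir / "truth.json").write_text(json.dumps(manifest, indent=2))
        paths["manifest"] = str(outdir / "truth.json")
        return paths


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Unit-variance smooth random field."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = raw.std()
    return raw / sd if sd > 0 else raw


def generate_map_surface(config: TruthConfig, grid: GridSpec,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Smooth west-to-east MAP gradient spanning ``map_range`` plus seeded
    smooth spatial texture, clipped to the range."""
    rng = rng or np.random.default_rng(config.seed)
    lo, hi = config.map_range
    cols = np.arange(grid.ncols)
    base = lo + (hi - lo) * (cols / max(grid.ncols - 1, 1))
    surface = np.broadcast_to(base, grid.shape).astype(float).copy()
    if config.map_noise_sd > 0:
        sigma = max(2.0, min(grid.shape) / 20.0)
        surface += config.map_noise_sd * _smooth_field(rng, grid.shape, sigma)
        # rescale (rather than clip) into the range: clipping would pile a
        # point mass at the range ends, which a smooth field must not have
        smin, smax = surface.min(), surface.max()
        if smax > smin:
            surface = lo + (hi - lo) * (surface - smin) / (smax - smin)
    return np.clip(surface, lo, hi)


def generate_year_factors(config: TruthConfig, map_true: np.ndarray,
                          rng: np.random.Generator | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free precipitation multipliers per (year, pixel).

    Returns ``(factors, deficit)`` where ``factors[t]`` multiplies MAP in
    year ``t`` and ``deficit`` is the per-pixel dry-year fractional
    deficit.  The deficit deepens with MAP (relative slope
    ``deficit_map_slope`` about the mid-range MAP) and carries a smooth
    spatial heterogeneity multiplier so that, as in observations, pixels
    with a similar MAP experienced different degrees of drying.
    """
    rng = rng or np.random.default_rng(config.seed)
    lo, hi = config.map_range
    mid = 0.5 * (lo + hi)
    gradient = 1.0 + config.deficit_map_slope * (map_true - mid) / mid
    if config.deficit_spatial_sd > 0:
        sigma = max(2.0, min(map_true.shape) / 25.0)
        hetero = 1.0 + config.deficit_spatial_sd * _smooth_field(
            rng, map_true.shape, sigma
        )
    else:
        hetero = np.ones_like(map_true)
    deficit = np.clip(config.dry_deficit * gradient * hetero, 0.005, 0.95)
    # normalize so the *precipitation-weighted* regional deficit equals the
    # configured fraction (the regional anomaly weights wet pixels more)
    weighted = float(np.sum(map_true * deficit) / np.sum(map_true))
    if weighted > 0:
        deficit = np.clip(deficit * (config.dry_deficit / weighted), 0.005, 0.95)

    jitter = (
        rng.normal(0.0, config.noise_sd_year, size=config.n_years)
        if config.noise_sd_year > 0 else np.zeros(config.n_years)
    )
    n_n, n_d = config.n_years_normal, config.n_years_dry
    factors = np.empty((config.n_years,) + map_true.shape)
    for t in range(config.n_years):
        if t < n_n:
            eff = config.normal_surplus
            factors[t] = 1.0 + eff + jitter[t]
        elif t < n_n + n_d:
            factors[t] = 1.0 - deficit + jitter[t]
        else:
            factors[t] = 1.0 + config.recovery_surplus + jitter[t]
    return factors, deficit


def _true_rain_reduction(config: TruthConfig,
                         factors: np.ndarray) -> np.ndarray:
    """Rain reduction implied by the noise-free factors (what the pipeline
    estimates from the precipitation cube, before pixel noise)."""
    n_n, n_d = config.n_years_normal, config.n_years_dry
    f_normal = factors[:n_n].mean(axis=0)
    f_dry = factors[n_n:n_n + n_d].mean(axis=0)
    return (f_normal - f_dry) / f_normal


def generate_precip_cube(config: TruthConfig, grid: GridSpec,
                         map_true: np.ndarray, factors: np.ndarray,
                         rng: np.random.Generator) -> GridCube:
    values = map_true[None] * factors
    if config.noise_sd_precip > 0:
        values = values * (
            1.0 + rng.normal(0.0, config.noise_sd_precip, size=values.shape)
        )
    return GridCube(np.clip(values, 0.0, None), config.years, grid, kind="precip")


def generate_station_records(config: TruthConfig, grid: GridSpec,
                             map_true: np.ndarray, factors: np.ndarray,
                             rng: np.random.Generator) -> StationTable:
    """Stations at random pixel centers sampling the precipitation field
    with independent multiplicative observation noise."""
    n_px = grid.nrows * grid.ncols
    flat = rng.choice(n_px, size=min(config.n_stations, n_px), replace=False)
    rows, cols = np.unravel_index(flat, grid.shape)
    lons = grid.lons[cols]
    lats = grid.lats[rows]
    records = []
    for k, (r, c) in enumerate(zip(rows, cols)):
        site_map = map_true[r, c]
        vals = site_map * factors[:, r, c]
        if config.noise_sd_precip > 0:
            vals = vals * (
                1.0 + rng.normal(0.0, config.noise_sd_precip, size=vals.size)
            )
        vals = np.clip(vals, 0.0, None)
        for year, v in zip(config.years, vals):
            records.append(
                {
                    "station_id": f"S{k + 1:03d}",
                    "lon": float(lons[k]),
                    "lat": float(lats[k]),
                    "year": int(year),
                    "precip_mm": float(v),
                }
            )
    import pandas as pd
    return StationTable(pd.DataFrame.from_records(records))


def generate_ndvi_cube(config: TruthConfig, grid: GridSpec,
                       map_true: np.ndarray, resistance_true: np.ndarray,
                       resilience_true: np.ndarray,
                       rain_reduction_true: np.ndarray,
                       rng: np.random.Generator) -> tuple[GridCube, int]:
    """NDVI cube constructed by inverting the stability definitions.

    Returns the cube and the count of cells clipped into [0, 1].
    """
    if np.any(resistance_true <= 0):
        raise ValueError("resistance_true must be positive everywhere")
    n_normal = config.background_ndvi(map_true)
    dry_level = n_normal * (1.0 - rain_reduction_true / resistance_true)
    if config.recovery_denominator == "normal":
        post_level = resilience_true * n_normal
    else:
        post_level = resilience_true * dry_level

    n_n, n_d = config.n_years_normal, config.n_years_dry
    values = np.empty((config.n_years,) + grid.shape)
    for t in range(config.n_years):
        if t < n_n:
            values[t] = n_normal
        elif t < n_n + n_d:
            values[t] = dry_level
        else:
            values[t] = post_level
    if config.noise_sd_ndvi > 0:
        values = values * (
            1.0 + rng.normal(0.0, config.noise_sd_ndvi, size=values.shape)
        )
    n_clipped = int(np.sum((values < 0.0) | (values > 1.0)))
    if n_clipped:
        logger.warning("clipped %d NDVI cells into [0, 1]", n_clipped)
        values = np.clip(values, 0.0, 1.0)
    return GridCube(values, config.years, grid, kind="ndvi"), n_clipped


def generate_scene(config: TruthConfig | None = None,
                   grid: GridSpec | None = None) -> SyntheticScene:
    """Compose the generators into a fully reproducible scene."""
    config = config or TruthConfig()
    grid = grid or default_grid()
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    rng_map, rng_year, rng_precip, rng_station, rng_ndvi = (
        np.random.default_rng(s) for s in seeds
    )
    map_true = generate_map_surface(config, grid, rng_map)
    factors, deficit = generate_year_factors(config, map_true, rng_year)
    rain_red_true = _true_rain_reduction(config, factors)
    resistance_true = config.true_resistance(map_true)
    resilience_true = config.true_resilience(map_true)
    precip_cube = generate_precip_cube(config, grid, map_true, factors, rng_precip)
    stations = generate_station_records(config, grid, map_true, factors, rng_station)
    ndvi_cube, n_clipped = generate_ndvi_cube(
        config, grid, map_true, resistance_true, resilience_true,
        rain_red_true, rng_ndvi,
    )
    return SyntheticScene(
        config=config,
        grid=grid,
        map_true=map_true,
        resistance_true=resistance_true,
        resilience_true=resilience_true,
        rain_reduction_true=rain_red_true,
        deficit_true=deficit,
        year_factors=factors,
        stations=stations,
        precip_cube=precip_cube,
        ndvi_cube=ndvi_cube,
        partition_true=config.partition(),
        n_ndvi_clipped=n_clipped,
    )
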