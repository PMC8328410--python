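"""End-to-end orchestration: interpolate -> periods -> metrics -> gradient.

Every stage logs its pixel counts and exclusion tallies; identical config
and inputs produce byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .gradient import (
    BinnedProfile,
    GradientFit,
    bin_by_map,
    fit_candidates,
    subset_by_rain_reduction,
    write_fits_json,
)
from .grids import GridCube, apply_mask, read_cube, read_mask, resample_to
from .metrics import MetricsConfig, PixelMetrics, compute_pixel_metrics
from .periods import PeriodPartition, partition_years, period_stats, regional_anomaly
from .tps import StationTable, interpolate_precip

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]

# responses profiled along the MAP gradient (all-pixels variant)
GRADIENT_RESPONSES = ("rain_reduction", "ndvi_reduction", "resistance", "resilience")
# responses additionally profiled on the similar-rain-reduction subset
SUBSET_RESPONSES = ("resistance", "resilience")


@dataclass
class PipelineResult:
    partition: PeriodPartition
    precip_stats: dict
    metrics: PixelMetrics
    pixels: pd.DataFrame
    profiles: dict[str, BinnedProfile]
    fits: dict[str, list[GradientFit] | None]
    outputs: dict[str, str]


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage '{stage}': {err}")
        self.stage = stage


def _load_inputs(config: PipelineConfig) -> tuple[GridCube, GridCube]:
    ndvi = read_cube(config.ndvi_path, variable=config.ndvi_variable, kind="ndvi")
    if config.precip_path:
        precip = read_cube(
            config.precip_path, variable=config.precip_variable, kind="precip"
        )
        if not precip.grid.approx_equals(ndvi.grid):
            logger.info("resampling precipitation onto the NDVI grid (bilinear)")
            precip = resample_to(precip, ndvi.grid, method="bilinear")
    elif config.stations_path:
        stations = StationTable.read_csv(config.stations_path)
        precip = interpolate_precip(
            stations, ndvi.grid, smoothing=config.smoothing, years=ndvi.years
        )
    else:
        raise ValueError("need precip_path or stations_path")
    if config.mask_path:
        mask, mgrid = read_mask(config.mask_path)
        if not mgrid.approx_equals(ndvi.grid):
            raise ValueError("mask grid does not match the NDVI grid")
        ndvi = apply_mask(ndvi, mask)
        precip = apply_mask(precip, mask)
    common = [y for y in ndvi.years if y in precip.years]
    if not common:
        raise ValueError("NDVI and precipitation share no years")
    return precip, ndvi


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis; see :class:`PipelineConfig` for the knobs.

    Writes, under ``config.output_dir``: anomaly CSVs, the partition and
    period-stat JSONs, per-pixel metric NetCDF + CSV, binned-profile CSVs
    for each response (all-pixels and similar-rain-reduction subset), and
    the candidate-fit JSON.  A stage failure raises :class:`StageError`
    naming the stage; an under-populated subset variant is recorded as
    absent (with a logged warning) rather than aborting.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    try:
        precip, ndvi = _load_inputs(config)
    except Exception as err:
        raise StageError("load", err) from err

    try:
        precip_anom = regional_anomaly(precip, weights=config.weights)
        ndvi_anom = regional_anomaly(ndvi, weights=config.weights)
        outputs["precip_anomaly"] = str(precip_anom.write_csv(outdir / "precip_anomaly.csv"))
        outputs["ndvi_anomaly"] = str(ndvi_anom.write_csv(outdir / "ndvi_anomaly.csv"))
        if config.period_mode == "explicit":
            part = partition_years(
                precip_anom, mode="explicit",
                normal=config.normal_range, dry=config.dry_range,
                recovery=config.recovery_range,
            )
        else:
            part = partition_years(precip_anom, mode="auto", min_run=config.min_run)
        stats = period_stats(precip, part)
        logger.info(
            "periods: normal %s-%s, dry %s-%s (deficit %.1f%% / %.0f mm), recovery %s",
            part.normal_years[0], part.normal_years[-1],
            part.dry_years[0], part.dry_years[-1],
            stats.regional["deficit_pct"], stats.regional["deficit_mm"],
            part.recovery_years or "none",
        )
        payload = {"partition": part.to_dict(), "regional": stats.regional}
        (outdir / "periods.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        outputs["periods"] = str(outdir / "periods.json")
    except StageError:
        raise
    except Exception as err:
        raise StageError("periods", err) from err

    try:
        mconfig = MetricsConfig(
            min_ndvi_reduction=config.min_ndvi_reduction,
            resilience_denominator=config.resilience_denominator,
            map_window=config.map_window,
        )
        metrics = compute_pixel_metrics(precip, ndvi, part, mconfig)
        tallies = metrics.reason_counts()
        n_px = metrics.valid.size
        logger.info("metrics: %d pixels, exclusion tally %s", n_px, tallies)
        if tallies["none"] == 0:
            logger.warning("metrics: no valid pixels remain after filtering")
        elif tallies["none"] < 0.05 * n_px:
            logger.warning(
                "metrics: only %d of %d pixels valid", tallies["none"], n_px
            )
        outputs["metrics_nc"] = str(metrics.write(outdir / "metrics.nc"))
        pixels = metrics.to_dataframe()
        pixels.to_csv(outdir / "metrics.csv", index=False)
        outputs["metrics_csv"] = str(outdir / "metrics.csv")
        (outdir / "exclusion_tally.json").write_text(
            json.dumps(tallies, indent=2, sort_keys=True)
        )
        outputs["exclusion_tally"] = str(outdir / "exclusion_tally.json")
    except Exception as err:
        raise StageError("metrics", err) from err

    profiles: dict[str, BinnedProfile] = {}
    fits: dict[str, list[GradientFit] | None] = {}
    try:
        any_valid = bool(metrics.valid.any())
        for response in GRADIENT_RESPONSES:
            if not any_valid:
                logger.warning("no valid pixels; skipping %s profile", response)
                fits[response] = None
                continue
            profile = bin_by_map(
                pixels, response, width=config.bin_width, n_min=config.n_min
            )
            profiles[response] = profile
            profile.write_csv(outdir / f"profile_{response}.csv")
            fits[response] = _try_fit(profile, response, config)
        subset = subset_by_rain_reduction(pixels, config.subset_lo, config.subset_hi)
        logger.info(
            "subset %.0f%%-%.0f%% rain reduction: %d pixels",
            100 * config.subset_lo, 100 * config.subset_hi, len(subset),
        )
        for response in SUBSET_RESPONSES:
            name = f"{response}_subset"
            if len(subset) == 0:
                logger.warning("subset variant empty; skipping %s", name)
                fits[name] = None
                continue
            profile = bin_by_map(
                subset, response, width=config.bin_width, n_min=config.n_min
            )
            profiles[name] = profile
            profile.write_csv(outdir / f"profile_{name}.csv")
            fits[name] = _try_fit(profile, name, config)
        outputs["fits"] = str(write_fits_json(fits, outdir / "gradient_fits.json"))
    except Exception as err:
        raise StageError("gradient", err) from err

    return PipelineResult(
        partition=part,
        precip_stats=stats.regional,
        metrics=metrics,
        pixels=pixels,
        profiles=profiles,
        fits=fits,
        outputs=outputs,
    )


def _try_fit(profile: BinnedProfile, name: str,
             config: PipelineConfig) -> list[GradientFit] | None:
    """Fit candidates, tolerating under-populated profiles (a variant with
    too few retained bins is reported as unfitted, not a pipeline error)."""
    try:
        return fit_candidates(profile, p_gate=config.p_gate, seed=config.seed)
    except ValueError as err:
        logger.warning("gradient fit skipped for %s: %s", name, err)
        return None
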