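"""Regional anomaly series and normal / dry / recovery period partition.

An anomaly is a yearly regional mean minus the whole-series mean of those
yearly means, so an :class:`AnomalySeries` sums to zero by construction.
A *dry period* is a multi-year run of consecutive below-average years; the
partition places every series year into exactly one of three contiguous
blocks: normal (before the dry run), dry, recovery (after it).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import GridCube

__all__ = [
    "AnomalySeries",
    "PeriodPartition",
    "PeriodStats",
    "regional_anomaly",
    "partition_years",
    "period_stats",
]


@dataclass
class AnomalySeries:
    """Yearly regional anomalies relative to the whole-series mean."""

    years: list[int]
    values: np.ndarray
    baseline: float  # the long-term mean that was subtracted

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.years) != self.values.size:
            raise ValueError("years/values length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "anomaly": self.values})

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)
        return path


@dataclass
class PeriodPartition:
    """Disjoint, ordered normal / dry / recovery year blocks."""

    normal_years: list[int]
    dry_years: list[int]
    recovery_years: list[int]

    def __post_init__(self) -> None:
        for name in ("normal_years", "dry_years", "recovery_years"):
            setattr(self, name, [int(y) for y in getattr(self, name)])
        if not self.normal_years:
            raise ValueError("normal period is empty")
        if not self.dry_years:
            raise ValueError("dry period is empty")
        dry = self.dry_years
        if dry != list(range(dry[0], dry[-1] + 1)):
            raise ValueError("dry period must be contiguous")
        seq = self.normal_years + self.dry_years + self.recovery_years
        if seq != sorted(set(seq)):
            raise ValueError("periods must be disjoint and ordered normal < dry < recovery")
        if seq != list(range(seq[0], seq[-1] + 1)):
            raise ValueError("partition must cover a gapless year range")

    @property
    def all_years(self) -> list[int]:
        return self.normal_years + self.dry_years + self.recovery_years

    def to_dict(self) -> dict:
        return {
            "normal": [self.normal_years[0], self.normal_years[-1]],
            "dry": [self.dry_years[0], self.dry_years[-1]],
            "recovery": (
                [self.recovery_years[0], self.recovery_years[-1]]
                if self.recovery_years else None
            ),
        }

    @classmethod
    def from_ranges(cls, normal: Sequence[int], dry: Sequence[int],
                    recovery: Sequence[int] | None) -> "PeriodPartition":
        """Build from three inclusive (first, last) year ranges."""
        def expand(rng) -> list[int]:
            if rng is None:
                return []
            lo, hi = int(rng[0]), int(rng[-1])
            return list(range(lo, hi + 1))
        return cls(expand(normal), expand(dry), expand(recovery))


def regional_anomaly(cube: GridCube, weights: str = "uniform") -> AnomalySeries:
    """Regional yearly means minus their long-term mean.

    ``weights``: ``"uniform"`` (every valid pixel equal) or ``"cos-lat"``
    (area weighting by the cosine of latitude).
    """
    if cube.n_years < 2:
        raise ValueError("need at least 2 years for an anomaly series")
    if weights == "uniform":
        w = np.ones(cube.grid.shape)
    elif weights == "cos-lat":
        w = np.cos(np.deg2rad(cube.grid.lats))[:, None] * np.ones(cube.grid.shape)
    else:
        raise ValueError(f"unknown weighting {weights!r}")

    means = np.empty(cube.n_years)
    for i, year in enumerate(cube.years):
        layer = cube.values[i]
        valid = np.isfinite(layer)
        if not valid.any():
            raise ValueError(f"year {year}: no valid pixels")
        means[i] = np.sum(layer[valid] * w[valid]) / np.sum(w[valid])
    baseline = float(means.mean())
    return AnomalySeries(list(cube.years), means - baseline, baseline)


def _negative_runs(values: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs (start, stop exclusive) of consecutive negative entries."""
    runs, start = [], None
    for i, v in enumerate(values):
        if v < 0:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(values)))
    return runs


def partition_years(anom: AnomalySeries, mode: str = "auto",
                    normal: Sequence[int] | None = None,
                    dry: Sequence[int] | None = None,
                    recovery: Sequence[int] | None = None,
                    min_run: int = 5) -> PeriodPartition:
    """Partition the year axis into normal / dry / recovery.

    ``explicit`` mode validates user-supplied inclusive ranges against the
    series.  ``auto`` mode takes the dry period as the longest maximal run
    of >= ``min_run`` consecutive negative-anomaly years that does not
    reach the series start (a baseline of normal years must precede it);
    length ties are broken toward the more negative run mean.
    """
    years = anom.years
    if mode == "explicit":
        if normal is None or dry is None:
            raise ValueError("explicit mode requires normal and dry ranges")
        part = PeriodPartition.from_ranges(normal, dry, recovery)
        if part.all_years != years:
            raise ValueError("explicit ranges do not cover the series years")
        return part
    if mode != "auto":
        raise ValueError(f"unknown mode {mode!r}")

    if len(years) < min_run + 2:
        raise ValueError(
            f"series of {len(years)} years too short for auto detection"
        )
    runs = [
        (start, stop) for start, stop in _negative_runs(anom.values)
        if stop - start >= min_run
    ]
    if not runs:
        raise ValueError("no dry period detected")
    interior = [r for r in runs if r[0] > 0]
    if not interior:
        raise ValueError(
            "dry period starts at the series start; no normal baseline precedes it"
        )
    # longest run; ties toward the more negative run mean
    interior.sort(key=lambda r: (-(r[1] - r[0]), float(np.mean(anom.values[r[0]:r[1]]))))
    start, stop = interior[0]
    return PeriodPartition(
        normal_years=years[:start],
        dry_years=years[start:stop],
        recovery_years=years[stop:],
    )


@dataclass
class PeriodStats:
    """Regional and per-pixel period means plus the dry-period deficit.

    ``deficit_pct`` is positive when the dry period is below the all-years
    mean: ``100 * (mean_all - mean_dry) / mean_all``.  ``surplus_pct`` is
    the same convention for the normal period (positive = above average).
    """

    regional: dict
    pixel_normal: np.ndarray
    pixel_dry: np.ndarray
    pixel_recovery: np.ndarray | None
    pixel_deficit_pct: np.ndarray


def period_stats(cube: GridCube, part: PeriodPartition) -> PeriodStats:
    """Period means (regional and per pixel) and dry-period deficit."""
    missing = [y for y in part.all_years if y not in cube.years]
    if missing:
        raise ValueError(f"partition years missing from cube: {missing}")

    def regional_mean(years: Sequence[int]) -> float:
        if not years:
            raise ValueError("empty period")
        vals = []
        for y in years:
            layer = cube.values[cube.year_index(y)]
            valid = np.isfinite(layer)
            if not valid.any():
                raise ValueError(f"year {y}: no valid pixels")
            vals.append(layer[valid].mean())
        return float(np.mean(vals))

    mean_all = regional_mean(part.all_years)
    mean_normal = regional_mean(part.normal_years)
    mean_dry = regional_mean(part.dry_years)
    mean_recovery = (
        regional_mean(part.recovery_years) if part.recovery_years else None
    )
    deficit_pct = 100.0 * (mean_all - mean_dry) / mean_all
    surplus_pct = 100.0 * (mean_normal - mean_all) / mean_all

    px_normal = cube.period_mean(part.normal_years)
    px_dry = cube.period_mean(part.dry_years)
    px_recovery = (
        cube.period_mean(part.recovery_years) if part.recovery_years else None
    )
    px_all = cube.period_mean(part.all_years)
    with np.errstate(invalid="ignore", divide="ignore"):
        px_deficit = 100.0 * (px_all - px_dry) / px_all

    return PeriodStats(
        regional={
            "mean_all": mean_all,
            "mean_normal": mean_normal,
            "mean_dry": mean_dry,
            "mean_recovery": mean_recovery,
            "deficit_pct": float(deficit_pct),
            "deficit_mm": float(mean_all - mean_dry),
            "normal_surplus_pct": float(surplus_pct),
        },
        pixel_normal=px_normal,
        pixel_dry=px_dry,
        pixel_recovery=px_recovery,
        pixel_deficit_pct=px_deficit,
    )
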