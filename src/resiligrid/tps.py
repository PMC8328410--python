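"""Thin-plate smoothing spline interpolation of station precipitation.

The spline minimizes ``sum_i (f(x_i) - y_i)^2 + n * lambda * J(f)`` where
``J`` is the 2-D bending energy.  The solution is ``f(x) = sum_i c_i
phi(|x - x_i|) + d0 + d1 x + d2 y`` with ``phi(r) = r^2 log r``, obtained
from the standard augmented linear system with ``n * lambda`` added to the
kernel diagonal.  ``lambda = 0`` interpolates the stations exactly and
reproduces any affine surface sampled without noise; ``lambda -> inf``
tends to the least-squares affine fit.

The penalty can be chosen by generalized cross-validation (GCV),
``GCV(lambda) = n ||(I - A) y||^2 / tr(I - A)^2`` with ``A`` the influence
matrix — the small station count makes forming ``A`` explicitly cheap.
Coordinates are treated as planar (lon, lat in degrees), adequate at the
regional scale this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import GridCube, GridSpec

__all__ = ["StationTable", "ThinPlateSpline", "tps_fit", "interpolate_precip"]

_GCV_GRID = np.logspace(-8, 3, 45)


@dataclass
class StationTable:
    """Per-station annual precipitation records.

    Backed by a tidy DataFrame with columns
    ``station_id, lon, lat, year, precip_mm``.
    """

    frame: pd.DataFrame

    REQUIRED = ("station_id", "lon", "lat", "year", "precip_mm")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"station table missing column(s): {missing}")
        f = self.frame
        if f[["lon", "lat"]].apply(lambda c: ~np.isfinite(c)).any().any():
            raise ValueError("non-finite station coordinates")
        if (f["precip_mm"] < 0).any():
            raise ValueError("negative precipitation in station records")
        if f.duplicated(["station_id", "year"]).any():
            raise ValueError("duplicate (station_id, year) records")
        coords = f.groupby("station_id")[["lon", "lat"]].nunique()
        if (coords > 1).any().any():
            raise ValueError("a station_id appears with multiple coordinates")

    @property
    def station_ids(self) -> list[str]:
        return sorted(self.frame["station_id"].astype(str).unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.frame["year"].astype(int).unique())

    def for_year(self, year: int) -> pd.DataFrame:
        sub = self.frame[self.frame["year"] == int(year)]
        return sub.dropna(subset=["precip_mm"])

    def incomplete_stations(self) -> list[str]:
        """Stations not covering the full year range of the table."""
        n_years = len(self.years)
        counts = self.frame.groupby("station_id")["year"].nunique()
        return sorted(counts[counts < n_years].index.astype(str))

    @classmethod
    def read_csv(cls, path: str | Path) -> "StationTable":
        return cls(pd.read_csv(path, dtype={"station_id": str}))

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(path, index=False)
        return path


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * np.log(r[nz])
    return out


@dataclass
class ThinPlateSpline:
    """Fitted 2-D thin-plate smoothing spline with optional extra covariates."""

    centers: np.ndarray          # (n, 2) scaled coordinates
    coef_kernel: np.ndarray      # (n,)
    coef_poly: np.ndarray        # (3 + n_extra,)
    shift: np.ndarray
    scale: float
    smoothing: float
    gcv_score: float | None = None
    extra_shift: np.ndarray | None = None
    extra_scale: np.ndarray | None = None

    @classmethod
    def fit(cls, xy: np.ndarray, values: np.ndarray,
            smoothing: float | str = 0.0,
            extra: np.ndarray | None = None) -> "ThinPlateSpline":
        """Fit to points ``xy`` (n, 2) with values ``values``.

        ``smoothing`` is the non-negative penalty, or ``"gcv"`` to select it
        by generalized cross-validation (smallest penalty among minima).
        ``extra`` optionally appends covariate columns to the affine part.
        """
        xy = np.asarray(xy, dtype=float)
        y = np.asarray(values, dtype=float)
        n = xy.shape[0]
        if n < 4:
            raise ValueError(f"need >= 4 stations, got {n}")
        # degenerate (collinear) configurations make the polynomial block rank
        # deficient and the problem ill-posed
        ones = np.ones(n)
        if np.linalg.matrix_rank(np.column_stack([ones, xy])) < 3:
            raise ValueError("degenerate station configuration (collinear)")

        shift = xy.mean(axis=0)
        scale = float(np.sqrt(((xy - shift) ** 2).sum(axis=1).mean()))
        if scale == 0:
            raise ValueError("degenerate station configuration (coincident)")
        z = (xy - shift) / scale

        extra_shift = extra_scale = None
        poly = np.column_stack([ones, z])
        if extra is not None:
            extra = np.atleast_2d(np.asarray(extra, dtype=float))
            if extra.shape[0] != n:
                extra = extra.T
            extra_shift = extra.mean(axis=0)
            extra_scale = extra.std(axis=0)
            extra_scale[extra_scale == 0] = 1.0
            poly = np.column_stack([poly, (extra - extra_shift) / extra_scale])

        dist = np.sqrt(((z[:, None, :] - z[None, :, :]) ** 2).sum(-1))
        K = _tps_kernel(dist)

        def solve(lam: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
            m = poly.shape[1]
            A = np.zeros((n + m, n + m))
            A[:n, :n] = K + n * lam * np.eye(n)
            A[:n, n:] = poly
            A[n:, :n] = poly.T
            rhs = np.zeros(n + m)
            rhs[:n] = y
            sol = np.linalg.solve(A, rhs)
            c, d = sol[:n], sol[n:]
            fitted = K @ c + poly @ d
            return c, d, fitted

        gcv_score = None
        if isinstance(smoothing, str):
            if smoothing != "gcv":
                raise ValueError(f"unknown smoothing mode {smoothing!r}")
            scores = []
            for lam in _GCV_GRID:
                m = poly.shape[1]
                A = np.zeros((n + m, n + m))
                A[:n, :n] = K + n * lam * np.eye(n)
                A[:n, n:] = poly
                A[n:, :n] = poly.T
                rhs = np.zeros((n + m, n))
                rhs[:n] = np.eye(n)
                sol = np.linalg.solve(A, rhs)
                infl = K @ sol[:n] + poly @ sol[n:]  # influence matrix A(lam)
                resid = y - infl @ y
                denom = (n - np.trace(infl)) ** 2
                scores.append(n * (resid @ resid) / denom if denom > 0 else np.inf)
            scores = np.asarray(scores)
            best = np.flatnonzero(scores == scores.min())[0]  # smallest lambda wins ties
            lam = float(_GCV_GRID[best])
            gcv_score = float(scores[best])
        else:
            lam = float(smoothing)
            if lam < 0:
                raise ValueError("smoothing penalty must be >= 0")

        c, d, _ = solve(lam)
        return cls(
            centers=z, coef_kernel=c, coef_poly=d, shift=shift, scale=scale,
            smoothing=lam, gcv_score=gcv_score,
            extra_shift=extra_shift, extra_scale=extra_scale,
        )

    def __call__(self, xy: np.ndarray,
                 extra: np.ndarray | None = None) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        z = (xy - self.shift) / self.scale
        dist = np.sqrt(((z[:, None, :] - self.centers[None, :, :]) ** 2).sum(-1))
        out = _tps_kernel(dist) @ self.coef_kernel
        poly = np.column_stack([np.ones(len(z)), z])
        if self.extra_shift is not None:
            if extra is None:
                raise ValueError("spline was fitted with extra covariates")
            extra = np.atleast_2d(np.asarray(extra, dtype=float))
            if extra.shape[0] != len(z):
                extra = extra.T
            poly = np.column_stack(
                [poly, (extra - self.extra_shift) / self.extra_scale]
            )
        return out + poly @ self.coef_poly

    def evaluate_grid(self, grid: GridSpec) -> np.ndarray:
        lon, lat = grid.lonlat_grids()
        pts = np.column_stack([lon.ravel(), lat.ravel()])
        return self(pts).reshape(grid.shape)


def tps_fit(stations: StationTable, year: int,
            smoothing: float | str = "gcv") -> ThinPlateSpline:
    """Fit a thin-plate smoothing spline to one year of station records."""
    sub = stations.for_year(year)
    if len(sub) < 4:
        raise ValueError(
            f"year {year}: need >= 4 stations with data, got {len(sub)}"
        )
    try:
        return ThinPlateSpline.fit(
            sub[["lon", "lat"]].to_numpy(), sub["precip_mm"].to_numpy(),
            smoothing=smoothing,
        )
    except ValueError as err:
        raise ValueError(f"year {year}: {err}") from err


def interpolate_precip(stations: StationTable, target: GridSpec,
                       smoothing: float | str = "gcv",
                       years: Sequence[int] | None = None) -> GridCube:
    """Interpolate station annual precipitation to ``target``, one surface
    per year; negative evaluations are clamped to 0."""
    lons = stations.frame["lon"]
    lats = stations.frame["lat"]
    w, s, e, n = target.bounds()
    if lons.max() < w or lons.min() > e or lats.max() < s or lats.min() > n:
        raise ValueError("target grid does not overlap the station bounding box")
    if years is None:
        years = stations.years
    layers = []
    for year in years:
        spline = tps_fit(stations, year, smoothing=smoothing)
        layers.append(np.clip(spline.evaluate_grid(target), 0.0, None))
    return GridCube(np.stack(layers), list(years), target, kind="precip")
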