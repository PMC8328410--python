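"""Gridded annual raster time series: containers, I/O, aggregation, resampling.

The in-memory convention throughout the package:

* grids are regular lon/lat (WGS84, decimal degrees), pixel-center
  registered, row 0 = northernmost row;
* missing cells are ``NaN``; file-level nodata sentinels are converted on
  read and restored on write;
* a cube's ``year`` axis is a gapless, strictly increasing run of calendar
  years.

Supported on-disk formats are CF-style NetCDF (one 3-D variable over a
``year`` coordinate) and stacks of single-band GeoTIFFs, one file per year
with the four-digit year in the filename.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "GridSpec",
    "GridCube",
    "CompositeCube",
    "read_cube",
    "write_cube",
    "read_mask",
    "write_mask",
    "annual_from_composites",
    "resample_to",
    "apply_mask",
]

# GeoTIFF tag ids (minimal georeferencing subset)
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113

_YEAR_RE = re.compile(r"(\d{4})")


@dataclass(frozen=True)
class GridSpec:
    """Regular pixel-center lon/lat grid (WGS84, row 0 north)."""

    lon0: float  # longitude of column-0 pixel centers
    lat0: float  # latitude of row-0 pixel centers (northernmost)
    dlon: float  # column step, degrees (> 0, eastward)
    dlat: float  # row step, degrees (> 0, southward)
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.dlon <= 0 or self.dlat <= 0:
            raise ValueError("grid steps must be positive")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def lons(self) -> np.ndarray:
        return self.lon0 + self.dlon * np.arange(self.ncols)

    @property
    def lats(self) -> np.ndarray:
        """Latitudes of row centers, north to south."""
        return self.lat0 - self.dlat * np.arange(self.nrows)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) outer cell edges."""
        return (
            self.lon0 - self.dlon / 2,
            self.lats[-1] - self.dlat / 2,
            self.lons[-1] + self.dlon / 2,
            self.lat0 + self.dlat / 2,
        )

    def lonlat_grids(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.lons, self.lats)

    def approx_equals(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.lon0 - other.lon0) <= tol
            and abs(self.lat0 - other.lat0) <= tol
            and abs(self.dlon - other.dlon) <= tol
            and abs(self.dlat - other.dlat) <= tol
        )

    @classmethod
    def from_coords(cls, lons: np.ndarray, lats: np.ndarray) -> "GridSpec":
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        if lons.size > 1:
            dlon = float(np.mean(np.diff(lons)))
            if not np.allclose(np.diff(lons), dlon, rtol=0, atol=1e-6):
                raise ValueError("longitude coordinate is not regular")
        else:
            dlon = 1.0
        if lats.size > 1:
            step = np.diff(lats)
            dlat = float(np.mean(-step))
            if dlat <= 0:
                raise ValueError("latitude coordinate must run north to south")
            if not np.allclose(-step, dlat, rtol=0, atol=1e-6):
                raise ValueError("latitude coordinate is not regular")
        else:
            dlat = 1.0
        return cls(float(lons[0]), float(lats[0]), dlon, dlat, lats.size, lons.size)


def _check_years(years: Sequence[int]) -> list[int]:
    years = [int(y) for y in years]
    if len(set(years)) != len(years):
        dupes = sorted({y for y in years if years.count(y) > 1})
        raise ValueError(f"duplicate year(s): {dupes}")
    if sorted(years) != years:
        raise ValueError("years must be strictly increasing")
    for prev, nxt in zip(years, years[1:]):
        if nxt != prev + 1:
            raise ValueError(f"gap at {prev + 1}")
    return years


@dataclass
class GridCube:
    """A (year, row, col) raster time series on a :class:`GridSpec`.

    ``values`` is float64 with NaN marking missing cells.  ``kind`` optionally
    enforces physical ranges: ``"ndvi"`` requires values in [-1, 1],
    ``"precip"`` requires non-negative values.
    """

    values: np.ndarray
    years: list[int]
    grid: GridSpec
    kind: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.years = _check_years(self.years)
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D (year, row, col)")
        expected = (len(self.years),) + self.grid.shape
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"years x grid {expected}"
            )
        finite = self.values[np.isfinite(self.values)]
        if self.kind == "ndvi" and finite.size and (
            finite.min() < -1.0 or finite.max() > 1.0
        ):
            raise ValueError("NDVI values outside [-1, 1]")
        if self.kind == "precip" and finite.size and finite.min() < 0:
            raise ValueError("precipitation values must be >= 0")

    @property
    def n_years(self) -> int:
        return len(self.years)

    def year_index(self, year: int) -> int:
        try:
            return self.years.index(int(year))
        except ValueError:
            raise KeyError(f"year {year} not in cube ({self.years[0]}-{self.years[-1]})")

    def select_years(self, years: Iterable[int]) -> np.ndarray:
        """Stack of layers for the given years (view-copy)."""
        idx = [self.year_index(y) for y in years]
        return self.values[idx]

    def period_mean(self, years: Iterable[int]) -> np.ndarray:
        """Per-pixel mean over the given years, NaN-aware."""
        block = self.select_years(years)
        with np.errstate(invalid="ignore"):
            return np.nanmean(block, axis=0)

    def copy(self) -> "GridCube":
        return replace(self, values=self.values.copy(), years=list(self.years))

    def to_dataset(self, name: str = "value") -> xr.Dataset:
        return xr.Dataset(
            {name: (("year", "lat", "lon"), self.values)},
            coords={
                "year": np.asarray(self.years, dtype=np.int32),
                "lat": self.grid.lats,
                "lon": self.grid.lons,
            },
            attrs={"crs": "EPSG:4326", "registration": "pixel-center"},
        )


@dataclass
class CompositeCube:
    """Sub-annual composites (e.g. 15-day NDVI, up to 24 per year)."""

    values: np.ndarray
    timestamps: list[tuple[int, int]]  # (year, within-year index 1..24)
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D (composite, row, col)")
        if self.values.shape[0] != len(self.timestamps):
            raise ValueError("one timestamp required per composite slice")
        if self.values.shape[1:] != self.grid.shape:
            raise ValueError("composite grid shape mismatch")
        per_year: dict[int, int] = {}
        for year, idx in self.timestamps:
            if not 1 <= idx <= 24:
                raise ValueError(f"within-year index {idx} outside 1..24")
            per_year[year] = per_year.get(year, 0) + 1
        if any(n > 24 for n in per_year.values()):
            raise ValueError("more than 24 composites in a year")

    @property
    def years(self) -> list[int]:
        return sorted({y for y, _ in self.timestamps})


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _geotiff_tags(grid: GridSpec, nodata: float) -> list[tuple]:
    west, _, _, north = grid.bounds()
    geokeys = (
        1, 1, 0, 3,          # version, revision, minor, key count
        1024, 0, 1, 2,       # GTModelTypeGeoKey = geographic
        1025, 0, 1, 1,       # GTRasterTypeGeoKey = PixelIsArea
        2048, 0, 1, 4326,    # GeographicTypeGeoKey = WGS84
    )
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.dlon, grid.dlat, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, west, north, 0.0)),
        (_TAG_GEOKEYS, "H", len(geokeys), geokeys),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(nodata))),
    ]


def _write_geotiff_band(path: Path, data: np.ndarray, grid: GridSpec,
                        nodata: float) -> None:
    out = np.where(np.isfinite(data), data, nodata)
    tifffile.imwrite(
        path, out.astype(np.float64), extratags=_geotiff_tags(grid, nodata)
    )


def _read_geotiff_band(path: Path) -> tuple[np.ndarray, GridSpec, float | None]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(np.float64)
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        dlon, dlat = tags[_TAG_PIXEL_SCALE].value[:2]
        tie = tags[_TAG_TIEPOINT].value
        west, north = tie[3], tie[4]
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster")
    grid = GridSpec(
        lon0=west + dlon / 2,
        lat0=north - dlat / 2,
        dlon=float(dlon),
        dlat=float(dlat),
        nrows=data.shape[0],
        ncols=data.shape[1],
    )
    return data, grid, nodata


def _year_from_name(path: Path) -> int:
    m = _YEAR_RE.findall(path.stem)
    if not m:
        raise ValueError(f"cannot parse a 4-digit year from {path.name}")
    return int(m[-1])


def _read_geotiff_stack(paths: list[Path], kind: str | None) -> GridCube:
    if not paths:
        raise ValueError("no GeoTIFF files found")
    per_year: dict[int, Path] = {}
    for p in paths:
        year = _year_from_name(p)
        if year in per_year:
            raise ValueError(f"duplicate year {year}: {per_year[year].name}, {p.name}")
        per_year[year] = p
    years = sorted(per_year)
    layers, grid = [], None
    for year in years:
        data, g, nodata = _read_geotiff_band(per_year[year])
        if grid is None:
            grid = g
        elif not grid.approx_equals(g):
            raise ValueError(f"inconsistent grid in {per_year[year].name}")
        if nodata is not None and np.isfinite(nodata):
            data = np.where(data == nodata, np.nan, data)
        layers.append(data)
    return GridCube(np.stack(layers), years, grid, kind=kind)


def _read_netcdf(path: Path, variable: str | None, kind: str | None) -> GridCube:
    with xr.open_dataset(path, engine="scipy") as ds:
        if variable is None:
            candidates = [v for v in ds.data_vars if ds[v].ndim == 3]
            if len(candidates) != 1:
                raise ValueError(
                    f"{path}: specify variable, found {sorted(ds.data_vars)}"
                )
            variable = candidates[0]
        da = ds[variable]
        dims = da.dims
        if len(dims) != 3:
            raise ValueError(f"{path}:{variable} is not 3-D")
        tdim = dims[0]
        years = [int(y) for y in da[tdim].values]
        lats = da[dims[1]].values.astype(float)
        lons = da[dims[2]].values.astype(float)
        values = da.values.astype(np.float64)
        fill = da.encoding.get("_FillValue", da.attrs.get("_FillValue"))
    if lats.size > 1 and lats[0] < lats[-1]:  # stored south-to-north
        lats = lats[::-1]
        values = values[:, ::-1, :]
    if fill is not None and np.isfinite(fill):
        values = np.where(values == fill, np.nan, values)
    grid = GridSpec.from_coords(lons, lats)
    return GridCube(values, years, grid, kind=kind)


def read_cube(path: str | Path, variable: str | None = None,
              kind: str | None = None) -> GridCube:
    """Read a :class:`GridCube` from NetCDF or a GeoTIFF stack.

    ``path`` may be a NetCDF file, a directory of single-band per-year
    GeoTIFFs, or a single GeoTIFF.  Years are parsed from filenames for
    TIFF stacks; missing or duplicate years raise with the offending year
    named.
    """
    path = Path(path)
    if path.is_dir():
        tifs = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
        return _read_geotiff_stack(tifs, kind)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return _read_geotiff_stack([path], kind)
    return _read_netcdf(path, variable, kind)


def write_cube(cube: GridCube, path: str | Path, variable: str = "value",
               nodata: float = -9999.0) -> Path:
    """Write a cube to NetCDF (``.nc``) or a per-year GeoTIFF directory."""
    path = Path(path)
    if path.suffix.lower() == ".nc":
        path.parent.mkdir(parents=True, exist_ok=True)
        ds = cube.to_dataset(variable)
        ds.to_netcdf(path, engine="scipy")
        return path
    path.mkdir(parents=True, exist_ok=True)
    for i, year in enumerate(cube.years):
        _write_geotiff_band(
            path / f"{variable}_{year}.tif", cube.values[i], cube.grid, nodata
        )
    return path


def read_mask(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read a 0/1 single-band GeoTIFF mask as a boolean grid."""
    data, grid, nodata = _read_geotiff_band(Path(path))
    if nodata is not None:
        data = np.where(data == nodata, 0.0, data)
    return data > 0.5, grid


def write_mask(mask: np.ndarray, grid: GridSpec, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _write_geotiff_band(path, mask.astype(np.float64), grid, nodata=-1.0)
    return path


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def annual_from_composites(cube: CompositeCube,
                           min_coverage: float = 0.8) -> GridCube:
    """Aggregate sub-annual composites to annual means.

    Per pixel and year, the mean of non-missing composites; set to NaN when
    the fraction of non-missing composites in that year falls below
    ``min_coverage``.  A gap year (no composites at all between the first
    and last year) is a hard error.
    """
    years = cube.years
    _check_years(years)  # gap in the year sequence -> error naming the year
    layers = []
    for year in years:
        idx = [i for i, (y, _) in enumerate(cube.timestamps) if y == year]
        block = cube.values[idx]
        n_present = np.sum(np.isfinite(block), axis=0)
        coverage = n_present / block.shape[0]
        with np.errstate(invalid="ignore"):
            mean = np.where(
                n_present > 0, np.nanmean(np.where(np.isfinite(block), block, np.nan), axis=0), np.nan
            )
        mean = np.where(coverage >= min_coverage, mean, np.nan)
        layers.append(mean)
    return GridCube(np.stack(layers), years, cube.grid, kind="ndvi")


def resample_to(cube: GridCube, target: GridSpec,
                method: str = "bilinear") -> GridCube:
    """Resample a cube onto ``target`` (same CRS) by bilinear or nearest.

    Under bilinear, any NaN contributor makes the output cell NaN; target
    cells outside the source pixel-center hull are NaN.  Non-overlapping
    extents are a hard error.
    """
    if method not in {"bilinear", "nearest"}:
        raise ValueError(f"unknown method {method!r}")
    if cube.grid.approx_equals(target):
        return replace(cube, values=cube.values.copy(), grid=target)
    sw, ss, se, sn = cube.grid.bounds()
    tw, ts, te, tn = target.bounds()
    if te <= sw or tw >= se or tn <= ss or ts >= sn:
        raise ValueError("target grid does not overlap the source extent")

    src_lats = cube.grid.lats[::-1]  # ascending for the interpolator
    src_lons = cube.grid.lons
    tlon, tlat = target.lonlat_grids()
    points = np.column_stack([tlat.ravel(), tlon.ravel()])
    interp_method = "linear" if method == "bilinear" else "nearest"
    out = np.empty((cube.n_years,) + target.shape)
    for i in range(cube.n_years):
        itp = RegularGridInterpolator(
            (src_lats, src_lons),
            cube.values[i, ::-1, :],
            method=interp_method,
            bounds_error=False,
            fill_value=np.nan,
        )
        out[i] = itp(points).reshape(target.shape)
    return GridCube(out, list(cube.years), target, kind=cube.kind)


def apply_mask(cube: GridCube, mask: np.ndarray) -> GridCube:
    """Set cells where ``mask`` is False to NaN in every year."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.grid.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match grid {cube.grid.shape}"
        )
    values = np.where(mask[None, :, :], cube.values, np.nan)
    return replace(cube, values=values)
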