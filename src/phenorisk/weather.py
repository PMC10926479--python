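"""Gridded daily Tmin/Tmax: container, synthesis, I/O, and point extraction.

A :class:`DailyTemperatureGrid` holds one calendar year of daily minimum
and maximum temperature layers with simple georeferencing (GDAL-style
geotransform, row 0 = northernmost row).  :func:`synth_weather` generates
deterministic synthetic weather — a sinusoidal annual cycle with a
latitudinal gradient, diurnal range, and seeded Gaussian noise — so the
full pipeline can run without external climate downloads.
"""

from __future__ import annotations

import calendar
import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from phenorisk import raster

__all__ = [
    "DailyTemperatureGrid",
    "SyntheticWeatherConfig",
    "synth_weather",
    "read_daily_grids",
    "write_daily_grids",
    "extract_at_points",
]

Transform = tuple[float, float, float, float, float, float]

DEFAULT_TRANSFORM: Transform = (0.0, 1.0, 0.0, 0.0, 0.0, -1.0)


def year_dates(year: int) -> np.ndarray:
    start = np.datetime64(f"{year}-01-01", "D")
    ndays = 366 if calendar.isleap(year) else 365
    return start + np.arange(ndays).astype("timedelta64[D]")


@dataclasses.dataclass
class DailyTemperatureGrid:
    """One calendar year of daily Tmin/Tmax layers on a regular grid.

    ``tmin``/``tmax`` are (days, rows, cols) float arrays in °C; missing
    values are NaN.  ``missing_mask`` is True for any cell with at least
    one missing day; such cells are excluded from all downstream outputs.
    """

    tmin: np.ndarray
    tmax: np.ndarray
    dates: np.ndarray
    transform: Transform = DEFAULT_TRANSFORM
    crs: str = "EPSG:4326"
    missing_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.tmin = np.asarray(self.tmin, dtype=np.float64)
        self.tmax = np.asarray(self.tmax, dtype=np.float64)
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        if self.tmin.shape != self.tmax.shape or self.tmin.ndim != 3:
            raise ValueError(
                f"tmin/tmax must be matching (days, rows, cols) arrays, got "
                f"{self.tmin.shape} and {self.tmax.shape}"
            )
        year = self.year
        expected = 366 if calendar.isleap(year) else 365
        if self.tmin.shape[0] != expected or len(self.dates) != self.tmin.shape[0]:
            raise ValueError(
                f"expected {expected} day layers for year {year}, got "
                f"{self.tmin.shape[0]} layers / {len(self.dates)} dates"
            )
        absent = np.isnan(self.tmin).any(axis=0) | np.isnan(self.tmax).any(axis=0)
        if self.missing_mask is None:
            self.missing_mask = absent
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool) | absent
        ok = ~self.missing_mask[None, :, :]
        with np.errstate(invalid="ignore"):
            bad = (self.tmin > self.tmax) & ok
        if bad.any():
            idx = np.argwhere(bad)[:10]
            raise ValueError(f"tmin > tmax at (day, row, col) indices {idx.tolist()}")

    @property
    def year(self) -> int:
        return int(str(self.dates[0])[:4])

    @property
    def shape(self) -> tuple[int, int]:
        return self.tmin.shape[1:]

    @property
    def n_days(self) -> int:
        return self.tmin.shape[0]


@dataclasses.dataclass(frozen=True)
class SyntheticWeatherConfig:
    """Configuration for the synthetic weather generator."""

    shape: tuple[int, int] = (10, 10)
    base: float = 10.0  # annual-mean temperature at row 0, °C
    amplitude: float = 14.0  # seasonal half-range, °C
    peak_doy: int = 200  # day of year of the warm peak
    diurnal_range: float = 8.0  # tmax - tmin, °C
    gradient: float = 0.0  # cooling per row toward the south edge, °C/row
    noise_sd: float = 0.0
    seed: int = 0
    year: int = 2021
    transform: Transform = DEFAULT_TRANSFORM
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.diurnal_range < 0:
            raise ValueError("diurnal_range must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def synth_weather(cfg: SyntheticWeatherConfig) -> DailyTemperatureGrid:
    """Generate a deterministic synthetic :class:`DailyTemperatureGrid`.

    Daily means follow
    ``base - gradient*row + amplitude*cos(2*pi*(doy - peak)/365) + noise``;
    the diurnal range is applied after the noise, so ``tmin <= tmax``
    always holds.  The seasonal period is fixed at 365 days even in leap
    years (the one-day slippage is negligible at daily resolution).
    """
    rows, cols = cfg.shape
    dates = year_dates(cfg.year)
    ndays = len(dates)
    doy = np.arange(1, ndays + 1, dtype=float)
    seasonal = cfg.amplitude * np.cos(2.0 * np.pi * (doy - cfg.peak_doy) / 365.0)
    row_term = -cfg.gradient * np.arange(rows, dtype=float)
    tmean = cfg.base + seasonal[:, None, None] + row_term[None, :, None]
    tmean = np.broadcast_to(tmean, (ndays, rows, cols)).copy()
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        tmean += rng.normal(0.0, cfg.noise_sd, size=tmean.shape)
    half = 0.5 * cfg.diurnal_range
    return DailyTemperatureGrid(
        tmin=tmean - half,
        tmax=tmean + half,
        dates=dates,
        transform=cfg.transform,
        crs=cfg.crs,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_daily_grids(source, format: str) -> DailyTemperatureGrid:
    """Read a year of daily Tmin/Tmax data.

    Parameters
    ----------
    source
        For ``geotiff-stack``: ``(tmin_path, tmax_path)`` — paired
        multi-band files, one band per day.  For ``netcdf``: one file with
        ``tmin``/``tmax`` variables.  For ``site-csv``: a CSV with columns
        ``date,tmin,tmax`` covering one calendar year (yields a 1×1 grid).
    """
    if format == "geotiff-stack":
        tmin_path, tmax_path = source
        tmin, transform, crs, _, meta = raster.read_geotiff(tmin_path)
        tmax, transform2, _, _, _ = raster.read_geotiff(tmax_path)
        if tmin.shape != tmax.shape:
            raise ValueError(
                f"tmin stack {tmin.shape} and tmax stack {tmax.shape} differ"
            )
        if tuple(transform) != tuple(transform2):
            raise ValueError("tmin/tmax stacks have different geotransforms")
        year = int(meta["year"])
        return DailyTemperatureGrid(
            tmin=tmin, tmax=tmax, dates=year_dates(year), transform=transform, crs=crs
        )
    if format == "netcdf":
        arrays, transform, crs, dates, _ = raster.read_netcdf(source, ["tmin", "tmax"])
        return DailyTemperatureGrid(
            tmin=arrays["tmin"],
            tmax=arrays["tmax"],
            dates=dates,
            transform=transform,
            crs=crs,
        )
    if format == "site-csv":
        df = pd.read_csv(source, parse_dates=["date"])
        df = df.sort_values("date")
        dates = df["date"].to_numpy().astype("datetime64[D]")
        return DailyTemperatureGrid(
            tmin=df["tmin"].to_numpy()[:, None, None],
            tmax=df["tmax"].to_numpy()[:, None, None],
            dates=dates,
        )
    raise ValueError(f"unknown format {format!r}")


def write_daily_grids(grid: DailyTemperatureGrid, dest, format: str) -> None:
    """Inverse of :func:`read_daily_grids`; round-trips bit-exactly."""
    if format == "geotiff-stack":
        tmin_path, tmax_path = dest
        meta = {"year": grid.year}
        raster.write_geotiff(tmin_path, grid.tmin, grid.transform, grid.crs, meta=meta)
        raster.write_geotiff(tmax_path, grid.tmax, grid.transform, grid.crs, meta=meta)
        return
    if format == "netcdf":
        raster.write_netcdf(
            dest,
            {"tmin": grid.tmin, "tmax": grid.tmax},
            grid.transform,
            grid.crs,
            dates=grid.dates,
        )
        return
    if format == "site-csv":
        if grid.shape != (1, 1):
            raise ValueError("site-csv output requires a 1x1 grid")
        pd.DataFrame(
            {
                "date": grid.dates.astype("datetime64[s]"),
                "tmin": grid.tmin[:, 0, 0],
                "tmax": grid.tmax[:, 0, 0],
            }
        ).to_csv(dest, index=False)
        return
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Point extraction
# ---------------------------------------------------------------------------


def point_to_cell(
    lon: float, lat: float, transform: Transform, shape: tuple[int, int]
) -> tuple[int, int] | None:
    """Map a lon/lat point to its containing (row, col), or None if outside.

    Cell extents are half-open ``[x, x+dx) x (y-dy, y]``: points on a
    shared edge belong to the west/north cell.
    """
    x0, dx, _, y0, _, ndy = transform
    dy = -ndy
    col = int(np.floor((lon - x0) / dx))
    row = int(np.floor((y0 - lat) / dy))
    nrows, ncols = shape
    if not (0 <= row < nrows and 0 <= col < ncols):
        return None
    return row, col


def extract_at_points(
    values: np.ndarray, transform: Transform, coords
) -> np.ma.MaskedArray:
    """Nearest-cell value of a single-layer grid at each lon/lat point.

    Out-of-extent points are flagged (masked), never dropped, so output
    order and length match the input coordinate list.
    """
    values = np.asarray(values)
    out = np.full(len(coords), np.nan)
    outside = np.zeros(len(coords), dtype=bool)
    for i, (lon, lat) in enumerate(coords):
        cell = point_to_cell(lon, lat, transform, values.shape)
        if cell is None:
            outside[i] = True
        else:
            out[i] = values[cell]
    return np.ma.MaskedArray(out, mask=outside)
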