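"""Minimal GeoTIFF and NetCDF raster I/O.

GeoTIFFs are written with :mod:`tifffile`, embedding the standard
ModelPixelScale / ModelTiepoint GeoTIFF tags plus a JSON sidecar in the
ImageDescription tag (CRS string, band names, arbitrary metadata).  NetCDF
files use :mod:`netCDF4` with ``time``/``y``/``x`` dimensions.  Both paths
round-trip float arrays bit-exactly.

The geotransform follows the GDAL convention
``(x0, dx, 0, y0, 0, -dy)`` with row 0 the northernmost row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["write_geotiff", "read_geotiff", "write_netcdf", "read_netcdf"]

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


def write_geotiff(
    path: str | Path,
    data: np.ndarray,
    transform: tuple[float, float, float, float, float, float],
    crs: str = "EPSG:4326",
    band_names: list[str] | None = None,
    meta: dict | None = None,
) -> None:
    """Write a (bands, rows, cols) or (rows, cols) array as a GeoTIFF."""
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    x0, dx, _, y0, _, ndy = transform
    desc = {
        "crs": crs,
        "transform": list(transform),
        "band_names": band_names,
        "meta": meta or {},
    }
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (dx, -ndy, 0.0), True),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0), True),
    ]
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        planarconfig="separate" if data.shape[0] > 1 else None,
        description=json.dumps(desc, sort_keys=True),
        extratags=extratags,
    )


def read_geotiff(path: str | Path):
    """Read a GeoTIFF written by :func:`write_geotiff`.

    Returns ``(data, transform, crs, band_names, meta)`` with ``data`` of
    shape (bands, rows, cols).
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        page = tif.pages[0]
        desc_tag = page.tags.get("ImageDescription")
        desc = {}
        if desc_tag is not None:
            try:
                desc = json.loads(desc_tag.value)
            except (TypeError, json.JSONDecodeError):
                desc = {}
        transform = desc.get("transform")
        if transform is None:
            scale = page.tags.get(_MODEL_PIXEL_SCALE)
            tie = page.tags.get(_MODEL_TIEPOINT)
            if scale is not None and tie is not None:
                dx, dy, _ = scale.value
                _, _, _, x0, y0, _ = tie.value
                transform = [x0, dx, 0.0, y0, 0.0, -dy]
        if transform is None:
            raise ValueError(f"{path}: no georeferencing found")
    if data.ndim == 2:
        data = data[None]
    return (
        data,
        tuple(transform),
        desc.get("crs", "EPSG:4326"),
        desc.get("band_names"),
        desc.get("meta", {}),
    )


def write_netcdf(
    path: str | Path,
    arrays: dict[str, np.ndarray],
    transform: tuple[float, float, float, float, float, float],
    crs: str = "EPSG:4326",
    dates: np.ndarray | None = None,
    meta: dict | None = None,
) -> None:
    """Write named (time, y, x) arrays into one NetCDF file."""
    import netCDF4

    first = next(iter(arrays.values()))
    nt, ny, nx = first.shape
    x0, dx, _, y0, _, ndy = transform
    with netCDF4.Dataset(path, "w", format="NETCDF4") as ds:
        ds.createDimension("time", nt)
        ds.createDimension("y", ny)
        ds.createDimension("x", nx)
        ds.crs = crs
        ds.geotransform = json.dumps(list(transform))
        if meta:
            ds.meta = json.dumps(meta, sort_keys=True)
        xv = ds.createVariable("x", "f8", ("x",))
        yv = ds.createVariable("y", "f8", ("y",))
        xv[:] = x0 + dx * (np.arange(nx) + 0.5)
        yv[:] = y0 + ndy * (np.arange(ny) + 0.5)
        tv = ds.createVariable("time", "f8", ("time",))
        if dates is not None:
            dates = np.asarray(dates, dtype="datetime64[D]")
            epoch = dates[0]
            tv.units = f"days since {str(epoch)}"
            tv[:] = (dates - epoch).astype(float)
        else:
            tv.units = "days since start"
            tv[:] = np.arange(nt, dtype=float)
        for name, arr in arrays.items():
            v = ds.createVariable(name, "f8", ("time", "y", "x"))
            v[:] = np.asarray(arr, dtype=np.float64)


def read_netcdf(path: str | Path, names: list[str]):
    """Read named arrays plus georeferencing and dates back from NetCDF."""
    import netCDF4

    with netCDF4.Dataset(path, "r") as ds:
        arrays = {n: np.array(ds.variables[n][:], dtype=np.float64) for n in names}
        transform = tuple(json.loads(ds.geotransform))
        crs = getattr(ds, "crs", "EPSG:4326")
        meta = json.loads(ds.meta) if hasattr(ds, "meta") else {}
        tv = ds.variables["time"]
        dates = None
        units = getattr(tv, "units", "")
        if units.startswith("days since ") and units != "days since start":
            epoch = np.datetime64(units.removeprefix("days since "), "D")
            offsets = np.rint(np.asarray(tv[:], dtype=float)).astype(np.int64)
            dates = epoch + offsets.astype("timedelta64[D]")
    return arrays, transform, crs, dates, meta
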