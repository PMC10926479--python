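"""Closed-form daily degree-day and thermal stress-unit kernels.

All kernels model the diurnal temperature course as a triangle rising from
``tmin`` to ``tmax`` and back over a 24 h day ("single triangle" method).
The area of that curve above a horizontal line gives degree-days above a
threshold; development uses a second horizontal cutoff at the upper
developmental threshold.  All functions are NumPy ufunc-like: they accept
scalars or arrays and broadcast.
"""

from __future__ import annotations

import numpy as np

__all__ = ["single_triangle_dd", "cold_stress_units", "heat_stress_units"]


def _check_order(tmin, tmax) -> None:
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    bad = tmin > tmax
    if np.any(bad & ~np.isnan(tmin) & ~np.isnan(tmax)):
        idx = np.argwhere(np.atleast_1d(bad))
        raise ValueError(f"tmin > tmax at indices {idx[:10].tolist()}")


def _area_above(tmin, tmax, level):
    """Area (degree-days) of the daily triangle above a horizontal ``level``.

    Degenerate days (tmin == tmax) are treated as a constant temperature,
    contributing max(T - level, 0).
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    rng = tmax - tmin
    mean = 0.5 * (tmin + tmax)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        partial = (tmax - level) ** 2 / (2.0 * rng)
    area = np.where(
        tmax <= level,
        0.0,
        np.where(
            tmin >= level,
            mean - level,
            partial,
        ),
    )
    # constant-temperature day: triangle degenerates to a point
    const = np.maximum(mean - level, 0.0)
    area = np.where(rng < 1e-12, const, area)
    return area if area.ndim else float(area)


def _area_below(tmin, tmax, level):
    """Mirror image of :func:`_area_above`: area below ``level``."""
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    rng = tmax - tmin
    mean = 0.5 * (tmin + tmax)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        partial = (level - tmin) ** 2 / (2.0 * rng)
    area = np.where(
        tmin >= level,
        0.0,
        np.where(
            tmax <= level,
            level - mean,
            partial,
        ),
    )
    const = np.maximum(level - mean, 0.0)
    area = np.where(rng < 1e-12, const, area)
    return area if area.ndim else float(area)


def single_triangle_dd(tmin, tmax, ldt: float, udt: float):
    """Daily development degree-days, single triangle with upper cutoff.

    Returns the triangle area between the lower developmental threshold
    ``ldt`` and the horizontal cutoff at ``udt``; result lies in
    ``[0, udt - ldt]``.

    >>> round(single_triangle_dd(10, 20, 12.2, 36), 3)
    3.042
    """
    if not ldt < udt:
        raise ValueError(f"ldt ({ldt}) must be below udt ({udt})")
    _check_order(tmin, tmax)
    dd = np.clip(
        np.asarray(_area_above(tmin, tmax, ldt)) - np.asarray(_area_above(tmin, tmax, udt)),
        0.0,
        udt - ldt,
    )
    if np.ndim(tmin) == 0 and np.ndim(tmax) == 0:
        return float(dd)
    return dd


def cold_stress_units(tmin, tmax, threshold: float):
    """Daily cold stress units: triangle area below ``threshold`` (°C·day)."""
    _check_order(tmin, tmax)
    return _area_below(tmin, tmax, threshold)


def heat_stress_units(tmin, tmax, threshold: float):
    """Daily heat stress units: triangle area above ``threshold``, no cutoff."""
    _check_order(tmin, tmax)
    return _area_above(tmin, tmax, threshold)
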