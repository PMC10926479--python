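"""Climatic suitability: stress accumulation, exclusion classes, integration.

Cold and heat stress units (degree-days below/above the species stress
thresholds) are summed over the whole calendar year per cell.  Yearly
totals are classified on a three-level scale: ``0`` (no exclusion),
``-1`` (moderate exclusion, total exceeds the first limit) and ``-2``
(severe exclusion, total exceeds the second limit); totals exactly at a
limit are not excluded.  The combined class is the worse of the cold and
heat classes.  Class-0 cells constitute the potential distribution.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from phenorisk.degree_days import cold_stress_units, heat_stress_units
from phenorisk.params import SpeciesParams
from phenorisk.weather import DailyTemperatureGrid, Transform, extract_at_points
from phenorisk.phenology import EventMaps

__all__ = [
    "StressResult",
    "classify_stress",
    "accumulate_stress",
    "integrate_phenology_suitability",
    "multi_year_agreement",
    "presence_sensitivity",
    "longest_run_below",
]

# integration category codes (four-way map legend)
CAT_OK = 0
CAT_MODERATE = 1
CAT_SEVERE = 2
CAT_INSUFFICIENT = 3


def classify_stress(total: np.ndarray, max1: float, max2: float) -> np.ndarray:
    """Three-level exclusion class from a yearly stress-unit total.

    Strict inequality at both limits: a total exactly equal to a limit
    stays in the milder class.
    """
    total = np.asarray(total, float)
    cls = np.zeros(total.shape, dtype=np.int8)
    cls[total > max1] = -1
    cls[total > max2] = -2
    return cls


@dataclasses.dataclass
class StressResult:
    """Yearly stress-unit totals and exclusion classes per cell."""

    cold_total: np.ndarray
    heat_total: np.ndarray
    cold_class: np.ndarray  # int8 in {0, -1, -2}
    heat_class: np.ndarray
    combined_class: np.ndarray  # min(cold, heat): the worse severity
    missing_mask: np.ndarray
    transform: Transform
    crs: str = "EPSG:4326"


def accumulate_stress(temps: DailyTemperatureGrid, params: SpeciesParams) -> StressResult:
    """Accumulate daily cold/heat stress units over the year and classify.

    Stress accrues every day of the year, independent of life stage, with
    no daily cap.
    """
    cold = np.zeros(temps.shape)
    heat = np.zeros(temps.shape)
    for d in range(temps.n_days):
        cold += np.nan_to_num(
            cold_stress_units(temps.tmin[d], temps.tmax[d], params.coldstress_threshold)
        )
        heat += np.nan_to_num(
            heat_stress_units(temps.tmin[d], temps.tmax[d], params.heatstress_threshold)
        )
    masked = temps.missing_mask
    cold = np.where(masked, np.nan, cold)
    heat = np.where(masked, np.nan, heat)
    cold_cls = classify_stress(np.nan_to_num(cold), params.coldstress_units_max1, params.coldstress_units_max2)
    heat_cls = classify_stress(np.nan_to_num(heat), params.heatstress_units_max1, params.heatstress_units_max2)
    combined = np.minimum(cold_cls, heat_cls)
    for cls in (cold_cls, heat_cls, combined):
        cls[masked] = 0  # class content is meaningless under the mask
    return StressResult(
        cold_total=cold,
        heat_total=heat,
        cold_class=cold_cls,
        heat_class=heat_cls,
        combined_class=combined,
        missing_mask=masked,
        transform=temps.transform,
        crs=temps.crs,
    )


def integrate_phenology_suitability(events: EventMaps, stress: StressResult) -> dict:
    """Overlay event DOY maps on the exclusion classification.

    For each event, returns ``(doy, category)`` grids: the DOY is retained
    only where the combined class is 0 and the event occurred; the
    category grid carries the four-way legend (0 = dated, 1 = moderate
    exclusion, 2 = severe exclusion, 3 = insufficient accumulation).
    Missing cells are NaN / category -1.
    """
    if events.missing_mask.shape != stress.combined_class.shape:
        raise ValueError(
            f"grid mismatch: events {events.missing_mask.shape} vs "
            f"stress {stress.combined_class.shape}"
        )
    from phenorisk.phenology import EVENTS

    out = {}
    masked = events.missing_mask | stress.missing_mask
    for ev in EVENTS:
        doy = events.combined(ev)
        insufficient = events.insufficient_mask(ev)
        category = np.full(doy.shape, CAT_OK, dtype=np.int8)
        category[insufficient] = CAT_INSUFFICIENT
        category[stress.combined_class == -1] = CAT_MODERATE
        category[stress.combined_class == -2] = CAT_SEVERE
        category[masked] = -1
        dated = (category == CAT_OK) & ~np.isnan(doy)
        out[ev] = (np.where(dated, doy, np.nan), category)
    return out


def multi_year_agreement(stress_by_year: list[StressResult]) -> np.ndarray:
    """Count of years in which each cell is in the potential distribution.

    A cell counts for a year when its combined exclusion class is 0.
    Cells missing in any year are NaN.
    """
    if not stress_by_year:
        raise ValueError("need at least one year of stress results")
    shape = stress_by_year[0].combined_class.shape
    count = np.zeros(shape, float)
    missing = np.zeros(shape, bool)
    for sr in stress_by_year:
        if sr.combined_class.shape != shape:
            raise ValueError("stress results are not co-registered")
        count += sr.combined_class == 0
        missing |= sr.missing_mask
    return np.where(missing, np.nan, count)


def presence_sensitivity(
    records: list[tuple[float, float]],
    stress: StressResult,
    mode: str = "both-levels",
) -> dict:
    """Fraction of presence records falling in cells modeled as included.

    ``both-levels``: included means combined class 0; ``severe-only``: the
    conservative option, included means class >= -1 (not severely
    excluded).  Out-of-extent records are reported separately and excluded
    from the denominator.
    """
    if not records:
        raise ValueError("empty presence-record list")
    if mode not in ("both-levels", "severe-only"):
        raise ValueError(f"unknown mode {mode!r}")
    cls = extract_at_points(stress.combined_class.astype(float), stress.transform, records)
    inside = ~cls.mask
    threshold = 0 if mode == "both-levels" else -1
    included = np.zeros(len(records), bool)
    included[inside] = cls.data[inside] >= threshold
    n_inside = int(inside.sum())
    return {
        "sensitivity": float(included[inside].mean()) if n_inside else float("nan"),
        "n_records": len(records),
        "n_inside": n_inside,
        "n_included": int(included[inside].sum()),
        "included": included,
        "outside": ~inside,
    }


def longest_run_below(tmin_series: np.ndarray, threshold: float) -> int:
    """Longest run of consecutive days with tmin below a threshold.

    Diagnostic helper (e.g. for exploring cold-stress limits); plays no
    part in the exclusion classification.
    """
    below = np.asarray(tmin_series) < threshold
    best = run = 0
    for b in below:
        run = run + 1 if b else 0
        best = max(best, run)
    return best
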