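"""Daily time-step, cohort-structured life-cycle simulation.

Each cohort starts 1 January as an overwintered J-larva (stage ``OL``) and
advances through pupa, adult, egg, and larva as degree-days accumulate
under the current stage's thresholds.  Five phenological events are
recorded, one per stage transition:

======================  =====================================  ==============
event                   trigger                                requirement
======================  =====================================  ==============
pupation                OL completes development               per-cohort
adult_emergence         pupal requirement met                  pupaeEventDD
oviposition             adult accrues its egg-laying offset    adultEventDD
egg_hatch               egg requirement met                    eggEventDD
jlarval_formation       larval requirement met                 larvaeEventDD
======================  =====================================  ==============

Event requirements chain: each is measured from the previous event, so at a
constant 10 DD/day with a 200-DD cohort the cumulative thresholds are
200/335/407/579/1279 and the event days are 20/34/41/58/128.  Excess
degree-days on a transition day are carried into the next stage.  With
obligate diapause the trajectory ends the year at J-larval formation
(univoltine: no second generation).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from phenorisk.degree_days import single_triangle_dd
from phenorisk.params import SpeciesParams
from phenorisk.weather import DailyTemperatureGrid
from phenorisk.cohorts import CohortSet

__all__ = [
    "EVENTS",
    "STAGE_CODES",
    "CohortTrajectoryGrid",
    "EventMaps",
    "run_cohort",
    "run_all_cohorts",
    "stage_snapshot",
]

#: The five phenological events, in life-cycle order.
EVENTS = ("pupation", "adult_emergence", "oviposition", "egg_hatch", "jlarval_formation")

#: Simulation stage codes in order; index 5 is the terminal (diapause) state.
STAGE_CODES = ("OL", "P", "A", "E", "L", "DONE")

#: Events whose cohort-combined map is conventionally the earliest DOY
#: (oviposition is conventionally combined as a weighted average).
FIRST_EVENTS = ("pupation", "adult_emergence", "egg_hatch")

# stage code -> event recorded when the stage's requirement is met
_STAGE_EVENT = {
    "OL": "pupation",
    "P": "adult_emergence",
    "A": "oviposition",
    "E": "egg_hatch",
    "L": "jlarval_formation",
}


def _stage_requirement(params: SpeciesParams, stage: str, completion_dd: float) -> float:
    return {
        "OL": completion_dd,
        "P": params.pupae_event_dd,
        "A": params.adult_event_dd,
        "E": params.egg_event_dd,
        "L": params.larvae_event_dd,
    }[stage]


@dataclasses.dataclass
class CohortTrajectoryGrid:
    """End-of-year state of one cohort on every grid cell.

    ``events`` maps event name to a float DOY grid (NaN = never reached);
    ``stage_index`` is the final stage (0..5 into :data:`STAGE_CODES`);
    ``cum_dd`` is the annual degree-day total accumulated under the
    per-stage thresholds; ``within_dd`` the unused remainder in the final
    stage.
    """

    events: dict[str, np.ndarray]
    stage_index: np.ndarray
    cum_dd: np.ndarray
    within_dd: np.ndarray
    completion_dd: float
    missing_mask: np.ndarray

    def stage_on(self, doy: int) -> np.ndarray:
        """Stage index occupied on a given day, reconstructed from events."""
        shape = self.stage_index.shape
        idx = np.zeros(shape, dtype=np.int8)
        for i, ev in enumerate(EVENTS):
            d = self.events[ev]
            idx = np.where(~np.isnan(d) & (d <= doy), i + 1, idx)
        return idx


def run_cohort(
    temps: DailyTemperatureGrid, params: SpeciesParams, completion_dd: float
) -> CohortTrajectoryGrid:
    """Simulate one cohort over the year, per cell.

    ``completion_dd`` is the cohort's overwintering (J-larval) completion
    requirement and must fall within ``[xdist1, xdist2]``.
    """
    if not (params.xdist1 <= completion_dd <= params.xdist2):
        raise ValueError(
            f"completion_dd {completion_dd} outside "
            f"[{params.xdist1}, {params.xdist2}]"
        )
    order = params.stgorder  # permutation of OL,P,A,E,L starting at OL
    reqs = [_stage_requirement(params, code, completion_dd) for code in order]
    thresholds = [params.stage_thresholds(code) for code in order]
    n_stages = len(order)

    shape = temps.shape
    masked = temps.missing_mask
    stage = np.zeros(shape, dtype=np.int8)
    within = np.zeros(shape)
    cum = np.zeros(shape)
    events = {ev: np.full(shape, np.nan) for ev in EVENTS}

    for d in range(temps.n_days):
        doy = d + 1
        tmin_d = temps.tmin[d]
        tmax_d = temps.tmax[d]
        active = (stage < n_stages) & ~masked
        if not active.any():
            break
        # degree-days under each active stage's thresholds
        for si in range(n_stages):
            sel = active & (stage == si)
            if not sel.any():
                continue
            ldt, udt = thresholds[si]
            dd = single_triangle_dd(tmin_d[sel], tmax_d[sel], ldt, udt)
            within[sel] += dd
            cum[sel] += dd
        # transitions (ascending, so one day's surplus can cascade);
        # the 1e-9 guard keeps exact-threshold days from slipping a day
        # through binary rounding of the temperature arithmetic
        for si in range(n_stages):
            done = active & (stage == si) & (within >= reqs[si] - 1e-9)
            if not done.any():
                continue
            ev = _STAGE_EVENT[order[si]]
            events[ev][done] = doy
            within[done] -= reqs[si]
            stage[done] += 1

    for ev in EVENTS:
        events[ev][masked] = np.nan
    cum = np.where(masked, np.nan, cum)
    within = np.where(masked, np.nan, within)
    return CohortTrajectoryGrid(
        events=events,
        stage_index=stage,
        cum_dd=cum,
        within_dd=within,
        completion_dd=completion_dd,
        missing_mask=masked,
    )


@dataclasses.dataclass
class EventMaps:
    """Per-cohort and cohort-combined event day-of-year grids.

    ``per_cohort[ev]`` has shape (n_cohorts, rows, cols); cohort order
    follows the :class:`~phenorisk.cohorts.CohortSet` (ascending completion
    requirement).  Combined grids renormalize weights over the cohorts that
    actually reached the event.
    """

    per_cohort: dict[str, np.ndarray]
    weights: np.ndarray
    missing_mask: np.ndarray

    def first(self, event: str) -> np.ndarray:
        """Earliest DOY across cohorts (NaN where no cohort reached it)."""
        import warnings

        stack = self.per_cohort[event]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmin(stack, axis=0)

    def weighted_average(self, event: str) -> np.ndarray:
        """Cohort-weight-weighted mean DOY over cohorts reaching the event."""
        stack = self.per_cohort[event]
        w = self.weights[:, None, None] * ~np.isnan(stack)
        wsum = w.sum(axis=0)
        with np.errstate(invalid="ignore"):
            avg = np.nansum(stack * w, axis=0) / wsum
        return np.where(wsum > 0, avg, np.nan)

    def weighted_median(self, event: str) -> np.ndarray:
        """Earliest DOY by which cohorts holding >= 50% of total weight
        have reached the event (NaN if that never happens)."""
        stack = self.per_cohort[event]  # cohorts ordered by completion req
        reached = ~np.isnan(stack)
        cumw = np.cumsum(self.weights[:, None, None] * reached, axis=0)
        hit = cumw >= 0.5
        any_hit = hit.any(axis=0)
        k = np.argmax(hit, axis=0)
        med = np.take_along_axis(stack, k[None], axis=0)[0]
        return np.where(any_hit, med, np.nan)

    def insufficient_mask(self, event: str) -> np.ndarray:
        """True where no cohort reached the event (excluding missing cells)."""
        none = np.isnan(self.per_cohort[event]).all(axis=0)
        return none & ~self.missing_mask

    def combined(self, event: str) -> np.ndarray:
        """The conventional combined map: earliest DOY for pupation, adult
        emergence, and egg hatch; weighted average for oviposition and
        J-larval formation."""
        if event in FIRST_EVENTS:
            return self.first(event)
        return self.weighted_average(event)


def run_all_cohorts(
    temps: DailyTemperatureGrid, params: SpeciesParams, cohorts: CohortSet
) -> EventMaps:
    """Run every cohort and assemble combined event maps."""
    per_cohort = {ev: np.empty((cohorts.n, *temps.shape)) for ev in EVENTS}
    for i, completion in enumerate(cohorts.completion_dd):
        traj = run_cohort(temps, params, float(completion))
        for ev in EVENTS:
            per_cohort[ev][i] = traj.events[ev]
    return EventMaps(
        per_cohort=per_cohort,
        weights=cohorts.weights.copy(),
        missing_mask=temps.missing_mask.copy(),
    )


def stage_snapshot(
    trajectories: list[CohortTrajectoryGrid],
    weights: np.ndarray,
    doy: int,
    n_days: int = 365,
) -> dict:
    """Per-cell life-stage summary on a given day of year.

    Returns a dict with ``stage_index`` (n_cohorts, rows, cols),
    ``occupied`` (rows, cols set-encoded as a 6-bit mask over
    :data:`STAGE_CODES`), ``dominant`` (weight-dominant stage index), and
    ``generations`` (0 before any cohort forms J-larvae, 1 after).
    """
    if not 1 <= doy <= n_days:
        raise ValueError(f"doy {doy} outside the modeled year (1..{n_days})")
    weights = np.asarray(weights, float)
    stages = np.stack([t.stage_on(doy) for t in trajectories])
    occupied = np.zeros(stages.shape[1:], dtype=np.uint8)
    wsum = np.zeros((len(STAGE_CODES), *stages.shape[1:]))
    for si in range(len(STAGE_CODES)):
        present = (stages == si).any(axis=0)
        occupied |= (present.astype(np.uint8)) << si
        wsum[si] = (weights[:, None, None] * (stages == si)).sum(axis=0)
    dominant = wsum.argmax(axis=0).astype(np.int8)
    jform = np.stack([t.events["jlarval_formation"] for t in trajectories])
    generations = ((~np.isnan(jform)) & (jform <= doy)).any(axis=0).astype(np.int8)
    return {
        "stage_index": stages,
        "occupied": occupied,
        "dominant": dominant,
        "generations": generations,
    }
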