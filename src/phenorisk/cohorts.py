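"""Time-distributed overwintering cohorts and their calibration.

Within-population variation in the degree-days required for the
overwintered J-larva to complete development is represented by a lognormal
distribution (arithmetic mean ``distro_mean``, variance ``distro_var``)
truncated to ``[xdist1, xdist2]``.  The truncated density is partitioned
into ``n_cohorts`` equal-width bins; each cohort carries the bin's
probability mass (renormalized over the truncation window) as its weight
and the density-weighted mean of the bin as its completion requirement.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy import stats as sps

from phenorisk.params import SpeciesParams

__all__ = ["CohortSet", "make_cohorts", "calibrate_cohort_params"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class CohortSet:
    """Per-cohort completion degree-days and relative population weights."""

    completion_dd: np.ndarray  # strictly increasing, degree-days C
    weights: np.ndarray  # > 0, sum to 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "completion_dd", np.asarray(self.completion_dd, float))
        object.__setattr__(self, "weights", np.asarray(self.weights, float))
        if self.completion_dd.shape != self.weights.shape or self.completion_dd.ndim != 1:
            raise ValueError("completion_dd and weights must be matching 1-D arrays")
        if not np.all(np.diff(self.completion_dd) > 0):
            raise ValueError("completion_dd must be strictly increasing across cohorts")
        if not np.all(self.weights > 0):
            raise ValueError("cohort weights must be positive")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"cohort weights must sum to 1, got {self.weights.sum()!r}")

    @property
    def n(self) -> int:
        return len(self.weights)


def _lognormal(mean: float, var: float) -> sps.rv_continuous:
    """Lognormal with the given *arithmetic* mean and variance."""
    sigma2 = math.log(1.0 + var / mean**2)
    mu = math.log(mean) - sigma2 / 2.0
    return sps.lognorm(s=math.sqrt(sigma2), scale=math.exp(mu))


def _partial_mean(dist, mu: float, sigma2: float, a: float, b: float) -> float:
    """Closed-form ∫_a^b x f(x) dx for the lognormal (untruncated density)."""
    sigma = math.sqrt(sigma2)
    amean = math.exp(mu + sigma2 / 2.0)
    lo = (math.log(a) - mu - sigma2) / sigma if a > 0 else -math.inf
    hi = (math.log(b) - mu - sigma2) / sigma
    return amean * (sps.norm.cdf(hi) - sps.norm.cdf(lo))


def make_cohorts(params: SpeciesParams, n: int | None = None) -> CohortSet:
    """Build the cohort set implied by a species parameter file.

    Equal-width bins over ``[xdist1, xdist2]``; cohort weight is the bin's
    share of the truncated probability mass and the completion requirement
    is the density-weighted mean within the bin.
    """
    n = params.n_cohorts if n is None else n
    mean, var = params.distro_mean, params.distro_var
    x1, x2 = params.xdist1, params.xdist2
    sigma2 = math.log(1.0 + var / mean**2)
    mu = math.log(mean) - sigma2 / 2.0
    dist = _lognormal(mean, var)

    total_mass = dist.cdf(x2) - dist.cdf(x1)
    if total_mass < 1e-6:
        raise ValueError(
            f"lognormal(mean={mean}, var={var}) places mass {total_mass:.2e} "
            f"in [{x1}, {x2}]; truncation window is incompatible"
        )
    edges = np.linspace(x1, x2, n + 1)
    cdf = dist.cdf(edges)
    masses = np.diff(cdf)
    weights = masses / total_mass
    completion = np.empty(n)
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        if masses[i] <= 0:
            completion[i] = 0.5 * (a + b)  # empty bin: midpoint fallback
        else:
            completion[i] = _partial_mean(dist, mu, sigma2, a, b) / masses[i]
    # guard against zero-mass bins breaking CohortSet invariants
    keep = weights > 1e-12
    return CohortSet(completion_dd=completion[keep], weights=weights[keep] / weights[keep].sum())


def calibrate_cohort_params(
    observed: list[tuple[str, float, float]],
    site_weather: dict,
    candidate_grid: list[tuple[float, float, float, float]],
    params: SpeciesParams,
) -> list[dict]:
    """Rank candidate cohort-distribution parameters by combined MAE.

    Parameters
    ----------
    observed
        ``(site_year_key, first_emergence_doy, peak_emergence_doy)`` rows;
        either DOY may be NaN if unobserved.
    site_weather
        Mapping from ``site_year_key`` to a 1×1 (or larger)
        :class:`~phenorisk.weather.DailyTemperatureGrid`.
    candidate_grid
        ``(xdist1, distro_mean, xdist2, distro_var)`` tuples.  Candidates
        violating ``xdist1 < mean < xdist2`` are skipped with a warning.
    params
        Base species parameters; the cohort-distribution fields are
        overridden per candidate.

    Returns
    -------
    list of dict sorted ascending by combined MAE, each with keys
    ``candidate``, ``mae_first``, ``mae_peak``, ``combined_mae``.
    """
    from phenorisk.phenology import run_all_cohorts

    if not candidate_grid:
        raise ValueError("candidate grid is empty")
    missing = [key for key, *_ in observed if key not in site_weather]
    if missing:
        raise ValueError(f"no weather provided for site-years: {missing}")

    results = []
    for cand in candidate_grid:
        x1, mean, x2, var = cand
        if not (x1 < mean < x2) or var <= 0:
            logger.warning("skipping invalid cohort candidate %s", cand)
            continue
        p = params.replace(xdist1=x1, distro_mean=mean, xdist2=x2, distro_var=var)
        cohorts = make_cohorts(p)
        err_first, err_peak = [], []
        for key, obs_first, obs_peak in observed:
            events = run_all_cohorts(site_weather[key], p, cohorts)
            pred_first = float(events.first("adult_emergence")[0, 0])
            pred_peak = float(events.weighted_median("adult_emergence")[0, 0])
            if obs_first is not None and not np.isnan(obs_first):
                err_first.append(abs(pred_first - obs_first))
            if obs_peak is not None and not np.isnan(obs_peak):
                err_peak.append(abs(pred_peak - obs_peak))
        mae_first = float(np.mean(err_first)) if err_first else math.nan
        mae_peak = float(np.mean(err_peak)) if err_peak else math.nan
        combined = np.nansum([mae_first, mae_peak])
        results.append(
            {
                "candidate": tuple(cand),
                "mae_first": mae_first,
                "mae_peak": mae_peak,
                "combined_mae": float(combined),
            }
        )
    results.sort(key=lambda r: r["combined_mae"])
    return results
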