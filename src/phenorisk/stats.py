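"""Model-evaluation statistics: error summaries and TOST equivalence.

Differences are predicted − observed throughout (negative bias = model
predicts too early).  Equivalence follows the two one-sided tests (TOST)
procedure on a Welch two-sample comparison of means: the predicted and
observed samples are declared equivalent within ±delta when both
one-sided 95% confidence bounds of the mean difference lie strictly
inside the interval.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats as sps

__all__ = ["ErrorSummary", "EquivalenceResult", "error_summary", "tost_equivalence"]


@dataclasses.dataclass(frozen=True)
class ErrorSummary:
    """MAE / bias / SD / range of predicted − observed differences (days)."""

    n_obs: int
    mae: float
    bias: float
    sd: float  # sample (n-1) SD; NaN for a single pair
    range_low: float
    range_high: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class EquivalenceResult:
    """TOST verdict for a mean difference against an equivalence half-width."""

    mean_difference: float
    ci_low: float
    ci_high: float
    delta: float
    equivalent: bool
    degrees_of_freedom: float
    p_lower: float  # H0: difference <= -delta
    p_upper: float  # H0: difference >= +delta

    @property
    def p_tost(self) -> float:
        return max(self.p_lower, self.p_upper)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def error_summary(predicted, observed) -> ErrorSummary:
    """Summary statistics of paired predicted vs observed day-of-year lists."""
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ValueError(
            f"predicted and observed must be matching 1-D lists, got "
            f"{predicted.shape} and {observed.shape}"
        )
    if len(predicted) < 1:
        raise ValueError("need at least one pair")
    diff = predicted - observed
    sd = float(np.std(diff, ddof=1)) if len(diff) > 1 else math.nan
    return ErrorSummary(
        n_obs=len(diff),
        mae=float(np.mean(np.abs(diff))),
        bias=float(np.mean(diff)),
        sd=sd,
        range_low=float(diff.min()),
        range_high=float(diff.max()),
    )


def _welch(predicted: np.ndarray, observed: np.ndarray):
    n1, n2 = len(predicted), len(observed)
    v1, v2 = np.var(predicted, ddof=1), np.var(observed, ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        raise ValueError("both samples have zero variance; TOST is degenerate")
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return math.sqrt(se2), df


def tost_equivalence(
    predicted,
    observed,
    delta: float,
    alpha: float = 0.05,
    paired: bool = False,
) -> EquivalenceResult:
    """Two one-sided tests for equivalence of means within ±``delta`` days.

    Default is the two-sample Welch formulation (unequal variances, with
    Welch–Satterthwaite degrees of freedom); set ``paired=True`` for a
    paired-differences test.  The one-sided confidence bounds are at level
    ``1 - alpha`` each (jointly a 90% two-sided interval for the default
    alpha); equivalence requires ``-delta < ci_low`` and ``ci_high < delta``
    with strict inequalities.
    """
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    if len(predicted) < 2 or len(observed) < 2:
        raise ValueError("TOST requires n >= 2 in both samples")
    if delta <= 0:
        raise ValueError("delta must be positive")
    if paired:
        if predicted.shape != observed.shape:
            raise ValueError("paired test requires matching lengths")
        d = predicted - observed
        n = len(d)
        v = np.var(d, ddof=1)
        if v == 0:
            raise ValueError("paired differences have zero variance; TOST is degenerate")
        se = math.sqrt(v / n)
        df = float(n - 1)
        diff = float(np.mean(d))
    else:
        se, df = _welch(predicted, observed)
        diff = float(np.mean(predicted) - np.mean(observed))
    tcrit = sps.t.ppf(1 - alpha, df)
    ci_low = diff - tcrit * se
    ci_high = diff + tcrit * se
    p_lower = float(sps.t.sf((diff + delta) / se, df))
    p_upper = float(sps.t.cdf((diff - delta) / se, df))
    return EquivalenceResult(
        mean_difference=diff,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        delta=float(delta),
        equivalent=bool(-delta < ci_low and ci_high < delta),
        degrees_of_freedom=float(df),
        p_lower=p_lower,
        p_upper=p_upper,
    )
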