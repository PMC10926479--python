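"""Mann-Kendall monotone-trend testing, scalar and per-pixel.

The test statistic is ``S = sum_{i<j} sign(x_j - x_i)`` with the
tie-corrected variance, Kendall's tau-b effect size, and a
continuity-corrected normal approximation for the p-value.  Trends are
flagged significant at p <= 0.1 (the conventional level for short,
low-power environmental time series).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as sps

__all__ = ["TrendResult", "mann_kendall", "trend_map"]

SIGNIFICANCE_LEVEL = 0.1


@dataclasses.dataclass(frozen=True)
class TrendResult:
    """Outcome of a Mann-Kendall test on one yearly series."""

    n: int
    S: float
    var_S: float
    tau: float  # Kendall tau-b (tie-adjusted)
    z: float
    p: float
    significant: bool
    computable: bool = True

    @staticmethod
    def not_computable(n: int) -> "TrendResult":
        return TrendResult(
            n=n, S=np.nan, var_S=np.nan, tau=np.nan, z=np.nan, p=np.nan,
            significant=False, computable=False,
        )


def mann_kendall(series) -> TrendResult:
    """Mann-Kendall trend test of an ordered yearly series.

    Missing (NaN) years are dropped; fewer than 3 remaining values yields
    a flagged not-computable result rather than an exception.

    >>> mann_kendall([1, 2, 3, 4, 5]).S
    10.0
    """
    x = np.asarray(series, float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 3:
        return TrendResult.not_computable(n)

    diff = np.sign(x[None, :] - x[:, None])
    S = float(np.triu(diff, k=1).sum())

    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_S = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0

    n0 = n * (n - 1) / 2.0
    t_adj = np.sum(ties * (ties - 1)) / 2.0
    denom = np.sqrt((n0 - t_adj) * n0)  # time axis has no ties
    tau = S / denom if denom > 0 else 0.0

    if var_S > 0 and S > 0:
        z = (S - 1) / np.sqrt(var_S)
    elif var_S > 0 and S < 0:
        z = (S + 1) / np.sqrt(var_S)
    else:
        z = 0.0
    p = float(2.0 * sps.norm.sf(abs(z)))
    return TrendResult(
        n=n,
        S=S,
        var_S=float(var_S),
        tau=float(tau),
        z=float(z),
        p=p,
        significant=bool(p <= SIGNIFICANCE_LEVEL),
    )


def trend_map(stack, flip_sign: bool = False) -> dict:
    """Per-pixel Mann-Kendall test over co-registered yearly grids.

    Parameters
    ----------
    stack
        Sequence of >= 3 yearly (rows, cols) grids, or one
        (years, rows, cols) array.  Pixels with a missing (NaN) value in
        any year are masked.
    flip_sign
        Negate values before testing — used for exclusion-class stacks
        (classes 0/−1/−2 become 0/1/2) so a decreasing trend reads as
        decreasing stress.

    Returns
    -------
    dict with ``tau``, ``p``, ``z`` grids, a boolean ``significant`` mask,
    a ``no_trend`` mask (S == 0), and the ``masked`` missing-data mask.
    """
    arr = np.asarray(stack, float)
    if arr.ndim != 3:
        raise ValueError(f"expected a (years, rows, cols) stack, got shape {arr.shape}")
    if arr.shape[0] < 3:
        raise ValueError(f"need >= 3 yearly layers, got {arr.shape[0]}")
    if flip_sign:
        arr = -arr
    ny, rows, cols = arr.shape
    masked = np.isnan(arr).any(axis=0)
    tau = np.full((rows, cols), np.nan)
    p = np.full((rows, cols), np.nan)
    z = np.full((rows, cols), np.nan)
    no_trend = np.zeros((rows, cols), bool)
    sig = np.zeros((rows, cols), bool)
    for r in range(rows):
        for c in range(cols):
            if masked[r, c]:
                continue
            res = mann_kendall(arr[:, r, c])
            tau[r, c] = res.tau
            p[r, c] = res.p
            z[r, c] = res.z
            no_trend[r, c] = res.S == 0
            sig[r, c] = res.significant
    return {
        "tau": tau,
        "p": p,
        "z": z,
        "significant": sig,
        "no_trend": no_trend,
        "masked": masked,
    }
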