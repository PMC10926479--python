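"""PNG summary-map rendering with fixed, documented color classes.

Colors are constant across runs so maps remain comparable: event dates use
a viridis gradient; moderate exclusion is medium gray, severe exclusion
dark gray, insufficient degree-day accumulation light gray, and missing
data white.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib import colors as mcolors
from matplotlib.patches import Patch

__all__ = ["render_event_map", "render_trend_map", "render_scatter"]

COL_MODERATE = "#969696"
COL_SEVERE = "#525252"
COL_INSUFFICIENT = "#d9d9d9"
COL_NOTREND = "#d9d9d9"


def render_event_map(
    doy: np.ndarray, category: np.ndarray, path: str | Path, title: str = ""
) -> None:
    """Render an integrated event map with the four-way legend."""
    fig, ax = plt.subplots(figsize=(7, 5))
    base = np.full((*doy.shape, 3), 1.0)  # missing stays white
    cmap = plt.get_cmap("viridis")
    finite = np.isfinite(doy)
    if finite.any():
        norm = mcolors.Normalize(np.nanmin(doy), max(np.nanmax(doy), np.nanmin(doy) + 1))
        base[finite] = cmap(norm(doy[finite]))[:, :3]
        sm = plt.cm.ScalarMappable(norm=norm, cmap=cmap)
        fig.colorbar(sm, ax=ax, label="day of year", shrink=0.8)
    for code, col in ((1, COL_MODERATE), (2, COL_SEVERE), (3, COL_INSUFFICIENT)):
        base[category == code] = mcolors.to_rgb(col)
    ax.imshow(base, interpolation="nearest")
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.legend(
        handles=[
            Patch(color=COL_MODERATE, label="excl.-moderate"),
            Patch(color=COL_SEVERE, label="excl.-severe"),
            Patch(color=COL_INSUFFICIENT, label="insufficient accumulation"),
        ],
        loc="lower left",
        fontsize=7,
    )
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_trend_map(tau: np.ndarray, significant: np.ndarray, no_trend: np.ndarray,
                     path: str | Path, title: str = "") -> None:
    """Render a tau map (diverging) with a significance panel."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    cmap = plt.get_cmap("RdBu_r")
    norm = mcolors.Normalize(-1, 1)
    base = np.full((*tau.shape, 3), 1.0)
    finite = np.isfinite(tau)
    base[finite] = cmap(norm(tau[finite]))[:, :3]
    base[no_trend] = mcolors.to_rgb(COL_NOTREND)
    axes[0].imshow(base, interpolation="nearest")
    axes[0].set_title(f"{title} tau")
    sigimg = np.full((*tau.shape, 3), 1.0)
    sigimg[finite] = mcolors.to_rgb("#f0f0f0")
    sigimg[significant] = mcolors.to_rgb("#7a0177")
    axes[1].imshow(sigimg, interpolation="nearest")
    axes[1].set_title("significant (p ≤ 0.1)")
    for ax in axes:
        ax.set_xticks([])
        ax.set_yticks([])
    fig.colorbar(plt.cm.ScalarMappable(norm=norm, cmap=cmap), ax=axes[0], shrink=0.8)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_scatter(predicted, observed, path: str | Path, title: str = "") -> None:
    """Predicted vs observed scatter with a 1:1 line."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(observed, predicted, s=18, alpha=0.8)
    lo = min(np.min(observed), np.min(predicted))
    hi = max(np.max(observed), np.max(predicted))
    ax.plot([lo, hi], [lo, hi], color="0.4", lw=1)
    ax.set_xlabel("observed DOY")
    ax.set_ylabel("predicted DOY")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
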