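"""Quick-look PNG plots written beside the pipeline's CSV outputs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cytometry import TMR_CATEGORIES, BinGrid
from .frap import RecoveryCurve


def plot_recovery(curve: RecoveryCurve, path: str | Path,
                  title: str = "FRAP relative recovery") -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.plot(curve.times, curve.relative_recovery, "o-", ms=3)
    ax.set_xlabel("time after bleach (min)")
    ax.set_ylabel("relative recovery")
    ax.set_title(title)
    ax.set_ylim(0, max(1.05, curve.relative_recovery.max() * 1.05))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bin_grid(grid: BinGrid, path: str | Path) -> None:
    """Inclusion fraction vs expression bin, one line per modifier category."""
    fig, ax = plt.subplots(figsize=(5, 3.4))
    centers = np.sqrt(grid.cerulean_edges[:-1] * grid.cerulean_edges[1:])
    for j, cat in enumerate(TMR_CATEGORIES):
        frac = grid.fraction[:, j]
        ok = grid.counts[:, j] > 0
        ax.plot(centers[ok], frac[ok], "o-", ms=3, label=cat)
    ax.set_xscale("log")
    ax.set_xlabel("cerulean pulse area (a.u.)")
    ax.set_ylabel("fraction of cells with inclusions")
    ax.set_title(grid.construct)
    ax.legend(title="modifier", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
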