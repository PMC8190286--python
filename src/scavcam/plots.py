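"""Optional figure helpers. Analysis outputs are files-first; these
render the two standard displays from already-computed results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .activity import ActivityDensity
from .events import PeriEventHistogram

HOURS = np.arange(0, 25, 6)


def plot_activity_densities(densities: dict[str, ActivityDensity], path: str | Path) -> Path:
    """Diel activity densities for each group on one 24-h axis."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for label, d in densities.items():
        hours = d.grid / (2 * np.pi) * 24.0
        ax.plot(hours, d.density, label=label.replace("_", " "))
    ax.set_xticks(HOURS)
    ax.set_xlim(0, 24)
    ax.set_xlabel("Time of day (h)")
    ax.set_ylabel("Density")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_peri_event_histogram(hist: PeriEventHistogram, path: str | Path) -> Path:
    """Subordinate-species image counts around dominant-species presence."""
    fig, ax = plt.subplots(figsize=(7, 4))
    centers = (hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2.0
    width = float(hist.bin_edges[1] - hist.bin_edges[0])
    ax.bar(centers, hist.counts, width=width * 0.9, color="0.4")
    ax.axvline(0.0, linestyle="--", color="k")
    ax.set_xlabel("Minutes relative to presence (before arrival | after departure)")
    ax.set_ylabel("Image count")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
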