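"""Simple figure helpers: rate-vs-level fits and trajectory curves."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def plot_rate_fit(slopes, rate_function, path: str | Path, truth_rate=None):
    """Scatter of interval slopes with the fitted rate curve overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(slopes["level"], slopes["rate"], s=6, alpha=0.3, label="interval slopes")
    grid = np.linspace(*rate_function.domain, 300)
    ax.plot(grid, rate_function(grid), color="C1", lw=2, label="penalized spline")
    if truth_rate is not None:
        ax.plot(grid, truth_rate(grid), color="k", ls="--", lw=1, label="ground truth")
    ax.set_xlabel("SUVR")
    ax.set_ylabel("rate (SUVR/year)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trajectories(curves: dict, path: str | Path, landmarks: dict | None = None):
    """Overlay per-stratum trajectory curves with optional landmark rules."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        ax.plot(curve.time_grid, curve.level_grid, label=str(label))
    for name, level in (landmarks or {}).items():
        ax.axhline(level, color="grey", lw=0.8, ls=":")
        ax.annotate(name, (0.2, level), fontsize=8, va="bottom")
    ax.set_xlabel("time from anchor (years)")
    ax.set_ylabel("SUVR")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
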