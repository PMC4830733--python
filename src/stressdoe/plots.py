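"""Optional matplotlib renderings: Pareto chart and surface-slice curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["pareto_chart", "surface_plot"]


def pareto_chart(rows, path=None, ax=None):
    """Bar chart of normalized squares per ranked effect."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    labels = [r.effect_label for r in rows]
    values = [r.normalized_square for r in rows]
    ax.bar(range(len(rows)), values, color="steelblue")
    ax.set_xticks(range(len(rows)), labels, rotation=45, ha="right")
    ax.set_ylabel("normalized square (% of $\\Sigma E^2$)")
    ax.set_xlabel("effect (ranked)")
    ax.figure.tight_layout()
    if path is not None:
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax


def surface_plot(sl, path=None, ax=None):
    """Solved-factor curves vs the grid factor, one line per target."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = np.asarray(sl.grid_levels)
    for j, t in enumerate(sl.targets):
        ax.plot(x, sl.solutions[:, j], marker="o", label=f"{t:g}%")
    ax.axhspan(-1, 1, color="0.9", zorder=0)
    ax.set_xlabel(sl.grid_factor or "fixed slice")
    ax.set_ylabel(f"solved {sl.solve_factor} (coded)")
    ax.legend(title="target degradation")
    ax.figure.tight_layout()
    if path is not None:
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
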