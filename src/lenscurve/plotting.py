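"""Plots for accommodation-response results (matplotlib)."""

from __future__ import annotations

import numpy as np

SECTOR_COLORS = {"horizontal": "tab:green", "vertical": "tab:blue"}


def plot_relative_series(results, groups=None, ax=None):
    """Relative eccentricity vs accommodative demand, one panel per group.

    Green = horizontal meridian, blue = vertical; values below the dashed
    1.0 line mean a steeper anterior surface than at baseline.
    """
    import matplotlib.pyplot as plt

    resp = results.group_response()
    if groups is None:
        groups = [g for g in ("TG", "G1", "G2", "G3", "G4", "G5")
                  if g in set(resp["group"])]
    if ax is None:
        fig, axes = plt.subplots(
            1, len(groups), figsize=(3.2 * len(groups), 3.2), sharey=True
        )
        axes = np.atleast_1d(axes)
    else:
        axes = np.atleast_1d(ax)
        fig = axes[0].figure
    for a, g in zip(axes, groups):
        sub = resp[resp["group"] == g]
        for sector, color in SECTOR_COLORS.items():
            ss = sub[sub["sector"] == sector].sort_values("demand")
            a.plot(ss["demand"], ss["value"], "o-", color=color, label=sector)
        a.axhline(1.0, ls="--", c="gray", lw=0.8)
        a.set_title(g)
        a.set_xlabel("demand (D)")
    axes[0].set_ylabel("relative eccentricity")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def plot_conic_fit(fit_results, ax=None):
    """Capsule points and the fitted conic curve (elliptical fits)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = fit_results.model.points
    ax.plot(pts[:, 0], pts[:, 1], "ko", label="landmarks")
    if fit_results.conic_class in ("ellipse", "circle"):
        can = fit_results.canonical
        t = np.linspace(0, 2 * np.pi, 400)
        c, s = np.cos(can.orientation), np.sin(can.orientation)
        x = can.center[0] + can.semi_major * np.cos(t) * c - can.semi_minor * np.sin(t) * s
        y = can.center[1] + can.semi_major * np.cos(t) * s + can.semi_minor * np.sin(t) * c
        ax.plot(x, y, "r-", lw=0.8, label=f"fit (e={fit_results.shape.e:.3f})")
    ax.set_aspect("equal")
    ax.legend(frameon=False, fontsize=8)
    return ax.figure
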