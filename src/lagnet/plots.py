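"""Simple figures: degree log-log distributions and overlap curves."""

from __future__ import annotations

import numpy as np

from .comparison import EdgeOccurrence
from .netstats import DegreeHistogram, fit_power_law


def plot_degree_distribution(hist: DegreeHistogram, ax=None, label: str = ""):
    """Scatter the total-degree histogram on log-log axes with its LS fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = sorted((d, c) for d, c in hist.total.items() if d >= 1 and c >= 1)
    x = np.array([d for d, _ in pts], dtype=float)
    y = np.array([c for _, c in pts], dtype=float)
    ax.loglog(x, y, "o", label=label or "degree counts")
    try:
        fit = fit_power_law(hist)
    except Exception:
        fit = None
    if fit is not None:
        xs = np.linspace(x.min(), x.max(), 50)
        ax.loglog(
            xs,
            10**fit.intercept * xs**fit.slope,
            "-",
            label=f"slope {fit.slope:.2f}, R² {fit.r_squared:.3f}",
        )
    ax.set_xlabel("degree")
    ax.set_ylabel("number of genes")
    ax.legend()
    return ax


def plot_overlap_curve(occ: EdgeOccurrence, ax=None):
    """Edges shared by at least m networks, as a function of m."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ms = sorted(occ.at_least_m)
    ax.plot(ms, [occ.at_least_m[m] for m in ms], "o-")
    ax.set_xlabel("number of networks m")
    ax.set_ylabel("edges present in ≥ m networks")
    return ax
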