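"""Plot helpers for MR results (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_instruments", "plot_piecewise_curve", "plot_cluster_assignments"]


def _axes(ax):
    if ax is None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_instruments(instruments, results=None, ax=None):
    """Scatter of per-SNP outcome vs exposure effects with fitted slopes."""
    ax = _axes(ax)
    bx, sx, by, sy = instruments.arrays()
    ax.errorbar(bx, by, xerr=sx, yerr=sy, fmt="o", ms=3, alpha=0.6, lw=0.5)
    if results is not None:
        xs = np.linspace(0, bx.max() * 1.05, 50)
        for name, res in results.results.items():
            icpt = res.intercept or 0.0
            ax.plot(xs, icpt + res.beta * xs, label=name)
        ax.legend(frameon=False)
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    return ax


def plot_piecewise_curve(curve, ax=None):
    """Cumulative piecewise-linear log-OR curve with pointwise 95% bands."""
    ax = _axes(ax)
    ax.plot(curve.x_knots, curve.y_knots, "-o", ms=3)
    lo = curve.y_knots - 1.96 * curve.y_se
    hi = curve.y_knots + 1.96 * curve.y_se
    ax.fill_between(curve.x_knots, lo, hi, alpha=0.2)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("exposure")
    ax.set_ylabel("log OR vs reference")
    return ax


def plot_cluster_assignments(results, ax=None):
    """Per-SNP estimates coloured by mixture-cluster assignment."""
    ax = _axes(ax)
    df = results.assignments
    for cluster, sub in df.groupby("cluster"):
        ax.errorbar(range(len(sub)), sub["theta"], yerr=1.96 * sub["se"],
                    fmt="o", ms=3, label=cluster, alpha=0.7, lw=0.5)
    for mu in results.means:
        ax.axhline(mu, ls="--", lw=0.5, color="k")
    ax.set_ylabel("per-SNP causal estimate")
    ax.legend(frameon=False)
    return ax
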