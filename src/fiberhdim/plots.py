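"""Figure output: phasor plots and lambda-tau maps (PNG/SVG)."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .contrast import LambdaTauMap, PhasorSet

__all__ = ["save_phasor_plot", "save_lambda_tau_plot"]


def save_phasor_plot(phasors: PhasorSet, path, labels=None) -> Path:
    """Scatter the (g, s) points on the universal semicircle."""
    fig, ax = plt.subplots(figsize=(5, 4))
    arc = np.linspace(0, np.pi, 200)
    ax.plot(0.5 + 0.5 * np.cos(arc), 0.5 * np.sin(arc), "k-", lw=0.8,
            label="universal semicircle")
    ax.scatter(phasors.g, phasors.s, c=labels, cmap="coolwarm", s=25,
               edgecolors="k", linewidths=0.3)
    ax.set_xlabel("g")
    ax.set_ylabel("s")
    ax.set_xlim(0, 1.05)
    ax.set_ylim(0, 0.65)
    ax.set_aspect("equal")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def save_lambda_tau_plot(lt: LambdaTauMap, path) -> Path:
    """Lambda-tau map: 2-D histogram with the per-cell scatter overlaid."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.pcolormesh(lt.x_edges, lt.y_edges, lt.hist.T, cmap="viridis")
    if len(lt.scatter):
        x, y = lt.scatter.iloc[:, 0], lt.scatter.iloc[:, 1]
        ax.plot(x, y, "w.", ms=4, alpha=0.8)
    ax.set_xlabel(lt.scatter.columns[0] if len(lt.scatter.columns) else "peak")
    ax.set_ylabel(lt.scatter.columns[1] if len(lt.scatter.columns) > 1 else "lifetime (ns)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
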