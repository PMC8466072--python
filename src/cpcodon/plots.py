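"""Basic diagnostic scatter plots (ENC-plot, PR2-plot, neutrality plot)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .mutation_selection import EncPlotPoint, NeutralityFit, Pr2Point
from .usage_indices import expected_enc


def plot_enc(points: Sequence[EncPlotPoint], path: str | Path) -> None:
    """ENC against GC3s with the mutation-only expected curve."""
    fig, ax = plt.subplots(figsize=(5, 4))
    s = np.linspace(0.01, 0.99, 200)
    ax.plot(s, [expected_enc(v) for v in s], "k-", lw=1, label="expected")
    ax.scatter([p.gc3s for p in points], [p.enc for p in points], s=12, alpha=0.7)
    ax.set_xlabel("GC3s")
    ax.set_ylabel("ENC")
    ax.set_xlim(0, 1)
    ax.set_ylim(15, 65)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pr2(points: Sequence[Pr2Point], path: str | Path) -> None:
    """A3/(A3+T3) against G3/(G3+C3) with center lines at 0.5."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter([p.gc_bias for p in points], [p.at_bias for p in points], s=12, alpha=0.7)
    ax.axhline(0.5, color="k", lw=0.8)
    ax.axvline(0.5, color="k", lw=0.8)
    ax.set_xlabel("G3 / (G3 + C3)")
    ax.set_ylabel("A3 / (A3 + T3)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_neutrality(fit: NeutralityFit, path: str | Path) -> None:
    """GC12 against GC3 with the fitted regression line."""
    fig, ax = plt.subplots(figsize=(5, 4))
    x = np.asarray(fit.gc3_per_gene)
    y = np.asarray(fit.gc12_per_gene)
    ax.scatter(x, y, s=12, alpha=0.7)
    if not np.isnan(fit.slope):
        xs = np.linspace(np.nanmin(x), np.nanmax(x), 2)
        ax.plot(
            xs,
            fit.slope * xs + fit.intercept,
            "r-",
            lw=1,
            label=f"slope={fit.slope:.3f}, r={fit.pearson_r:.3f}",
        )
        ax.legend(frameon=False)
    ax.set_xlabel("GC3")
    ax.set_ylabel("GC12")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
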