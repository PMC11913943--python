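"""Figure helpers: intensity bar charts and the QADI graph."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .intensity import CategoryIntensity, IntervalIntensity

__all__ = ["interval_intensity_bars", "category_intensity_bars", "qadi_plot"]


def interval_intensity_bars(ii: IntervalIntensity, path: str | Path) -> Path:
    """Annual change intensity per interval with the uniform line U."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar([str(x) for x in ii.s_t.index], ii.s_t.to_numpy(), color="#777777")
    ax.axhline(ii.u, color="crimson", linestyle="--", label=f"uniform U = {ii.u:.2f} %/yr")
    ax.set_ylabel("annual change intensity (%/yr)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def category_intensity_bars(
    reports: Sequence[CategoryIntensity], labels: Sequence[str], path: str | Path
) -> Path:
    """Per-interval gain/loss intensity per category, losses drawn leftward."""
    fig, axes = plt.subplots(1, len(reports), figsize=(4 * len(reports), 3.5), sharey=True)
    if len(reports) == 1:
        axes = [axes]
    for ax, ci, label in zip(axes, reports, labels):
        names = list(ci.gain_intensity.index)
        y = range(len(names))
        ax.barh(y, ci.gain_intensity.to_numpy(), color="#2a7f3f", label="gain")
        ax.barh(y, -ci.loss_intensity.to_numpy(), color="#a0522d", label="loss")
        ax.axvline(ci.u, color="crimson", linestyle="--")
        ax.axvline(-ci.u, color="crimson", linestyle="--")
        ax.set_yticks(list(y), names)
        ax.set_title(label)
        ax.set_xlabel("intensity (%/yr)")
    axes[0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def qadi_plot(q: float, a: float, path: str | Path) -> Path:
    """QADI graph: quantity disagreement on x, allocation on y, dot at (Q, A)."""
    fig, ax = plt.subplots(figsize=(4, 4))
    lim = max(0.2, 1.2 * max(q, a))
    ax.plot([0, lim], [lim, 0], linestyle=":", color="grey")
    ax.plot([q], [a], "ko", markersize=8)
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("quantity disagreement Q")
    ax.set_ylabel("allocation disagreement A")
    ax.set_title(f"QADI = {(q ** 2 + a ** 2) ** 0.5:.3f}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
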