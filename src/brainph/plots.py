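"""Barcode and persistence-diagram figures.

One panel per homological dimension; essential classes are drawn as arrows
truncated at the maximum filtration threshold.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # file output only; no display needed
import matplotlib.pyplot as plt  # noqa: E402

from .persist import PersistenceDiagram

__all__ = ["plot_barcode", "plot_persistence_diagram"]


def plot_barcode(diag: PersistenceDiagram, path: str | Path,
                 dims: tuple[int, ...] | None = None) -> Path:
    """Horizontal bars, one per interval, grouped by dimension."""
    dims = dims if dims is not None else tuple(range(diag.max_dimension + 1))
    fig, axes = plt.subplots(len(dims), 1, figsize=(7, 2 + 1.2 * len(dims)),
                             sharex=True, squeeze=False)
    from matplotlib.collections import LineCollection
    for ax, dim in zip(axes[:, 0], dims):
        bars = sorted(diag.in_dimension(dim), key=lambda iv: (iv.birth, iv.death))
        segments, colors = [], []
        for row, iv in enumerate(bars):
            death = diag.eps_max if iv.essential else iv.death
            segments.append([(iv.birth, row), (death, row)])
            colors.append("tab:red" if iv.essential else "tab:blue")
        ax.add_collection(LineCollection(segments, colors=colors, lw=2))
        ax.set_ylabel(f"Dim{dim}")
        ax.set_ylim(-1, max(len(bars), 1))
    axes[-1, 0].set_xlabel("filtration threshold")
    axes[-1, 0].set_xlim(0, diag.eps_max * 1.02)
    fig.suptitle("Persistence barcode")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_persistence_diagram(diag: PersistenceDiagram, path: str | Path,
                             dims: tuple[int, ...] | None = None) -> Path:
    """Birth/death scatter with the diagonal; points far off-diagonal persist."""
    dims = dims if dims is not None else tuple(range(diag.max_dimension + 1))
    fig, ax = plt.subplots(figsize=(5, 5))
    markers = ["o", "s", "^", "D"]
    for k, dim in enumerate(dims):
        pts = diag.in_dimension(dim)
        births = [iv.birth for iv in pts]
        deaths = [diag.eps_max if iv.essential else iv.death for iv in pts]
        ax.scatter(births, deaths, marker=markers[k % len(markers)],
                   label=f"Dim{dim}", alpha=0.7)
    lim = diag.eps_max * 1.02
    ax.plot([0, lim], [0, lim], color="grey", lw=0.8)
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("birth")
    ax.set_ylabel("death")
    ax.set_title("Persistence diagram")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
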