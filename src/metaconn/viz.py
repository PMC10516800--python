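"""Figures: Fisher-z heatmaps with significance dots, and network graphs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # file output only
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .metrics import layout as kk_layout
from .registry import ROIRegistry

__all__ = ["heatmap", "graph_figure"]

_STRUCT_COLORS = {"CP": "tab:red", "SNr": "tab:blue", "GPe": "tab:green",
                  "MOTOR": "black", "PFC": "gold", "TH": "lightgray"}


def _structure_boundaries(registry: ROIRegistry) -> list[int]:
    bounds, prev = [], None
    for i, roi in enumerate(registry):
        if roi.structure != prev:
            bounds.append(i)
            prev = roi.structure
    return bounds


def heatmap(matrix: np.ndarray, registry: ROIRegistry, path: str | Path,
            significant: np.ndarray | None = None, title: str = "",
            vlim: float | None = None) -> None:
    """Symmetric ROI x ROI heatmap (e.g. Fisher-z or Z-difference matrix).

    ``significant`` marks reliable entries with white dots.  Structure blocks
    are outlined on both axes.
    """
    fig, ax = plt.subplots(figsize=(8, 7))
    v = vlim or float(np.nanmax(np.abs(matrix[~np.eye(len(matrix), dtype=bool)])) or 1)
    im = ax.imshow(matrix, cmap="RdBu_r", vmin=-v, vmax=v, interpolation="nearest")
    if significant is not None:
        ii, jj = np.nonzero(np.triu(significant, k=1) | np.tril(significant, k=-1))
        ax.scatter(jj, ii, s=1.5, c="white", marker=".")
    bounds = _structure_boundaries(registry)
    for b in bounds[1:]:
        ax.axhline(b - 0.5, color="black", lw=0.6)
        ax.axvline(b - 0.5, color="black", lw=0.6)
    centers = bounds + [len(registry)]
    labels = [registry[i].structure for i in bounds]
    ticks = [(centers[k] + centers[k + 1]) / 2 for k in range(len(bounds))]
    ax.set_xticks(ticks, labels, rotation=90, fontsize=8)
    ax.set_yticks(ticks, labels, fontsize=8)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def graph_figure(graph: nx.Graph, registry: ROIRegistry, path: str | Path,
                 seed: int = 0, title: str = "") -> None:
    """Energised network figure: node colour = structure, size ~ degree,
    solid lines positive edges, dashed negative."""
    pos = kk_layout(graph, seed=seed)
    fig, ax = plt.subplots(figsize=(8, 8))
    degrees = dict(graph.degree())
    colors = [_STRUCT_COLORS.get(graph.nodes[n].get("structure", ""), "gray")
              for n in graph.nodes]
    sizes = [20 + 12 * degrees[n] for n in graph.nodes]
    for style, sign in (("solid", 1), ("dashed", -1)):
        es = [(u, v) for u, v, d in graph.edges(data=True) if d.get("sign", 1) == sign]
        nx.draw_networkx_edges(graph, pos, edgelist=es, style=style, alpha=0.35,
                               edge_color="red" if sign > 0 else "blue", ax=ax)
    nx.draw_networkx_nodes(graph, pos, node_color=colors, node_size=sizes,
                           edgecolors="black", linewidths=0.3, ax=ax)
    ax.set_title(title)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
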