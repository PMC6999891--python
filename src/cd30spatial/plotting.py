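"""Static plot helpers (optional outputs, PNG/SVG via matplotlib)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .diameters import CorrectedDistribution, DiameterHistogram
from .scoring import NetworkSpec, to_networkx


def plot_diameter_histogram(
    hist: DiameterHistogram | CorrectedDistribution, path: str | Path, title: str = ""
) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    centers = hist.centers
    width = float(hist.edges[1] - hist.edges[0])
    ax.bar(centers, hist.freqs, width=0.9 * width)
    ax.set_xlabel("maximal Feret diameter [μm]")
    ax.set_ylabel("relative fraction")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_network(network: NetworkSpec, path: str | Path) -> Path:
    g = to_networkx(network)
    pos = nx.circular_layout(g)
    fig, ax = plt.subplots(figsize=(5, 5))
    nx.draw_networkx_nodes(g, pos, node_color="lightgray", node_size=700, ax=ax)
    nx.draw_networkx_labels(g, pos, {i: f"PC{i}" for i in g.nodes}, ax=ax,
                            font_size=8)
    for u, v, d in g.edges(data=True):
        color = "green" if d["sign"] > 0 else "red"
        width = max(0.5, d["weight"] / 25.0)
        nx.draw_networkx_edges(
            g, pos, [(u, v)], edge_color=color, width=width, ax=ax,
            connectionstyle="arc3,rad=0.1",
        )
    ax.set_axis_off()
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
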