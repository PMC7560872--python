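"""Presentation-only plotting helpers (layout is never part of analysis)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from topostates.density import UNASSIGNED, StatePartition, VertexDensity
from topostates.dynamics import CorrelationSeries, smooth_correlation
from topostates.mapper import MapperGraph


def plot_mapper_graph(
    g: MapperGraph,
    path: str | Path,
    densities: dict[int, VertexDensity] | None = None,
    partition: StatePartition | None = None,
    seed: int = 0,
) -> None:
    """Force-directed rendering; vertex size encodes member count.

    Vertices are colored by state when a partition is given (gray for
    unassigned), else by density. Layout is seed-controlled and purely
    cosmetic.
    """
    pos = nx.spring_layout(g.graph, seed=seed)
    sizes = [30 + 20 * len(g.members(v)) for v in g.graph.nodes]
    if partition is not None:
        cmap = plt.get_cmap("tab10")
        colors = [
            "lightgray"
            if partition.state_of[v] == UNASSIGNED
            else cmap(partition.state_of[v] % 10)
            for v in g.graph.nodes
        ]
    elif densities is not None:
        vals = np.array([densities[v].density for v in g.graph.nodes])
        finite = vals[np.isfinite(vals)]
        top = finite.max() if finite.size else 1.0
        colors = plt.get_cmap("viridis")(np.clip(vals / top, 0, 1))
    else:
        colors = "steelblue"
    fig, ax = plt.subplots(figsize=(6, 6))
    nx.draw_networkx_edges(g.graph, pos, ax=ax, alpha=0.4)
    nx.draw_networkx_nodes(g.graph, pos, ax=ax, node_size=sizes, node_color=colors)
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_correlation(
    c: CorrelationSeries,
    path: str | Path,
    bandwidth: float | None = None,
) -> None:
    """Dots (raw f' pairs), line (smoothed mean), ribbon (SEM)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(c.raw[:, 0], c.raw[:, 1], ".", alpha=0.3, label="raw f'")
    line = (
        smooth_correlation(c, bandwidth)
        if bandwidth is not None and c.taus.size >= 2
        else c.means
    )
    ax.plot(c.taus, line, "-", color="firebrick", label="mean")
    sem = np.nan_to_num(c.sems, nan=0.0)
    ax.fill_between(c.taus, line - sem, line + sem, color="firebrick", alpha=0.2)
    ax.set_xlabel("lag tau")
    state = "unassigned" if c.state == UNASSIGNED else c.state
    ax.set_ylabel(f"corr_{state}(tau)")
    ax.set_ylim(-0.05, 1.05)
    ax.legend(frameon=False)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
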